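# treeloops

Exact counting of non-isomorphic trees with self-loops, and bounds on the
number of tree-like polymer topologies of a given cycle rank.

## The problem

A *loop tree* is a connected acyclic graph on `n` vertices in which each
vertex may carry any number of self-loops (no multi-edges).  Its cycle rank
equals its self-loop total `Δ`.  Such graphs matter in chemoinformatics:
collapsing all degree-1 and degree-2 vertices of a chemical graph yields a
*polymer topology* — a connected graph with every vertex of degree ≥ 3 —
and loop trees are precisely the tree-like such topologies once multi-edges
are excluded.  Knowing how many isomorphism classes exist at a given size
tells you the size of a search space before any generation is attempted.

`treeloops` counts these classes exactly, with arbitrary-precision
integers, without generating a single tree.

## The method

Rooted trees are counted by dynamic programming over two invariants of the
root's children: `Maxv`, the vertex count of the largest child subtree, and
`Maxs`, the largest loop count among child subtrees attaining `Maxv`.
Three count families are tabulated for every subinstance `(i, j)`:

    h(i, j, m≤, d≤)   Maxv ≤ m, Maxs ≤ d
    h(i, j, m=, d≤)   Maxv = m, Maxs ≤ d
    h(i, j, m=, d=)   Maxv = m, Maxs = d

The first two telescope over `m` and `d`; the exact-exact family satisfies
a product recurrence obtained by stripping the `q ≥ 1` maximal child
subtrees (members of the family `H(m, d, m−1≤, d≤)` of size `h`), which
contribute the combinations-with-repetition factor `C(h + q − 1, q)`, and
recursing on the residual tree left at the root.  The rooted total is
`h(n, Δ) = h(n, Δ, n−1≤, Δ≤)`.

Unrooted counting reduces to rooted counting through Jordan's centroid:
every tree has either a unique centroid vertex (components ≤ ⌊(n−1)/2⌋
after removal) or, for even `n`, a centroid edge splitting it into equal
halves.  So

    t(n, Δ) = h(n, Δ, ⌊(n−1)/2⌋≤, Δ≤)  +  [n even] · (pairs of half-trees),

where the bicentroid term sums `h(n/2, i, n/2−1≤, i≤) · h(n/2, Δ−i, …)`
over loop splits `i < Δ/2` and, for even `Δ`, adds the unordered-pair
count `C(h + 1, 2)` over the same half family.

From `t(n, Δ)` the package brackets `p(r)`, the number of tree-like
polymer topologies of cycle rank `r`:

    Σ_{nk = r} t(n, 0)   ≤   p(r)   ≤   Σ_{⌈n/2⌉+1 ≤ r} t(n, r).

A brute-force enumerator (`treeloops.oracle`) independently certifies all
of this on small instances by exhaustive generation and canonical-code
deduplication.

## Worked example

```python
>>> from treeloops import h_rooted, t_unrooted, polymer_bounds
>>> h_rooted(3, 1)        # rooted trees, 3 vertices, 1 self-loop
5
>>> t_unrooted(10, 5)     # unrooted trees, 10 vertices, 5 self-loops
91037
>>> t_unrooted(30, 10)    # exact, far beyond enumeration range
2547562522909694331
>>> b = polymer_bounds(4)
>>> (b.lower, b.upper)    # tree-like polymer topologies of rank 4
(4, 454)
```

The five rooted classes at `(3, 1)` are: the path rooted at an end with
the loop on any of its three vertices, and the star rooted at its center
with the loop on the center or on a leaf.  Exactly two of them survive as
unrooted classes (`t_unrooted(3, 1) == 2`): the loop sits either on the
center of the path or on an end.

Longer narrative scripts live in `examples/` — one per capability
(rooted counts, unrooted counts, polymer bounds, brute-force
cross-check).  The same functionality is exposed on the command line:

```sh
$ treeloops unrooted 10 0
106
$ treeloops bounds 2
rank 2: lower 2, upper 3, valid True
$ treeloops table            # the six reference instances
```

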