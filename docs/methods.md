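# Methods

## Model and scope

The objects counted are *loop trees*: connected acyclic graphs on `n ≥ 1`
vertices where each vertex carries `s(v) ≥ 0` self-loops and multi-edges
are excluded.  Isomorphism of rooted loop trees is a bijection that maps
root to root, preserves adjacency, and preserves every vertex's loop
count; unrooted isomorphism drops the root condition.  Counting — not
generation — is the deliverable: listing the classes is out of scope and
exists only inside the brute-force oracle, at toy sizes.

## The rooted dynamic program

For a rooted tree `H`, `Maxv(H)` is the largest vertex count among the
root's child subtrees (0 for a single vertex) and `Maxs(H)` the largest
loop total among child subtrees attaining `Maxv` (0 if none).  Three
families are tabulated: `h(n, Δ, m≤, d≤)`, `h(n, Δ, m=, d≤)` and
`h(n, Δ, m=, d=)`, connected by the telescoping identities

    h(n,Δ,m≤,d≤) = h(n,Δ,m−1≤,d≤) + h(n,Δ,m=,d≤)     (m ≥ 1)
    h(n,Δ,m=,d≤) = h(n,Δ,m=,d−1≤) + h(n,Δ,m=,d=)     (d ≥ 1)

and the boundary values: a size cap of 0 admits only the single loopless
profile (`h(1,Δ,0=,d=) = 1` iff `d = 0`, `h(1,Δ,0≤,d≤) = 1`, zero for
`n ≥ 2`), and for `m = 1` the child subtrees are singletons, giving
`h(2,Δ,1=,d=) = 1` and `h(n,Δ,1=,0=) = 1` (the star).

The exact-exact family recurses through the *residual tree*: in a tree
with `Maxv = m, Maxs = d`, some number `q ≥ 1` of child subtrees belong
to the maximal family `H(m, d, m−1≤, d≤)`; deleting them leaves a
residual tree on `n − qm` vertices whose own profile is strictly smaller.
The valid range is `1 ≤ q ≤ ⌊(n−1)/m⌋`, additionally `q ≤ ⌊Δ/d⌋` when
`d ≥ 1` (no division by zero is ever attempted for `d = 0`; an empty
range contributes 0).  Writing `h* = h(m, d, m−1≤, d≤)` and
`c(m,d;q) = C(h* + q − 1, q)` for the number of multisets of `q` subtrees
drawn from that family:

* `d = 0`:  `h(n,Δ,m=,0=) = Σ_q c(m,0;q) · h(n−qm, Δ, min(n−qm−1, m−1)≤, Δ≤)`
* `d ≥ 1`:  `h(n,Δ,m=,d=) = Σ_q c(m,d;q) · [ h(n−qm, Δ−dq, m=, min(Δ−dq, d−1)≤)
   + h(n−qm, Δ−dq, min(n−qm−1, m−1)≤, Δ−dq≤) ]`

The two residual terms are disjoint: either the residual still has a
size-`m` child subtree (necessarily with fewer than `d` loops), or all
its child subtrees are strictly smaller.  An exact-family lookup whose
size cap exceeds the residual's vertex budget names an empty family and
reads as 0.

The top-level answer is `h(n, Δ) = h(n, Δ, n−1≤, Δ≤)`; closed forms
`h(1, Δ) = 1` and `h(2, Δ) = Δ + 1` fall out of the boundaries.

### Table layout

`build_table(n, Δ)` fills all three families for `1 ≤ i ≤ n`,
`0 ≤ j ≤ Δ`, `0 ≤ k ≤ i − 1`, `0 ≤ p ≤ j`, in `i, j, k, p` loop order, so
every recurrence reads only finished cells.  The fourth index runs to the
full `j` rather than to any requested cap `d`: the residual recurrence
reads entries with loop caps up to the whole remaining budget (`Δ−dq`,
and `j` itself in the `d = 0` branch), so a table truncated at `p ≤ d`
would be missing cells its own recurrence needs.  Storing the full table
costs `O(n²·(Δ+1)²)` integers, which is a deliberate trade of space
accounting for unconditional correctness — and the top-level query has
`d = Δ` anyway.  Likewise the third index runs to `i − 1` for every
subinstance `i`, since sub-queries need size caps up to their own
`i − 1`.  Query helpers clamp caps (`m → min(m, i−1)`, `d → min(d, j)`),
which never changes a count; exact-family queries beyond range return 0.

### Arithmetic

All counts are Python `int`s — the reference instances already reach
2.5 × 10¹⁸ and growth is unbounded, so fixed-width arithmetic is excluded
by contract.  The multiset factor is maintained incrementally along the
`q`-loop as `c := c · (h* + q − 1) / q`; each step divides exactly
because `c` is a binomial coefficient throughout, and the division is
asserted exact (`divmod`), turning any future arithmetic regression into
a loud failure instead of a silently wrong count.  The closed form
`multiset_coefficient` (via `math.comb`) is the independent cross-check
in tests.

### Two engines

A second, top-down memoized evaluator (`treeloops.recursive`) implements
the same boundaries and recurrence as plain recursion with caching.  It
exists purely as a cross-check: the test suite compares the two engines
cell by cell, which catches loop-order and initialization bugs that a
single implementation would mask.  Production entry points use only the
bottom-up table.

## Unrooted counts

Jordan's centroid makes rooting canonical: removal of the unicentroid
leaves components of at most `⌊(n−1)/2⌋` vertices; even `n` may instead
have a bicentroid edge splitting the tree into halves of exactly `n/2`.
Self-loops never move the centroid (they do not change component vertex
counts), so

* odd `n`: `t(n, Δ) = h(n, Δ, ⌊(n−1)/2⌋≤, Δ≤)`;
* even `n`: add the bicentroid term
  `Σ_{i=0}^{⌊(Δ−1)/2⌋} h(n/2, i, n/2−1≤, i≤) · h(n/2, Δ−i, n/2−1≤, Δ−i≤)`
  plus, when `Δ` is even, the same-family unordered pairs
  `C(h(n/2, Δ/2, n/2−1≤, Δ/2≤) + 1, 2)`.

The same-family term is the multiset count of two halves drawn from one
family, `h(h+1)/2`; it was verified against brute force at `(2, even Δ)`
and `(4, 0)`.  The virtual root on the centroid edge is never
materialized — the unordered-pair formula already accounts for the swap
symmetry.  For `Δ = 0` the `i`-sum is empty and only the pair term
survives.  All half-size counts are read from the single `(n, Δ)` table,
which covers every subinstance; `t_unrooted` also accepts a prebuilt
table so callers can batch queries.

## Polymer bounds

With `p(r)` the number of tree-like polymer topologies (every vertex of
degree ≥ 3, self-loops allowed, no multi-edges) of cycle rank `r`, and a
self-loop counting two toward its vertex's degree:

* **Lower** — placing `k` loops on every vertex of any simple tree on `n`
  vertices yields a polymer of rank `nk`, distinct trees staying
  non-isomorphic: `Σ_{nk=r} t(n, 0) ≤ p(r)`, a sum over divisors of `r`.
* **Upper** — `⌈n/2⌉ + 1` loops are necessary and sufficient for a
  tree-like polymer on `n` vertices (a backbone path with pendant leaves
  and loops on the degree-deficient vertices witnesses sufficiency; the
  oracle's `polymer_witness` constructs it), so
  `p(r) ≤ Σ_{⌈n/2⌉+1 ≤ r} t(n, r)`, finite since `n ≤ 2(r−1)`.

**Rank-1 anomaly.**  The lower sum's `(n, k) = (1, 1)` term counts the
single vertex with one loop, which has degree 2 and is not a polymer, so
`lower(1) = 1 > upper(1) = 0`.  The formulas are computed exactly as
stated and the result carries a `valid` flag (with a logged warning)
rather than a silent correction.  Whether the upper sum should start at
`n = 2` is equally open; `n = 1` satisfies the condition for `r ≥ 2` and
is included as stated (it only loosens the upper bound).

## The brute-force oracle

`treeloops.oracle` is the independent ground truth: it exhausts parent
arrays (vertex `i` chooses its parent among `0..i−1` — every rooted tree
shape on `n` labeled vertices appears) crossed with all compositions of
`Δ` over the vertices, and deduplicates by canonical code
`code(v) = (loops(v), sorted child codes)`.  Code equality characterizes
rooted isomorphism; the child order (loop count first, then
lexicographic on code sequences) is one valid choice among many, frozen
for reproducibility.  Unrooted classes are keyed by the code at the
centroid, or by the sorted pair of half codes across the bicentroid
edge.  The design is deliberately naive — exhaustion plus deduplication
is auditable by inspection, which is the entire point of an oracle — and
guarded to desk scale (`n ≤ 8`, `Δ ≤ 5` by default, explicitly
overridable).  Within the guard the enumeration is exhaustive, so
agreement there certifies the DP's recurrences and boundaries; it says
nothing new about larger instances beyond what the recurrence's
correctness argument provides.

There is no synthetic-data realism question here: the objects are the
mathematical universe itself, enumerated completely at small size.

## Numerical and design choices

* No floating point and no randomness anywhere in the counting path;
  results are bit-for-bit reproducible across runs and platforms.
* Degenerate conventions: empty `q`-ranges contribute 0; out-of-range
  exact caps read as 0; cap clamping is idempotent and rejected for
  negative inputs with `ValueError`.
* Missing table cells raise `CorruptTableError` rather than defaulting,
  so a query against the wrong table cannot fabricate a count.
* Test problem sizes: engine-vs-engine agreement is checked on the full
  `(9, 4)` table and spot totals to `n = 10`; oracle equivalence on
  `n ≤ 7, Δ ≤ 4` (rooted and unrooted) and bucket-level on
  `n ≤ 6, Δ ≤ 3`; internal identities on the `(12, 6)` table.  These
  grids run the whole suite in well under a minute while covering every
  recurrence branch (both `d = 0`/`d ≥ 1` residual forms, star and path
  boundaries, odd/even centroid cases, even/odd loop splits).
* The CLI prints big counts as decimal strings in JSON output because
  common JSON consumers silently round integers above 2⁵³.

## Limitations

* Multi-edges are out of scope throughout; the polymer bounds therefore
  bracket only the tree-like, multi-edge-free topologies.
* `p(r)` itself is bounded, not computed; the gap between the bounds
  grows quickly with `r`.
* The oracle cannot independently certify instances beyond its guard;
  large-instance confidence rests on the recurrence argument plus the
  exact reproduction of the six published-scale reference counts.
* Complexity was not tuned to the tightest possible table footprint (see
  the fourth-index discussion above); instances far beyond the reference
  scale will pay memory proportional to the full table.
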