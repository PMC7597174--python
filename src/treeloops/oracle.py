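"""Brute-force enumerator of loop trees — independent ground truth.

The dynamic program never constructs a tree, so an enumeration-based
cross-check is the natural certificate on small instances.  This module
generates *all* rooted trees with ``n`` vertices and ``delta`` self-loops
by exhausting parent arrays (vertex ``i`` picks its parent among vertices
``0 .. i-1``) crossed with all compositions of ``delta`` over the ``n``
vertices, and collapses isomorphic duplicates through a canonical code.

The canonical code of a rooted tree is the nested sequence
``code(v) = (loops(v), sorted child codes)``; two rooted trees are
isomorphic — under the root-preserving, loop-preserving, adjacency-
preserving bijection — exactly when their root codes are equal.  Any
fixed total order on child codes works; Python's tuple ordering
(loop count first, then lexicographically on the child-code sequences)
is used and frozen for reproducibility.

Deliberately naive: auditability over speed.  Size guards keep instances
desk-scale; they can be lifted explicitly by the caller.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Set, TextIO, Tuple

__all__ = [
    "LoopTree",
    "canonical_code",
    "centroid",
    "classify_counts",
    "enumerate_rooted",
    "enumerate_rooted_trees",
    "enumerate_unrooted",
    "iter_loop_trees",
    "max_v_max_s",
    "polymer_witness",
    "write_trees",
]

# code(v) = (loop count, tuple of sorted child codes)
Code = Tuple[int, tuple]

DEFAULT_MAX_N = 8
DEFAULT_MAX_DELTA = 5


@dataclass
class LoopTree:
    """A concrete tree with per-vertex self-loop counts.

    Vertices are ``0 .. n-1``; ``parent`` maps every non-root vertex to
    its parent, implicitly rooting the tree (``root`` records the single
    vertex absent from ``parent``).  For unrooted questions the rooting is
    incidental — the centroid is recomputed as needed.
    """

    n: int
    parent: Dict[int, int]
    loops: Dict[int, int] = field(default_factory=dict)
    root: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("a tree needs at least one vertex")
        if len(self.parent) != self.n - 1:
            raise ValueError("parent map must cover exactly the non-root vertices")
        if self.root in self.parent:
            raise ValueError("root must not have a parent")
        for v, p in self.parent.items():
            if not (0 <= v < self.n and 0 <= p < self.n):
                raise ValueError(f"edge {v}-{p} leaves the vertex range")
        if any(s < 0 for s in self.loops.values()):
            raise ValueError("self-loop counts must be nonnegative")
        # n-1 parent edges on n vertices are acyclic iff every vertex
        # reaches the root, which walking parent chains verifies.
        for v in range(self.n):
            seen = set()
            while v != self.root:
                if v in seen:
                    raise ValueError("parent map contains a cycle")
                seen.add(v)
                v = self.parent[v]

    @property
    def delta(self) -> int:
        return sum(self.loops.values())

    def loop_count(self, v: int) -> int:
        return self.loops.get(v, 0)

    def children(self) -> Dict[int, List[int]]:
        ch: Dict[int, List[int]] = {v: [] for v in range(self.n)}
        for v, p in self.parent.items():
            ch[p].append(v)
        return ch

    def adjacency(self) -> Dict[int, List[int]]:
        adj: Dict[int, List[int]] = {v: [] for v in range(self.n)}
        for v, p in self.parent.items():
            adj[p].append(v)
            adj[v].append(p)
        return adj

    def degree(self, v: int) -> int:
        """Degree with each self-loop counting two (polymer convention)."""
        return len(self.adjacency()[v]) + 2 * self.loop_count(v)

    def relabel(self, perm: Dict[int, int]) -> "LoopTree":
        """Apply a vertex permutation; the result is isomorphic by construction."""
        return LoopTree(
            n=self.n,
            parent={perm[v]: perm[p] for v, p in self.parent.items()},
            loops={perm[v]: s for v, s in self.loops.items() if s},
            root=perm[self.root],
        )


def canonical_code(tree: LoopTree, root: Optional[int] = None) -> Code:
    """Canonical code of ``tree`` rooted at ``root`` (default: its own root).

    Equal codes characterize rooted isomorphism.  Computed iteratively
    (explicit stack) so deep paths cannot hit the recursion limit.
    """
    if root is None:
        root = tree.root
    if not 0 <= root < tree.n:
        raise ValueError(f"root {root} not a vertex")
    adj = tree.adjacency()
    codes: Dict[int, Code] = {}
    stack: List[Tuple[int, int, bool]] = [(root, -1, False)]
    while stack:
        v, par, expanded = stack.pop()
        if expanded:
            kids = sorted(codes[c] for c in adj[v] if c != par)
            codes[v] = (tree.loop_count(v), tuple(kids))
        else:
            stack.append((v, par, True))
            for c in adj[v]:
                if c != par:
                    stack.append((c, v, False))
    return codes[root]


def _compositions(total: int, parts: int) -> Iterator[Tuple[int, ...]]:
    """All tuples of ``parts`` nonnegative integers summing to ``total``."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def _check_guard(n: int, delta: int, max_n: int, max_delta: int) -> None:
    if n < 1 or delta < 0:
        raise ValueError(f"invalid instance (n={n}, delta={delta})")
    if n > max_n or delta > max_delta:
        raise ValueError(
            f"instance (n={n}, delta={delta}) exceeds the brute-force guard "
            f"(n <= {max_n}, delta <= {max_delta}); pass larger guards "
            "explicitly to override"
        )


def iter_loop_trees(
    n: int,
    delta: int,
    max_n: int = DEFAULT_MAX_N,
    max_delta: int = DEFAULT_MAX_DELTA,
) -> Iterator[LoopTree]:
    """Yield every labeled rooted loop tree on ``n`` vertices, ``delta`` loops.

    Trees repeat up to isomorphism; callers deduplicate by code.
    """
    _check_guard(n, delta, max_n, max_delta)
    parent_choices = [range(i) for i in range(1, n)]
    for parents in itertools.product(*parent_choices):
        parent = {v + 1: p for v, p in enumerate(parents)}
        for comp in _compositions(delta, n):
            loops = {v: s for v, s in enumerate(comp) if s}
            yield LoopTree(n=n, parent=parent, loops=loops, root=0)


def enumerate_rooted_trees(
    n: int,
    delta: int,
    max_n: int = DEFAULT_MAX_N,
    max_delta: int = DEFAULT_MAX_DELTA,
) -> Dict[Code, LoopTree]:
    """One representative tree per rooted isomorphism class, keyed by code."""
    reps: Dict[Code, LoopTree] = {}
    for tree in iter_loop_trees(n, delta, max_n, max_delta):
        code = canonical_code(tree)
        if code not in reps:
            reps[code] = tree
    return reps


def enumerate_rooted(
    n: int,
    delta: int,
    max_n: int = DEFAULT_MAX_N,
    max_delta: int = DEFAULT_MAX_DELTA,
) -> Set[Code]:
    """Canonical codes of all rooted classes; the set size is ground-truth
    for the rooted count ``h(n, delta)``."""
    return set(enumerate_rooted_trees(n, delta, max_n, max_delta))


def centroid(tree: LoopTree) -> Tuple[int, ...]:
    """Jordan centroid of the underlying simple tree.

    Returns one vertex (unicentroid) or two adjacent vertices
    (bicentroid, even ``n`` only).  Self-loops are ignored — they do not
    change component sizes.
    """
    n = tree.n
    if n == 1:
        return (0,)
    adj = tree.adjacency()
    size = [1] * n
    order: List[int] = []
    seen = [False] * n
    stack = [0]
    seen[0] = True
    par = [-1] * n
    while stack:
        v = stack.pop()
        order.append(v)
        for c in adj[v]:
            if not seen[c]:
                seen[c] = True
                par[c] = v
                stack.append(c)
    for v in reversed(order):
        if par[v] >= 0:
            size[par[v]] += size[v]
    best = [
        v
        for v in range(n)
        if max(
            [n - size[v]] + [size[c] for c in adj[v] if par[c] == v]
        )
        <= n // 2
    ]
    if len(best) == 1:
        return (best[0],)
    assert len(best) == 2 and n % 2 == 0
    return tuple(sorted(best))


def enumerate_unrooted(
    n: int,
    delta: int,
    max_n: int = DEFAULT_MAX_N,
    max_delta: int = DEFAULT_MAX_DELTA,
) -> Set[tuple]:
    """One canonical key per unrooted isomorphism class.

    A unicentroid class is keyed by its code rooted at the centroid; a
    bicentroid class by the sorted pair of half codes on either side of
    the centroid edge — equivalent to rooting at a virtual vertex placed
    on that edge, without materializing it.
    """
    _check_guard(n, delta, max_n, max_delta)
    keys: Set[tuple] = set()
    for tree in iter_loop_trees(n, delta, max_n, max_delta):
        ctr = centroid(tree)
        if len(ctr) == 1:
            keys.add(("uni", canonical_code(tree, root=ctr[0])))
        else:
            u, v = ctr
            halves = _split_codes(tree, u, v)
            keys.add(("bi", tuple(sorted(halves))))
    return keys


def _split_codes(tree: LoopTree, u: int, v: int) -> Tuple[Code, Code]:
    """Codes of the two halves obtained by deleting the edge ``u``–``v``."""
    adj = tree.adjacency()

    def side_code(root: int, banned: int) -> Code:
        codes: Dict[int, Code] = {}
        stack = [(root, banned, False)]
        while stack:
            w, par, expanded = stack.pop()
            if expanded:
                kids = sorted(codes[c] for c in adj[w] if c != par)
                codes[w] = (tree.loop_count(w), tuple(kids))
            else:
                stack.append((w, par, True))
                for c in adj[w]:
                    if c != par:
                        stack.append((c, w, False))
        return codes[root]

    return side_code(u, v), side_code(v, u)


def max_v_max_s(tree: LoopTree) -> Tuple[int, int]:
    """The pair ``(Maxv, Maxs)`` of a rooted tree.

    ``Maxv`` is the largest vertex count among child subtrees of the
    root, ``Maxs`` the largest loop total among child subtrees attaining
    ``Maxv``; both are 0 for a single vertex.
    """
    ch = tree.children()
    best: Tuple[int, int] = (0, 0)
    for c in ch[tree.root]:
        nv = 0
        ns = 0
        stack = [c]
        while stack:
            w = stack.pop()
            nv += 1
            ns += tree.loop_count(w)
            stack.extend(ch[w])
        if nv > best[0] or (nv == best[0] and ns > best[1]):
            best = (nv, ns)
    return best


def classify_counts(
    n: int,
    delta: int,
    max_n: int = DEFAULT_MAX_N,
    max_delta: int = DEFAULT_MAX_DELTA,
) -> Dict[Tuple[int, int], int]:
    """Count rooted classes bucketed by ``(Maxv, Maxs)``.

    Ground truth for the exact-exact table cells; the bucket sizes sum to
    the rooted class count.
    """
    buckets: Dict[Tuple[int, int], int] = {}
    for tree in enumerate_rooted_trees(n, delta, max_n, max_delta).values():
        key = max_v_max_s(tree)
        buckets[key] = buckets.get(key, 0) + 1
    return buckets


def polymer_witness(n: int) -> LoopTree:
    """A tree-like polymer witness: ``n`` vertices, ``n/2 + 1`` self-loops.

    For even ``n >= 4``, build a backbone path of ``n/2 + 1`` vertices,
    hang one leaf off each internal backbone vertex (making it degree 3),
    and place one self-loop on every remaining degree-deficient vertex —
    the two backbone ends and the leaves, ``n/2 + 1`` vertices in all.
    Counting a self-loop as degree two, every vertex then has degree at
    least three, certifying that ``n/2 + 1`` loops suffice for a
    tree-like polymer on ``n`` vertices.
    """
    if n < 4 or n % 2 != 0:
        raise ValueError("witness construction requires even n >= 4")
    backbone = n // 2 + 1
    parent = {v: v - 1 for v in range(1, backbone)}
    leaf = backbone
    for anchor in range(1, backbone - 1):
        parent[leaf] = anchor
        leaf += 1
    assert leaf == n
    loops = {0: 1, backbone - 1: 1}
    for v in range(backbone, n):
        loops[v] = 1
    return LoopTree(n=n, parent=parent, loops=loops, root=0)


def write_trees(trees: List[LoopTree], out: TextIO) -> None:
    """Write trees as plain-text blocks: ``n delta``, edge lines ``u v``,
    then ``v:loops`` lines for loop-carrying vertices; blocks separated by
    a blank line."""
    for tree in trees:
        out.write(f"{tree.n} {tree.delta}\n")
        for v in sorted(tree.parent):
            out.write(f"{tree.parent[v]} {v}\n")
        for v in sorted(tree.loops):
            if tree.loops[v]:
                out.write(f"{v}:{tree.loops[v]}\n")
        out.write("\n")
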