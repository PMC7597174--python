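"""Bottom-up dynamic program for counting rooted trees with self-loops.

For integers ``n >= 1`` and ``delta >= 0`` let ``H(n, delta)`` be a maximal
set of mutually non-isomorphic rooted trees with ``n`` vertices and
``delta`` self-loops (no multi-edges).  Rooted isomorphism maps root to
root, preserves adjacency and preserves each vertex's self-loop count.

The recursion classifies every rooted tree ``H`` by two invariants of the
root's child subtrees:

* ``Maxv(H)`` — the largest vertex count among child subtrees of the root
  (0 for a single vertex);
* ``Maxs(H)`` — the largest self-loop total among the child subtrees that
  attain ``Maxv(H)`` (0 if there are none).

Three count families are tabulated, all exact integers:

* ``h(n, delta, m<=, d<=)`` — classes with ``Maxv <= m`` and ``Maxs <= d``;
* ``h(n, delta, m=,  d<=)`` — ``Maxv == m`` and ``Maxs <= d``;
* ``h(n, delta, m=,  d=)``  — ``Maxv == m`` and ``Maxs == d``.

The ``m=``/``d=`` family satisfies a product recurrence: strip the ``q``
maximal child subtrees (those belonging to the family
``H(m, d, m-1<=, d<=)``); what remains at the root is a *residual tree*
with ``n - q*m`` vertices counted by strictly smaller table entries, while
the stripped subtrees contribute a combinations-with-repetition factor
``c(m, d; q) = C(h(m, d, m-1<=, d<=) + q - 1, q)``.

The total rooted count is ``h(n, delta) = h(n, delta, n-1<=, delta<=)``.

Everything here is deterministic and uses Python's arbitrary-precision
integers; printed counts already exceed 10^18 at (30, 10) and grow without
bound, so fixed-width arithmetic is ruled out by contract.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

__all__ = [
    "CorruptTableError",
    "CountTable",
    "DPKey",
    "build_table",
    "h_eq_eq",
    "h_eq_le",
    "h_le_le",
    "h_rooted",
    "multiset_coefficient",
    "normalize_key",
]

Index = Tuple[int, int, int, int]


class CorruptTableError(LookupError):
    """A table entry required by a query or recurrence is missing."""


@dataclass(frozen=True)
class DPKey:
    """A normalized query ``(n, delta, m_cap, d_cap)``.

    Capping ``m`` at ``n - 1`` and ``d`` at ``delta`` never changes the
    count: no child subtree can hold more than ``n - 1`` vertices and no
    subtree can carry more than ``delta`` loops.  After normalization
    ``0 <= m_cap <= n - 1`` and ``0 <= d_cap <= delta``.
    """

    n: int
    delta: int
    m_cap: int
    d_cap: int


def normalize_key(n: int, delta: int, m: int, d: int) -> DPKey:
    """Clamp a raw query to its canonical equivalent.

    Parameters
    ----------
    n : int
        Vertex count, ``n >= 1``.
    delta : int
        Self-loop count, ``delta >= 0``.
    m : int
        Requested cap on the largest child-subtree vertex count.
    d : int
        Requested cap on the self-loop count among largest child subtrees.

    Returns
    -------
    DPKey
        Key with ``m_cap = min(m, n - 1)`` and ``d_cap = min(d, delta)``.
        Normalization is idempotent.
    """
    if n < 1:
        raise ValueError(f"vertex count must be >= 1, got {n}")
    if delta < 0:
        raise ValueError(f"self-loop count must be >= 0, got {delta}")
    if m < 0 or d < 0:
        raise ValueError(f"caps must be nonnegative, got m={m}, d={d}")
    return DPKey(n, delta, min(m, n - 1), min(d, delta))


def multiset_coefficient(family_size: int, t: int) -> int:
    """Number of multisets of size ``t`` drawn from ``family_size`` items.

    This is the combinations-with-repetition count
    ``C(family_size + t - 1, t)``, the number of ways to attach ``t``
    unordered, repeatable child subtrees chosen from a family of
    ``family_size`` isomorphism classes.
    """
    if family_size < 0 or t < 0:
        raise ValueError("multiset_coefficient requires nonnegative arguments")
    if t == 0:
        return 1
    if family_size == 0:
        return 0
    return math.comb(family_size + t - 1, t)


@dataclass
class CountTable:
    """The four-index memo holding all three count families.

    Keys are ``(i, j, k, p)`` with ``1 <= i <= n_max``,
    ``0 <= j <= delta_max``, ``0 <= k <= i - 1`` and ``0 <= p <= j``.
    The fourth index deliberately runs all the way to ``j`` (not merely to
    a requested cap ``d``): the residual-tree recurrence reads entries with
    loop caps up to the full remaining loop budget, so the complete table
    is the correct — and for top-level queries the only needed — store.
    """

    n_max: int
    delta_max: int
    le_le: Dict[Index, int] = field(default_factory=dict, repr=False)
    eq_le: Dict[Index, int] = field(default_factory=dict, repr=False)
    eq_eq: Dict[Index, int] = field(default_factory=dict, repr=False)

    def _get(self, family: Dict[Index, int], idx: Index) -> int:
        try:
            return family[idx]
        except KeyError as exc:
            raise CorruptTableError(
                f"table built for (n={self.n_max}, delta={self.delta_max}) "
                f"has no entry at {idx}"
            ) from exc

    def le_le_at(self, i: int, j: int, k: int, p: int) -> int:
        """``h(i, j, k<=, p<=)`` with cap clamping; out-of-range caps clamp."""
        return self._get(self.le_le, (i, j, min(k, i - 1), min(p, j)))

    def eq_le_at(self, i: int, j: int, k: int, p: int) -> int:
        """``h(i, j, k=, p<=)``; a size cap ``k > i - 1`` names an empty family."""
        if k > i - 1:
            return 0
        return self._get(self.eq_le, (i, j, k, min(p, j)))

    def eq_eq_at(self, i: int, j: int, k: int, p: int) -> int:
        """``h(i, j, k=, p=)``; exact ``k`` or ``p`` beyond range is empty."""
        if k > i - 1 or p > j:
            return 0
        return self._get(self.eq_eq, (i, j, k, p))

    def to_json(self) -> str:
        """Serialize for debugging; values as decimal strings (lossless)."""
        def encode(family: Dict[Index, int]) -> Dict[str, str]:
            return {",".join(map(str, k)): str(v) for k, v in sorted(family.items())}

        return json.dumps(
            {
                "n_max": self.n_max,
                "delta_max": self.delta_max,
                "le_le": encode(self.le_le),
                "eq_le": encode(self.eq_le),
                "eq_eq": encode(self.eq_eq),
            }
        )


def build_table(
    n: int,
    delta: int,
    on_coefficient: Optional[Callable[[int, int, int, int], None]] = None,
) -> CountTable:
    """Fill the full count table for all subinstances of ``(n, delta)``.

    The iteration order is vertices ``i``, then loops ``j``, then the size
    cap ``k``, then the loop cap ``p``; every recurrence only reads cells
    with smaller ``i`` or, within a row, smaller ``k``/``p``.

    The multiset factor ``c(k, p; q)`` is maintained incrementally along
    the ``q``-loop as ``c := c * (h(k, p, k-1<=, p<=) + q - 1) / q``; each
    division is asserted exact (``c`` is a binomial coefficient at every
    step), so an inexact division signals an implementation bug rather
    than rounding.

    Parameters
    ----------
    n, delta : int
        Target instance, ``n >= 1`` and ``delta >= 0``.
    on_coefficient : callable, optional
        Hook called as ``on_coefficient(k, p, q, c)`` after each
        incremental update; used by tests to cross-check ``c`` against the
        closed-form multiset coefficient.

    Returns
    -------
    CountTable
        Table covering ``1 <= i <= n`` and ``0 <= j <= delta``.
    """
    if n < 1 or delta < 0:
        raise ValueError(f"invalid instance (n={n}, delta={delta})")

    le_le: Dict[Index, int] = {}
    eq_le: Dict[Index, int] = {}
    eq_eq: Dict[Index, int] = {}

    # Size cap 0: only the single vertex qualifies, and its Maxs is 0.
    for j in range(delta + 1):
        for p in range(j + 1):
            eq_eq[1, j, 0, p] = 1 if p == 0 else 0
            eq_le[1, j, 0, p] = 1
            le_le[1, j, 0, p] = 1
    for i in range(2, n + 1):
        for j in range(delta + 1):
            for p in range(j + 1):
                eq_eq[i, j, 0, p] = 0
                eq_le[i, j, 0, p] = 0
                le_le[i, j, 0, p] = 0
    # Two vertices: the child is a singleton carrying p loops for Maxs = p.
    if n >= 2:
        for j in range(delta + 1):
            for p in range(j + 1):
                eq_eq[2, j, 1, p] = 1
                eq_le[2, j, 1, p] = p + 1
                le_le[2, j, 1, p] = p + 1

    for i in range(3, n + 1):
        for j in range(delta + 1):
            for k in range(1, i):
                for p in range(j + 1):
                    if p == 0 and k == 1:
                        # All children are loopless singletons: the star.
                        eq_eq[i, j, 1, 0] = 1
                        eq_le[i, j, 1, 0] = 1
                        le_le[i, j, 1, 0] = le_le[i, j, 0, 0] + 1
                        continue
                    base = le_le[k, p, k - 1, p]
                    q_max = (i - 1) // k if p == 0 else min((i - 1) // k, j // p)
                    c = 1
                    total = 0
                    for q in range(1, q_max + 1):
                        c, rem = divmod(c * (base + q - 1), q)
                        if rem:
                            raise AssertionError(
                                "incremental multiset update not exactly "
                                f"divisible at (k={k}, p={p}, q={q})"
                            )
                        if on_coefficient is not None:
                            on_coefficient(k, p, q, c)
                        if p == 0:
                            i2 = i - q * k
                            total += c * le_le[i2, j, min(i2 - 1, k - 1), j]
                        else:
                            i2 = i - q * k
                            j2 = j - q * p
                            residual = le_le[i2, j2, min(i2 - 1, k - 1), j2]
                            if k <= i2 - 1:
                                residual += eq_le[i2, j2, k, min(j2, p - 1)]
                            total += c * residual
                    eq_eq[i, j, k, p] = total
                    eq_le[i, j, k, p] = (
                        total if p == 0 else eq_le[i, j, k, p - 1] + total
                    )
                    le_le[i, j, k, p] = le_le[i, j, k - 1, p] + eq_le[i, j, k, p]

    return CountTable(n_max=n, delta_max=delta, le_le=le_le, eq_le=eq_le, eq_eq=eq_eq)


def h_le_le(key: DPKey, table: CountTable) -> int:
    """``h(n, delta, m<=, d<=)`` for a normalized key, read from ``table``."""
    return table.le_le_at(key.n, key.delta, key.m_cap, key.d_cap)


def h_eq_le(key: DPKey, table: CountTable) -> int:
    """``h(n, delta, m=, d<=)`` for a normalized key, read from ``table``."""
    return table.eq_le_at(key.n, key.delta, key.m_cap, key.d_cap)


def h_eq_eq(key: DPKey, table: CountTable) -> int:
    """``h(n, delta, m=, d=)`` for a normalized key, read from ``table``."""
    return table.eq_eq_at(key.n, key.delta, key.m_cap, key.d_cap)


def h_rooted(n: int, delta: int) -> int:
    """Number of rooted isomorphism classes with ``n`` vertices, ``delta`` loops.

    Equals ``h(n, delta, n-1<=, delta<=)``: the caps are vacuous at the top
    level.  Closed forms: ``h(1, delta) = 1`` and ``h(2, delta) = delta + 1``.
    """
    table = build_table(n, delta)
    return h_le_le(normalize_key(n, delta, n - 1 if n > 1 else 0, delta), table)
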