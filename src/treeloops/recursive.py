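"""Top-down memoized evaluator of the count recurrences.

A second, independent route to the same three count families as
:func:`treeloops.rooted.build_table`: plain recursion with memoization,
written directly from the boundary cases and the residual-tree recurrence
rather than from the bottom-up loop nest.  The test suite cross-checks the
two engines cell by cell, which catches loop-order and initialization
mistakes that a single implementation would hide.

Not used by the production entry points; the bottom-up table is the
primary engine.
"""

from __future__ import annotations

from functools import lru_cache

from .rooted import multiset_coefficient

__all__ = ["h_le_rec", "h_eq_rec", "h_eq_eq_rec", "h_rooted_rec", "clear_caches"]


@lru_cache(maxsize=None)
def h_le_rec(n: int, delta: int, m: int, d: int) -> int:
    """``h(n, delta, m<=, d<=)`` by recursion on the size cap ``m``."""
    m = min(m, n - 1)
    d = min(d, delta)
    if n == 1:
        return 1
    if m <= 0:
        return 0
    return h_le_rec(n, delta, m - 1, d) + h_eq_rec(n, delta, m, d)


@lru_cache(maxsize=None)
def h_eq_rec(n: int, delta: int, m: int, d: int) -> int:
    """``h(n, delta, m=, d<=)`` by recursion on the loop cap ``d``."""
    d = min(d, delta)
    if m > n - 1:
        return 0
    if m == 0:
        return 1 if n == 1 else 0
    if d == 0:
        return h_eq_eq_rec(n, delta, m, 0)
    return h_eq_rec(n, delta, m, d - 1) + h_eq_eq_rec(n, delta, m, d)


@lru_cache(maxsize=None)
def h_eq_eq_rec(n: int, delta: int, m: int, d: int) -> int:
    """``h(n, delta, m=, d=)`` via the residual-tree decomposition.

    Strip the ``q >= 1`` maximal child subtrees (members of
    ``H(m, d, m-1<=, d<=)``); the residual tree either still has a
    size-``m`` child subtree with strictly fewer than ``d`` loops, or all
    its child subtrees are smaller than ``m``.
    """
    if d > delta or m > n - 1:
        return 0
    if m == 0:
        return 1 if (n == 1 and d == 0) else 0
    if n == 2:
        return 1
    if m == 1 and d == 0:
        return 1
    q_max = (n - 1) // m
    if d >= 1:
        q_max = min(q_max, delta // d)
    family = h_le_rec(m, d, m - 1, d)
    total = 0
    for q in range(1, q_max + 1):
        c = multiset_coefficient(family, q)
        n2 = n - q * m
        if d == 0:
            residual = h_le_rec(n2, delta, min(n2 - 1, m - 1), delta)
        else:
            d2 = delta - q * d
            residual = h_le_rec(n2, d2, min(n2 - 1, m - 1), d2)
            residual += h_eq_rec(n2, d2, m, min(d2, d - 1))
        total += c * residual
    return total


def h_rooted_rec(n: int, delta: int) -> int:
    """Rooted class count via the memoized recursion."""
    if n < 1 or delta < 0:
        raise ValueError(f"invalid instance (n={n}, delta={delta})")
    return h_le_rec(n, delta, n - 1, delta)


def clear_caches() -> None:
    """Drop all memo tables (keeps long test sessions memory-bounded)."""
    h_le_rec.cache_clear()
    h_eq_rec.cache_clear()
    h_eq_eq_rec.cache_clear()
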