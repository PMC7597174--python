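"""Bounds on the number of tree-like polymer topologies of a given cycle rank.

A *polymer topology* is a connected graph (self-loops and multi-edges
allowed) in which every vertex has degree at least three, a self-loop
contributing two to its vertex's degree.  Restricting to topologies with
self-loops but no multi-edges — exactly the loop trees this package
counts — let ``p(r)`` be the number of such topologies of cycle rank
``r``; for a loop tree the cycle rank equals the self-loop total.

Two sums of exact tree counts ``t(n, delta)`` bracket ``p(r)``:

* lower bound: a tree on ``n`` vertices with ``k`` self-loops placed on
  *every* vertex is a polymer of rank ``n * k``, and distinct underlying
  trees stay non-isomorphic, so ``sum over n*k = r of t(n, 0) <= p(r)``;
* upper bound: a tree-like polymer on ``n`` vertices needs at least
  ``ceil(n/2) + 1`` self-loops (and that many suffice), so
  ``p(r) <= sum over n with ceil(n/2) + 1 <= r of t(n, r)`` — a finite
  sum since the condition forces ``n <= 2 * (r - 1)``.

The bounds are computed exactly as stated.  At ``r = 1`` the lower bound's
premise fails — the single vertex with one loop has degree two, so it is
not a polymer, yet the ``(n, k) = (1, 1)`` term counts it — and the
printed formulas give ``lower = 1 > upper = 0``.  The result carries a
``valid`` flag instead of silently patching the formula.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .unrooted import t_unrooted

__all__ = ["PolymerBounds", "polymer_lower", "polymer_upper", "polymer_bounds"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PolymerBounds:
    """Exact integer bounds on ``p(rank)``; ``valid`` iff ``lower <= upper``."""

    rank: int
    lower: int
    upper: int
    valid: bool


def _check_rank(r: int) -> None:
    if r < 1:
        raise ValueError(f"cycle rank must be >= 1, got {r}")


def polymer_lower(r: int) -> int:
    """Lower bound: ``sum of t(n, 0)`` over factorizations ``n * k = r``.

    Each divisor ``n`` of ``r`` contributes the simple-tree count
    ``t(n, 0)`` (placing ``r / n`` loops on every vertex).
    """
    _check_rank(r)
    return sum(t_unrooted(n, 0) for n in range(1, r + 1) if r % n == 0)


def polymer_upper(r: int) -> int:
    """Upper bound: ``sum of t(n, r)`` over ``n`` with ``ceil(n/2) + 1 <= r``.

    Every tree-like polymer of rank ``r`` on ``n`` vertices is a loop tree
    with ``r`` loops, and ``n`` cannot exceed ``2 * (r - 1)``; the sum is
    empty (zero) for ``r = 1``.
    """
    _check_rank(r)
    return sum(
        t_unrooted(n, r) for n in range(1, 2 * (r - 1) + 1) if (n + 1) // 2 + 1 <= r
    )


def polymer_bounds(r: int) -> PolymerBounds:
    """Bundle both bounds for rank ``r``; warn when they cross (``r = 1``)."""
    _check_rank(r)
    lower = polymer_lower(r)
    upper = polymer_upper(r)
    valid = lower <= upper
    if not valid:
        logger.warning(
            "polymer bounds cross at rank %d (lower=%d > upper=%d): the "
            "lower bound's all-vertices-looped construction is not a "
            "polymer at rank 1",
            r,
            lower,
            upper,
        )
    return PolymerBounds(rank=r, lower=lower, upper=upper, valid=valid)
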