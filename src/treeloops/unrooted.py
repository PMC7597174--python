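"""Unrooted tree counts via the unicentroid/bicentroid decomposition.

Every simple tree on ``n`` vertices has a Jordan centroid: either a unique
vertex whose removal leaves components of at most ``floor((n-1)/2)``
vertices (the *unicentroid*), or — only when ``n`` is even — a unique edge
whose removal splits the tree into two halves of exactly ``n/2`` vertices
(the *bicentroid*).  Self-loops do not move the centroid, since they do
not change component vertex counts.

Rooting at the centroid makes unrooted counting a rooted problem:

* unicentroid classes = rooted classes whose child subtrees all have at
  most ``floor((n-1)/2)`` vertices, i.e. ``h(n, delta, floor((n-1)/2)<=,
  delta<=)``;
* bicentroid classes = unordered pairs of rooted half-trees on ``n/2``
  vertices splitting the loop budget, counted without ever materializing
  a virtual root on the centroid edge.
"""

from __future__ import annotations

from typing import Optional

from .rooted import CountTable, build_table

__all__ = ["unicentroid_count", "bicentroid_count", "t_unrooted"]


def unicentroid_count(n: int, delta: int, table: CountTable) -> int:
    """Trees with ``n`` vertices, ``delta`` loops and a unicentroid.

    Reads ``h(n, delta, floor((n-1)/2)<=, delta<=)`` from a table built
    for ``(n, delta)``.
    """
    return table.le_le_at(n, delta, (n - 1) // 2, delta)


def bicentroid_count(n: int, delta: int, half_tables: CountTable) -> int:
    """Trees with ``n`` vertices (``n`` even), ``delta`` loops, a bicentroid.

    Removing the bicentroid edge leaves two rooted halves of ``n/2``
    vertices carrying ``i`` and ``delta - i`` loops.  Halves with unequal
    loop counts pair freely; when ``delta`` is even the two halves may
    also come from the same family ``H(n/2, delta/2, n/2-1<=, delta/2<=)``
    of size ``h``, contributing the unordered-pair count
    ``C(h + 1, 2) = h * (h + 1) / 2``.

    The half counts ``h(n/2, i, n/2-1<=, i<=)`` are read from the table
    built for ``(n, delta)``, which already covers every subinstance.
    """
    if n % 2 != 0:
        raise ValueError(f"a bicentroid exists only for even n, got n={n}")

    def half(i: int) -> int:
        return half_tables.le_le_at(n // 2, i, n // 2 - 1, i)

    total = sum(half(i) * half(delta - i) for i in range((delta - 1) // 2 + 1))
    if delta % 2 == 0:
        h = half(delta // 2)
        total += h * (h + 1) // 2
    return total


def t_unrooted(n: int, delta: int, table: Optional[CountTable] = None) -> int:
    """Number of unrooted isomorphism classes with ``n`` vertices, ``delta`` loops.

    Odd ``n`` has only unicentroid classes; even ``n`` adds the bicentroid
    classes.  A prebuilt table for ``(n, delta)`` may be supplied to avoid
    rebuilding; otherwise one is built.

    Closed form for two vertices: ``t(2, delta) = floor(delta / 2) + 1``.
    """
    if n < 1 or delta < 0:
        raise ValueError(f"invalid instance (n={n}, delta={delta})")
    if table is None:
        table = build_table(n, delta)
    total = unicentroid_count(n, delta, table)
    if n % 2 == 0:
        total += bicentroid_count(n, delta, table)
    return total
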