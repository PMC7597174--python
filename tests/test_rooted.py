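"""Unit and property tests for the rooted-count dynamic program."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treeloops import (
    CorruptTableError,
    build_table,
    h_eq_eq,
    h_eq_le,
    h_le_le,
    h_rooted,
    multiset_coefficient,
    normalize_key,
)
from treeloops.recursive import h_eq_eq_rec, h_eq_rec, h_le_rec, h_rooted_rec


class TestNormalizeKey:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ((5, 2, 99, 99), (5, 2, 4, 2)),
            ((1, 0, 0, 0), (1, 0, 0, 0)),
            ((4, 3, 2, 7), (4, 3, 2, 3)),
        ],
    )
    def test_clamps_caps(self, raw, expected):
        key = normalize_key(*raw)
        assert (key.n, key.delta, key.m_cap, key.d_cap) == expected

    @pytest.mark.parametrize(
        "bad", [(0, 0, 0, 0), (-1, 0, 0, 0), (3, -1, 0, 0), (3, 0, -1, 0), (3, 0, 0, -1)]
    )
    def test_rejects_out_of_domain(self, bad):
        with pytest.raises(ValueError):
            normalize_key(*bad)

    @given(
        n=st.integers(1, 40),
        delta=st.integers(0, 40),
        m=st.integers(0, 80),
        d=st.integers(0, 80),
    )
    @settings(max_examples=200, derandomize=True)
    def test_idempotent(self, n, delta, m, d):
        key = normalize_key(n, delta, m, d)
        again = normalize_key(key.n, key.delta, key.m_cap, key.d_cap)
        assert again == key
        assert 0 <= key.m_cap <= n - 1 or n == 1
        assert 0 <= key.d_cap <= delta


class TestMultisetCoefficient:
    @pytest.mark.parametrize("q", [0, 1, 5, 17])
    def test_singleton_family(self, q):
        assert multiset_coefficient(1, q) == 1

    @pytest.mark.parametrize(
        "family, t, expected",
        [(3, 2, 6), (2, 3, 4), (0, 0, 1), (0, 4, 0), (5, 0, 1)],
    )
    def test_small_values(self, family, t, expected):
        assert multiset_coefficient(family, t) == expected

    @given(family=st.integers(0, 6), t=st.integers(0, 6))
    @settings(max_examples=60, derandomize=True)
    def test_matches_explicit_enumeration(self, family, t):
        from itertools import combinations_with_replacement

        explicit = sum(1 for _ in combinations_with_replacement(range(family), t))
        assert multiset_coefficient(family, t) == explicit

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            multiset_coefficient(-1, 2)


class TestCountFamilies:
    """Boundary and small hand-checkable values of the three families."""

    @pytest.mark.parametrize(
        "query, expected",
        [
            ((1, 0, 0, 0), 1),  # the lone vertex, no loops on a maximal subtree
            ((1, 2, 0, 1), 0),  # Maxs = d >= 1 impossible for a single vertex
            ((3, 0, 1, 0), 1),  # the star: all child subtrees are singletons
            ((3, 1, 1, 1), 1),  # star, the loop on one child
            ((3, 1, 2, 1), 2),  # end-rooted path, loop on a non-root vertex
        ],
    )
    def test_eq_eq_values(self, query, expected):
        n, delta, m, d = query
        table = build_table(n, delta)
        assert h_eq_eq(normalize_key(n, delta, m, d), table) == expected

    @pytest.mark.parametrize(
        "query, expected",
        [
            ((2, 5, 1, 3), 4),  # d + 1 placements of <=3 loops on the child
            ((1, 2, 0, 2), 1),
            ((3, 1, 2, 1), 3),  # loop anywhere on the end-rooted path
        ],
    )
    def test_eq_le_values(self, query, expected):
        n, delta, m, d = query
        table = build_table(n, delta)
        assert h_eq_le(normalize_key(n, delta, m, d), table) == expected

    @pytest.mark.parametrize(
        "query, expected",
        [
            ((1, 5, 0, 5), 1),
            ((3, 0, 0, 0), 0),  # n >= 2 with size cap 0 is empty
            ((2, 3, 1, 3), 4),
            ((10, 0, 9, 0), 719),  # rooted simple trees on 10 vertices
        ],
    )
    def test_le_le_values(self, query, expected):
        n, delta, m, d = query
        table = build_table(n, delta)
        assert h_le_le(normalize_key(n, delta, m, d), table) == expected

    def test_missing_entry_raises(self):
        table = build_table(3, 2)
        with pytest.raises(CorruptTableError):
            table.le_le_at(4, 0, 3, 0)


class TestBuildTable:
    def test_two_vertex_row(self):
        table = build_table(2, 3)
        assert table.eq_le_at(2, 3, 1, 3) == 4
        assert table.eq_eq_at(2, 3, 1, 2) == 1

    def test_single_vertex(self):
        table = build_table(1, 0)
        assert table.le_le_at(1, 0, 0, 0) == 1

    def test_rejects_bad_instance(self):
        with pytest.raises(ValueError):
            build_table(0, 0)
        with pytest.raises(ValueError):
            build_table(3, -1)

    def test_partition_identities(self):
        """le_le telescopes over the size cap, eq_le over the loop cap."""
        n, delta = 8, 4
        table = build_table(n, delta)
        for (i, j, k, p), value in table.eq_le.items():
            if k >= 1:
                diff = table.le_le[i, j, k, p] - table.le_le[i, j, k - 1, p]
                assert diff == value >= 0
            if p >= 1:
                diff = value - table.eq_le[i, j, k, p - 1]
                assert diff == table.eq_eq[i, j, k, p] >= 0

    def test_incremental_coefficient_matches_closed_form(self):
        """The running c in the q-loop is always a multiset coefficient."""
        records = []
        table = build_table(9, 4, on_coefficient=lambda k, p, q, c: records.append((k, p, q, c)))
        assert records, "instrumentation hook never fired"
        for k, p, q, c in records:
            family = table.le_le_at(k, p, k - 1, p)
            assert c == multiset_coefficient(family, q)

    def test_json_serialization_is_lossless(self):
        table = build_table(6, 2)
        data = json.loads(table.to_json())
        assert data["n_max"] == 6 and data["delta_max"] == 2
        key = "6,2,5,2"
        assert int(data["le_le"][key]) == table.le_le_at(6, 2, 5, 2)
        assert all(isinstance(v, str) for v in data["eq_eq"].values())


class TestHRooted:
    @pytest.mark.parametrize(
        "n, delta, expected",
        [(1, 7, 1), (2, 3, 4), (4, 0, 4), (3, 1, 5), (10, 0, 719)],
    )
    def test_known_values(self, n, delta, expected):
        assert h_rooted(n, delta) == expected

    def test_closed_forms(self):
        for delta in range(0, 31):
            assert h_rooted(1, delta) == 1
            assert h_rooted(2, delta) == delta + 1

    def test_monotone_in_both_arguments(self):
        grid = {(n, d): h_rooted(n, d) for n in range(1, 8) for d in range(0, 4)}
        for (n, d), value in grid.items():
            if (n, d + 1) in grid:
                assert grid[n, d + 1] >= value
            if (n + 1, d) in grid:
                assert grid[n + 1, d] >= value


class TestTwoEngines:
    """The bottom-up table and the top-down recursion must agree cell-wise."""

    def test_all_cells_agree(self):
        n, delta = 9, 4
        table = build_table(n, delta)
        for (i, j, k, p), value in table.le_le.items():
            assert h_le_rec(i, j, k, p) == value
            assert h_eq_rec(i, j, k, p) == table.eq_le[i, j, k, p]
            assert h_eq_eq_rec(i, j, k, p) == table.eq_eq[i, j, k, p]

    def test_top_level_counts_agree(self):
        for n in range(1, 11):
            for delta in (0, 1, 3):
                assert h_rooted(n, delta) == h_rooted_rec(n, delta)
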