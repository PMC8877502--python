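"""Compartment annotation, Venn decomposition, enrichment, overlap fractions."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ticquant import datasets
from ticquant.errors import ConfigError, ParameterError
from ticquant.io_formats import GeneSet
from ticquant.set_analysis import annotate_compartments, compare_overlap_fraction, enrich, venn


def gs(name, *ids):
    return GeneSet(name=name, ids=frozenset(ids))


class TestAnnotateCompartments:
    def test_simple_intersection(self):
        ann = annotate_compartments({"A", "B", "C"}, [gs("mito", "B", "C", "D")])
        assert ann.counts == {"mito": 2}
        assert ann.members["mito"] == frozenset({"B", "C"})
        assert ann.unassigned == frozenset({"A"})

    def test_multi_membership_counts_in_both(self):
        ann = annotate_compartments({"A", "B"}, [gs("mito", "A"), gs("er", "A", "B")])
        assert ann.counts == {"mito": 1, "er": 2}
        assert ann.multi_label == frozenset({"A"})

    def test_random_fixture_matches_brute_force(self):
        rng = np.random.default_rng(31)
        proteins = {f"P{i}" for i in rng.choice(100, 50, replace=False)}
        sets = [gs(f"c{j}", *(f"P{i}" for i in rng.choice(100, 30, replace=False))) for j in range(3)]
        ann = annotate_compartments(proteins, sets)
        for s in sets:
            assert ann.counts[s.name] == len(proteins & s.ids)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ConfigError):
            annotate_compartments({"A"}, [gs("x", "A"), gs("x", "B")])

    def test_empty_protein_list_rejected(self):
        with pytest.raises(ParameterError):
            annotate_compartments(set(), [gs("x", "A")])


class TestVenn:
    def test_stress_signature_decomposition(self):
        """The two shipped stress-shared lists (29 and 12 entries) intersect in 8."""
        upr = datasets.upr_er_shared()
        men = datasets.menadione_shared()
        assert len(upr) == 29
        assert len(men) == 12
        result = venn([upr, men])
        assert result.intersection_count(upr.name, men.name) == 8
        # the shipped triple-overlap list is exactly that intersection
        assert upr.ids & men.ids == datasets.triple_shared().ids

    def test_identical_sets_fill_the_centre(self):
        a, b = gs("a", "x", "y"), gs("b", "x", "y")
        result = venn([a, b])
        assert result.count("a", "b") == 2
        assert result.count("a") == result.count("b") == 0

    def test_disjoint_sets_empty_centre(self):
        result = venn([gs("a", "x"), gs("b", "y")])
        assert result.count("a", "b") == 0

    def test_more_than_three_sets_unsupported(self):
        with pytest.raises(ParameterError):
            venn([gs(str(i), "x") for i in range(4)])

    @given(
        st.lists(
            st.sets(st.integers(0, 30), min_size=1, max_size=20), min_size=3, max_size=3
        )
    )
    def test_regions_partition_the_union(self, raw_sets):
        sets = [gs(f"s{i}", *(str(x) for x in ids)) for i, ids in enumerate(raw_sets)]
        result = venn(sets)
        union = frozenset().union(*(s.ids for s in sets))
        members = list(result.region_members.values())
        assert sum(len(m) for m in members) == len(union)
        for a, b in combinations(members, 2):
            assert not (a & b)

    def test_region_counts_symmetric_under_set_order(self):
        sets = [gs("a", "1", "2", "3"), gs("b", "2", "3", "4"), gs("c", "3", "4", "5")]
        forward = venn(sets).region_counts
        backward = venn(sets[::-1]).region_counts
        assert forward == backward


def hypergeom_tail_by_enumeration(N, K, n, k):
    """P(X >= k) by exhaustive counting of all C(N, n) draws."""
    universe = range(N)
    category = set(range(K))
    hits = total = 0
    for draw in combinations(universe, n):
        total += 1
        if len(category & set(draw)) >= k:
            hits += 1
    return hits / total


class TestEnrich:
    def _frame(self, query, cats, universe):
        return enrich(query, cats, universe).set_index("category")

    def test_category_equal_to_query_is_minimal_p(self):
        universe = gs("u", *(f"P{i}" for i in range(12)))
        query = gs("q", "P0", "P1", "P2")
        exact = gs("exact", "P0", "P1", "P2")
        table = self._frame(query, [exact], universe)
        # the most extreme possible draw: p = 1 / C(12, 3)
        assert table.loc["exact", "p_value"] == pytest.approx(1 / math.comb(12, 3), rel=1e-9)

    def test_closed_form_matches_exhaustive_enumeration(self):
        universe = gs("u", *(f"P{i}" for i in range(20)))
        category = gs("cat", *(f"P{i}" for i in range(5)))  # K = 5
        query = gs("q", "P0", "P1", "P2", "P3", "P10")  # n = 5, k = 4
        table = self._frame(query, [category], universe)
        expected = hypergeom_tail_by_enumeration(N=20, K=5, n=5, k=4)
        assert table.loc["cat", "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_overlap_at_expectation_is_not_significant(self):
        # N=20, K=10, n=4 -> E[k] = 2; k = 2 sits mid-distribution
        universe = gs("u", *(f"P{i}" for i in range(20)))
        category = gs("cat", *(f"P{i}" for i in range(10)))
        query = gs("q", "P0", "P1", "P15", "P16")
        table = self._frame(query, [category], universe)
        assert table.loc["cat", "p_value"] > 0.3

    def test_query_outside_universe_lists_ids(self):
        universe = gs("u", "P0", "P1")
        with pytest.raises(ParameterError, match="P99"):
            enrich(gs("q", "P0", "P99"), [gs("c", "P0")], universe)

    def test_adjusted_values_monotone_in_raw_p(self):
        rng = np.random.default_rng(33)
        universe = gs("u", *(f"P{i}" for i in range(60)))
        query = gs("q", *(f"P{i}" for i in range(12)))
        cats = [
            gs(f"c{j}", *(f"P{i}" for i in rng.choice(60, rng.integers(5, 25), replace=False)))
            for j in range(8)
        ]
        table = enrich(query, cats, universe).sort_values("p_value")
        assert (table["q_value"].diff().dropna() >= -1e-12).all()
        assert (table["q_value"] >= table["p_value"] - 1e-12).all()


class TestOverlapFraction:
    def test_fraction_uses_diff_list_denominator(self):
        diff = gs("diff", *(f"P{i}" for i in range(97)))
        sig = gs("sig", *(f"P{i}" for i in range(29)))
        count, fraction = compare_overlap_fraction(diff, sig)
        assert count == 29
        assert fraction == pytest.approx(29 / 97)

    def test_disjoint_signature(self):
        count, fraction = compare_overlap_fraction(gs("d", "A"), gs("s", "B"))
        assert (count, fraction) == (0, 0.0)

    def test_signature_superset_gives_one(self):
        count, fraction = compare_overlap_fraction(gs("d", "A", "B"), gs("s", "A", "B", "C"))
        assert fraction == 1.0

    def test_empty_diff_list_rejected(self):
        with pytest.raises(ParameterError):
            compare_overlap_fraction(GeneSet(name="d", ids=frozenset()), gs("s", "A"))
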