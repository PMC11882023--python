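"""Geographic overlap, endemism, range breadth and species-concept contrasts."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hiddendiv._util import round_half_up
from hiddendiv.biogeo import (
    SpeciesRangeTable,
    classify_breadth,
    effort_correlation,
    endemism_summary,
    intercontinental_fraction,
    overlap_summary,
    sorensen,
    venn_counts,
)

from ._reference import reference_venn

TERRITORIES = ("bra", "gua", "mad", "may", "tai", "ncl")


_REGION = {"bra": "Neo", "gua": "Neo", "mad": "Afr", "may": "Afr", "tai": "East", "ncl": "East"}


@st.composite
def range_tables(draw, max_species: int = 8):
    """Random tables over the six-territory toy scheme, with morphospecies.

    Mirrors the structure of cryptic complexes: lineages sharing a
    morphospecies are each mono-regional (possibly on different
    continents), while genuinely multi-region species keep a name of
    their own — lumping look-alikes is what creates spurious
    intercontinental ranges in the first place.
    """
    n = draw(st.integers(1, max_species))
    ranges, morpho = {}, {}
    for i in range(n):
        terrs = draw(
            st.sets(st.sampled_from(TERRITORIES), min_size=1, max_size=4)
        )
        ranges[f"sp{i}"] = frozenset(terrs)
        if len({_REGION[t] for t in terrs}) >= 2:
            morpho[f"sp{i}"] = f"solo{i}"
        else:
            morpho[f"sp{i}"] = f"m{draw(st.integers(0, 3))}"
    return SpeciesRangeTable(ranges=ranges, morphospecies=morpho)


class TestSorensen:
    def test_identical_sets(self):
        assert sorensen({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert sorensen({"a"}, {"b"}) == 0.0

    def test_study_scale_territory_pair(self):
        # 31 shared species between territories holding 98 and 123 species
        a = {f"s{i}" for i in range(98)}
        b = {f"s{i}" for i in range(67, 67 + 123)}
        assert len(a & b) == 31
        assert sorensen(a, b) == pytest.approx(0.2805, abs=5e-5)

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            sorensen(set(), {"a"})

    @settings(max_examples=100)
    @given(
        a=st.sets(st.integers(0, 20), min_size=1),
        b=st.sets(st.integers(0, 20), min_size=1),
    )
    def test_bounds_and_symmetry(self, a, b):
        s = sorensen(a, b)
        assert 0.0 <= s <= 1.0
        assert s == sorensen(b, a)
        assert (s == 1.0) == (a == b)


class TestOverlapSummary:
    def test_single_species_single_territory(self, toy_scheme):
        table = SpeciesRangeTable(ranges={"sp1": frozenset({"bra"})})
        summary = overlap_summary(table, toy_scheme, "territory")
        assert summary.units == ("bra",)
        assert summary.sorensen.loc["bra", "bra"] == 1.0

    def test_fully_shared_pair(self, toy_scheme):
        table = SpeciesRangeTable(
            ranges={"sp1": frozenset({"bra", "gua"}), "sp2": frozenset({"bra", "gua"})}
        )
        summary = overlap_summary(table, toy_scheme, "territory")
        assert summary.sorensen.loc["bra", "gua"] == 1.0
        assert summary.shared.loc["bra", "gua"] == 2

    @settings(max_examples=100)
    @given(table=range_tables())
    def test_matrix_matches_brute_force(self, toy_scheme, table):
        summary = overlap_summary(table, toy_scheme, "territory")
        by_unit = {u: set() for u in summary.units}
        for sp, terrs in table.ranges.items():
            for t in terrs:
                by_unit[t].add(sp)
        for i in summary.units:
            for j in summary.units:
                assert summary.shared.loc[i, j] == len(by_unit[i] & by_unit[j])
                assert summary.sorensen.loc[i, j] == pytest.approx(
                    2 * len(by_unit[i] & by_unit[j]) / (len(by_unit[i]) + len(by_unit[j]))
                )

    def test_unknown_territory_is_an_error(self, toy_scheme):
        table = SpeciesRangeTable(ranges={"sp1": frozenset({"atlantis"})})
        with pytest.raises(KeyError):
            overlap_summary(table, toy_scheme, "territory")


class TestEndemism:
    def test_study_scale_percent(self):
        # 397 single-territory species out of 473 -> 84%
        assert round_half_up(100.0 * 397 / 473) == 84

    def test_everything_everywhere_zero_endemism(self, toy_scheme):
        table = SpeciesRangeTable(
            ranges={f"sp{i}": frozenset(TERRITORIES) for i in range(4)}
        )
        summary = endemism_summary(table, toy_scheme)
        assert summary["territory"]["percent"] == 0

    def test_single_territory_species_endemic_at_all_levels(self, toy_scheme):
        table = SpeciesRangeTable(ranges={"sp1": frozenset({"mad"})})
        summary = endemism_summary(table, toy_scheme)
        assert all(summary[level]["endemic"] == 1 for level in summary)

    @settings(max_examples=100)
    @given(table=range_tables())
    def test_aggregation_consistency(self, toy_scheme, table):
        # endemism can only grow (or stay) when units are merged upward
        summary = endemism_summary(table, toy_scheme)
        assert (
            summary["territory"]["endemic"]
            <= summary["realm"]["endemic"]
            <= summary["region"]["endemic"]
        )


class TestBreadthClassification:
    def test_all_three_tropical_regions_is_pantropical(self, toy_scheme):
        assert classify_breadth(frozenset({"bra", "mad", "tai"}), toy_scheme) == "pantropical"

    def test_single_territory_is_narrow(self, toy_scheme):
        assert classify_breadth(frozenset({"gua"}), toy_scheme) == "narrow"

    def test_two_territories_one_region_is_continental_wide(self, toy_scheme):
        assert classify_breadth(frozenset({"bra", "gua"}), toy_scheme) == "continental_wide"

    def test_two_regions_is_bicontinental(self, toy_scheme):
        assert classify_breadth(frozenset({"bra", "mad"}), toy_scheme) == "bicontinental"

    def test_empty_range_is_an_error(self, toy_scheme):
        with pytest.raises(ValueError):
            classify_breadth(frozenset(), toy_scheme)


class TestConceptComparison:
    def test_all_single_region_is_zero_under_both(self, toy_scheme):
        table = SpeciesRangeTable(
            ranges={"sp1": frozenset({"bra"}), "sp2": frozenset({"gua"})},
            morphospecies={"sp1": "m1", "sp2": "m1"},
        )
        for concept in ("integrative", "phenotype"):
            assert intercontinental_fraction(table, toy_scheme, concept) == 0.0

    def test_cryptic_pair_inflates_phenotype_estimate(self, toy_scheme):
        # two single-region species under one name, on different continents
        table = SpeciesRangeTable(
            ranges={"sp1": frozenset({"bra"}), "sp2": frozenset({"mad"})},
            morphospecies={"sp1": "m1", "sp2": "m1"},
        )
        assert intercontinental_fraction(table, toy_scheme, "integrative") == 0.0
        assert intercontinental_fraction(table, toy_scheme, "phenotype") == 100.0

    def test_missing_morphospecies_labels_is_an_error(self, toy_scheme):
        table = SpeciesRangeTable(ranges={"sp1": frozenset({"bra"})})
        with pytest.raises(ValueError):
            intercontinental_fraction(table, toy_scheme, "phenotype")

    @settings(max_examples=200)
    @given(table=range_tables())
    def test_phenotype_dominates_integrative(self, toy_scheme, table):
        phen = intercontinental_fraction(table, toy_scheme, "phenotype")
        integ = intercontinental_fraction(table, toy_scheme, "integrative")
        assert phen >= integ


class TestVenn:
    def test_disjoint_units(self, toy_scheme):
        table = SpeciesRangeTable(
            ranges={"sp1": frozenset({"bra"}), "sp2": frozenset({"tai"})}
        )
        cells = venn_counts(table, toy_scheme, "territory", ("bra", "tai"))
        assert cells == {frozenset({"bra"}): 1, frozenset({"tai"}): 1}

    def test_identical_units_only_intersection(self, toy_scheme):
        table = SpeciesRangeTable(
            ranges={"sp1": frozenset({"bra", "gua"}), "sp2": frozenset({"bra", "gua"})}
        )
        cells = venn_counts(table, toy_scheme, "territory", ("bra", "gua"))
        assert cells == {frozenset({"bra", "gua"}): 2}

    @settings(max_examples=200)
    @given(table=range_tables())
    def test_cells_partition_the_union(self, toy_scheme, table):
        units = ("Neo", "Afr", "East")
        cells = venn_counts(table, toy_scheme, "region", units)
        by_unit = {u: set() for u in units}
        for sp, terrs in table.ranges.items():
            for t in terrs:
                by_unit[toy_scheme.lift(t, "region")].add(sp)
        assert cells == reference_venn(by_unit, units)
        union = set().union(*by_unit.values())
        assert sum(cells.values()) == len(union)

    def test_too_many_units_is_an_error(self, toy_scheme):
        table = SpeciesRangeTable(ranges={"sp1": frozenset({"bra"})})
        with pytest.raises(ValueError):
            venn_counts(table, toy_scheme, "territory", ("bra", "gua", "mad", "may", "tai"))


class TestEffortCorrelation:
    def test_proportional_counts_give_unity(self):
        specs = {"a": 10, "b": 20, "c": 40}
        specie = {"a": 5, "b": 10, "c": 20}
        r, p = effort_correlation(specs, specie)
        assert r == pytest.approx(1.0)

    def test_anti_proportional_counts(self):
        r, _ = effort_correlation({"a": 1, "b": 2, "c": 3}, {"a": 30, "b": 20, "c": 10})
        assert r == pytest.approx(-1.0)

    def test_near_linear_with_small_noise(self):
        import numpy as np

        rng = np.random.default_rng(0)
        specs = {f"t{i}": 50 + 30 * i for i in range(12)}
        specie = {k: v / 2 + rng.normal(0, 1) for k, v in specs.items()}
        r, p = effort_correlation(specs, specie)
        assert r > 0.99 and p < 1e-6

    def test_degenerate_inputs_are_errors(self):
        with pytest.raises(ValueError):
            effort_correlation({"a": 1, "b": 2}, {"a": 1, "b": 2})
        with pytest.raises(ValueError):
            effort_correlation({"a": 1, "b": 1, "c": 1}, {"a": 1, "b": 2, "c": 3})
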