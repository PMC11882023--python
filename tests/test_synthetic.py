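"""Synthetic-study generator: determinism, degenerate cases, truth
consistency and fixture round-trips."""

import numpy as np
import pandas as pd
import pytest

import hiddendiv.io as hio
from hiddendiv.accounting import MorphospeciesComplex, compute_hidden_ratios
from hiddendiv.consensus import consensus, count_otus
from hiddendiv.synthetic import (
    ConfigurationError,
    MethodProfile,
    SimulationConfig,
    simulate_sampling,
    simulate_species_pool,
    simulate_study,
    write_fixtures,
)


def _perfect_methods(n=4):
    return tuple(
        MethodProfile(f"m{i}", split_rate=0.0, lump_rate=0.0, coverage=1.0,
                      is_tiebreaker=(i == n)) for i in range(1, n + 1)
    )


def _small_config(**kw):
    defaults = dict(
        n_true_species=30,
        method_profiles=_perfect_methods(),
        specimens_per_species=("poisson", {"mean": 2.0}),
        seed=11,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            _small_config(range_breadth_weights={
                "narrow": 0.5, "continental_wide": 0.2,
                "bicontinental": 0.2, "pantropical": 0.2,
            })

    def test_exactly_one_tiebreaker(self):
        methods = tuple(MethodProfile(f"m{i}", is_tiebreaker=True) for i in (1, 2))
        with pytest.raises(ConfigurationError):
            _small_config(method_profiles=methods)

    def test_zero_coverage_rejected(self):
        with pytest.raises(ConfigurationError):
            MethodProfile("m", coverage=0.0)

    def test_bad_distribution_names_field(self):
        with pytest.raises(ConfigurationError, match="complex_size_distribution"):
            _small_config(complex_size_distribution=("geometric", {"p": 0.0}))


class TestSpeciesPool:
    def test_degenerate_single_narrow_species(self):
        cfg = _small_config(
            n_true_species=1,
            complex_size_distribution=("fixed", {"value": 1}),
            range_breadth_weights={
                "narrow": 1.0, "continental_wide": 0.0,
                "bicontinental": 0.0, "pantropical": 0.0,
            },
            prop_unidentifiable=0.0,
        )
        truth = simulate_species_pool(cfg)
        assert len(truth) == 1
        assert ";" not in truth["territories"].iloc[0]

    def test_seeded_determinism(self):
        cfg = _small_config()
        pd.testing.assert_frame_equal(
            simulate_species_pool(cfg), simulate_species_pool(cfg)
        )

    def test_exact_species_count(self):
        truth = simulate_species_pool(_small_config(n_true_species=47))
        assert len(truth) == 47
        assert truth["species_id"].is_unique

    def test_fixed_complex_size_forces_hidden_ratio(self):
        cfg = _small_config(
            n_true_species=28 * 4,
            complex_size_distribution=("fixed", {"value": 28}),
            prop_described=1.0,
            prop_unidentifiable=0.0,
        )
        truth = simulate_species_pool(cfg)
        complexes = []
        for morpho, grp in truth.groupby("morphospecies"):
            complexes.append(MorphospeciesComplex(
                morphospecies=str(morpho),
                n_described_in_dataset=int((grp["category"] == "known").sum()),
                n_hidden=int((grp["category"] == "hidden").sum()),
                breadth_class="pantropical",
            ))
        assert all(cx.hidden_ratio == 28 for cx in complexes)
        assert compute_hidden_ratios(complexes)["R_pantropical"] == 28

    def test_narrow_species_occupy_one_territory(self):
        truth = simulate_species_pool(_small_config(n_true_species=100))
        narrow = truth[truth["breadth_class"] == "narrow"]
        assert (narrow["territories"].str.count(";") == 0).all()


class TestSampling:
    def test_zero_specimens_everywhere(self):
        cfg = _small_config(specimens_per_species=("fixed", {"value": 0}))
        truth = simulate_species_pool(cfg)
        specimens, truth, by_level, _ = simulate_sampling(truth, cfg)
        assert specimens.empty
        assert (truth["n_specimens"] == 0).all()
        assert by_level == {}

    def test_one_specimen_per_species(self):
        cfg = _small_config(specimens_per_species=("fixed", {"value": 1}))
        truth = simulate_species_pool(cfg)
        specimens, truth, _, _ = simulate_sampling(truth, cfg)
        assert len(specimens) == len(truth)

    def test_poisson_total_concentrates(self):
        cfg = SimulationConfig(
            n_true_species=473,
            specimens_per_species=("poisson", {"mean": 2.7}),
            seed=5,
        )
        truth = simulate_species_pool(cfg)
        specimens, _, _, _ = simulate_sampling(truth, cfg)
        mean, sd = 473 * 2.7, np.sqrt(473 * 2.7)
        assert abs(len(specimens) - mean) < 3 * sd

    def test_specimens_stay_in_true_ranges(self):
        cfg = _small_config(n_true_species=60)
        truth = simulate_species_pool(cfg)
        specimens, truth, _, _ = simulate_sampling(truth, cfg)
        allowed = {r.species_id: set(r.territories.split(";")) for r in truth.itertuples()}
        for rec in specimens.itertuples():
            assert rec.territory in allowed[rec.species_id]


class TestPartitions:
    def test_zero_error_methods_reproduce_truth(self):
        study = simulate_study(_small_config(n_true_species=50))
        truth_clusters = {
            frozenset(grp["specimen_id"])
            for _, grp in study.specimen_table.groupby("species_id")
        }
        for p in study.partitions.partitions:
            groups = {}
            for sp, lab in p.assignment.items():
                groups.setdefault(lab, set()).add(sp)
            assert {frozenset(g) for g in groups.values()} == truth_clusters

    def test_coverage_fraction_respected(self):
        methods = (
            MethodProfile("partial", coverage=0.5),
            MethodProfile("tb", coverage=1.0, is_tiebreaker=True),
        )
        study = simulate_study(_small_config(n_true_species=80, method_profiles=methods))
        n = len(study.specimen_table)
        partial = next(p for p in study.partitions.partitions if p.method_name == "partial")
        assert len(partial.specimens) == round(0.5 * n)
        assert partial.specimens <= set(study.specimen_table["specimen_id"])

    def test_full_lumping_merges_within_morphospecies(self):
        cfg = _small_config(
            n_true_species=12,
            complex_size_distribution=("fixed", {"value": 2}),
            prop_described=1.0,
            prop_unidentifiable=0.0,
            specimens_per_species=("fixed", {"value": 2}),
            method_profiles=(
                MethodProfile("lumper", lump_rate=1.0),
                MethodProfile("tb", is_tiebreaker=True),
            ),
        )
        study = simulate_study(cfg)
        lumper = next(p for p in study.partitions.partitions if p.method_name == "lumper")
        # every 2-species morphospecies collapses to one cluster: half the OTUs
        assert count_otus(lumper) == count_otus(study.partitions.tiebreaker_partition()) / 2

    def test_consensus_recovers_truth_under_moderate_splitting(self):
        rates = []
        for seed in range(5):
            methods = tuple(
                MethodProfile(f"m{i}", split_rate=0.1, coverage=1.0,
                              is_tiebreaker=(i == 4)) for i in range(1, 5)
            )
            cfg = SimulationConfig(
                n_true_species=380, seed=seed, method_profiles=methods,
                specimens_per_species=("poisson", {"mean": 2.7}),
            )
            study = simulate_study(cfg)
            cons = consensus(study.partitions)
            truth_clusters = {
                frozenset(grp["specimen_id"])
                for _, grp in study.specimen_table.groupby("species_id")
            }
            got = {}
            for sp, lab in cons.assignment.items():
                got.setdefault(lab, set()).add(sp)
            got_clusters = {frozenset(g) for g in got.values()}
            rates.append(len(truth_clusters & got_clusters) / len(truth_clusters))
        assert np.mean(rates) >= 0.95


class TestFixtures:
    def test_round_trip_specimen_and_partition_tables(self, tmp_path):
        study = simulate_study(_small_config(n_true_species=40))
        write_fixtures(study, tmp_path)
        specimens = hio.read_table(tmp_path / "specimen_table.tsv")
        pd.testing.assert_frame_equal(
            specimens, study.specimen_table.astype(str), check_dtype=False
        )
        pset = hio.read_partition_set(tmp_path / "partitions.tsv", tiebreaker="m4")
        assert {p.method_name for p in pset.partitions} == {"m1", "m2", "m3", "m4"}
        for orig in study.partitions.partitions:
            back = next(p for p in pset.partitions if p.method_name == orig.method_name)
            assert back.assignment == orig.assignment

    def test_byte_identical_fixtures_for_same_seed(self, tmp_path):
        cfg = _small_config(n_true_species=35)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        f1 = write_fixtures(simulate_study(cfg), d1)
        f2 = write_fixtures(simulate_study(cfg), d2)
        assert [p.name for p in f1] == [p.name for p in f2]
        for p1, p2 in zip(f1, f2):
            assert p1.read_bytes() == p2.read_bytes()

    def test_incidence_matrix_round_trip_and_row_count(self, tmp_path):
        study = simulate_study(_small_config(n_true_species=60))
        write_fixtures(study, tmp_path)
        matrix = hio.read_incidence_matrix(tmp_path / "incidence_territory.tsv")
        n_sampled = int((study.truth_table["n_specimens"] > 0).sum())
        assert len(matrix.species) == n_sampled
        assert (matrix.cells == study.incidence_by_level["territory"].cells).all()

    def test_geography_round_trip(self, tmp_path):
        study = simulate_study(_small_config())
        write_fixtures(study, tmp_path)
        scheme = hio.read_geography(tmp_path / "geography.tsv")
        assert scheme == study.scheme

    def test_empty_study_writes_readable_headers(self, tmp_path):
        cfg = _small_config(specimens_per_species=("fixed", {"value": 0}))
        study = simulate_study(cfg)
        write_fixtures(study, tmp_path)
        specimens = hio.read_table(tmp_path / "specimen_table.tsv")
        assert specimens.empty
        assert list(specimens.columns) == hio.SPECIMEN_COLUMNS
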