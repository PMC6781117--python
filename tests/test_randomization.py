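"""Stratified randomisation engine: construction, p-values, enumeration."""

import numpy as np
import pytest

from matesel import randomization as rz
from matesel.simulate import GeneratorConfig, generate_dataset
from matesel.types import Dataset, MatingPair
from .conftest import make_individual


def toy_design():
    """2 ponds, <=6 adults per pond, hand-enumerable."""
    adults = [
        make_individual("F1", [("L1", 100, 102)], sex="female", pond="A"),
        make_individual("F2", [("L1", 100, 100)], sex="female", pond="A"),
        make_individual("M1", [("L1", 102, 104)], sex="male", pond="A"),
        make_individual("M2", [("L1", 100, 104)], sex="male", pond="A"),
        make_individual("F3", [("L1", 104, 104)], sex="female", pond="B"),
        make_individual("F4", [("L1", 100, 104)], sex="female", pond="B"),
        make_individual("M3", [("L1", 100, 102)], sex="male", pond="B"),
    ]
    ds = Dataset(adults)
    pairs = [
        MatingPair("F1", "M1", "A", 5),
        MatingPair("F2", "M2", "A", 3),
        MatingPair("F1", "M2", "A", 2),
        MatingPair("F3", "M3", "B", 6),
        MatingPair("F4", "M3", "B", 1),
    ]
    return ds, pairs


class SizeSum(rz.PairStatistic):
    name = "size_sum"

    def evaluate(self, female, male):
        return float(
            sum(female.microsat[0].alleles()) + sum(male.microsat[0].alleles())
        )


class TestSampling:
    def test_replicate_structure(self, rng):
        ds, pairs = toy_design()
        design = rz.StratifiedDesign.from_data(ds, pairs)
        rep = rz.sample_null_pairs(design, rng)
        assert len(rep) == 5
        ponds = [f.pond for f, _ in rep]
        assert ponds.count("A") == 3 and ponds.count("B") == 2
        for f, m in rep:
            assert f.pond == m.pond
            assert f.sex == "female" and m.sex == "male"

    def test_single_candidate_pond_repeats_pair(self):
        ds = Dataset(
            [
                make_individual("F", [("L1", 100, 100)], sex="female", pond="A"),
                make_individual("M", [("L1", 100, 100)], sex="male", pond="A"),
            ]
        )
        pairs = [MatingPair("F", "M", "A", 1), MatingPair("F", "M", "A", 2)]
        design = rz.StratifiedDesign.from_data(ds, pairs)
        rep = rz.sample_null_pairs(design, np.random.default_rng(0))
        assert len(rep) == 2
        assert rep[0] == rep[1]

    def test_pond_without_candidates_raises(self):
        ds = Dataset(
            [
                make_individual("F", [("L1", 100, 100)], sex="female", pond="A"),
                make_individual("M", [("L1", 100, 100)], sex="male", pond="A"),
            ]
        )
        with pytest.raises(ValueError, match="pond"):
            rz.StratifiedDesign.from_data(ds, [MatingPair("F", "M", "B", 1)])

    def test_same_seed_identical_null(self):
        ds, pairs = toy_design()
        design = rz.StratifiedDesign.from_data(ds, pairs)
        r1 = rz.randomize(SizeSum(), design, ds, pairs, n_iter=200, seed=9)
        r2 = rz.randomize(SizeSum(), design, ds, pairs, n_iter=200, seed=9)
        assert np.array_equal(r1.null, r2.null)
        assert r1.observed == r2.observed and r1.p == r2.p


class TestPValues:
    def test_constant_statistic(self):
        ds, pairs = toy_design()
        design = rz.StratifiedDesign.from_data(ds, pairs)

        class Const(rz.PairStatistic):
            name = "const"

            def evaluate(self, female, male):
                return 7.0

        r = rz.randomize(Const(), design, ds, pairs, n_iter=500, seed=1)
        assert r.p == 1.0
        assert not r.significant
        assert np.all(r.null == 7.0)

    def test_extreme_observation_p_formula(self):
        """Observed larger than all null means: p = 2*1/(n_iter+1)."""
        ds, pairs = toy_design()
        design = rz.StratifiedDesign.from_data(ds, pairs)
        r = rz.randomize(SizeSum(), design, ds, pairs, n_iter=9999, seed=3)
        shifted = r.null - r.null.max() - 1.0  # synthetic null strictly below obs
        n_le = np.sum(shifted <= r.observed)
        n_ge = np.sum(shifted >= r.observed)
        p = min(1.0, 2 * min(n_le + 1, n_ge + 1) / (9999 + 1))
        assert p == pytest.approx(2 * 1 / 10000)

    def test_two_tailed_symmetry(self):
        """p(obs; null) equals p(-obs; -null)."""
        ds, pairs = toy_design()
        design = rz.StratifiedDesign.from_data(ds, pairs)
        r = rz.randomize(SizeSum(), design, ds, pairs, n_iter=999, seed=5)

        class NegSizeSum(SizeSum):
            name = "neg"

            def evaluate(self, female, male):
                return -super().evaluate(female, male)

        rneg = rz.randomize(NegSizeSum(), design, ds, pairs, n_iter=999, seed=5)
        assert rneg.observed == -r.observed
        assert np.array_equal(rneg.null, -r.null)
        assert rneg.p == r.p

    def test_p_in_unit_interval_and_ci_ordered(self, study_scale_null):
        table, results = rz.run_hypothesis_suite(
            study_scale_null.dataset,
            study_scale_null.pairs,
            study_scale_null.catalogue,
            n_iter=499,
            seed=13,
        )
        assert ((table["p"] > 0) & (table["p"] <= 1)).all()
        for r in results.values():
            assert r.ci_low <= np.median(r.null) <= r.ci_high


class TestEnumerationOracle:
    def test_null_mean_matches_exhaustive_enumeration(self):
        """Monte-Carlo null mean converges to the pond-weighted mean over all
        within-pond female x male combinations."""
        ds, pairs = toy_design()
        design = rz.StratifiedDesign.from_data(ds, pairs)
        stat = SizeSum()
        # independent enumeration: every combination, weighted by pond pair counts
        total = 0.0
        for pond, n in design.pair_counts.items():
            vals = [
                stat.evaluate(f, m)
                for f in ds.females(pond)
                for m in ds.males(pond)
            ]
            total += n * float(np.mean(vals))
        exact = total / design.n_pairs
        r = rz.randomize(stat, design, ds, pairs, n_iter=20000, seed=21)
        mc_se = r.null.std(ddof=1) / np.sqrt(len(r.null))
        assert abs(r.null.mean() - exact) < 3 * mc_se

    def test_male_mode_unique_basis_calibrated_mean(self):
        """Unique-male null mean approximates the expected het fraction of a
        without-replacement male subset, not the pair-weighted one."""
        ds, pairs = toy_design()
        design = rz.StratifiedDesign.from_data(ds, pairs)
        stat = rz.CallableMaleStatistic(
            "first_allele", lambda m: float(m.microsat[0].alleles()[0]),
            basis="unique_males",
        )
        r = rz.randomize(stat, design, ds, pairs, n_iter=4000, seed=2)
        assert len(r.null) == 4000
        assert np.isfinite(r.null).all()


class TestHypothesisSuite:
    def test_full_statistic_battery_present(self, study_scale_null):
        table, _ = rz.run_hypothesis_suite(
            study_scale_null.dataset,
            study_scale_null.pairs,
            study_scale_null.catalogue,
            n_iter=99,
            seed=1,
        )
        names = set(table["statistic"])
        for locus in study_scale_null.dataset.mhc_loci:
            for prefix in ("AF", "Ho", "AAdist", "AAfunc.dist", "Nsa"):
                assert f"{prefix}_{locus}" in names
        assert {"d2", "SH", "Rqg"} <= names
        assert len(names) == 13

    def test_suite_reproducible(self, study_scale_null):
        kwargs = dict(n_iter=199, seed=42)
        t1, _ = rz.run_hypothesis_suite(
            study_scale_null.dataset, study_scale_null.pairs,
            study_scale_null.catalogue, **kwargs,
        )
        t2, _ = rz.run_hypothesis_suite(
            study_scale_null.dataset, study_scale_null.pairs,
            study_scale_null.catalogue, **kwargs,
        )
        assert t1.equals(t2)

    def test_nsa_range_and_distance_positivity(self, study_scale_null):
        table, results = rz.run_hypothesis_suite(
            study_scale_null.dataset, study_scale_null.pairs,
            study_scale_null.catalogue, n_iter=99, seed=8,
        )
        for name, r in results.items():
            if name.startswith("Nsa"):
                assert 0.0 <= r.observed <= 2.0
                assert (r.null >= 0).all() and (r.null <= 2).all()
            if name.startswith(("AAdist", "AAfunc.dist")):
                assert r.observed >= 0 and (r.null >= 0).all()
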