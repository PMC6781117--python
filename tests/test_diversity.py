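"""Diversity indices against hand computations and brute-force oracles."""

import numpy as np
import pytest

from matesel import diversity
from matesel.types import Dataset
from .conftest import make_individual


def brute_force_frequencies(individuals):
    """Independent gene-counting oracle."""
    out = {}
    for ind in individuals:
        for g in list(ind.microsat) + list(ind.mhc):
            if g.is_missing:
                continue
            locus = out.setdefault(g.locus_id, [])
            locus.extend(g.alleles())
    return {
        locus: {a: copies.count(a) / len(copies) for a in set(copies)}
        for locus, copies in out.items()
    }


class TestAlleleFrequencies:
    def test_simple_counting(self):
        inds = [
            make_individual("a", [("L1", 100, 100)]),
            make_individual("b", [("L1", 100, 102)]),
        ]
        freqs = diversity.allele_frequencies(inds)
        assert freqs["L1"][100] == 0.75 and freqs["L1"][102] == 0.25

    def test_monomorphic(self):
        inds = [make_individual(str(i), [("L1", 100, 100)]) for i in range(3)]
        assert diversity.allele_frequencies(inds)["L1"][100] == 1.0

    def test_matches_brute_force_and_sums_to_one(self, rng):
        inds = [
            make_individual(
                f"i{k}",
                [("L1", int(rng.choice([100, 102, 104, 106])),
                  int(rng.choice([100, 102, 104, 106])))],
            )
            for k in range(10)
        ]
        freqs = diversity.allele_frequencies(inds)
        oracle = brute_force_frequencies(inds)
        assert abs(sum(freqs["L1"].values()) - 1.0) < 1e-12
        for a, p in oracle["L1"].items():
            assert freqs["L1"][a] == pytest.approx(p, abs=1e-12)

    def test_untyped_locus_raises(self):
        inds = [make_individual("a", [("L1", None, None)])]
        with pytest.raises(ValueError, match="L1"):
            diversity.allele_frequencies(inds)


class TestSH:
    def test_fully_heterozygous_vs_half_het_population(self):
        ind = make_individual("x", [("L1", 100, 102), ("L2", 100, 104)])
        assert diversity.standardized_heterozygosity(ind, {"L1": 0.5, "L2": 0.5}) == 2.0

    def test_fully_homozygous_is_zero(self):
        ind = make_individual("x", [("L1", 100, 100), ("L2", 104, 104)])
        assert diversity.standardized_heterozygosity(ind, {"L1": 0.5, "L2": 0.5}) == 0.0

    def test_monomorphic_population_flagged_undefined(self):
        ind = make_individual("x", [("L1", 100, 100)])
        assert diversity.standardized_heterozygosity(ind, {"L1": 0.0}) is None

    def test_against_per_locus_hand_summation(self, rng):
        """20-individual population: SH recomputed independently per locus."""
        sizes = [100, 102, 104, 106]
        inds = [
            make_individual(
                f"i{k}",
                [(f"L{j}", int(rng.choice(sizes)), int(rng.choice(sizes)))
                 for j in range(4)],
            )
            for k in range(20)
        ]
        pop_ho = diversity.observed_heterozygosity(inds)
        for ind in inds:
            het = [g.is_heterozygous for g in ind.microsat]
            expected = (sum(het) / len(het)) / np.mean(
                [pop_ho[g.locus_id] for g in ind.microsat]
            )
            assert diversity.standardized_heterozygosity(ind, pop_ho) == pytest.approx(
                expected, abs=1e-9
            )


class TestHL:
    def test_extremes(self):
        freqs = {"L1": {100: 0.5, 102: 0.5}, "L2": {100: 0.25, 102: 0.75}}
        het = make_individual("h", [("L1", 100, 102), ("L2", 100, 102)])
        hom = make_individual("o", [("L1", 100, 100), ("L2", 102, 102)])
        assert diversity.heterozygosity_by_locus(het, freqs) == 0.0
        assert diversity.heterozygosity_by_locus(hom, freqs) == 1.0

    def test_two_locus_worked_case(self):
        # E1 = 1 - 2*(0.5^2) = 0.5 (homozygous); E2 = 1 - (0.25^2 + 0.75^2) = 0.375 (het)
        freqs = {"L1": {100: 0.5, 102: 0.5}, "L2": {100: 0.25, 102: 0.75}}
        ind = make_individual("x", [("L1", 100, 100), ("L2", 100, 102)])
        assert diversity.heterozygosity_by_locus(ind, freqs) == pytest.approx(
            0.5 / 0.875, abs=1e-9
        )


class TestIR:
    def test_heterozygous_everywhere_frequency_half(self):
        n = 4
        freqs = {f"L{j}": {100: 0.5, 102: 0.5} for j in range(n)}
        ind = make_individual("x", [(f"L{j}", 100, 102) for j in range(n)])
        # (2*0 - sum f) / (2N - sum f) with sum f = N -> -1 * N / N = -1
        assert diversity.internal_relatedness(ind, freqs) == pytest.approx(-1.0)

    def test_single_locus_hand_case(self):
        freqs = {"L1": {100: 0.25, 102: 0.25, 104: 0.5}}
        ind = make_individual("x", [("L1", 100, 102)])
        assert diversity.internal_relatedness(ind, freqs) == pytest.approx(
            (0 - 0.5) / (2 - 0.5), abs=1e-12
        )

    def test_degenerate_fixed_population_flagged(self):
        freqs = {"L1": {100: 1.0}}
        ind = make_individual("x", [("L1", 100, 100)])
        assert diversity.internal_relatedness(ind, freqs) is None


class TestD2:
    def test_homozygote_is_zero(self):
        ind = make_individual("x", [("L1", 100, 100), ("L2", 88, 88)])
        assert diversity.mean_d2(ind) == 0.0

    def test_repeat_units_vs_bp(self):
        ind = make_individual("x", [("L1", 100, 104)], motif=2)
        assert diversity.mean_d2(ind, unit="repeats") == pytest.approx(4.0)
        assert diversity.mean_d2(ind, unit="bp") == pytest.approx(16.0)

    def test_swap_invariance(self):
        a = make_individual("a", [("L1", 100, 104), ("L2", 90, 96)])
        b = make_individual("b", [("L1", 104, 100), ("L2", 96, 90)])
        assert diversity.mean_d2(a) == diversity.mean_d2(b)


class TestHoAndAF:
    def test_proportion_among_males(self):
        males = [
            make_individual(f"m{i}", [], [("M", "A01", "A02")]) for i in range(26)
        ] + [
            make_individual(f"h{i}", [], [("M", "A01", "A01")]) for i in range(15)
        ]
        assert diversity.mhc_het_proportion(males, "M") == pytest.approx(
            26 / 41, abs=1e-12
        )

    def test_all_homozygous_and_empty(self):
        males = [make_individual("m", [], [("M", "A01", "A01")])]
        assert diversity.mhc_het_proportion(males, "M") == 0.0
        with pytest.raises(ValueError):
            diversity.mhc_het_proportion([], "M")

    def test_good_gene_score_definitions(self):
        freqs = {"M": {"A01": 0.7, "A02": 0.3}}
        hom = make_individual("h", [], [("M", "A01", "A01")])
        het = make_individual("e", [], [("M", "A01", "A02")])
        assert diversity.good_gene_score(hom, freqs, "M") == pytest.approx(1.4)
        assert diversity.good_gene_score(het, freqs, "M") == pytest.approx(1.0)
        fixed = {"M": {"A01": 1.0}}
        assert diversity.good_gene_score(hom, fixed, "M") == pytest.approx(2.0)


class TestInvariants:
    def test_untyped_locus_changes_no_index(self):
        freqs = {"L1": {100: 0.5, 102: 0.5}, "L2": {100: 0.3, 102: 0.7}}
        pop_ho = {"L1": 0.5, "L2": 0.4}
        base = make_individual("x", [("L1", 100, 102)])
        extended = make_individual("y", [("L1", 100, 102), ("L2", None, None)])
        for fn in (
            lambda i: diversity.standardized_heterozygosity(i, pop_ho),
            lambda i: diversity.heterozygosity_by_locus(i, freqs),
            lambda i: diversity.internal_relatedness(i, freqs),
            diversity.mean_d2,
        ):
            assert fn(base) == fn(extended)

    def test_hl_ir_invariant_to_allele_relabelling(self):
        freqs1 = {"L1": {100: 0.25, 102: 0.75}}
        freqs2 = {"L1": {900: 0.25, 444: 0.75}}
        a = make_individual("a", [("L1", 100, 102)])
        b = make_individual("b", [("L1", 900, 444)])
        assert diversity.heterozygosity_by_locus(
            a, freqs1
        ) == diversity.heterozygosity_by_locus(b, freqs2)
        assert diversity.internal_relatedness(
            a, freqs1
        ) == diversity.internal_relatedness(b, freqs2)

    def test_heterozygosity_indices_rank_correlated_on_simulation(self):
        """SH, HL (reversed) and IR (reversed) should co-rank strongly."""
        from scipy.stats import spearmanr

        from matesel.simulate import GeneratorConfig, generate_population

        dataset, _, _ = generate_population(
            GeneratorConfig(seed=5, ponds=((100, 100),))
        )
        profiles = diversity.diversity_profiles(dataset)
        rho_sh_hl = spearmanr(profiles["SH"], profiles["HL"]).statistic
        rho_sh_ir = spearmanr(profiles["SH"], profiles["IR"]).statistic
        assert rho_sh_hl**2 > 0.8 and rho_sh_hl < 0
        assert rho_sh_ir**2 > 0.8 and rho_sh_ir < 0
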