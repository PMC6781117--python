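"""Synthetic generator: determinism, structure, Mendelian guarantees,
preference calibration."""

import numpy as np
import pytest
from scipy.stats import chisquare

from matesel import diversity, mhcdist
from matesel.parentage import audit_dataset
from matesel.relatedness import relatedness_qg
from matesel.simulate import (
    GeneratorConfig,
    clutches_frame,
    generate_dataset,
    generate_matings,
    generate_population,
)


class TestDeterminism:
    def test_identical_datasets_from_same_seed(self):
        cfg = GeneratorConfig(seed=1, ponds=((4, 2),), n_microsat_loci=3,
                              n_clutches=4, clutch_lambda=5.0)
        d1 = generate_dataset(cfg)
        d2 = generate_dataset(cfg)
        assert [i.id for i in d1.dataset.individuals] == [
            i.id for i in d2.dataset.individuals
        ]
        for a, b in zip(d1.dataset.individuals, d2.dataset.individuals):
            assert a.microsat == b.microsat and a.mhc == b.mhc
        assert d1.pairs == d2.pairs
        assert d1.catalogue["mhc_M1"]["A01"].dna == d2.catalogue["mhc_M1"]["A01"].dna

    def test_different_seeds_differ(self):
        d1 = generate_dataset(GeneratorConfig(seed=1, ponds=((4, 2),), n_clutches=4))
        d2 = generate_dataset(GeneratorConfig(seed=2, ponds=((4, 2),), n_clutches=4))
        assert d1.catalogue["mhc_M1"]["A01"].dna != d2.catalogue["mhc_M1"]["A01"].dna


class TestStructure:
    def test_default_population_counts(self, study_scale_null):
        ds = study_scale_null.dataset
        assert len(ds.females()) == 123 and len(ds.males()) == 59
        assert len(ds.ponds) == 3
        assert len(ds.microsat_loci) == 13 and len(ds.mhc_loci) == 2
        assert len(study_scale_null.pairs) == 105

    def test_pairs_within_pond(self, study_scale_null):
        ds = study_scale_null.dataset
        for p in study_scale_null.pairs:
            assert ds[p.female_id].pond == ds[p.male_id].pond == p.pond

    def test_mhc_sequences_translate_cleanly(self, study_scale_null):
        for locus, alleles in study_scale_null.catalogue.items():
            for rec in alleles.values():
                assert len(rec.dna) == 270
                assert len(rec.protein) == 90
                assert "*" not in rec.protein

    def test_requested_aa_divergence_realised(self):
        for target in (0.05, 0.10):
            _, catalogue, truth = generate_population(
                GeneratorConfig(seed=9, mhc_target_pdist=target)
            )
            for locus, alleles in catalogue.items():
                d = mhcdist.aa_distance(
                    alleles["A01"].protein, alleles["A02"].protein
                )
                assert d == pytest.approx(target, abs=0.03)
                assert truth["realised_mhc_pdist"][locus] == pytest.approx(d)

    def test_truth_manifest_records_config(self, study_scale_null):
        truth = study_scale_null.truth
        assert truth["population"]["config"]["n_founders"] == 11
        assert set(truth["population"]["pedigree"]) == {
            i.id for i in study_scale_null.dataset.individuals
        }


class TestRelatednessBackground:
    def test_founders_only_mode_unrelated(self):
        ds, _, _ = generate_population(
            GeneratorConfig(seed=4, pedigree=False, ponds=((60, 60),))
        )
        freqs = diversity.allele_frequencies(ds.individuals)
        rng = np.random.default_rng(0)
        inds = ds.individuals
        vals = []
        for _ in range(300):
            i, j = rng.choice(len(inds), 2, replace=False)
            vals.append(relatedness_qg(inds[i], inds[j], freqs))
        assert np.mean(vals) == pytest.approx(0.0, abs=0.03)

    def test_pedigree_mode_creates_background_relatedness(self):
        ds, _, truth = generate_population(GeneratorConfig(seed=4, ponds=((60, 60),)))
        # referenced to the true base frequencies (sample-estimated ones
        # centre mean pairwise relatedness at 0 by construction)
        freqs = {
            locus: {int(a): p for a, p in table.items()}
            for locus, table in truth["microsat_base_frequencies"].items()
        }
        rng = np.random.default_rng(0)
        inds = ds.individuals
        vals = []
        for _ in range(300):
            i, j = rng.choice(len(inds), 2, replace=False)
            vals.append(relatedness_qg(inds[i], inds[j], freqs))
        # adults are sibs/half-sibs through 11 shared founders
        assert np.mean(vals) > 0.05


class TestMatings:
    def test_uniform_choice_under_null(self):
        """Chi-square goodness of fit on male choice counts, 1 pond, 5 males."""
        cfg = GeneratorConfig(
            seed=6, ponds=((40, 5),), n_clutches=2000, clutch_lambda=1.0,
            preference="null",
        )
        ds, catalogue, _ = generate_population(cfg)
        pairs, _, _ = generate_matings(ds, catalogue, cfg, include_offspring=False)
        males = [m.id for m in ds.males()]
        counts = [sum(p.male_id == m for p in pairs) for m in males]
        assert chisquare(counts).pvalue > 0.01

    def test_strong_heterozygote_preference_dominates(self):
        cfg = GeneratorConfig(
            seed=6, ponds=((40, 10),), n_clutches=400, clutch_lambda=1.0,
            preference="heterozygote", beta=12.0,
        )
        ds, catalogue, _ = generate_population(cfg)
        pairs, _, _ = generate_matings(ds, catalogue, cfg, include_offspring=False)
        locus = ds.mhc_loci[0]
        het_rate = np.mean(
            [ds[p.male_id].mhc_at(locus).is_heterozygous for p in pairs]
        )
        assert het_rate > 0.95  # softmax limit: heterozygous males take ~all

    def test_choice_probabilities_stored_and_normalised(self, study_scale_null):
        probs = study_scale_null.truth["matings"]["choice_probabilities"]
        for pond, matrix in probs.items():
            rows = np.array(matrix)
            assert np.allclose(rows.sum(axis=1), 1.0)

    def test_offspring_trios_mendelian_when_noise_free(self, small_synthetic):
        audit = audit_dataset(small_synthetic.trios)
        assert audit["consistent"].all()

    def test_clutch_table_for_reproductive_model(self, small_synthetic):
        table = clutches_frame(
            small_synthetic.pairs, small_synthetic.dataset,
            small_synthetic.dataset.mhc_loci[0],
        )
        assert set(table.columns) == {"male_id", "zygosity", "count"}
        assert len(table) == len(small_synthetic.pairs)
        assert set(table["zygosity"]) <= {0, 1}


class TestReaderInvariants:
    def test_generated_dataset_survives_write_read_cycle(self, tmp_path, small_synthetic):
        """Generator output satisfies every reader invariant."""
        from matesel import io

        io.write_individuals(small_synthetic.dataset, tmp_path / "a.tsv")
        ds = io.read_individuals(tmp_path / "a.tsv")
        io.write_pairs(small_synthetic.pairs, tmp_path / "p.tsv")
        io.read_pairs(tmp_path / "p.tsv", ds)
        io.write_allele_fasta(small_synthetic.catalogue, tmp_path / "f.fasta")
        io.read_allele_fasta(tmp_path / "f.fasta")
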