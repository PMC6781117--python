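"""Synthetic alligator-like populations with known ground truth.

The generator emulates the structure of the study population: three
physically isolated breeding ponds holding 123 adult females and 59 adult
males in total, all descended from a small closed founder base (default 11
wild founders, which creates background relatedness), genotyped at 13
polymorphic microsatellite loci and 2 biallelic MHC class I loci whose
alleles carry generated coding sequences with a controllable amino-acid
divergence.  Mating is simulated per clutch: a female is drawn from her
pond (with replacement — a female may breed in several seasons), and she
picks a male with probability proportional to

    exp(beta * het(male) + gamma * AAfunc.dist(female, male))

so ``beta = gamma = 0`` is an exact uniform-choice null, ``beta`` expresses
a preference for MHC-heterozygous males (at a configurable locus) and
``gamma`` a preference for MHC-dissimilar males.  Clutch sizes are
Poisson (default rate 16, about 1684 offspring over 105 clutches) and
offspring genotypes follow Mendelian segregation, error-free unless a
genotyping-noise rate is requested.  Every dataset is reproducible
bit-for-bit from its config and seed, and a ground-truth manifest records
the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from . import mhcdist
from .types import (
    AlleleSequence,
    Dataset,
    Individual,
    MatingPair,
    MhcGenotype,
    MicrosatGenotype,
    TrioRecord,
)

__all__ = ["GeneratorConfig", "SyntheticData", "generate_population",
           "generate_matings", "generate_dataset", "clutches_frame"]

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]

_CODON_TABLE = {}
for _codon in _SENSE_CODONS:
    from Bio.Seq import Seq as _Seq

    _CODON_TABLE[_codon] = str(_Seq(_codon).translate())


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic population.

    Defaults mirror the real population: 3 ponds, 123 females + 59 males,
    13 microsatellite loci (4-10 alleles, 2-4 bp motifs), 2 biallelic MHC
    loci with 270 bp coding fragments, 11 founders, 105 clutches at a
    Poisson clutch rate of 16.
    """

    seed: int = 0
    ponds: Sequence[tuple[int, int]] = ((41, 20), (41, 20), (41, 19))
    n_microsat_loci: int = 13
    microsat_alleles: tuple[int, int] = (4, 10)
    motif_lengths: tuple[int, ...] = (2, 3, 4)
    n_mhc_loci: int = 2
    mhc_coding_length: int = 270
    mhc_target_pdist: float = 0.05
    mhc_founder_freq: float = 0.65  # common-allele frequency per MHC locus
    n_founders: int = 11
    pedigree: bool = True  # False: adults drawn unrelated from the base frequencies
    preference: str = "null"  # null | heterozygote | compatibility | mixed
    beta: float = 0.0
    gamma: float = 0.0
    preference_locus: Optional[int] = 0  # locus index for the heterozygote term
    clutch_lambda: float = 16.0
    n_clutches: int = 105
    noise_rate: float = 0.0  # per-allele offspring mistyping rate

    def __post_init__(self) -> None:
        if self.mhc_coding_length % 3 != 0:
            raise ValueError("MHC coding length must be divisible by 3")
        if self.n_clutches <= 0 or self.n_founders <= 0:
            raise ValueError("counts must be positive")
        if self.preference not in ("null", "heterozygote", "compatibility", "mixed"):
            raise ValueError(f"unknown preference model {self.preference!r}")


@dataclass
class SyntheticData:
    dataset: Dataset
    catalogue: dict[str, dict[str, AlleleSequence]]
    pairs: list[MatingPair]
    trios: list[TrioRecord]
    truth: dict


def _simulate_mhc_alleles(
    rng: np.random.Generator, locus: str, length: int, target_pdist: float
) -> dict[str, AlleleSequence]:
    """Two allele coding sequences at an exact amino-acid p-distance."""
    n_codons = length // 3
    codons = [
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    ]
    k = int(round(target_pdist * n_codons))
    positions = rng.choice(n_codons, size=k, replace=False)
    codons2 = list(codons)
    for pos in positions:
        aa = _CODON_TABLE[codons2[pos]]
        alternatives = [c for c in _SENSE_CODONS if _CODON_TABLE[c] != aa]
        codons2[pos] = alternatives[rng.integers(0, len(alternatives))]
    out = {}
    for name, cs in (("A01", codons), ("A02", codons2)):
        dna = "".join(cs)
        protein = "".join(_CODON_TABLE[c] for c in cs)
        out[name] = AlleleSequence(name, locus, dna, protein)
    return out


def generate_population(
    config: GeneratorConfig,
) -> tuple[Dataset, dict[str, dict[str, AlleleSequence]], dict]:
    """Adults + MHC allele catalogue + ground truth for one synthetic study."""
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    # --- locus panels -----------------------------------------------------
    ms_loci = []
    for l in range(config.n_microsat_loci):
        n_all = int(rng.integers(config.microsat_alleles[0], config.microsat_alleles[1] + 1))
        motif = int(config.motif_lengths[rng.integers(0, len(config.motif_lengths))])
        base = int(rng.integers(25, 75)) * motif
        sizes = [base + motif * k for k in range(n_all)]
        freqs = rng.dirichlet(np.ones(n_all))
        ms_loci.append(
            {"locus": f"ms_L{l + 1:02d}", "motif": motif, "sizes": sizes, "freqs": freqs}
        )
    mhc_locus_names = [f"mhc_M{l + 1}" for l in range(config.n_mhc_loci)]
    catalogue = {
        name: _simulate_mhc_alleles(
            rng, name, config.mhc_coding_length, config.mhc_target_pdist
        )
        for name in mhc_locus_names
    }
    p_mhc = config.mhc_founder_freq

    def draw_genotype() -> tuple[list[MicrosatGenotype], list[MhcGenotype]]:
        ms = []
        for loc in ms_loci:
            a, b = rng.choice(loc["sizes"], size=2, p=loc["freqs"])
            ms.append(MicrosatGenotype(loc["locus"], int(a), int(b), motif_length=loc["motif"]))
        mhc = []
        for name in mhc_locus_names:
            a2, b2 = rng.choice(["A01", "A02"], size=2, p=[p_mhc, 1 - p_mhc])
            mhc.append(MhcGenotype(name, str(a2), str(b2)))
        return ms, mhc

    def mendel(
        mother: tuple[list[MicrosatGenotype], list[MhcGenotype]],
        father: tuple[list[MicrosatGenotype], list[MhcGenotype]],
    ) -> tuple[list[MicrosatGenotype], list[MhcGenotype]]:
        ms = []
        for gm, gf in zip(mother[0], father[0]):
            ms.append(
                MicrosatGenotype(
                    gm.locus_id,
                    gm.alleles()[rng.integers(0, 2)],
                    gf.alleles()[rng.integers(0, 2)],
                    motif_length=gm.motif_length,
                )
            )
        mhc = []
        for hm, hf in zip(mother[1], father[1]):
            mhc.append(
                MhcGenotype(
                    hm.locus_id,
                    hm.alleles()[rng.integers(0, 2)],
                    hf.alleles()[rng.integers(0, 2)],
                )
            )
        return ms, mhc

    # --- pedigree: founders, then adults as their descendants -------------
    founders = [draw_genotype() for _ in range(config.n_founders)]
    founder_sex = ["female" if i % 2 == 0 else "male" for i in range(config.n_founders)]

    slots: list[tuple[str, str]] = []  # (pond, sex) for every adult to create
    for p, (n_f, n_m) in enumerate(config.ponds):
        pond = f"P{p + 1}"
        slots += [(pond, "female")] * n_f + [(pond, "male")] * n_m
    order = rng.permutation(len(slots))

    individuals: list[Individual] = []
    pedigree: dict[str, tuple[str, str]] = {}
    # adults are offspring of founder matings: related through shared
    # founders (sibships) but themselves non-inbred
    pool_f = [(f"F{i:02d}", g) for i, (g, s) in enumerate(zip(founders, founder_sex)) if s == "female"]
    pool_m = [(f"F{i:02d}", g) for i, (g, s) in enumerate(zip(founders, founder_sex)) if s == "male"]
    for k, idx in enumerate(order):
        pond, sex = slots[idx]
        ind_id = f"A{k + 1:03d}"
        if config.pedigree:
            mid, mg = pool_f[rng.integers(0, len(pool_f))]
            fid, fg = pool_m[rng.integers(0, len(pool_m))]
            geno = mendel(mg, fg)
            pedigree[ind_id] = (mid, fid)
            # adult MHC genotypes are fresh draws from the pond gene pool:
            # with only ~30 founder sibships, inheriting MHC through the
            # pedigree would tie MHC zygosity to family-level microsatellite
            # genotypes, building a genome-wide correlate into what should
            # be a purely MHC-targeted preference
            _, mhc_geno = draw_genotype()
            geno = (geno[0], mhc_geno)
        else:
            geno = draw_genotype()
            pedigree[ind_id] = ("wild", "wild")
        individuals.append(Individual(ind_id, sex, pond, geno[0], geno[1]))

    dataset = Dataset(
        individuals,
        microsat_loci=[loc["locus"] for loc in ms_loci],
        mhc_loci=mhc_locus_names,
    )
    truth = {
        "config": asdict(config),
        "pedigree": pedigree,
        "microsat_base_frequencies": {
            loc["locus"]: dict(zip(map(str, loc["sizes"]), map(float, loc["freqs"])))
            for loc in ms_loci
        },
        "mhc_founder_freq": p_mhc,
        "realised_mhc_pdist": {
            name: mhcdist.aa_distance(
                catalogue[name]["A01"].protein, catalogue[name]["A02"].protein
            )
            for name in mhc_locus_names
        },
    }
    return dataset, catalogue, truth


def _choice_weights(
    config: GeneratorConfig,
    dataset: Dataset,
    catalogue: dict[str, dict[str, AlleleSequence]],
    pond: str,
) -> tuple[list[Individual], list[Individual], np.ndarray]:
    """Per-pond female x male mate-choice weight matrix under the model."""
    females = dataset.females(pond)
    males = dataset.males(pond)
    log_w = np.zeros((len(females), len(males)))
    use_het = config.preference in ("heterozygote", "mixed")
    use_comp = config.preference in ("compatibility", "mixed")
    if use_het and config.beta != 0.0:
        if config.preference_locus is None:
            het = np.array(
                [sum(g.is_heterozygous for g in m.mhc) for m in males], dtype=float
            )
        else:
            locus = dataset.mhc_loci[config.preference_locus]
            het = np.array(
                [float(m.mhc_at(locus).is_heterozygous) for m in males]
            )
        log_w += config.beta * het[None, :]
    if use_comp and config.gamma != 0.0:
        ztable = mhcdist.load_zscales()
        func = np.zeros_like(log_w)
        for locus in dataset.mhc_loci:
            mat = mhcdist.allele_distance_matrix(
                catalogue[locus], "functional", ztable=ztable
            )
            for i, f in enumerate(females):
                for j, m in enumerate(males):
                    func[i, j] += mhcdist.pair_mhc_distance(
                        f.mhc_at(locus), m.mhc_at(locus), mat
                    )
        log_w += config.gamma * func
    w = np.exp(log_w - log_w.max(axis=1, keepdims=True))
    return females, males, w / w.sum(axis=1, keepdims=True)


def generate_matings(
    dataset: Dataset,
    catalogue: dict[str, dict[str, AlleleSequence]],
    config: GeneratorConfig,
    seed: Optional[int] = None,
    include_offspring: bool = True,
) -> tuple[list[MatingPair], list[TrioRecord], dict]:
    """Simulate clutches (pairs), offspring trios and the choice truth.

    Clutches are allocated to ponds proportionally to their female counts;
    each clutch draws its female uniformly with replacement and her male
    from the preference model.  Returns one :class:`MatingPair` per clutch.
    """
    if seed is None:
        seed = config.seed + 1_000_003
    rng = np.random.default_rng(seed)
    ponds = dataset.ponds
    n_females = np.array([len(dataset.females(p)) for p in ponds], dtype=float)
    alloc = np.floor(config.n_clutches * n_females / n_females.sum()).astype(int)
    remainder = config.n_clutches - alloc.sum()
    # largest-remainder allocation of the leftover clutches
    frac = config.n_clutches * n_females / n_females.sum() - alloc
    for idx in np.argsort(-frac)[:remainder]:
        alloc[idx] += 1

    pairs: list[MatingPair] = []
    trios: list[TrioRecord] = []
    choice_probs: dict[str, list[list[float]]] = {}
    offspring_counter = 0
    allele_pools = _allele_pools(dataset) if include_offspring else {}
    for pond, n_clutch in zip(ponds, alloc):
        females, males, weights = _choice_weights(config, dataset, catalogue, pond)
        choice_probs[pond] = weights.tolist()
        for _ in range(int(n_clutch)):
            fi = int(rng.integers(0, len(females)))
            mi = int(rng.choice(len(males), p=weights[fi]))
            female, male = females[fi], males[mi]
            n_off = int(rng.poisson(config.clutch_lambda))
            pairs.append(MatingPair(female.id, male.id, pond, n_off))
            if include_offspring:
                for _ in range(n_off):
                    offspring_counter += 1
                    trios.append(
                        _make_trio(
                            f"O{offspring_counter:05d}", female, male, rng,
                            config.noise_rate, allele_pools,
                        )
                    )
    truth = {
        "seed": seed,
        "preference": config.preference,
        "beta": config.beta,
        "gamma": config.gamma,
        "choice_probabilities": choice_probs,
        "clutch_allocation": dict(zip(ponds, map(int, alloc))),
    }
    return pairs, trios, truth


def _allele_pools(dataset: Dataset) -> dict[str, list[str]]:
    pools: dict[str, list[str]] = {}
    for ind in dataset.individuals:
        for g in list(ind.microsat) + list(ind.mhc):
            if not g.is_missing:
                pool = pools.setdefault(g.locus_id, [])
                for a in map(str, g.alleles()):
                    if a not in pool:
                        pool.append(a)
    return pools


def _make_trio(
    offspring_id: str,
    mother: Individual,
    father: Individual,
    rng: np.random.Generator,
    noise_rate: float,
    allele_pools: dict[str, list[str]],
) -> TrioRecord:
    """Mendelian offspring trio, with optional per-allele mistyping noise."""
    genotypes: dict[str, dict[str, tuple[Optional[str], Optional[str]]]] = {
        "offspring": {}, "mother": {}, "father": {},
    }
    for gm, gf in zip(
        list(mother.microsat) + list(mother.mhc),
        list(father.microsat) + list(father.mhc),
    ):
        locus = gm.locus_id
        a = str(gm.alleles()[rng.integers(0, 2)])
        b = str(gf.alleles()[rng.integers(0, 2)])
        if noise_rate > 0.0:
            pool = allele_pools[locus]
            if rng.random() < noise_rate and len(pool) > 1:
                a = str(pool[rng.integers(0, len(pool))])
            if rng.random() < noise_rate and len(pool) > 1:
                b = str(pool[rng.integers(0, len(pool))])
        genotypes["offspring"][locus] = (a, b)
        genotypes["mother"][locus] = tuple(map(str, gm.alleles()))
        genotypes["father"][locus] = tuple(map(str, gf.alleles()))
    return TrioRecord(offspring_id, mother.id, father.id, genotypes)


def generate_dataset(config: GeneratorConfig, include_offspring: bool = True) -> SyntheticData:
    """One self-contained synthetic study: adults, alleles, pairs, trios."""
    dataset, catalogue, truth_pop = generate_population(config)
    pairs, trios, truth_mat = generate_matings(
        dataset, catalogue, config, include_offspring=include_offspring
    )
    return SyntheticData(
        dataset, catalogue, pairs, trios,
        {"population": truth_pop, "matings": truth_mat},
    )


def clutches_frame(pairs: Sequence[MatingPair], dataset: Dataset, locus: str):
    """Clutch table (male_id, zygosity, count) for the reproductive model."""
    import pandas as pd

    rows = []
    for p in pairs:
        g = dataset[p.male_id].mhc_at(locus)
        if g.is_missing:
            continue
        rows.append(
            {
                "male_id": p.male_id,
                "zygosity": int(g.is_heterozygous),
                "count": p.n_offspring,
            }
        )
    return pd.DataFrame(rows)
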