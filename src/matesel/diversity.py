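"""Individual-level genetic diversity indices.

These are the statistics used to test the good-gene and the
heterozygosity-advantage hypotheses of mate choice:

* ``SH`` — standardised heterozygosity: an individual's proportion of
  heterozygous typed microsatellite loci divided by the mean population
  observed heterozygosity of those same loci, so the population mean of SH
  over fully typed individuals is ~1.
* ``HL`` — heterozygosity by locus: sum of expected heterozygosities
  (``E_l = 1 - sum_k p_lk^2``) over the individual's homozygous loci divided
  by the sum over all its typed loci; 0 = fully heterozygous, 1 = fully
  homozygous.
* ``IR`` — internal relatedness: ``(2H - sum f_i) / (2N - sum f_i)`` with
  ``H`` homozygous loci, ``N`` typed loci, ``f_i`` the reference frequency of
  each of the 2N allele copies carried.
* ``d2`` — mean squared difference between an individual's two allele
  lengths, in repeat units by default, a proxy for parental divergence.
* ``Ho`` — proportion of MHC-heterozygous males in a male set.
* ``AF`` — a male's summed carried-allele frequency at an MHC locus, the
  good-gene score (a homozygote for an allele of frequency p scores 2p).

Frequency-based indices take an allele-frequency table estimated by gene
counting from a declared reference population (by default all adults).
Undefined values (zero denominators) are returned as ``None``, never as a
silent 0.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import Dataset, Individual

__all__ = [
    "allele_frequencies",
    "observed_heterozygosity",
    "standardized_heterozygosity",
    "heterozygosity_by_locus",
    "internal_relatedness",
    "mean_d2",
    "mhc_het_proportion",
    "good_gene_score",
    "diversity_profiles",
]

AlleleFrequencyTable = dict[str, dict[object, float]]


def _typed_genotypes(individuals: Iterable[Individual]):
    for ind in individuals:
        for g in list(ind.microsat) + list(ind.mhc):
            if not g.is_missing:
                yield g


def allele_frequencies(individuals: Sequence[Individual]) -> AlleleFrequencyTable:
    """Gene-counting allele frequencies per locus over a reference population.

    Each typed diploid contributes two allele copies; missing genotypes are
    excluded from the denominator.  Raises for a locus in the panel at which
    no individual is typed.
    """
    counts: dict[str, dict[object, int]] = {}
    panel: list[str] = []
    for ind in individuals:
        for g in list(ind.microsat) + list(ind.mhc):
            if g.locus_id not in panel:
                panel.append(g.locus_id)
    for g in _typed_genotypes(individuals):
        bucket = counts.setdefault(g.locus_id, {})
        for a in g.alleles():
            bucket[a] = bucket.get(a, 0) + 1
    for locus in panel:
        if locus not in counts:
            raise ValueError(f"locus {locus!r}: no typed individuals")
    return {
        locus: {a: n / sum(bucket.values()) for a, n in bucket.items()}
        for locus, bucket in counts.items()
    }


def observed_heterozygosity(individuals: Sequence[Individual]) -> dict[str, float]:
    """Observed heterozygosity per locus (fraction of typed heterozygotes)."""
    het: dict[str, int] = {}
    typed: dict[str, int] = {}
    for g in _typed_genotypes(individuals):
        typed[g.locus_id] = typed.get(g.locus_id, 0) + 1
        if g.is_heterozygous:
            het[g.locus_id] = het.get(g.locus_id, 0) + 1
    return {locus: het.get(locus, 0) / n for locus, n in typed.items()}


def standardized_heterozygosity(
    ind: Individual, pop_ho: dict[str, float]
) -> Optional[float]:
    """SH: individual heterozygosity scaled by mean population Ho.

    ``pop_ho`` is per-locus population observed heterozygosity (see
    :func:`observed_heterozygosity`); only the individual's typed
    microsatellite loci enter either side of the ratio.  Returns ``None``
    when the population is monomorphic at all of the individual's typed loci.
    """
    typed = [g for g in ind.microsat if not g.is_missing]
    if not typed:
        return None
    prop_het = sum(g.is_heterozygous for g in typed) / len(typed)
    mean_ho = sum(pop_ho.get(g.locus_id, 0.0) for g in typed) / len(typed)
    if mean_ho == 0.0:
        return None
    return prop_het / mean_ho


def heterozygosity_by_locus(
    ind: Individual, freqs: AlleleFrequencyTable
) -> Optional[float]:
    """HL: expected-heterozygosity-weighted homozygosity in [0, 1]."""
    e_hom = 0.0
    e_het = 0.0
    typed = 0
    for g in ind.microsat:
        if g.is_missing:
            continue
        typed += 1
        e_l = 1.0 - sum(p * p for p in freqs[g.locus_id].values())
        if g.is_heterozygous:
            e_het += e_l
        else:
            e_hom += e_l
    if typed == 0 or (e_hom + e_het) == 0.0:
        return None
    return e_hom / (e_hom + e_het)


def internal_relatedness(
    ind: Individual, freqs: AlleleFrequencyTable
) -> Optional[float]:
    """IR: allele-frequency-weighted homozygosity; positive = inbred-like."""
    n_typed = 0
    n_hom = 0
    f_sum = 0.0
    for g in ind.microsat:
        if g.is_missing:
            continue
        n_typed += 1
        if not g.is_heterozygous:
            n_hom += 1
        for a in g.alleles():
            f_sum += freqs[g.locus_id][a]
    if n_typed == 0:
        return None
    denom = 2 * n_typed - f_sum
    if denom == 0.0:
        return None
    return (2 * n_hom - f_sum) / denom


def mean_d2(ind: Individual, unit: str = "repeats") -> Optional[float]:
    """Mean squared allele-length difference over typed microsatellite loci.

    ``unit="repeats"`` (default) divides the base-pair difference by the
    locus motif length before squaring; ``unit="bp"`` uses raw sizes.
    """
    if unit not in ("repeats", "bp"):
        raise ValueError(f"unknown d2 unit {unit!r}")
    total = 0.0
    n = 0
    for g in ind.microsat:
        if g.is_missing:
            continue
        diff = float(g.allele_a - g.allele_b)  # type: ignore[operator]
        if unit == "repeats":
            diff /= g.motif_length
        total += diff * diff
        n += 1
    if n == 0:
        return None
    return total / n


def mhc_het_proportion(males: Sequence[Individual], locus: str) -> float:
    """Ho: proportion of males heterozygous at one MHC locus.

    Computed over the given male set (typed individuals only); the caller
    decides the basis (unique breeding males vs pair-weighted).
    """
    typed = [m for m in males if not m.mhc_at(locus).is_missing]
    if not typed:
        raise ValueError(f"locus {locus!r}: empty or fully untyped male set")
    return sum(m.mhc_at(locus).is_heterozygous for m in typed) / len(typed)


def good_gene_score(
    male: Individual,
    freqs: AlleleFrequencyTable,
    locus: str,
    definition: str = "carried_sum",
) -> float:
    """AF: good-gene score of a male at one MHC locus.

    ``carried_sum`` (default) sums the reference frequencies of the male's
    two allele copies (range [0, 2]); ``carried_mean`` halves that.
    """
    g = male.mhc_at(locus)
    total = sum(freqs[locus][a] for a in g.alleles())
    if definition == "carried_sum":
        return total
    if definition == "carried_mean":
        return total / 2.0
    raise ValueError(f"unknown AF definition {definition!r}")


def diversity_profiles(
    dataset: Dataset,
    *,
    reference: Optional[Sequence[Individual]] = None,
    d2_unit: str = "repeats",
) -> pd.DataFrame:
    """One row per individual with SH, HL, IR, d2 and per-locus MHC het flags.

    The reference population for frequency-based indices defaults to all
    adults in the dataset (both sexes, all ponds).
    """
    reference = list(reference) if reference is not None else dataset.individuals
    freqs = allele_frequencies(reference)
    pop_ho = observed_heterozygosity(reference)
    rows = []
    for ind in dataset.individuals:
        row: dict[str, object] = {
            "id": ind.id,
            "sex": ind.sex,
            "pond": ind.pond,
            "SH": standardized_heterozygosity(ind, pop_ho),
            "HL": heterozygosity_by_locus(ind, freqs),
            "IR": internal_relatedness(ind, freqs),
            "d2": mean_d2(ind, unit=d2_unit),
        }
        for locus in dataset.mhc_loci:
            g = ind.mhc_at(locus)
            row[f"het_{locus}"] = None if g.is_missing else g.is_heterozygous
        rows.append(row)
    return pd.DataFrame(rows)
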