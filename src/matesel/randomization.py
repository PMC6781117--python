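"""Stratified Monte-Carlo randomisation tests of the mate-choice hypotheses.

The null model: within each breeding pond, a female and a male are drawn
uniformly and independently with replacement, and as many random pairs are
formed per pond as there are true mating pairs in that pond.  Pooling the
ponds gives one replicate whose mean statistic is recorded; repeating
(default 9999 times) yields the null distribution.  The observed mean of
the true pairs is then tested two-tailed: the empirical p-value uses the
add-one rule ``p = 2 min(#{null <= obs}+1, #{null >= obs}+1) / (n_iter+1)``
(capped at 1) and the significance decision follows the 95 percent CI rule
(observed outside the null's 2.5-97.5 percentile band).

Statistics come in two modes.  Pair statistics (allele sharing, amino-acid
and functional distances, relatedness) are evaluated on each sampled
female x male pair.  Male statistics (AF, SH, d2, Ho) are evaluated on the
male of each sampled pair, so males are weighted by pond pair counts;
for Ho the suite instead uses the unique-male basis on both the observed
and the null side (each replicate computes the heterozygote fraction over
the distinct males it sampled), keeping the decision rule calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import diversity, mhcdist, relatedness
from .types import AlleleSequence, Dataset, Individual, MatingPair

__all__ = [
    "StratifiedDesign",
    "RandomizationResult",
    "PairStatistic",
    "MaleStatistic",
    "sample_null_pairs",
    "randomize",
    "run_hypothesis_suite",
]


@dataclass
class StratifiedDesign:
    """Per-pond pair counts and candidate pools for the stratified null."""

    pair_counts: dict[str, int]
    females: dict[str, list[Individual]]
    males: dict[str, list[Individual]]

    @classmethod
    def from_data(cls, dataset: Dataset, pairs: Sequence[MatingPair]) -> "StratifiedDesign":
        counts: dict[str, int] = {}
        for p in pairs:
            counts[p.pond] = counts.get(p.pond, 0) + 1
        females = {pond: dataset.females(pond) for pond in counts}
        males = {pond: dataset.males(pond) for pond in counts}
        for pond, n in counts.items():
            if n >= 1 and (not females[pond] or not males[pond]):
                raise ValueError(
                    f"pond {pond!r} has {n} true pairs but no candidate "
                    f"{'females' if not females[pond] else 'males'}"
                )
        return cls(counts, females, males)

    @property
    def n_pairs(self) -> int:
        return sum(self.pair_counts.values())


@dataclass
class RandomizationResult:
    """Observed mean, null sample, empirical p and the CI decision."""

    statistic: str
    observed: float
    null: np.ndarray
    p: float
    ci_low: float
    ci_high: float
    significant: bool
    n_iter: int
    seed: Optional[int]

    def summary(self) -> dict[str, object]:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "null_mean": float(np.mean(self.null)),
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "significant": self.significant,
            "n_iter": self.n_iter,
        }


class PairStatistic:
    """A statistic evaluated on a female x male pair.

    Subclasses either override :meth:`evaluate` (scalar per pair) or
    :meth:`pair_values` (full females x males value matrix for one pond).
    """

    name = "pair_statistic"

    def evaluate(self, female: Individual, male: Individual) -> float:
        raise NotImplementedError

    def pair_values(
        self, females: Sequence[Individual], males: Sequence[Individual]
    ) -> np.ndarray:
        out = np.empty((len(females), len(males)))
        for i, f in enumerate(females):
            for j, m in enumerate(males):
                v = self.evaluate(f, m)
                out[i, j] = np.nan if v is None else v
        return out


class MaleStatistic:
    """A statistic evaluated on the male of a pair.

    ``basis="pairs"`` weights males by how often they are sampled;
    ``basis="unique_males"`` computes each replicate's mean over the
    distinct males sampled (the convention used for Ho).
    """

    name = "male_statistic"
    basis = "pairs"

    def evaluate(self, male: Individual) -> float:
        raise NotImplementedError

    def male_values(self, males: Sequence[Individual]) -> np.ndarray:
        return np.array(
            [np.nan if (v := self.evaluate(m)) is None else v for m in males],
            dtype=float,
        )


class CallablePairStatistic(PairStatistic):
    def __init__(self, name: str, fn: Callable[[Individual, Individual], float]):
        self.name = name
        self._fn = fn

    def evaluate(self, female: Individual, male: Individual) -> float:
        return self._fn(female, male)


class CallableMaleStatistic(MaleStatistic):
    def __init__(
        self, name: str, fn: Callable[[Individual], float], basis: str = "pairs"
    ):
        self.name = name
        self._fn = fn
        self.basis = basis

    def evaluate(self, male: Individual) -> float:
        return self._fn(male)


def sample_null_pairs(
    design: StratifiedDesign, rng: np.random.Generator
) -> list[tuple[Individual, Individual]]:
    """Draw one replicate's random pair list (with replacement, per pond)."""
    out: list[tuple[Individual, Individual]] = []
    for pond, n in design.pair_counts.items():
        fi = rng.integers(0, len(design.females[pond]), size=n)
        mi = rng.integers(0, len(design.males[pond]), size=n)
        out.extend(
            (design.females[pond][i], design.males[pond][j]) for i, j in zip(fi, mi)
        )
    return out


def _dedup(pairs: Sequence[MatingPair]) -> list[MatingPair]:
    seen: set[tuple[str, str]] = set()
    out: list[MatingPair] = []
    for p in pairs:
        key = (p.female_id, p.male_id)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def randomize(
    statistic: PairStatistic | MaleStatistic,
    design: StratifiedDesign,
    dataset: Dataset,
    pairs: Sequence[MatingPair],
    n_iter: int = 9999,
    seed: Optional[int] = None,
    dedup_pairs: bool = True,
) -> RandomizationResult:
    """Stratified randomisation test of one statistic.

    Deterministic given (data, statistic, n_iter, seed).  Replicates in
    which the statistic is undefined on some sampled pairs drop those pairs
    from the replicate mean (NaN-aware means).
    """
    rng = np.random.default_rng(seed)
    ponds = list(design.pair_counts)

    if isinstance(statistic, PairStatistic):
        matrices = {
            pond: statistic.pair_values(design.females[pond], design.males[pond])
            for pond in ponds
        }
        true_pairs = _dedup(pairs) if dedup_pairs else list(pairs)
        obs_vals = []
        for p in true_pairs:
            v = statistic.evaluate(dataset[p.female_id], dataset[p.male_id])
            obs_vals.append(np.nan if v is None else v)
        observed = float(np.nanmean(obs_vals))
        null_sum = np.zeros(n_iter)
        null_n = np.zeros(n_iter)
        for pond in ponds:
            n = design.pair_counts[pond]
            fi = rng.integers(0, matrices[pond].shape[0], size=(n_iter, n))
            mi = rng.integers(0, matrices[pond].shape[1], size=(n_iter, n))
            vals = matrices[pond][fi, mi]
            null_sum += np.nansum(vals, axis=1)
            null_n += np.sum(~np.isnan(vals), axis=1)
        null = null_sum / null_n
    else:
        vectors = {pond: statistic.male_values(design.males[pond]) for pond in ponds}
        if statistic.basis == "unique_males":
            observed = _unique_male_mean(statistic, dataset, pairs)
            null = _null_unique_male(design, vectors, n_iter, rng)
        else:
            obs_vals = []
            for p in pairs:
                v = statistic.evaluate(dataset[p.male_id])
                obs_vals.append(np.nan if v is None else v)
            observed = float(np.nanmean(obs_vals))
            null_sum = np.zeros(n_iter)
            null_n = np.zeros(n_iter)
            for pond in ponds:
                n = design.pair_counts[pond]
                mi = rng.integers(0, len(vectors[pond]), size=(n_iter, n))
                vals = vectors[pond][mi]
                null_sum += np.nansum(vals, axis=1)
                null_n += np.sum(~np.isnan(vals), axis=1)
            null = null_sum / null_n

    n_le = int(np.sum(null <= observed))
    n_ge = int(np.sum(null >= observed))
    p = min(1.0, 2.0 * min(n_le + 1, n_ge + 1) / (n_iter + 1))
    ci_low, ci_high = np.percentile(null, [2.5, 97.5])
    significant = bool(observed < ci_low or observed > ci_high)
    return RandomizationResult(
        statistic.name, observed, null, p, float(ci_low), float(ci_high),
        significant, n_iter, seed,
    )


def _unique_male_mean(
    statistic: MaleStatistic, dataset: Dataset, pairs: Sequence[MatingPair]
) -> float:
    male_ids = sorted({p.male_id for p in pairs})
    vals = [statistic.evaluate(dataset[m]) for m in male_ids]
    return float(np.nanmean([np.nan if v is None else v for v in vals]))


def _null_unique_male(
    design: StratifiedDesign,
    vectors: dict[str, np.ndarray],
    n_iter: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per replicate, mean of the statistic over the distinct males sampled."""
    total = np.zeros(n_iter)
    count = np.zeros(n_iter)
    rows = np.arange(n_iter)[:, None]
    for pond, n in design.pair_counts.items():
        v = vectors[pond]
        mi = rng.integers(0, len(v), size=(n_iter, n))
        occupied = np.zeros((n_iter, len(v)), dtype=bool)
        occupied[rows, mi] = True
        valid = occupied & ~np.isnan(v)[None, :]
        total += valid @ np.nan_to_num(v)
        count += valid.sum(axis=1)
    return total / count


def suite_statistics(
    dataset: Dataset,
    catalogue: dict[str, dict[str, AlleleSequence]],
    *,
    d2_unit: str = "repeats",
    aa_model: str = "p",
    ho_basis: str = "unique_males",
) -> list[PairStatistic | MaleStatistic]:
    """The full battery of mate-choice statistics tested by the suite."""
    freqs = diversity.allele_frequencies(dataset.individuals)
    pop_ho = diversity.observed_heterozygosity(dataset.individuals)
    ztable = mhcdist.load_zscales()
    stats: list[PairStatistic | MaleStatistic] = []

    for locus in dataset.mhc_loci:
        stats.append(
            CallableMaleStatistic(
                f"AF_{locus}",
                lambda m, loc=locus: diversity.good_gene_score(m, freqs, loc),
            )
        )
    stats.append(
        CallableMaleStatistic("d2", lambda m: diversity.mean_d2(m, unit=d2_unit))
    )
    stats.append(
        CallableMaleStatistic(
            "SH", lambda m: diversity.standardized_heterozygosity(m, pop_ho)
        )
    )
    for locus in dataset.mhc_loci:
        stats.append(
            CallableMaleStatistic(
                f"Ho_{locus}",
                lambda m, loc=locus: float(m.mhc_at(loc).is_heterozygous)
                if not m.mhc_at(loc).is_missing
                else None,
                basis=ho_basis,
            )
        )
    for locus in dataset.mhc_loci:
        aa_mat = mhcdist.allele_distance_matrix(catalogue[locus], "aa", model=aa_model)
        fn_mat = mhcdist.allele_distance_matrix(
            catalogue[locus], "functional", ztable=ztable
        )
        stats.append(
            CallablePairStatistic(
                f"AAdist_{locus}",
                lambda f, m, loc=locus, mat=aa_mat: mhcdist.pair_mhc_distance(
                    f.mhc_at(loc), m.mhc_at(loc), mat
                ),
            )
        )
        stats.append(
            CallablePairStatistic(
                f"AAfunc.dist_{locus}",
                lambda f, m, loc=locus, mat=fn_mat: mhcdist.pair_mhc_distance(
                    f.mhc_at(loc), m.mhc_at(loc), mat
                ),
            )
        )
        stats.append(
            CallablePairStatistic(
                f"Nsa_{locus}",
                lambda f, m, loc=locus: float(
                    mhcdist.allele_sharing(f.mhc_at(loc), m.mhc_at(loc))
                ),
            )
        )
    stats.append(
        CallablePairStatistic(
            "Rqg", lambda f, m: relatedness.relatedness_qg(f, m, freqs)
        )
    )
    return stats


def run_hypothesis_suite(
    dataset: Dataset,
    pairs: Sequence[MatingPair],
    catalogue: dict[str, dict[str, AlleleSequence]],
    n_iter: int = 9999,
    seed: Optional[int] = None,
    **stat_kwargs: object,
) -> tuple[pd.DataFrame, dict[str, RandomizationResult]]:
    """Run every mate-choice statistic through the stratified null.

    Returns a summary table (one row per statistic: observed, null mean,
    CI, empirical p, significance) plus the full results keyed by name.
    No multiple-testing correction is applied; the table length tells the
    reader how many tests were run.
    """
    design = StratifiedDesign.from_data(dataset, pairs)
    stats = suite_statistics(dataset, catalogue, **stat_kwargs)  # type: ignore[arg-type]
    seeds = np.random.SeedSequence(seed).generate_state(len(stats))
    results: dict[str, RandomizationResult] = {}
    for stat, s in zip(stats, seeds):
        results[stat.name] = randomize(
            stat, design, dataset, pairs, n_iter=n_iter, seed=int(s)
        )
    table = pd.DataFrame([r.summary() for r in results.values()])
    return table, results
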