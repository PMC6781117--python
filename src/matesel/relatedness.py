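"""Pairwise relatedness estimators from codominant marker genotypes.

Three moment estimators are provided, all referenced to a declared
population allele-frequency table and all returning values that are ~0 for
unrelated dyads, ~0.5 for parent-offspring or full sibs and ~1 for
identical genotypes drawn from the same individual:

* Queller-Goodnight (``r_qg``, the primary estimator here): for a focal
  individual with alleles a,b and a partner with c,d, the locus numerator
  is ``0.5(I_ac + I_ad + I_bc + I_bd) - p_a - p_b`` and the denominator
  ``1 + I_ab - p_a - p_b`` (I = allele identity indicators); numerators and
  denominators are summed over loci before dividing, and the estimate is
  symmetrised by averaging the two focal choices.
* Wang's joint-genotype moment estimator (``r_wang``): each locus assigns
  the dyad to one of four similarity categories (identical genotypes;
  homozygote vs heterozygote sharing its allele; heterozygotes sharing one
  allele; no sharing).  The category probabilities are linear in the two
  identity coefficients (Delta: both allele pairs identical by descent;
  phi: exactly one pair), with coefficients that are polynomials b-g in the
  allele-frequency power sums a2, a3, a4.  The coefficients are solved by
  generalised least squares weighted by the null multinomial covariance,
  and ``r = Delta + phi/2``.
* Lynch-Ritland (``r_lr``): the regression estimator with its published
  locus weights, symmetrised across the focal choice.

Loci where either individual is untyped are dropped pairwise; monomorphic
loci carry no information and are skipped.  ``None`` is returned when no
informative locus remains.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diversity import AlleleFrequencyTable
from .types import Individual

__all__ = [
    "relatedness_qg",
    "relatedness_wang",
    "relatedness_lr",
    "relatedness_table",
]


def _shared_loci(x: Individual, y: Individual, freqs: AlleleFrequencyTable):
    """Yield (x-genotype, y-genotype, locus frequencies) at informative loci."""
    y_by_locus = {g.locus_id: g for g in y.microsat if not g.is_missing}
    for gx in x.microsat:
        if gx.is_missing or gx.locus_id not in y_by_locus:
            continue
        p = freqs[gx.locus_id]
        if len(p) < 2 or max(p.values()) >= 1.0 - 1e-12:
            continue  # monomorphic: no information
        yield gx.alleles(), y_by_locus[gx.locus_id].alleles(), p


def relatedness_qg(
    x: Individual, y: Individual, freqs: AlleleFrequencyTable
) -> Optional[float]:
    """Queller-Goodnight relatedness, symmetrised over the focal choice."""
    num_x = den_x = num_y = den_y = 0.0
    informative = 0
    for (a, b), (c, d), p in _shared_loci(x, y, freqs):
        informative += 1
        sim = 0.5 * ((a == c) + (a == d) + (b == c) + (b == d))
        num_x += sim - p[a] - p[b]
        den_x += 1.0 + (a == b) - p[a] - p[b]
        num_y += sim - p[c] - p[d]
        den_y += 1.0 + (c == d) - p[c] - p[d]
    if informative == 0 or den_x == 0.0 or den_y == 0.0:
        return None
    return 0.5 * (num_x / den_x + num_y / den_y)


def _wang_category(a: str, b: str, c: str, d: str) -> int:
    """Similarity category of a dyad's genotypes {a,b} vs {c,d} (1..4)."""
    g1, g2 = tuple(sorted((a, b))), tuple(sorted((c, d)))
    if g1 == g2:
        return 1
    shared = len(set(g1) & set(g2))
    hom1, hom2 = g1[0] == g1[1], g2[0] == g2[1]
    if shared == 0:
        return 4
    if hom1 or hom2:
        # one homozygote whose allele appears in the other genotype
        return 2 if ((hom1 and g1[0] in g2) or (hom2 and g2[0] in g1)) else 4
    return 3


def relatedness_wang(
    x: Individual, y: Individual, freqs: AlleleFrequencyTable
) -> Optional[float]:
    """Wang's (2002-style) joint-genotype moment estimator of relatedness."""
    ys: list[np.ndarray] = []
    designs: list[np.ndarray] = []
    covs: list[np.ndarray] = []
    weights: list[float] = []
    for (a, b), (c, d), p in _shared_loci(x, y, freqs):
        pv = np.array(list(p.values()))
        a2 = float(np.sum(pv**2))
        a3 = float(np.sum(pv**3))
        a4 = float(np.sum(pv**4))
        bb = 2.0 * a2**2 - a4
        cc = a2 - bb
        dd = 4.0 * (a3 - a4)
        ee = 2.0 * (a2 - 3.0 * a3 + 2.0 * a4)
        ff = 4.0 * (a2 - a2**2 - 2.0 * a3 + 2.0 * a4)
        gg = 1.0 - 7.0 * a2 + 4.0 * a2**2 + 10.0 * a3 - 8.0 * a4
        cat = _wang_category(str(a), str(b), str(c), str(d))
        indicator = np.array([cat == 1, cat == 2, cat == 3], dtype=float)
        ys.append(indicator - np.array([bb, dd, ff]))
        designs.append(np.array([[1.0 - bb, cc], [-dd, ee], [-ff, gg]]))
        q = np.array([bb, dd, ff])
        covs.append(np.diag(q) - np.outer(q, q))
        u = 2.0 * a2 - a4  # locus information weight (Wang's 1/u weighting)
        weights.append(1.0 / u)
    if not ys:
        return None
    w = np.array(weights)
    w /= w.sum()
    ybar = np.sum([wi * yi for wi, yi in zip(w, ys)], axis=0)
    abar = np.sum([wi * ai for wi, ai in zip(w, designs)], axis=0)
    cov = np.sum([wi**2 * ci for wi, ci in zip(w, covs)], axis=0)
    winv = np.linalg.pinv(cov)
    lhs = abar.T @ winv @ abar
    rhs = abar.T @ winv @ ybar
    try:
        delta, phi = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError:
        delta, phi = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
    return float(delta + phi / 2.0)


def _lr_one_way(fa, fb, ma, mb, p) -> Optional[tuple[float, float]]:
    """Lynch-Ritland locus estimate and weight with (fa, fb) as reference."""
    pa, pb = p[fa], p[fb]
    s_ab = float(fa == fb)
    denom = (1.0 + s_ab) * (pa + pb) - 4.0 * pa * pb
    if denom == 0.0:
        return None
    num = (
        pa * ((fb == ma) + (fb == mb))
        + pb * ((fa == ma) + (fa == mb))
        - 4.0 * pa * pb
    )
    weight = denom / (2.0 * pa * pb)
    return num / denom, weight


def relatedness_lr(
    x: Individual, y: Individual, freqs: AlleleFrequencyTable
) -> Optional[float]:
    """Lynch-Ritland regression relatedness, symmetrised over focal choice."""
    estimates = []
    for focal_first in (True, False):
        num = 0.0
        den = 0.0
        for (a, b), (c, d), p in _shared_loci(x, y, freqs):
            if not focal_first:
                (a, b), (c, d) = (c, d), (a, b)
            res = _lr_one_way(a, b, c, d, p)
            if res is None:
                continue
            r_l, w_l = res
            num += w_l * r_l
            den += w_l
        if den == 0.0:
            return None
        estimates.append(num / den)
    return 0.5 * (estimates[0] + estimates[1])


_ESTIMATORS = {
    "qg": relatedness_qg,
    "wang": relatedness_wang,
    "lr": relatedness_lr,
}


def relatedness_table(
    dyads: Sequence[tuple[Individual, Individual]],
    freqs: AlleleFrequencyTable,
    estimators: Sequence[str] = ("qg",),
) -> pd.DataFrame:
    """Relatedness estimates for a list of dyads, one row per dyad."""
    rows = []
    for x, y in dyads:
        row: dict[str, object] = {"id_x": x.id, "id_y": y.id}
        n_loci = sum(1 for _ in _shared_loci(x, y, freqs))
        row["n_loci_used"] = n_loci
        for name in estimators:
            row[f"r_{name}"] = _ESTIMATORS[name](x, y, freqs)
        rows.append(row)
    return pd.DataFrame(rows)
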