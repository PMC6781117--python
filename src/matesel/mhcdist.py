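"""Pair-compatibility statistics on MHC genotypes.

Three pairwise estimators address the compatible-gene hypothesis:

* ``Nsa`` — allele sharing between two diploid genotypes at one locus:
  0, 1 or 2 allele copies shared (size of a maximum matching between the
  two 2-allele multisets).
* ``AAdist`` — pairwise amino-acid distance: with the female carrying
  alleles A/a and the male B/b, ``AAdist = D(A,B) + D(A,b) + D(a,B) + D(a,b)``
  where D is a sequence distance between allele proteins (p-distance by
  default, Poisson-corrected optional).
* ``AAfunc.dist`` — same four-term sum with D replaced by a physiochemical
  distance: per aligned site, the Euclidean distance between the two
  residues' five z-descriptor vectors (Sandberg five-factor scales shipped
  as ``data/zscales.tsv``), averaged over sites by default.

Distances are computed per locus over the amplified exon fragment; no
implicit alignment is performed (allele proteins of one locus must already
be equal length).
"""

from __future__ import annotations

import math
from importlib import resources
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import AlleleSequence, MhcGenotype

__all__ = [
    "load_zscales",
    "aa_distance",
    "functional_distance",
    "allele_distance_matrix",
    "pair_mhc_distance",
    "allele_sharing",
]

ZScaleTable = dict[str, np.ndarray]


def load_zscales(path: Optional[str] = None) -> ZScaleTable:
    """Load the 20x5 amino-acid z-descriptor table (five-factor scales)."""
    if path is None:
        source = resources.files("matesel").joinpath("data/zscales.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    table = {
        str(r["residue"]): np.array([r[f"z{i}"] for i in range(1, 6)], dtype=float)
        for _, r in df.iterrows()
    }
    if len(table) != 20 or any(v.shape != (5,) for v in table.values()):
        raise ValueError("z-scale table must map exactly 20 residues to 5-vectors")
    return table


def aa_distance(protein1: str, protein2: str, model: str = "p") -> float:
    """Distance between two aligned allele proteins.

    ``model="p"``: proportion of differing sites.  ``model="poisson"``:
    ``-ln(1 - p)`` (infinite, flagged by ``math.inf``, when every site
    differs).
    """
    if len(protein1) != len(protein2):
        raise ValueError(
            f"alignment error: protein lengths differ ({len(protein1)} vs {len(protein2)})"
        )
    if not protein1:
        raise ValueError("empty protein sequences")
    p_diff = sum(a != b for a, b in zip(protein1, protein2)) / len(protein1)
    if model == "p":
        return p_diff
    if model == "poisson":
        if p_diff >= 1.0:
            return math.inf
        return -math.log(1.0 - p_diff)
    raise ValueError(f"unknown distance model {model!r}")


def functional_distance(
    protein1: str,
    protein2: str,
    ztable: ZScaleTable,
    *,
    normalize: bool = True,
    skip_ambiguous: bool = False,
) -> float:
    """Physiochemical distance between two aligned allele proteins.

    Per site, the Euclidean distance between the two residues' z-descriptor
    5-vectors; the allele-level value is the mean over sites (sum when
    ``normalize=False``).  Unknown residues raise, naming the position,
    unless ``skip_ambiguous`` drops the site from both numerator and
    denominator.
    """
    if len(protein1) != len(protein2):
        raise ValueError(
            f"alignment error: protein lengths differ ({len(protein1)} vs {len(protein2)})"
        )
    total = 0.0
    n_sites = 0
    for pos, (a, b) in enumerate(zip(protein1, protein2), start=1):
        if a not in ztable or b not in ztable:
            if skip_ambiguous:
                continue
            bad = a if a not in ztable else b
            raise ValueError(f"unknown residue {bad!r} at alignment position {pos}")
        total += float(np.linalg.norm(ztable[a] - ztable[b]))
        n_sites += 1
    if n_sites == 0:
        raise ValueError("no scorable sites")
    return total / n_sites if normalize else total


def allele_distance_matrix(
    alleles: dict[str, AlleleSequence],
    kind: str = "aa",
    *,
    model: str = "p",
    ztable: Optional[ZScaleTable] = None,
    normalize: bool = True,
) -> pd.DataFrame:
    """Symmetric allele-by-allele distance matrix for one locus.

    ``kind="aa"`` uses :func:`aa_distance` (with ``model``); ``kind="functional"``
    uses :func:`functional_distance` over ``ztable``.
    """
    names = list(alleles)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for a, b in combinations(names, 2):
        if kind == "aa":
            d = aa_distance(alleles[a].protein, alleles[b].protein, model=model)
        elif kind == "functional":
            if ztable is None:
                ztable = load_zscales()
            d = functional_distance(
                alleles[a].protein, alleles[b].protein, ztable, normalize=normalize
            )
        else:
            raise ValueError(f"unknown matrix kind {kind!r}")
        mat.loc[a, b] = mat.loc[b, a] = d
    mat.attrs["kind"] = kind
    mat.attrs["model"] = model if kind == "aa" else "zscale-euclidean"
    return mat


def pair_mhc_distance(
    female: MhcGenotype, male: MhcGenotype, matrix: pd.DataFrame
) -> float:
    """Four-term pair distance: sum of female-allele x male-allele distances.

    Symmetric under exchanging partners; zero iff every female allele is at
    distance 0 from every male allele.
    """
    fa = female.alleles()
    ma = male.alleles()
    for allele in set(fa) | set(ma):
        if allele not in matrix.index:
            raise KeyError(f"allele {allele!r} absent from distance matrix")
    return float(sum(matrix.loc[f, m] for f in fa for m in ma))


def allele_sharing(female: MhcGenotype, male: MhcGenotype) -> int:
    """Nsa: number of allele copies shared between two diploid genotypes.

    Size of a maximum matching between the two 2-allele multisets — each
    copy is matched at most once, so A/A vs A/B shares one copy.
    """
    male_pool = list(male.alleles())
    shared = 0
    for a in female.alleles():
        if a in male_pool:
            male_pool.remove(a)
            shared += 1
    return shared
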