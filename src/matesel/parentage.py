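"""Mendelian-consistency audit of assigned parent-offspring trios.

External likelihood tools assign parentage; this module only audits the
assignments: a locus is consistent when the offspring's two alleles can be
split one-from-mother, one-from-father (both orderings tried), and a trio
passes when its mismatching loci do not exceed ``max_mismatch`` (default 0,
the rule used for the two MHC loci; a small positive tolerance accommodates
the genotyping error rate allowed on the microsatellite panel).
Missing genotypes at an audited locus are skipped and reported, never
counted as mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .types import TrioRecord

__all__ = ["TrioVerdict", "locus_consistent", "trio_consistent", "audit_dataset"]


@dataclass
class TrioVerdict:
    offspring_id: str
    consistent: bool
    mismatching_loci: list[str] = field(default_factory=list)
    skipped_loci: list[str] = field(default_factory=list)


def locus_consistent(
    offspring: tuple[str, str], mother: tuple[str, str], father: tuple[str, str]
) -> bool:
    """Can the offspring genotype be one maternal plus one paternal allele?"""
    o1, o2 = offspring
    return (o1 in mother and o2 in father) or (o2 in mother and o1 in father)


def trio_consistent(
    trio: TrioRecord,
    loci: Optional[Sequence[str]] = None,
    max_mismatch: int = 0,
) -> TrioVerdict:
    """Audit one trio at the given loci (default: all loci in the record)."""
    loci = list(loci) if loci is not None else trio.loci()
    mismatches: list[str] = []
    skipped: list[str] = []
    for locus in loci:
        geno = {role: trio.genotypes[role].get(locus, (None, None)) for role in
                ("offspring", "mother", "father")}
        if any(g[0] is None for g in geno.values()):
            skipped.append(locus)
            continue
        if not locus_consistent(geno["offspring"], geno["mother"], geno["father"]):
            mismatches.append(locus)
    return TrioVerdict(
        trio.offspring_id,
        consistent=len(mismatches) <= max_mismatch,
        mismatching_loci=mismatches,
        skipped_loci=skipped,
    )


def audit_dataset(
    trios: Sequence[TrioRecord],
    loci: Optional[Sequence[str]] = None,
    max_mismatch: int = 0,
) -> pd.DataFrame:
    """Per-trio verdicts as a table; empty input gives an empty table.

    Columns: offspring id, pass/fail, comma-joined mismatching and skipped
    loci.  ``df.attrs["locus_mismatch_counts"]`` holds per-locus totals.
    """
    rows = []
    locus_counts: dict[str, int] = {}
    for trio in trios:
        verdict = trio_consistent(trio, loci, max_mismatch)
        for locus in verdict.mismatching_loci:
            locus_counts[locus] = locus_counts.get(locus, 0) + 1
        rows.append(
            {
                "offspring_id": verdict.offspring_id,
                "consistent": verdict.consistent,
                "mismatching_loci": ",".join(verdict.mismatching_loci),
                "skipped_loci": ",".join(verdict.skipped_loci),
            }
        )
    df = pd.DataFrame(
        rows, columns=["offspring_id", "consistent", "mismatching_loci", "skipped_loci"]
    )
    df.attrs["locus_mismatch_counts"] = locus_counts
    return df
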