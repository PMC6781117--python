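"""Readers and writers for the delimited tables and the allele FASTA.

Genotype tables are delimited text (TSV by default, comma accepted) with one
row per adult.  Microsatellite loci use two columns per locus (``L1_a``,
``L1_b``); a combined ``L1`` column holding ``"a/b"`` is accepted as a
dialect.  MHC loci use the same convention with allele names.  Missing
genotypes are encoded by a sentinel (default ``NA``).

MHC allele coding sequences come from FASTA with headers ``locus|allele``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .types import (
    AlleleSequence,
    Dataset,
    Individual,
    MatingPair,
    MhcGenotype,
    MicrosatGenotype,
    TrioRecord,
    validate_pairs,
)

__all__ = [
    "read_individuals",
    "write_individuals",
    "read_pairs",
    "write_pairs",
    "read_trios",
    "write_trios",
    "read_allele_fasta",
    "write_allele_fasta",
    "write_manifest",
]

MISSING = "NA"


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _split_combined(value: str, row: str, col: str) -> tuple[str, str]:
    parts = re.split(r"[/|]", value)
    if len(parts) != 2:
        raise ValueError(f"row {row!r}, column {col!r}: cannot parse genotype {value!r}")
    return parts[0].strip(), parts[1].strip()


def _locus_columns(columns: Sequence[str], prefix: str) -> list[str]:
    """Locus ids for columns named ``<locus>_a``/``<locus>_b`` or combined."""
    loci: list[str] = []
    for col in columns:
        if not col.startswith(prefix):
            continue
        base = col[:-2] if col.endswith(("_a", "_b")) else col
        if base not in loci:
            loci.append(base)
    return loci


def _cell_pair(
    row: pd.Series, locus: str, missing: str, row_id: str
) -> tuple[Optional[str], Optional[str]]:
    if f"{locus}_a" in row.index:
        a, b = str(row[f"{locus}_a"]).strip(), str(row[f"{locus}_b"]).strip()
    else:
        raw = str(row[locus]).strip()
        if raw == missing or raw.lower() == "nan":
            return None, None
        a, b = _split_combined(raw, row_id, locus)
    if a == missing or b == missing or a.lower() == "nan" or b.lower() == "nan":
        if (a == missing or a.lower() == "nan") != (b == missing or b.lower() == "nan"):
            raise ValueError(f"row {row_id!r}, locus {locus!r}: half-missing genotype")
        return None, None
    return a, b


def read_individuals(
    path: str | Path,
    *,
    missing: str = MISSING,
    motif_lengths: Optional[dict[str, int]] = None,
    microsat_prefix: str = "ms_",
    mhc_prefix: str = "mhc_",
) -> Dataset:
    """Load the adult genotype table into a :class:`Dataset`.

    Columns: ``id``, ``sex``, ``pond``, then per-locus genotype columns with
    the declared prefixes.  Duplicate ids are rejected; malformed allele
    sizes raise with the offending row and column named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    for required in ("id", "sex", "pond"):
        if required not in df.columns:
            raise ValueError(f"{path}: missing required column {required!r}")
    ms_loci = _locus_columns(df.columns, microsat_prefix)
    mhc_loci = _locus_columns(df.columns, mhc_prefix)
    motif_lengths = motif_lengths or {}

    dupes = df["id"][df["id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicated individual ids {sorted(set(dupes))}")

    individuals: list[Individual] = []
    for _, row in df.iterrows():
        ind_id = str(row["id"])
        ms: list[MicrosatGenotype] = []
        for locus in ms_loci:
            a, b = _cell_pair(row, locus, missing, ind_id)
            if a is None:
                alleles: tuple[Optional[int], Optional[int]] = (None, None)
            else:
                try:
                    alleles = (int(a), int(b))  # type: ignore[arg-type]
                except ValueError as exc:
                    raise ValueError(
                        f"row {ind_id!r}, column {locus!r}: "
                        f"non-integer allele size {a!r}/{b!r}"
                    ) from exc
            ms.append(
                MicrosatGenotype(
                    locus, alleles[0], alleles[1],
                    motif_length=motif_lengths.get(locus, 2),
                )
            )
        mhc: list[MhcGenotype] = []
        for locus in mhc_loci:
            a2, b2 = _cell_pair(row, locus, missing, ind_id)
            mhc.append(MhcGenotype(locus, a2, b2))
        individuals.append(
            Individual(ind_id, str(row["sex"]), str(row["pond"]), ms, mhc)
        )
    return Dataset(individuals, microsat_loci=ms_loci, mhc_loci=mhc_loci)


def write_individuals(dataset: Dataset, path: str | Path, *, missing: str = MISSING) -> None:
    path = Path(path)
    records = []
    for ind in dataset.individuals:
        rec: dict[str, object] = {"id": ind.id, "sex": ind.sex, "pond": ind.pond}
        for g in ind.microsat:
            rec[f"{g.locus_id}_a"] = missing if g.is_missing else g.allele_a
            rec[f"{g.locus_id}_b"] = missing if g.is_missing else g.allele_b
        for m in ind.mhc:
            rec[f"{m.locus_id}_a"] = missing if m.is_missing else m.allele_a
            rec[f"{m.locus_id}_b"] = missing if m.is_missing else m.allele_b
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, sep=_sep(path), index=False)


def read_pairs(path: str | Path, dataset: Dataset) -> list[MatingPair]:
    """Load the true mating-pair table and validate it against the adults."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    for required in ("female_id", "male_id", "pond", "n_offspring"):
        if required not in df.columns:
            raise ValueError(f"{path}: missing required column {required!r}")
    pairs = [
        MatingPair(
            str(r["female_id"]), str(r["male_id"]), str(r["pond"]), int(r["n_offspring"])
        )
        for _, r in df.iterrows()
    ]
    validate_pairs(pairs, dataset)
    return pairs


def write_pairs(pairs: Sequence[MatingPair], path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "female_id": p.female_id,
                "male_id": p.male_id,
                "pond": p.pond,
                "n_offspring": p.n_offspring,
            }
            for p in pairs
        ]
    ).to_csv(path, sep=_sep(path), index=False)


def read_trios(path: str | Path, *, missing: str = MISSING) -> list[TrioRecord]:
    """Load offspring/mother/father genotype trios.

    Columns: ``offspring_id``, ``mother_id``, ``father_id`` then, per locus,
    ``<locus>__offspring``, ``<locus>__mother``, ``<locus>__father`` holding
    ``a/b`` genotypes.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    roles = ("offspring", "mother", "father")
    loci: list[str] = []
    for col in df.columns:
        if "__" in col:
            locus = col.rsplit("__", 1)[0]
            if locus not in loci:
                loci.append(locus)
    trios: list[TrioRecord] = []
    for _, row in df.iterrows():
        genotypes: dict[str, dict[str, tuple[Optional[str], Optional[str]]]] = {
            role: {} for role in roles
        }
        for locus in loci:
            for role in roles:
                raw = str(row[f"{locus}__{role}"]).strip()
                if raw == missing or raw.lower() == "nan":
                    genotypes[role][locus] = (None, None)
                else:
                    genotypes[role][locus] = _split_combined(
                        raw, str(row["offspring_id"]), f"{locus}__{role}"
                    )
        trios.append(
            TrioRecord(
                str(row["offspring_id"]),
                str(row["mother_id"]),
                str(row["father_id"]),
                genotypes,
            )
        )
    return trios


def write_trios(trios: Sequence[TrioRecord], path: str | Path, *, missing: str = MISSING) -> None:
    path = Path(path)
    records = []
    for t in trios:
        rec: dict[str, object] = {
            "offspring_id": t.offspring_id,
            "mother_id": t.mother_id,
            "father_id": t.father_id,
        }
        for role in ("offspring", "mother", "father"):
            for locus, (a, b) in t.genotypes[role].items():
                rec[f"{locus}__{role}"] = missing if a is None else f"{a}/{b}"
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, sep=_sep(path), index=False)


def read_allele_fasta(
    path: str | Path, *, frame: int = 1, frames: Optional[dict[str, int]] = None
) -> dict[str, dict[str, AlleleSequence]]:
    """Load MHC allele coding sequences, translating each in its frame.

    Headers follow ``locus|allele``.  Returns ``{locus: {allele: record}}``.
    Sequences must be pure ACGT, a whole number of codons in the chosen
    frame, and translate without internal stop codons.
    """
    path = Path(path)
    frames = frames or {}
    catalogue: dict[str, dict[str, AlleleSequence]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"{path}: header {rec.id!r} is not 'locus|allele'")
        locus, allele = rec.id.split("|", 1)
        dna = str(rec.seq).upper()
        if re.search(r"[^ACGT]", dna):
            raise ValueError(f"allele {rec.id}: non-ACGT character in sequence")
        fr = frames.get(locus, frame)
        if fr not in (1, 2, 3):
            raise ValueError(f"locus {locus}: reading frame must be 1, 2 or 3")
        coding = dna[fr - 1 :]
        if len(coding) % 3 != 0:
            raise ValueError(
                f"allele {rec.id}: length {len(dna)} is not a whole number of "
                f"codons in frame {fr}"
            )
        protein = str(Seq(coding).translate())
        if "*" in protein.rstrip("*"):
            raise ValueError(f"allele {rec.id}: internal stop codon in translation")
        protein = protein.rstrip("*")
        bucket = catalogue.setdefault(locus, {})
        if allele in bucket:
            raise ValueError(f"duplicate allele {allele!r} at locus {locus!r}")
        bucket[allele] = AlleleSequence(allele, locus, dna, protein)
    return catalogue


def write_allele_fasta(
    catalogue: dict[str, dict[str, AlleleSequence]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for locus in catalogue:
            for allele, rec in catalogue[locus].items():
                fh.write(f">{locus}|{allele}\n{rec.dna}\n")


def write_manifest(path: str | Path, **entries: object) -> None:
    """Write a JSON run manifest (inputs, config, seed, versions)."""
    import matesel

    payload = {"matesel_version": matesel.__version__, **entries}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
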