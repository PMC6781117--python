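"""Domain types for the alligator mate-choice analyses.

The study population is a set of adult Chinese alligators kept in breeding
ponds that are physically isolated from one another, so mating can only
happen within a pond.  Every adult carries a multilocus microsatellite
genotype (allele sizes in base pairs) and a genotype at two MHC class I
exonic loci (allele names that resolve to coding sequences).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "MicrosatGenotype",
    "MhcGenotype",
    "Individual",
    "MatingPair",
    "AlleleSequence",
    "TrioRecord",
    "Dataset",
]


@dataclass(frozen=True)
class MicrosatGenotype:
    """Diploid genotype at one microsatellite locus.

    Allele sizes are PCR fragment lengths in base pairs; ``motif_length`` is
    the repeat-unit size of the locus (2-4 bp), needed to express allele
    differences in repeat units.  The pair (allele_a, allele_b) is unordered;
    ``None``/``None`` marks a missing genotype (distinct from a homozygote).
    """

    locus_id: str
    allele_a: Optional[int]
    allele_b: Optional[int]
    motif_length: int = 2

    def __post_init__(self) -> None:
        if (self.allele_a is None) != (self.allele_b is None):
            raise ValueError(
                f"locus {self.locus_id}: half-missing genotype "
                f"({self.allele_a}/{self.allele_b})"
            )
        for a in (self.allele_a, self.allele_b):
            if a is not None and a <= 0:
                raise ValueError(f"locus {self.locus_id}: allele size {a} <= 0")
        if self.motif_length <= 0:
            raise ValueError(f"locus {self.locus_id}: motif length must be positive")

    @property
    def is_missing(self) -> bool:
        return self.allele_a is None

    @property
    def is_heterozygous(self) -> bool:
        if self.is_missing:
            raise ValueError(f"locus {self.locus_id}: genotype missing")
        return self.allele_a != self.allele_b

    def alleles(self) -> tuple[int, int]:
        if self.is_missing:
            raise ValueError(f"locus {self.locus_id}: genotype missing")
        return (self.allele_a, self.allele_b)  # type: ignore[return-value]


@dataclass(frozen=True)
class MhcGenotype:
    """Diploid genotype at one MHC locus, as a pair of allele names."""

    locus_id: str
    allele_a: Optional[str]
    allele_b: Optional[str]

    def __post_init__(self) -> None:
        if (self.allele_a is None) != (self.allele_b is None):
            raise ValueError(f"locus {self.locus_id}: half-missing MHC genotype")

    @property
    def is_missing(self) -> bool:
        return self.allele_a is None

    @property
    def is_heterozygous(self) -> bool:
        if self.is_missing:
            raise ValueError(f"locus {self.locus_id}: genotype missing")
        return self.allele_a != self.allele_b

    def alleles(self) -> tuple[str, str]:
        if self.is_missing:
            raise ValueError(f"locus {self.locus_id}: genotype missing")
        return (self.allele_a, self.allele_b)  # type: ignore[return-value]


@dataclass
class Individual:
    """One adult: id, sex, pond, microsatellite and MHC genotypes."""

    id: str
    sex: str  # "female" | "male"
    pond: str
    microsat: list[MicrosatGenotype] = field(default_factory=list)
    mhc: list[MhcGenotype] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"individual {self.id}: sex must be female/male, got {self.sex!r}")
        if not self.pond:
            raise ValueError(f"individual {self.id}: pond must be non-empty")

    def microsat_at(self, locus_id: str) -> MicrosatGenotype:
        for g in self.microsat:
            if g.locus_id == locus_id:
                return g
        raise KeyError(f"individual {self.id}: no microsatellite locus {locus_id}")

    def mhc_at(self, locus_id: str) -> MhcGenotype:
        for g in self.mhc:
            if g.locus_id == locus_id:
                return g
        raise KeyError(f"individual {self.id}: no MHC locus {locus_id}")


@dataclass(frozen=True)
class MatingPair:
    """One realised female x male mating with its clutch size."""

    female_id: str
    male_id: str
    pond: str
    n_offspring: int

    def __post_init__(self) -> None:
        if self.n_offspring < 0:
            raise ValueError(
                f"pair {self.female_id}x{self.male_id}: negative clutch size"
            )


@dataclass(frozen=True)
class AlleleSequence:
    """Coding sequence of one MHC allele and its conceptual translation."""

    allele: str
    locus_id: str
    dna: str
    protein: str


@dataclass
class TrioRecord:
    """Offspring plus assigned mother and father, genotyped at shared loci.

    ``genotypes`` maps role ("offspring" | "mother" | "father") to a mapping
    locus_id -> (allele, allele); alleles are strings so microsatellite sizes
    and MHC names are handled uniformly.  ``None`` values mark missing data.
    """

    offspring_id: str
    mother_id: str
    father_id: str
    genotypes: dict[str, dict[str, tuple[Optional[str], Optional[str]]]]

    def loci(self) -> list[str]:
        return list(self.genotypes["offspring"].keys())


@dataclass
class Dataset:
    """An individual table plus lookups, the unit the pipeline operates on."""

    individuals: list[Individual]
    microsat_loci: list[str] = field(default_factory=list)
    mhc_loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ind in self.individuals:
            if ind.id in seen:
                raise ValueError(f"duplicate individual id {ind.id!r}")
            seen.add(ind.id)
        if not self.microsat_loci and self.individuals:
            self.microsat_loci = [g.locus_id for g in self.individuals[0].microsat]
        if not self.mhc_loci and self.individuals:
            self.mhc_loci = [g.locus_id for g in self.individuals[0].mhc]
        self._by_id = {ind.id: ind for ind in self.individuals}

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, ind_id: str) -> Individual:
        return self._by_id[ind_id]

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._by_id

    @property
    def ponds(self) -> list[str]:
        out: list[str] = []
        for ind in self.individuals:
            if ind.pond not in out:
                out.append(ind.pond)
        return out

    def females(self, pond: Optional[str] = None) -> list[Individual]:
        return [
            i
            for i in self.individuals
            if i.sex == "female" and (pond is None or i.pond == pond)
        ]

    def males(self, pond: Optional[str] = None) -> list[Individual]:
        return [
            i
            for i in self.individuals
            if i.sex == "male" and (pond is None or i.pond == pond)
        ]


def validate_pairs(pairs: Iterable[MatingPair], dataset: Dataset) -> None:
    """Check pair membership and pond consistency against the adult table."""
    for p in pairs:
        for role, ind_id in (("female", p.female_id), ("male", p.male_id)):
            if ind_id not in dataset:
                raise LookupError(f"pair {p.female_id}x{p.male_id}: unknown {role} id {ind_id!r}")
        f, m = dataset[p.female_id], dataset[p.male_id]
        if f.sex != "female":
            raise ValueError(f"pair {p.female_id}x{p.male_id}: {p.female_id} is not female")
        if m.sex != "male":
            raise ValueError(f"pair {p.female_id}x{p.male_id}: {p.male_id} is not male")
        if f.pond != m.pond:
            raise ValueError(
                f"cross-pond pair {p.female_id} (pond {f.pond}) x {p.male_id} (pond {m.pond})"
            )
        if p.pond not in (f.pond, m.pond):
            raise ValueError(
                f"pair {p.female_id}x{p.male_id}: declared pond {p.pond!r} "
                f"does not match members' pond {f.pond!r}"
            )
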