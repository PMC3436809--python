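"""Core domain objects shared by all analysis stages.

Genotypes are unordered, unphased allele pairs: a call is stored as a
two-character string in alphabetical order (``"AC"`` == ``"CA"``), or
``None`` for a missing call.  Patients belong to exactly one of two
phenotype groups, ``"affected"`` or ``"unaffected"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

VALID_BASES = frozenset("ACGT")

#: tokens that denote a missing genotype in common tab-separated dialects
MISSING_TOKENS = frozenset({"00", "NN", "--", ""})

AFFECTED = "affected"
UNAFFECTED = "unaffected"
GROUPS = (AFFECTED, UNAFFECTED)


class DataError(ValueError):
    """Raised when an input table violates the format contract."""


def canonical_call(token: str) -> Optional[str]:
    """Canonicalize a genotype token to an alphabetically ordered allele
    pair, or ``None`` if the token is a recognised missing-value marker.

    Raises :class:`DataError` for tokens that are neither.
    """
    if token is None:
        return None
    tok = str(token).strip().upper()
    if tok in MISSING_TOKENS or tok == "NAN":
        return None
    if len(tok) == 2 and tok[0] in VALID_BASES and tok[1] in VALID_BASES:
        a, b = sorted(tok)
        return a + b
    raise DataError(f"unparseable genotype token {token!r}")


_CHROM_POS = re.compile(r"^(?:chr)?(\w+):(\d+)$", re.IGNORECASE)


@dataclass(frozen=True)
class SnpMeta:
    """Identity and location of one SNP.

    ``chrom``/``pos`` may be unknown (``None``) when the SNP id does not
    encode a genomic location (e.g. a bare rs number with no map file);
    such SNPs cannot be assigned to a gene.
    """

    snp_id: str
    chrom: Optional[str] = None
    pos: Optional[int] = None
    ref_allele: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos is not None and self.pos < 1:
            raise DataError(f"SNP {self.snp_id}: position must be >= 1 (1-based)")
        if self.ref_allele is not None and self.ref_allele not in VALID_BASES:
            raise DataError(
                f"SNP {self.snp_id}: reference allele {self.ref_allele!r} "
                "is not one of A,C,G,T"
            )

    @classmethod
    def from_id(cls, snp_id: str, ref_allele: Optional[str] = None) -> "SnpMeta":
        """Build metadata from an id, parsing ``chrN:pos``-style ids."""
        m = _CHROM_POS.match(snp_id)
        if m:
            return cls(snp_id, m.group(1), int(m.group(2)), ref_allele)
        return cls(snp_id, None, None, ref_allele)


@dataclass(frozen=True)
class Patient:
    family_id: str
    individual_id: str
    group: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DataError(
                f"patient {self.family_id}/{self.individual_id}: "
                f"group {self.group!r} not in {GROUPS}"
            )


@dataclass(frozen=True)
class GeneLocus:
    """1-based, fully inclusive gene coordinates."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise DataError(
                f"gene {self.gene}: invalid locus {self.start}-{self.end}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def distance(self, pos: int) -> int:
        """bp distance from ``pos`` to the locus (0 inside)."""
        if self.contains(pos):
            return 0
        return min(abs(pos - self.start), abs(pos - self.end))


@dataclass(frozen=True)
class SingleLocusResult:
    """One single-locus association record (SNP vs one quantitative trait)."""

    snp_id: str
    trait_gene: str
    p: float
    r2: float
    flagged: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise DataError(f"{self.snp_id}/{self.trait_gene}: p={self.p} out of [0,1]")
        if not 0.0 <= self.r2 <= 1.0:
            raise DataError(f"{self.snp_id}/{self.trait_gene}: r2={self.r2} out of [0,1]")


def canonical_pair(snp_a: str, snp_b: str) -> tuple[str, str]:
    """Unordered SNP pair, canonicalized by sorting the ids."""
    if snp_a == snp_b:
        raise DataError(f"SNP pair with identical partners {snp_a!r}")
    return (snp_a, snp_b) if snp_a <= snp_b else (snp_b, snp_a)


@dataclass(frozen=True)
class PairResult:
    """One two-locus (epistasis) association record.

    The SNP pair is unordered; constructors must pass ids through
    :func:`canonical_pair` (``snp_a <= snp_b`` lexicographically).
    """

    snp_a: str
    snp_b: str
    trait_gene: str
    p: float
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.snp_a == self.snp_b:
            raise DataError(f"pair with identical SNPs {self.snp_a!r}")
        if not 0.0 <= self.p <= 1.0:
            raise DataError(
                f"pair {self.snp_a},{self.snp_b}/{self.trait_gene}: "
                f"p={self.p} out of [0,1]"
            )

    @classmethod
    def make(cls, snp_a: str, snp_b: str, trait_gene: str, p: float,
             flagged: bool = False) -> "PairResult":
        a, b = canonical_pair(snp_a, snp_b)
        return cls(a, b, trait_gene, p, flagged)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.snp_a, self.snp_b)


class GenotypeMatrix:
    """Patient x SNP grid of canonical allele calls.

    Backed by a pandas DataFrame (index = patient ids, columns = snp ids,
    values = canonical two-character strings or ``None``).
    """

    def __init__(self, calls: pd.DataFrame):
        if calls.index.has_duplicates:
            raise DataError("duplicate patient ids in genotype matrix")
        if calls.columns.has_duplicates:
            raise DataError("duplicate SNP ids in genotype matrix")
        self.calls = calls.astype(object).where(pd.notna(calls), None)

    @property
    def patients(self) -> list[str]:
        return list(self.calls.index)

    @property
    def snps(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def column(self, snp_id: str) -> pd.Series:
        if snp_id not in self.calls.columns:
            raise DataError(f"SNP {snp_id!r} not in genotype matrix")
        return self.calls[snp_id]

    def call(self, patient_id: str, snp_id: str) -> Optional[str]:
        return self.calls.at[patient_id, snp_id]

    def n_missing(self) -> int:
        return int(self.calls.isna().sum().sum())


class ExpressionMatrix:
    """Gene x patient grid of real-valued expression levels."""

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            raise DataError("duplicate gene names in expression matrix")
        if values.columns.has_duplicates:
            raise DataError("duplicate patient ids in expression matrix")
        self.values = values.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def patients(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ParseReport:
    """Counts accumulated while reading one input file."""

    n_rows: int = 0
    n_missing_calls: int = 0
    n_dropped: int = 0
    warnings: list[str] = field(default_factory=list)

    def warn(self, message: str) -> None:
        self.warnings.append(message)


def group_of(patients: list[Patient]) -> dict[str, str]:
    """Map individual id -> phenotype group."""
    return {p.individual_id: p.group for p in patients}


def patients_by_group(patients: list[Patient]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {AFFECTED: [], UNAFFECTED: []}
    for p in patients:
        out[p.group].append(p.individual_id)
    return out
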