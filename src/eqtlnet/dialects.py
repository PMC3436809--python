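"""Column-layout dialects for the tab-separated input tables.

Input files come from heterogeneous pipelines (PLINK runs, contest-style
exports), so every reader is header-keyed and the header names live in a
dialect object.  Two named dialects ship with the package:

``plink``
    PLINK-style headers (``SNP``/``SNP1``/``SNP2``/``P``/``R2``, phenotype
    coded 2 = affected, 1 = unaffected).
``contest``
    Identical column names but lower-case, with ``gene`` as the trait
    column; provided as a second starting point for contest-style files.

Users can override any field from a plain ``key = value`` config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path


@dataclass(frozen=True)
class Dialect:
    name: str = "plink"
    sep: str = "\t"
    comment: str = "#"
    # genotype / phenotype tables
    patient_col: str = "IID"
    family_col: str = "FID"
    status_col: str = "STATUS"
    affected_token: str = "2"
    unaffected_token: str = "1"
    # reference table
    snp_col: str = "SNP"
    base_col: str = "REF"
    # gene locus table
    gene_col: str = "GENE"
    chrom_col: str = "CHR"
    start_col: str = "START"
    end_col: str = "END"
    # single-locus result files
    single_trait_col: str = "GENE"
    p_col: str = "P"
    r2_col: str = "R2"
    # two-locus result files
    snp1_col: str = "SNP1"
    snp2_col: str = "SNP2"
    pair_trait_col: str = "GENE"
    pair_p_col: str = "P"

    def with_overrides(self, **kwargs) -> "Dialect":
        return replace(self, **kwargs)


PLINK = Dialect(name="plink")
CONTEST = Dialect(
    name="contest",
    patient_col="patient",
    family_col="family",
    status_col="status",
    snp_col="snp",
    base_col="ref",
    gene_col="gene",
    chrom_col="chrom",
    start_col="start",
    end_col="end",
    single_trait_col="gene",
    p_col="p",
    r2_col="r2",
    snp1_col="snp1",
    snp2_col="snp2",
    pair_trait_col="gene",
    pair_p_col="p",
)

DIALECTS = {"plink": PLINK, "contest": CONTEST}

_FIELD_NAMES = {f.name for f in fields(Dialect)}


def get_dialect(name: str) -> Dialect:
    try:
        return DIALECTS[name]
    except KeyError:
        raise ValueError(
            f"unknown dialect {name!r}; available: {sorted(DIALECTS)}"
        ) from None


def load_dialect_config(path: str | Path, base: str = "plink") -> Dialect:
    """Read ``key = value`` overrides from a plain-text config file.

    Lines starting with '#' and blank lines are ignored.  A ``base`` key in
    the file selects the named dialect to override (default ``plink``).
    """
    overrides: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "base":
            base = value
            continue
        if key not in _FIELD_NAMES:
            raise ValueError(f"{path}:{lineno}: unknown dialect key {key!r}")
        overrides[key] = value
    return get_dialect(base).with_overrides(name=f"{base}+{Path(path).name}", **overrides)
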