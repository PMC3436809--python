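"""Readers for the six tab-separated input tables and exporters for graphs.

All readers are header-keyed (column order never matters), treat
'#'-prefixed lines as comments and return validated domain objects plus a
:class:`~eqtlnet.domain.ParseReport` where lossy parsing can occur.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from .dialects import Dialect, PLINK
from .domain import (
    AFFECTED,
    UNAFFECTED,
    VALID_BASES,
    DataError,
    ExpressionMatrix,
    GeneLocus,
    GenotypeMatrix,
    PairResult,
    ParseReport,
    Patient,
    SingleLocusResult,
    SnpMeta,
    canonical_call,
)


def _read_table(path: str | Path, dialect: Dialect) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, sep=dialect.sep, comment=dialect.comment,
                         dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise DataError(f"empty file: {path}") from None
    except pd.errors.ParserError as exc:
        raise DataError(f"{path}: ragged or malformed rows ({exc})") from None
    if df.empty and df.columns.empty:
        raise DataError(f"empty file: {path}")
    df.columns = [c.strip() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, needed: list[str], path) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise DataError(
            f"{path}: missing mandatory column(s) {missing}; "
            f"found headers {list(df.columns)}"
        )


def read_genotype_table(
    path: str | Path, dialect: Dialect = PLINK
) -> tuple[GenotypeMatrix, list[SnpMeta], ParseReport]:
    """Read a patient x SNP genotype table.

    First column (``dialect.patient_col``) holds patient ids; every other
    column is one SNP.  Cells are two-letter allele pairs; recognised
    missing tokens become MISSING and are counted in the report, while
    tokens that are neither raise.
    """
    df = _read_table(path, dialect)
    _require_columns(df, [dialect.patient_col], path)
    if df.shape[0] == 0:
        raise DataError(f"{path}: no patient rows")
    # pandas silently renames duplicate columns, so check the raw header
    for raw in Path(path).read_text().splitlines():
        if raw.strip() and not raw.startswith(dialect.comment):
            header = [c.strip() for c in raw.split(dialect.sep)]
            if len(set(header)) != len(header):
                raise DataError(f"{path}: duplicate SNP column")
            break
    report = ParseReport(n_rows=df.shape[0])
    ids = df[dialect.patient_col].str.strip()
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise DataError(f"{path}: duplicate patient id {dup!r}")
    snp_cols = [c for c in df.columns if c != dialect.patient_col]
    if not snp_cols:
        raise DataError(f"{path}: no SNP columns")

    def parse_cell(tok: str) -> Optional[str]:
        call = canonical_call(tok)
        if call is None:
            report.n_missing_calls += 1
        return call

    calls = df[snp_cols].map(parse_cell)
    calls.index = pd.Index(ids, name="patient")
    matrix = GenotypeMatrix(calls)
    metas = [SnpMeta.from_id(s) for s in snp_cols]
    return matrix, metas, report


def read_phenotype_table(path: str | Path, dialect: Dialect = PLINK) -> list[Patient]:
    """Read the phenotype table: one row per patient with family id,
    individual id and affection status (dialect-coded, PLINK convention
    2 = affected / 1 = unaffected by default)."""
    df = _read_table(path, dialect)
    _require_columns(df, [dialect.family_col, dialect.patient_col,
                          dialect.status_col], path)
    mapping = {dialect.affected_token: AFFECTED,
               dialect.unaffected_token: UNAFFECTED}
    patients: list[Patient] = []
    seen: set[tuple[str, str]] = set()
    seen_iid: set[str] = set()
    for i, row in df.iterrows():
        fid = row[dialect.family_col].strip()
        iid = row[dialect.patient_col].strip()
        status = row[dialect.status_col].strip()
        if status not in mapping:
            raise DataError(
                f"{path}: row {i + 1} ({fid}/{iid}): unknown status token "
                f"{status!r} (expected {sorted(mapping)})"
            )
        key = (fid, iid)
        if key in seen:
            raise DataError(f"{path}: duplicate patient ({fid}, {iid})")
        if iid in seen_iid:
            raise DataError(
                f"{path}: individual id {iid!r} occurs in two families; "
                "ids must be unique to join with genotype/expression tables"
            )
        seen.add(key)
        seen_iid.add(iid)
        patients.append(Patient(fid, iid, mapping[status]))
    if not patients:
        raise DataError(f"{path}: no patient rows")
    return patients


def read_expression_table(
    path: str | Path, dialect: Dialect = PLINK, orientation: str = "rows"
) -> ExpressionMatrix:
    """Read the gene-expression table.

    ``orientation='rows'`` (default): genes in rows, patients in columns,
    first column holds gene names.  ``'columns'``: the transpose, first
    column holds patient ids.  ``'auto'`` keys on the first header token
    (``gene*`` vs anything else).
    """
    df = _read_table(path, dialect)
    if df.shape[1] < 2 or df.shape[0] < 1:
        raise DataError(f"{path}: expression table needs ids plus a numeric body")
    first = df.columns[0]
    if orientation == "auto":
        orientation = "rows" if first.lower().startswith("gene") else "columns"
    if orientation not in ("rows", "columns"):
        raise DataError(f"invalid orientation {orientation!r}")
    body = df.set_index(first)
    try:
        values = body.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for gene in body.index:
            for col in body.columns:
                try:
                    float(body.at[gene, col])
                except ValueError:
                    raise DataError(
                        f"{path}: non-numeric cell at row {gene!r}, "
                        f"column {col!r}: {body.at[gene, col]!r}"
                    ) from None
        raise
    if values.isna().any().any():
        bad = values.isna().stack()
        gene, col = bad[bad].index[0]
        raise DataError(f"{path}: missing/non-numeric cell at ({gene!r}, {col!r})")
    if orientation == "columns":
        values = values.T
    values.index.name = "gene"
    values.columns.name = "patient"
    return ExpressionMatrix(values)


def read_reference_table(path: str | Path, dialect: Dialect = PLINK) -> dict[str, str]:
    """Read the per-SNP reference-nucleotide table (snp_id, base)."""
    df = _read_table(path, dialect)
    _require_columns(df, [dialect.snp_col, dialect.base_col], path)
    refs: dict[str, str] = {}
    for i, row in df.iterrows():
        snp = row[dialect.snp_col].strip()
        base = row[dialect.base_col].strip().upper()
        if base not in VALID_BASES:
            raise DataError(
                f"{path}: row {i + 1}: reference base {base!r} for SNP {snp} "
                "is not one of A,C,G,T"
            )
        if snp in refs and refs[snp] != base:
            raise DataError(
                f"{path}: SNP {snp} listed with conflicting bases "
                f"{refs[snp]} and {base}"
            )
        refs[snp] = base
    return refs


def read_gene_loci(
    path: str | Path, dialect: Dialect = PLINK, bed: bool = False
) -> list[GeneLocus]:
    """Read gene loci (gene, chrom, start, end), 1-based inclusive.

    With ``bed=True`` coordinates are interpreted as BED-style 0-based
    half-open and converted.
    """
    df = _read_table(path, dialect)
    _require_columns(df, [dialect.gene_col, dialect.chrom_col,
                          dialect.start_col, dialect.end_col], path)
    loci: list[GeneLocus] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        gene = row[dialect.gene_col].strip()
        if gene in seen:
            raise DataError(f"{path}: duplicate gene {gene!r}")
        seen.add(gene)
        try:
            start = int(row[dialect.start_col])
            end = int(row[dialect.end_col])
        except ValueError:
            raise DataError(f"{path}: row {i + 1}: non-integer coordinates") from None
        if bed:
            start, end = start + 1, end
        loci.append(GeneLocus(gene, row[dialect.chrom_col].strip(), start, end))
    if not loci:
        raise DataError(f"{path}: no gene loci")
    return loci


def _parse_p(token: str) -> Optional[float]:
    try:
        return float(token)
    except (TypeError, ValueError):
        return None


def read_single_locus_results(
    path: str | Path, dialect: Dialect = PLINK
) -> tuple[list[SingleLocusResult], ParseReport]:
    """Read a PLINK-style single-locus quantitative-trait result file.

    Rows whose P (or R2) does not parse are dropped and counted in the
    report; out-of-bounds values raise.
    """
    df = _read_table(path, dialect)
    needed = [dialect.snp_col, dialect.single_trait_col, dialect.p_col, dialect.r2_col]
    _require_columns(df, needed, path)
    report = ParseReport(n_rows=df.shape[0])
    results: list[SingleLocusResult] = []
    seen: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        p = _parse_p(row[dialect.p_col])
        r2 = _parse_p(row[dialect.r2_col])
        snp = row[dialect.snp_col].strip()
        trait = row[dialect.single_trait_col].strip()
        if p is None or r2 is None:
            report.n_dropped += 1
            report.warn(f"dropped unparseable row for {snp}/{trait}")
            continue
        key = (snp, trait)
        if key in seen:
            raise DataError(f"{path}: duplicate (SNP, trait) record {key}")
        seen.add(key)
        results.append(SingleLocusResult(snp, trait, p, r2))
    return results, report


def read_pair_results(
    path: str | Path, dialect: Dialect = PLINK
) -> tuple[list[PairResult], ParseReport]:
    """Read a PLINK --epistasis-style two-locus result file.

    SNP pairs are canonicalized (sorted ids); exact duplicate records are
    collapsed with a warning; self-pairs and out-of-bounds P are rejected
    with a warning.
    """
    df = _read_table(path, dialect)
    needed = [dialect.snp1_col, dialect.snp2_col, dialect.pair_trait_col,
              dialect.pair_p_col]
    _require_columns(df, needed, path)
    report = ParseReport(n_rows=df.shape[0])
    results: list[PairResult] = []
    seen: dict[tuple[str, str, str], float] = {}
    for _, row in df.iterrows():
        s1 = row[dialect.snp1_col].strip()
        s2 = row[dialect.snp2_col].strip()
        trait = row[dialect.pair_trait_col].strip()
        p = _parse_p(row[dialect.pair_p_col])
        if s1 == s2:
            report.n_dropped += 1
            report.warn(f"rejected self-pair ({s1}, {s2})")
            continue
        if p is None or not 0.0 <= p <= 1.0:
            report.n_dropped += 1
            report.warn(f"rejected pair ({s1}, {s2})/{trait}: bad P {row[dialect.pair_p_col]!r}")
            continue
        a, b = (s1, s2) if s1 <= s2 else (s2, s1)
        key = (a, b, trait)
        if key in seen:
            report.n_dropped += 1
            report.warn(f"collapsed duplicate record for {key}")
            continue
        seen[key] = p
        results.append(PairResult(a, b, trait, p))
    return results, report


# ---------------------------------------------------------------------------
# PLINK-style result writers (emit the same dialects the readers accept)


def write_single_locus_results(
    results: list[SingleLocusResult], path: str | Path,
    dialect: Dialect = PLINK,
) -> None:
    """Write single-locus results in the tab-separated dialect layout."""
    with open(path, "w") as fh:
        fh.write(dialect.sep.join([dialect.snp_col, dialect.single_trait_col,
                                   dialect.p_col, dialect.r2_col]) + "\n")
        for r in results:
            fh.write(dialect.sep.join(
                [r.snp_id, r.trait_gene, repr(r.p), repr(r.r2)]) + "\n")


def write_pair_results(
    results: list[PairResult], path: str | Path, dialect: Dialect = PLINK,
) -> None:
    """Write two-locus results in the tab-separated dialect layout."""
    with open(path, "w") as fh:
        fh.write(dialect.sep.join([dialect.snp1_col, dialect.snp2_col,
                                   dialect.pair_trait_col,
                                   dialect.pair_p_col]) + "\n")
        for r in results:
            fh.write(dialect.sep.join(
                [r.snp_a, r.snp_b, r.trait_gene, repr(r.p)]) + "\n")


# ---------------------------------------------------------------------------
# Graph export


def _dot_quote(s: str) -> str:
    return '"' + str(s).replace('"', '\\"') + '"'


def export_graph(graph, fmt: str, path: str | Path) -> None:
    """Write an association graph to GraphML or Graphviz DOT.

    Every node carries (gene, color, colored, degree); every edge carries
    (weight, color_gene).  GraphML round-trips through networkx; DOT is a
    plain-text emitter suitable for ``dot``/``neato``.
    """
    import networkx as nx

    from .network import AssocGraph

    g = graph.graph if isinstance(graph, AssocGraph) else graph
    path = Path(path)
    if fmt == "graphml":
        out = nx.MultiGraph()
        degrees = dict(g.degree())
        for node, attrs in g.nodes(data=True):
            out.add_node(node, gene=node, colored=bool(attrs.get("colored", False)),
                         color=str(attrs.get("color", "gray")), degree=degrees[node])
        for u, v, key, attrs in g.edges(keys=True, data=True):
            out.add_edge(u, v, key=key, weight=int(attrs["weight"]),
                         color_gene=str(attrs["color_gene"]))
        nx.write_graphml(out, path)
    elif fmt == "dot":
        lines = ["graph association {"]
        degrees = dict(g.degree())
        for node, attrs in sorted(g.nodes(data=True)):
            color = attrs.get("color", "gray")
            colored = "true" if attrs.get("colored") else "false"
            lines.append(
                f"  {_dot_quote(node)} [gene={_dot_quote(node)}, "
                f"style=filled, fillcolor={_dot_quote(color)}, "
                f"colored={_dot_quote(colored)}, "
                f"degree={_dot_quote(degrees[node])}];"
            )
        for u, v, key, attrs in sorted(g.edges(keys=True, data=True)):
            lines.append(
                f"  {_dot_quote(u)} -- {_dot_quote(v)} "
                f"[weight={int(attrs['weight'])}, "
                f"color_gene={_dot_quote(attrs['color_gene'])}, "
                f"label={_dot_quote(attrs['weight'])}];"
            )
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise DataError(f"unknown graph export format {fmt!r} (graphml or dot)")


def import_graphml(path: str | Path):
    """Re-read a GraphML file written by :func:`export_graph` into an
    :class:`~eqtlnet.network.AssocGraph` (provenance is not serialized)."""
    import networkx as nx

    from .network import AssocGraph

    raw = nx.read_graphml(path, force_multigraph=True)
    g = nx.MultiGraph()
    for node, attrs in raw.nodes(data=True):
        g.add_node(str(node), colored=bool(attrs.get("colored", False)),
                   color=str(attrs.get("color", "gray")))
    for u, v, key, attrs in raw.edges(keys=True, data=True):
        g.add_edge(str(u), str(v), key=str(attrs["color_gene"]),
                   weight=int(attrs["weight"]), color_gene=str(attrs["color_gene"]))
    return AssocGraph(g, provenance={})


def write_edge_list(graph, path: str | Path) -> None:
    """Tab-separated edge list: gene_a, gene_b, color_gene, weight."""
    from .network import AssocGraph

    g = graph.graph if isinstance(graph, AssocGraph) else graph
    rows = []
    for u, v, key, attrs in g.edges(keys=True, data=True):
        a, b = sorted((u, v))
        rows.append((a, b, attrs["color_gene"], int(attrs["weight"])))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("GENE_A\tGENE_B\tCOLOR_GENE\tWEIGHT\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")
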