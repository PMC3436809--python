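"""End-to-end analysis workflow.

Wires the modules into the full filter cascade: parse inputs -> map SNPs
to genes -> build the association graph from significant two-locus
results (alpha) -> keep highly significant single-locus SNPs
(r2 > r2_min, p < p_max) -> restrict pairs to that set -> tau display
filter -> genotype summaries, relevance rule and chi-square on the
network's SNP set -> differential-expression statistics -> static
renders.  Every stage's SNP/pair sets are exported so the summary counts
can be recomputed from the artifacts.

The tau threshold filters the *displayed/exported* graph only; by default
the genotype view analyses every SNP of the post-restriction network
(``tau_restricts_view=True`` switches to the SNPs on tau-surviving
edges).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import io as eio
from .dialects import PLINK, Dialect
from .domain import AFFECTED, UNAFFECTED, DataError
from .exprstats import gene_stats, group_mean_profiles
from .genotype import build_genotype_view_model, view_model_table
from .network import (
    build_association_graph,
    filter_edges_by_weight,
    node_degree,
    pairs_per_snp,
    restrict_pairs_to_snp_set,
    significant_single_locus_snps,
    snps_in_pairs,
)
from .snpmap import assign_snps_to_genes
from .viz import RenderSpec, render_association_graph, render_genotype_view, \
    render_heatmap

logger = logging.getLogger(__name__)


class WorkflowError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"workflow stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    genotypes: Path
    expression: Path
    phenotypes: Path
    reference: Path
    loci: Path
    single_results: Path
    pair_results: Path
    out_dir: Path
    dialect: Dialect = PLINK
    alpha: float = 0.05
    r2_min: float = 0.1
    p_max: float = 0.05
    tau: int = 50
    delta: float = 0.10
    chi2_alpha: float = 0.05
    max_dist: Optional[int] = None
    focus_patient: Optional[str] = None
    tau_restricts_view: bool = False
    render: bool = True
    seed: int = 0
    view_mode: str = "stacked"

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1 or not 0 <= self.r2_min <= 1 \
                or not 0 <= self.p_max <= 1 or self.tau < 0 \
                or not 0 <= self.delta <= 1:
            raise DataError("threshold out of documented bounds")


def run_workflow(config: RunConfig) -> dict:
    """Execute the full cascade; returns the machine-readable summary
    (also written to ``summary.json``).

    Any stage failure aborts with the stage name and removes files
    already written to the output directory.
    """
    logger.info("resolved config: %s", config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str) -> Path:
        p = out / name
        written.append(p)
        return p

    stage = "parse"
    try:
        d = config.dialect
        matrix, snp_meta, geno_report = eio.read_genotype_table(
            config.genotypes, d)
        expr = eio.read_expression_table(config.expression, d)
        patients = eio.read_phenotype_table(config.phenotypes, d)
        refs = eio.read_reference_table(config.reference, d)
        loci = eio.read_gene_loci(config.loci, d)
        single, single_report = eio.read_single_locus_results(
            config.single_results, d)
        pairs, pair_report = eio.read_pair_results(config.pair_results, d)

        stage = "map_snps"
        smap = assign_snps_to_genes(snp_meta, loci, max_dist=config.max_dist)
        genes = [loc.gene for loc in loci]

        stage = "build_graph"
        graph = build_association_graph(pairs, smap, genes, alpha=config.alpha)
        n_significant = sum(1 for p in pairs if p.p < config.alpha)

        stage = "single_locus_filter"
        keep = significant_single_locus_snps(single, config.r2_min,
                                             config.p_max)

        stage = "pair_restriction"
        sig_pairs = [p for p in pairs if p.p < config.alpha]
        restricted = restrict_pairs_to_snp_set(sig_pairs, keep)
        network_snps = sorted(snps_in_pairs(restricted))
        restricted_graph = build_association_graph(restricted, smap, genes,
                                                   alpha=config.alpha)

        stage = "tau_filter"
        displayed = filter_edges_by_weight(restricted_graph, config.tau)
        eio.export_graph(restricted_graph, "graphml", emit("network.graphml"))
        eio.export_graph(displayed, "graphml", emit("network_tau.graphml"))
        eio.export_graph(displayed, "dot", emit("network_tau.dot"))
        eio.write_edge_list(restricted_graph, emit("edges.tsv"))
        with open(emit("single_locus_keep.txt"), "w") as fh:
            fh.write("\n".join(sorted(keep)) + "\n")
        with open(emit("network_snps.txt"), "w") as fh:
            fh.write("\n".join(network_snps) + "\n")

        stage = "genotype_view"
        if config.tau_restricts_view:
            surviving = {s for key, prov in displayed.provenance.items()
                         for pair in prov for s in pair}
            view_snps = sorted(surviving)
        else:
            view_snps = network_snps
        view_snps = [s for s in view_snps if s in set(matrix.snps)]
        meta_map = {m.snp_id: m for m in snp_meta}
        focus = config.focus_patient or matrix.patients[0]
        columns = build_genotype_view_model(
            view_snps, matrix, patients, refs, meta_map, single, focus,
            delta=config.delta)
        table = view_model_table(columns)
        table.to_csv(emit("genotype_view.tsv"), sep="\t", index=False)
        relevant = [c.snp_id for c in columns if c.relevant]
        chi2_reject = [c.snp_id for c in columns if c.chi2_p < config.chi2_alpha]
        overlap = sorted(set(relevant) & set(chi2_reject))
        ppersnp = pairs_per_snp(restricted, set(relevant))
        with open(emit("pairs_per_relevant_snp.tsv"), "w") as fh:
            fh.write("SNP\tN_PAIRS\n")
            for snp in sorted(ppersnp):
                fh.write(f"{snp}\t{ppersnp[snp]}\n")

        stage = "expression_stats"
        stats = gene_stats(expr, patients)
        with open(emit("gene_stats.tsv"), "w") as fh:
            fh.write("GENE\tT\tP\tQ\tRANK\n")
            for s in sorted(stats, key=lambda s: s.rank):
                fh.write(f"{s.gene}\t{s.t_stat!r}\t{s.p!r}\t{s.q!r}\t{s.rank}\n")
        profiles = group_mean_profiles(expr, patients)
        with open(emit("group_profiles.tsv"), "w") as fh:
            fh.write("GENE\tMEAN_AFFECTED\tMEAN_UNAFFECTED\n")
            for gene in expr.genes:
                fh.write(f"{gene}\t{profiles[AFFECTED][gene]!r}"
                         f"\t{profiles[UNAFFECTED][gene]!r}\n")

        if config.render:
            stage = "render"
            spec = RenderSpec(layout_seed=config.seed)
            if displayed.graph.number_of_nodes() > 0:
                render_association_graph(displayed, spec,
                                         emit("network.svg"))
            if columns:
                render_genotype_view(columns, mode=config.view_mode,
                                     path=emit("genotype_view.svg"), spec=spec)
            render_heatmap(expr, stats, patients, aggregate=False,
                           path=emit("heatmap.svg"), spec=spec)
            render_heatmap(expr, stats, patients, aggregate=True,
                           path=emit("heatmap_aggregated.svg"), spec=spec)

        stage = "summary"
        summary = {
            "config": {
                "alpha": config.alpha, "r2_min": config.r2_min,
                "p_max": config.p_max, "tau": config.tau,
                "delta": config.delta, "chi2_alpha": config.chi2_alpha,
            },
            "parse": {
                "n_patients": len(patients),
                "n_affected": sum(1 for p in patients if p.group == AFFECTED),
                "n_unaffected": sum(1 for p in patients
                                    if p.group == UNAFFECTED),
                "n_snps": len(matrix.snps),
                "n_genes": len(genes),
                "n_missing_calls": geno_report.n_missing_calls,
                "n_single_rows": single_report.n_rows,
                "n_pair_rows": pair_report.n_rows,
                "n_pair_rows_dropped": pair_report.n_dropped,
            },
            "cascade": {
                "n_pairs_in": len(pairs),
                "n_pairs_significant": n_significant,
                "n_pairs_skipped_unassigned": graph.n_skipped_unassigned,
                "n_snps_single_locus_pass": len(keep),
                "n_pairs_after_restriction": len(restricted),
                "n_network_snps": len(network_snps),
                "n_edges": len(restricted_graph.edge_records()),
                "n_edges_after_tau": len(displayed.edge_records()),
                "total_edge_weight": restricted_graph.total_weight(),
                "max_edge_weight": max(
                    (w for *_, w in restricted_graph.edge_records()),
                    default=0),
            },
            "genotype_view": {
                "n_view_snps": len(view_snps),
                "n_relevant_snps": len(relevant),
                "n_chi2_rejections": len(chi2_reject),
                "n_overlap": len(overlap),
                "relevant_snps": sorted(relevant),
            },
            "expression": {
                "top_gene": min(stats, key=lambda s: s.rank).gene if stats
                else None,
                "n_genes_q_lt_0.05": sum(1 for s in stats if s.q < 0.05),
            },
            "node_degree": node_degree(restricted_graph),
        }
        with open(emit("summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary
    except Exception as exc:
        for p in written:
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass
        raise WorkflowError(stage, exc) from exc
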