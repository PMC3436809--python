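"""Association gene network built from significant two-locus results.

Each significant SNP-pair record maps, through the closest-gene
assignment, to a triple <g_i, g_j, g_k>: the pair's SNPs sit in (or near)
genes g_i and g_j and the pair is associated with the expression of the
*trait* gene g_k.  For each g_k an edge {g_i, g_j} is added whose integer
weight counts the distinct canonical SNP pairs behind it; edges sharing
endpoints but differing in trait gene are distinct multi-edges ("differ
only in color").  Self-loops (both partners near the same gene) are legal.

Nodes cover *every* gene in the locus table.  A node is *colored* iff at
least one edge carries it as trait gene; the rest stay gray.  The edge
weight threshold tau filters what is displayed/exported, never which
nodes count as colored.

Edges whose trait gene equals one of their endpoints represent *cis*
effects and carry ``cis=True``; all other edges are *trans*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .domain import PairResult, SingleLocusResult
from .snpmap import SnpGeneMap

logger = logging.getLogger(__name__)

#: ~10 distinguishable categorical colors (Brewer Set1/Paired mix)
DEFAULT_PALETTE = (
    "#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00",
    "#ffff33", "#a65628", "#f781bf", "#66c2a5", "#1f78b4",
)

EdgeKey = tuple[tuple[str, str], str]  # (sorted endpoints, trait gene)


@dataclass
class AssocGraph:
    """Weighted multigraph of genes plus per-edge SNP-pair provenance."""

    graph: nx.MultiGraph
    provenance: dict[EdgeKey, set[tuple[str, str]]] = field(default_factory=dict)
    n_skipped_unassigned: int = 0

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edge_records(self) -> list[tuple[str, str, str, int]]:
        """Sorted (gene_a, gene_b, color_gene, weight) tuples."""
        recs = []
        for u, v, key, attrs in self.graph.edges(keys=True, data=True):
            a, b = sorted((u, v))
            recs.append((a, b, attrs["color_gene"], int(attrs["weight"])))
        return sorted(recs)

    def weights(self) -> dict[EdgeKey, int]:
        return {((a, b), c): w for a, b, c, w in self.edge_records()}

    def colored_genes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("colored")}

    def total_weight(self) -> int:
        return sum(w for *_, w in self.edge_records())


def build_association_graph(
    pairs: list[PairResult],
    snp_map: SnpGeneMap,
    genes: list[str],
    alpha: float = 0.05,
) -> AssocGraph:
    """Build the association graph from two-locus results.

    Keeps records with p < ``alpha`` (strict), maps both SNPs to genes and
    increments the ({g_i, g_j}, g_k) edge.  Pairs containing an UNASSIGNED
    SNP are skipped and counted.  ``genes`` is the full locus-table gene
    list; every one becomes a node, and a trait gene outside it is an
    error.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    gene_set = set(genes)
    g = nx.MultiGraph()
    for gene in sorted(gene_set):
        g.add_node(gene, colored=False, color="gray")
    provenance: dict[EdgeKey, set[tuple[str, str]]] = {}
    skipped = 0
    for rec in pairs:
        if rec.p >= alpha:
            continue
        if rec.trait_gene not in gene_set:
            raise ValueError(
                f"trait gene {rec.trait_gene!r} absent from the locus table"
            )
        gi = snp_map.gene_of(rec.snp_a)
        gj = snp_map.gene_of(rec.snp_b)
        if gi is None or gj is None:
            skipped += 1
            continue
        endpoints = tuple(sorted((gi, gj)))
        key: EdgeKey = (endpoints, rec.trait_gene)
        contributors = provenance.setdefault(key, set())
        if rec.pair in contributors:
            continue  # each canonical SNP pair counts at most once per edge
        contributors.add(rec.pair)
        u, v = endpoints
        if g.has_edge(u, v, key=rec.trait_gene):
            g[u][v][rec.trait_gene]["weight"] += 1
        else:
            g.add_edge(u, v, key=rec.trait_gene, weight=1,
                       color_gene=rec.trait_gene,
                       cis=rec.trait_gene in endpoints)
        g.nodes[rec.trait_gene]["colored"] = True
    if skipped:
        logger.info("skipped %d significant pair(s) with an UNASSIGNED SNP",
                    skipped)
    return AssocGraph(g, provenance, n_skipped_unassigned=skipped)


def filter_edges_by_weight(graph: AssocGraph, tau: int) -> AssocGraph:
    """Copy of the graph keeping only edges with weight >= tau.

    All nodes are retained, and colored flags are *kept from the
    unfiltered graph*: tau narrows the display, not the semantics.
    """
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    g = nx.MultiGraph()
    for node, attrs in graph.graph.nodes(data=True):
        g.add_node(node, **dict(attrs))
    provenance: dict[EdgeKey, set[tuple[str, str]]] = {}
    for u, v, key, attrs in graph.graph.edges(keys=True, data=True):
        if attrs["weight"] >= tau:
            g.add_edge(u, v, key=key, **dict(attrs))
            ekey = (tuple(sorted((u, v))), attrs["color_gene"])
            if ekey in graph.provenance:
                provenance[ekey] = set(graph.provenance[ekey])
    return AssocGraph(g, provenance,
                      n_skipped_unassigned=graph.n_skipped_unassigned)


def significant_single_locus_snps(
    results: list[SingleLocusResult],
    r2_min: float = 0.1,
    p_max: float = 0.05,
) -> set[str]:
    """SNPs with r2 > ``r2_min`` and p < ``p_max`` (both strict) for at
    least one trait gene — the highly significant single-locus set."""
    return {r.snp_id for r in results if r.r2 > r2_min and r.p < p_max}


def restrict_pairs_to_snp_set(
    pairs: list[PairResult], keep: set[str]
) -> list[PairResult]:
    """Keep pairs where at least one partner is in ``keep``."""
    return [p for p in pairs if p.snp_a in keep or p.snp_b in keep]


def snps_in_pairs(pairs: list[PairResult]) -> set[str]:
    """Distinct SNPs occurring in any pair."""
    out: set[str] = set()
    for p in pairs:
        out.add(p.snp_a)
        out.add(p.snp_b)
    return out


def node_degree(graph: AssocGraph) -> dict[str, int]:
    """Edges incident to each node, counting multi-edges separately and
    self-loops once."""
    degrees = {n: 0 for n in graph.graph.nodes}
    for u, v, _key in graph.graph.edges(keys=True):
        degrees[u] += 1
        if v != u:
            degrees[v] += 1
    return degrees


def node_degree_merged(graph: AssocGraph) -> dict[str, int]:
    """Degree counting parallel multi-edges between the same endpoints as
    one (the alternative reading of 'node degree')."""
    degrees = {n: 0 for n in graph.graph.nodes}
    seen: set[tuple[str, str]] = set()
    for u, v in graph.graph.edges():
        pair = tuple(sorted((u, v)))
        if pair in seen:
            continue
        seen.add(pair)
        degrees[pair[0]] += 1
        if pair[1] != pair[0]:
            degrees[pair[1]] += 1
    return degrees


def pairs_per_snp(pairs: list[PairResult], focus: set[str]) -> dict[str, int]:
    """For each focus SNP, the number of pairs containing it (distinct
    (pair, trait) records each count)."""
    counts = {s: 0 for s in focus}
    for p in pairs:
        if p.snp_a in counts:
            counts[p.snp_a] += 1
        if p.snp_b in counts:
            counts[p.snp_b] += 1
    return counts


def assign_node_colors(
    graph: AssocGraph, palette: tuple[str, ...] = DEFAULT_PALETTE
) -> AssocGraph:
    """Give each colored node a concrete palette color, in alphabetical
    gene-name order; gray otherwise.  Cycles (with a warning) if there are
    more colored genes than palette entries."""
    if not palette:
        raise ValueError("palette must be non-empty")
    colored = sorted(graph.colored_genes())
    if len(colored) > len(palette):
        logger.warning(
            "%d colored genes exceed the %d-color palette; colors will repeat",
            len(colored), len(palette),
        )
    for i, gene in enumerate(colored):
        graph.graph.nodes[gene]["color"] = palette[i % len(palette)]
    for gene in set(graph.graph.nodes) - set(colored):
        graph.graph.nodes[gene]["color"] = "gray"
    return graph
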