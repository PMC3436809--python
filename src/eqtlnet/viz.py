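"""Static renderings of the three analysis views (SVG/PNG).

Replaces the interactive GUI of the original tool with deterministic
matplotlib exports:

* association graph — genes as nodes (gray unless some edge carries them
  as trait gene), seeded force-directed layout, edge color = trait gene,
  edge width/label = weight;
* genotype view — one column per SNP with six stacked sectors
  (significance bar, identifier, per-group genotype distributions, the
  consensus summary boxes, reference base, focus patient's call);
* expression heatmap — per-gene centered values on a symmetric diverging
  gradient, columns grouped by disease state, rows sorted by FDR q, or
  the two group-mean profiles when aggregated.

Given the same inputs, spec and seed the SVG output is byte-identical
(fixed hash salt, no embedded timestamps).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
from matplotlib.patches import Rectangle

from .domain import AFFECTED, UNAFFECTED, DataError, ExpressionMatrix, Patient
from .exprstats import GeneStat, group_mean_profiles
from .genotype import SimplifiedState, SnpViewColumn
from .network import DEFAULT_PALETTE, AssocGraph, assign_node_colors

#: chromatogram-convention base colors
BASE_COLORS = {"A": "#33a02c", "C": "#1f78b4", "G": "#ff7f00", "T": "#e31a1c"}

STATE_GRAY = {SimplifiedState.REF: "#ffffff",
              SimplifiedState.HET: "#808080",
              SimplifiedState.HOM: "#000000"}

GROUP_COLORS = {AFFECTED: "#ff8c00", UNAFFECTED: "#00bcd4"}


@dataclass(frozen=True)
class RenderSpec:
    width: float = 8.0            # inches
    height: float = 6.0
    palette: tuple[str, ...] = DEFAULT_PALETTE
    layout_seed: int = 0
    fmt: str = "svg"

    def __post_init__(self) -> None:
        if self.fmt not in ("svg", "png"):
            raise DataError(f"unknown output format {self.fmt!r}")


def _save(fig, spec: RenderSpec, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with matplotlib.rc_context({"svg.hashsalt": str(spec.layout_seed)}):
        if spec.fmt == "svg":
            fig.savefig(path, format="svg", metadata={"Date": None})
        else:
            fig.savefig(path, format="png", dpi=150)
    plt.close(fig)


def _call_patch(x, y, w, h, call, ax) -> None:
    """Draw one allele-pair box: solid for homozygous, two-color hatched
    for heterozygous, light gray cross for missing."""
    if call is None:
        ax.add_patch(Rectangle((x, y), w, h, facecolor="#eeeeee",
                               edgecolor="#999999", hatch="xx", linewidth=0.3))
        return
    a, b = call[0], call[1]
    if a == b:
        ax.add_patch(Rectangle((x, y), w, h, facecolor=BASE_COLORS[a],
                               edgecolor="black", linewidth=0.3))
    else:
        ax.add_patch(Rectangle((x, y), w, h, facecolor=BASE_COLORS[a],
                               edgecolor=BASE_COLORS[b], hatch="////",
                               linewidth=0.5))


def render_association_graph(
    graph: AssocGraph, spec: RenderSpec, path: str | Path
) -> None:
    """Draw the association gene network with a seeded spring layout."""
    if graph.graph.number_of_nodes() == 0:
        raise DataError("cannot render an empty graph")
    assign_node_colors(graph, spec.palette)
    g = graph.graph
    pos = nx.spring_layout(g, seed=spec.layout_seed)
    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    max_w = max((attrs["weight"] for *_, attrs in g.edges(keys=True, data=True)),
                default=1)
    # parallel multi-edges get distinct curvatures so both arcs are visible
    by_pair: dict[tuple[str, str], int] = {}
    for u, v, key, attrs in sorted(g.edges(keys=True, data=True)):
        pair = tuple(sorted((u, v)))
        k = by_pair.get(pair, 0)
        by_pair[pair] = k + 1
        rad = 0.12 * ((k + 1) // 2) * (-1 if k % 2 else 1)
        color = g.nodes[attrs["color_gene"]].get("color", "gray")
        width = 0.5 + 3.0 * attrs["weight"] / max_w
        if u == v:
            rad = 0.3 + 0.15 * k
        ax.annotate(
            "", xy=pos[v], xytext=pos[u],
            arrowprops=dict(arrowstyle="-", color=color, linewidth=width,
                            connectionstyle=f"arc3,rad={rad}"),
        )
        mid = (np.asarray(pos[u]) + np.asarray(pos[v])) / 2
        ax.text(mid[0], mid[1] + rad * 0.3, str(attrs["weight"]),
                fontsize=7, ha="center", color=color)
    node_colors = [g.nodes[n].get("color", "gray") for n in g.nodes]
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color=node_colors,
                           edgecolors="black", node_size=600)
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=8)
    ax.set_axis_off()
    _save(fig, spec, path)


# sector heights (axis units) of the genotype view, top to bottom
_H_SIG, _H_ID, _H_DIST, _H_SUM, _H_REF, _H_IND = 2.0, 0.8, 3.0, 1.5, 0.5, 0.5


def render_genotype_view(
    columns: list[SnpViewColumn],
    mode: str = "side_by_side",
    path: str | Path = "genotype_view.svg",
    spec: RenderSpec = RenderSpec(),
) -> None:
    """Draw the genotype view: one column per SNP, six sectors each.

    ``mode`` switches the consensus summary boxes between ``side_by_side``
    (affected | unaffected at full sector height) and ``stacked``
    (on top of each other at half height).
    """
    if not columns:
        raise DataError("need at least one SNP column")
    if mode not in ("side_by_side", "stacked"):
        raise DataError(f"unknown genotype-view mode {mode!r}")
    ncol = len(columns)
    fig, ax = plt.subplots(
        figsize=(max(spec.width, 0.45 * ncol), spec.height))
    max_nlp = max(max(c.neg_log_p for c in columns), 1.0)
    total_h = _H_SIG + _H_ID + _H_DIST + _H_SUM + _H_REF + _H_IND
    y_sig = total_h - _H_SIG
    y_id = y_sig - _H_ID
    y_dist = y_id - _H_DIST
    y_sum = y_dist - _H_SUM
    y_ref = y_sum - _H_REF
    y_ind = 0.0

    for i, col in enumerate(columns):
        x = i + 0.05
        w = 0.9
        # 1: significance bar (-log10 p, Manhattan-style)
        bar_h = _H_SIG * min(col.neg_log_p / max_nlp, 1.0)
        ax.add_patch(Rectangle((x + 0.25 * w, y_sig), 0.5 * w, bar_h,
                               facecolor="#444444"))
        # 2: identifier
        ax.text(i + 0.5, y_id + _H_ID / 2, col.snp_id, fontsize=6,
                rotation=90, ha="center", va="center")
        # 3: cohort genotype distribution, two aligned sub-columns
        a, u = col.summaries[AFFECTED], col.summaries[UNAFFECTED]
        cats = sorted(set(a.dist) | set(u.dist))
        na, nu = max(a.n_called, 1), max(u.n_called, 1)
        slots = [max(a.dist.get(c, 0) / na, u.dist.get(c, 0) / nu)
                 for c in cats]
        scale = _H_DIST / max(sum(slots), 1e-9)
        y_cursor = y_dist + _H_DIST
        for cat, slot in zip(cats, slots):
            slot_h = slot * scale
            y_cursor -= slot_h
            fa = a.dist.get(cat, 0) / na * scale
            fu = u.dist.get(cat, 0) / nu * scale
            if fa > 0:
                _call_patch(x, y_cursor, w * 0.45, fa, cat, ax)
            if fu > 0:
                _call_patch(x + 0.5 * w, y_cursor, w * 0.45, fu, cat, ax)
        # 4: cohort genotype summary (consensus boxes)
        for k, summ in enumerate((a, u)):
            if summ.consensus is None:
                continue
            gray = STATE_GRAY[summ.consensus]
            if mode == "side_by_side":
                bh = _H_SUM * summ.strength
                ax.add_patch(Rectangle((x + k * 0.5 * w, y_sum), 0.45 * w, bh,
                                       facecolor=gray, edgecolor="black",
                                       linewidth=0.4))
            else:  # stacked: half height each, affected on top
                half = _H_SUM / 2
                bh = half * summ.strength
                y0 = y_sum + half if k == 0 else y_sum
                ax.add_patch(Rectangle((x, y0), w, bh, facecolor=gray,
                                       edgecolor="black", linewidth=0.4))
        # 5: genome reference box
        ax.add_patch(Rectangle((x, y_ref), w, _H_REF,
                               facecolor=BASE_COLORS[col.ref_allele],
                               edgecolor="black", linewidth=0.3))
        # 6: individual patient alleles
        _call_patch(x, y_ind, w, _H_IND, col.individual_call, ax)
        if col.relevant:
            ax.add_patch(Rectangle((i, 0), 1.0, total_h, fill=False,
                                   edgecolor="red", linewidth=0.8))
    ax.set_xlim(0, ncol)
    ax.set_ylim(0, total_h)
    ax.set_axis_off()
    _save(fig, spec, path)


def render_heatmap(
    expr: ExpressionMatrix,
    stats: list[GeneStat],
    patients: list[Patient],
    aggregate: bool = False,
    path: str | Path = "heatmap.svg",
    spec: RenderSpec = RenderSpec(),
) -> None:
    """Expression heatmap with the FDR-sorted gene order.

    Values are centered per gene and mapped to a symmetric diverging
    gradient.  Columns are grouped by disease state under a group color
    bar; ``aggregate=True`` collapses each group to its mean profile.
    """
    by_gene = {s.gene: s for s in stats}
    missing = [g for g in expr.genes if g not in by_gene]
    if missing:
        raise DataError(f"stats missing for gene(s) {missing}")
    gene_order = sorted(expr.genes, key=lambda g: (by_gene[g].q, by_gene[g].p,
                                                   g))
    values = expr.values.loc[gene_order]
    if aggregate:
        profiles = group_mean_profiles(expr, patients)
        data = np.column_stack([profiles[AFFECTED].loc[gene_order],
                                profiles[UNAFFECTED].loc[gene_order]])
        col_groups = [AFFECTED, UNAFFECTED]
    else:
        group = {p.individual_id: p.group for p in patients}
        cols = [p for p in expr.patients if group.get(p) == AFFECTED] \
            + [p for p in expr.patients if group.get(p) == UNAFFECTED]
        data = values[cols].to_numpy()
        col_groups = [group[c] for c in cols]
    centered = data - data.mean(axis=1, keepdims=True)
    vmax = max(np.abs(centered).max(), 1e-12)

    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    ax.imshow(centered, aspect="auto", cmap="PiYG_r", vmin=-vmax, vmax=vmax,
              interpolation="nearest")
    for j, grp in enumerate(col_groups):
        ax.add_patch(Rectangle((j - 0.5, -0.9), 1.0, 0.4,
                               facecolor=GROUP_COLORS[grp], clip_on=False))
    ax.set_yticks(range(len(gene_order)))
    ax.set_yticklabels(
        [f"{g} (q={by_gene[g].q:.3g})" for g in gene_order], fontsize=7)
    ax.set_xticks([])
    ax.set_title("aggregated group means" if aggregate else
                 "expression (centered per gene)", fontsize=9)
    _save(fig, spec, path)
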