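"""Genotype-view model: group distributions, consensus, relevance, chi2.

A patient's unordered allele pair at a SNP is *simplified* against the
reference base to one of three states — REF (no non-reference allele),
HET (one), HOM (two, even when the two non-reference alleles differ).
Within each phenotype group the majority simplified state is the group's
*consensus* and the fraction of non-missing patients carrying it is the
consensus *strength* (the height of the summary box in the rendered
view).

A SNP is *relevant* when the two groups disagree in consensus state or
their strengths differ by at least ``delta`` (default 10 percentage
points, inclusive).  Independently, a Pearson chi-square test compares
the raw genotype distributions (allele combinations) of the two groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import IntEnum
from typing import Optional

from scipy import stats as sps

from .domain import (
    AFFECTED,
    GROUPS,
    UNAFFECTED,
    DataError,
    GenotypeMatrix,
    Patient,
    SingleLocusResult,
    SnpMeta,
    patients_by_group,
)

logger = logging.getLogger(__name__)

#: strength-difference tolerance for the inclusive >= comparison on exact
#: fractions (guards against float rounding of e.g. 0.75 - 0.65)
STRENGTH_TOL = 1e-12

NEG_LOG_P_FLOOR = 1e-300


class SimplifiedState(IntEnum):
    """Number of non-reference alleles; the declared tie-break order is
    REF < HET < HOM."""

    REF = 0
    HET = 1
    HOM = 2


def simplify_genotype(call: Optional[str], ref: str) -> Optional[SimplifiedState]:
    """Simplify an allele pair against the reference base; MISSING -> None."""
    if ref not in "ACGT" or len(ref) != 1:
        raise DataError(f"invalid reference base {ref!r}")
    if call is None:
        return None
    non_ref = sum(1 for allele in call if allele != ref)
    return SimplifiedState(non_ref)


@dataclass
class GroupSummary:
    """Aggregate of one SNP within one phenotype group."""

    snp_id: str
    group: str
    dist: dict[str, int]                      # allele pair -> count
    state_counts: dict[SimplifiedState, int]  # simplified state -> count
    consensus: Optional[SimplifiedState]      # None when the group is all-missing
    strength: float                           # majority fraction, 0 if undefined
    n_missing: int
    tie: bool = False

    @property
    def n_called(self) -> int:
        return sum(self.state_counts.values())


def _summarize_one_group(snp_id: str, group: str, calls: list[Optional[str]],
                         ref: str) -> GroupSummary:
    dist: dict[str, int] = {}
    state_counts: dict[SimplifiedState, int] = {s: 0 for s in SimplifiedState}
    n_missing = 0
    for call in calls:
        state = simplify_genotype(call, ref)
        if state is None:
            n_missing += 1
            continue
        dist[call] = dist.get(call, 0) + 1
        state_counts[state] += 1
    n_called = sum(state_counts.values())
    if n_called == 0:
        return GroupSummary(snp_id, group, dist, state_counts,
                            consensus=None, strength=0.0, n_missing=n_missing)
    best = max(state_counts.values())
    # argmax with the declared REF < HET < HOM tie-break (IntEnum order)
    winners = [s for s in SimplifiedState if state_counts[s] == best]
    consensus = winners[0]
    tie = len(winners) > 1
    if tie:
        logger.debug("consensus tie for SNP %s in group %s: %s", snp_id, group,
                     winners)
    return GroupSummary(snp_id, group, dist, state_counts, consensus,
                        strength=best / n_called, n_missing=n_missing, tie=tie)


def summarize_group(
    matrix: GenotypeMatrix,
    patients: list[Patient],
    snp_id: str,
    ref: str,
) -> dict[str, GroupSummary]:
    """Per-group genotype aggregation for one SNP.

    Returns ``{"affected": ..., "unaffected": ...}``.  MISSING calls are
    excluded from all counts (but tallied in ``n_missing``); a group with
    only missing calls gets an undefined consensus and strength 0.
    """
    column = matrix.column(snp_id)  # raises on absent SNP
    groups = patients_by_group(patients)
    out: dict[str, GroupSummary] = {}
    for group in GROUPS:
        ids = [pid for pid in groups[group] if pid in column.index]
        calls = [column.at[pid] for pid in ids]
        out[group] = _summarize_one_group(snp_id, group, calls, ref)
    return out


def summarize_all(
    matrix: GenotypeMatrix,
    patients: list[Patient],
    refs: dict[str, str],
    snp_ids: Optional[list[str]] = None,
) -> dict[str, dict[str, GroupSummary]]:
    """``summarize_group`` over many SNPs -> {snp_id: {group: summary}}."""
    snp_ids = list(matrix.snps) if snp_ids is None else list(snp_ids)
    out = {}
    for snp_id in snp_ids:
        if snp_id not in refs:
            raise DataError(f"no reference base for SNP {snp_id!r}")
        out[snp_id] = summarize_group(matrix, patients, snp_id, refs[snp_id])
    return out


def detect_relevant_snps(
    summaries: dict[str, dict[str, GroupSummary]],
    delta: float = 0.10,
) -> set[str]:
    """SNPs whose groups differ in consensus state, or in consensus
    strength by at least ``delta`` (inclusive, compared on exact fractions
    with a 1e-12 tolerance).

    SNPs with an undefined consensus in either group are excluded (and
    logged).
    """
    relevant: set[str] = set()
    excluded = 0
    for snp_id, per_group in summaries.items():
        a, u = per_group[AFFECTED], per_group[UNAFFECTED]
        if a.consensus is None or u.consensus is None:
            excluded += 1
            continue
        if a.consensus != u.consensus:
            relevant.add(snp_id)
        elif abs(a.strength - u.strength) >= delta - STRENGTH_TOL:
            relevant.add(snp_id)
    if excluded:
        logger.info("%d SNP(s) excluded from relevance detection "
                    "(all-missing in one group)", excluded)
    return relevant


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p: float
    degenerate: bool = False
    low_expected: bool = False

    def __iter__(self):
        return iter((self.statistic, self.df, self.p))


def chi2_independence(
    dist_affected: dict[str, int],
    dist_unaffected: dict[str, int],
) -> Chi2Result:
    """Pearson chi-square test of independence between phenotype group and
    genotype category.

    The 2 x c contingency table has rows (affected, unaffected) and one
    column per genotype category with a nonzero column total; no
    continuity correction and no pooling of sparse cells (expected counts
    below 5 only set ``low_expected``).  Fewer than two nonzero columns
    (or an empty group) is degenerate: statistic 0, p = 1.
    """
    cats = sorted(set(dist_affected) | set(dist_unaffected))
    cols = [(dist_affected.get(c, 0), dist_unaffected.get(c, 0)) for c in cats]
    cols = [col for col in cols if col[0] + col[1] > 0]
    c = len(cols)
    row_a = sum(col[0] for col in cols)
    row_u = sum(col[1] for col in cols)
    total = row_a + row_u
    if c < 2 or row_a == 0 or row_u == 0:
        return Chi2Result(0.0, 0, 1.0, degenerate=True)
    statistic = 0.0
    low_expected = False
    for obs_a, obs_u in cols:
        col_total = obs_a + obs_u
        for obs, row_total in ((obs_a, row_a), (obs_u, row_u)):
            expected = row_total * col_total / total
            if expected < 5:
                low_expected = True
            statistic += (obs - expected) ** 2 / expected
    df = c - 1  # (2 - 1) * (c - 1)
    p = float(sps.chi2.sf(statistic, df))
    if low_expected:
        logger.debug("chi2 table has expected counts < 5")
    return Chi2Result(statistic, df, p, low_expected=low_expected)


def chi2_for_snp(per_group: dict[str, GroupSummary],
                 categories: str = "raw") -> Chi2Result:
    """chi2 test for one summarized SNP.

    ``categories='raw'`` (default) uses allele-pair genotypes;
    ``'simplified'`` uses the three-state simplification.
    """
    a, u = per_group[AFFECTED], per_group[UNAFFECTED]
    if categories == "raw":
        return chi2_independence(a.dist, u.dist)
    if categories == "simplified":
        da = {s.name: n for s, n in a.state_counts.items()}
        du = {s.name: n for s, n in u.state_counts.items()}
        return chi2_independence(da, du)
    raise ValueError(f"unknown chi2 category mode {categories!r}")


def neg_log_p(p: float, floor: float = NEG_LOG_P_FLOOR) -> float:
    """-log10(p), clamped at ``floor`` so p = 0 maps to 300."""
    return -math.log10(max(p, floor))


@dataclass
class SnpViewColumn:
    """Everything one column of the rendered genotype view needs."""

    snp_id: str
    chrom: Optional[str]
    pos: Optional[int]
    neg_log_p: float
    best_trait: Optional[str]        # argmin trait of the single-locus p
    summaries: dict[str, GroupSummary]
    ref_allele: str
    individual_call: Optional[str]
    relevant: bool
    chi2_stat: float
    chi2_p: float


def build_genotype_view_model(
    selection: list[str],
    matrix: GenotypeMatrix,
    patients: list[Patient],
    refs: dict[str, str],
    snp_meta: dict[str, SnpMeta],
    single_results: list[SingleLocusResult],
    focus_patient: str,
    delta: float = 0.10,
    order: str = "position",
    chi2_categories: str = "raw",
) -> list[SnpViewColumn]:
    """Assemble the ordered per-SNP column models of the genotype view.

    The significance bar shows -log10 of the SNP's best (minimum over
    traits) single-locus p, clamped at 1e-300.  ``order`` is
    ``"position"`` (chrom, pos; SNPs without coordinates last) or
    ``"majority"`` (consensus state of the affected group, then strength
    descending).
    """
    if focus_patient not in matrix.patients:
        raise DataError(f"focus patient {focus_patient!r} not in cohort")
    best_p: dict[str, tuple[float, str]] = {}
    for r in single_results:
        cur = best_p.get(r.snp_id)
        if cur is None or r.p < cur[0]:
            best_p[r.snp_id] = (r.p, r.trait_gene)
    summaries = summarize_all(matrix, patients, refs, selection)
    relevant = detect_relevant_snps(summaries, delta=delta)

    columns: list[SnpViewColumn] = []
    for snp_id in selection:
        meta = snp_meta.get(snp_id) or SnpMeta.from_id(snp_id)
        p, trait = best_p.get(snp_id, (1.0, None))
        chi2 = chi2_for_snp(summaries[snp_id], categories=chi2_categories)
        columns.append(SnpViewColumn(
            snp_id=snp_id,
            chrom=meta.chrom,
            pos=meta.pos,
            neg_log_p=neg_log_p(p),
            best_trait=trait,
            summaries=summaries[snp_id],
            ref_allele=refs[snp_id],
            individual_call=matrix.call(focus_patient, snp_id),
            relevant=snp_id in relevant,
            chi2_stat=chi2.statistic,
            chi2_p=chi2.p,
        ))
    if order == "position":
        columns.sort(key=lambda c: (c.chrom is None,
                                    c.chrom or "", c.pos or 0, c.snp_id))
    elif order == "majority":
        columns.sort(key=lambda c: (
            c.summaries[AFFECTED].consensus is None,
            int(c.summaries[AFFECTED].consensus or 0),
            -c.summaries[AFFECTED].strength,
            c.snp_id,
        ))
    else:
        raise ValueError(f"unknown column order {order!r}")
    return columns


def view_model_table(columns: list[SnpViewColumn]):
    """Flatten view columns to a pandas DataFrame (one row per SNP) for
    the tab-separated companion table."""
    import pandas as pd

    rows = []
    for c in columns:
        a = c.summaries[AFFECTED]
        u = c.summaries[UNAFFECTED]
        rows.append({
            "SNP": c.snp_id,
            "CHR": c.chrom or "",
            "POS": c.pos if c.pos is not None else "",
            "NEG_LOG_P": c.neg_log_p,
            "BEST_TRAIT": c.best_trait or "",
            "REF": c.ref_allele,
            "CONSENSUS_AFF": a.consensus.name if a.consensus is not None else "",
            "STRENGTH_AFF": a.strength,
            "N_MISSING_AFF": a.n_missing,
            "CONSENSUS_UNAFF": u.consensus.name if u.consensus is not None else "",
            "STRENGTH_UNAFF": u.strength,
            "N_MISSING_UNAFF": u.n_missing,
            "INDIVIDUAL": c.individual_call or "",
            "RELEVANT": int(c.relevant),
            "CHI2_STAT": c.chi2_stat,
            "CHI2_P": c.chi2_p,
        })
    return pd.DataFrame(rows)
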