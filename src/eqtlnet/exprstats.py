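"""Differential expression statistics and PLINK-mirror association scans.

The per-gene group comparison is a two-sample t-test (Welch by default)
with Benjamini-Hochberg FDR control across genes.  The single- and
two-locus scans regress expression on additive genotype codes (count of
non-reference alleles, 0/1/2, missing calls dropped per test) and mirror
the shape of PLINK quantitative-trait outputs so the whole pipeline can
be exercised without external tools; they are a mirror of that
convention, not a reimplementation of PLINK.  The two-locus model is

    expression ~ codeA + codeB + codeA * codeB

and the reported pair p-value is the t-test on the interaction term.

Both scans are closed-form least squares vectorized across SNPs/pairs
with per-test missing-data masks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .domain import (
    AFFECTED,
    UNAFFECTED,
    DataError,
    ExpressionMatrix,
    GenotypeMatrix,
    PairResult,
    Patient,
    SingleLocusResult,
    patients_by_group,
)

_COND_MAX = 1e10  # condition-number cutoff for a collinear two-locus design


@dataclass(frozen=True)
class GeneStat:
    gene: str
    t_stat: float
    p: float
    q: float
    rank: int  # 1 = most significant


def ttest_per_gene(
    expr: ExpressionMatrix,
    patients: list[Patient],
    equal_var: bool = False,
) -> list[tuple[str, float, float]]:
    """Two-sample t-test per gene between affected and unaffected
    patients (Welch by default; ``equal_var=True`` pools variances).

    Returns (gene, t, p) in the expression matrix's gene order.  Genes
    with zero variance in both groups get t=0, p=1 when the means agree
    (and p=0 otherwise).
    """
    groups = patients_by_group(patients)
    cols = set(expr.patients)
    aff = [p for p in groups[AFFECTED] if p in cols]
    unaff = [p for p in groups[UNAFFECTED] if p in cols]
    if len(aff) < 2 or len(unaff) < 2:
        raise DataError(
            f"need >= 2 patients per group, got {len(aff)} affected / "
            f"{len(unaff)} unaffected"
        )
    a = expr.values[aff].to_numpy()
    u = expr.values[unaff].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(a, u, axis=1, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        same = np.isclose(a.mean(axis=1), u.mean(axis=1))
        t[degenerate & same] = 0.0
        p[degenerate & same] = 1.0
        diff = degenerate & ~same
        t[diff] = np.sign(a.mean(axis=1)[diff] - u.mean(axis=1)[diff]) * np.inf
        p[diff] = 0.0
    return [(g, float(t[i]), float(p[i])) for i, g in enumerate(expr.genes)]


def bh_fdr(pvals: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} (m * p_(j) / j), clipped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def gene_stats(
    expr: ExpressionMatrix,
    patients: list[Patient],
    equal_var: bool = False,
) -> list[GeneStat]:
    """t-test + BH-FDR + significance rank for every gene.

    Ranks order genes by p ascending (ties broken by gene name), 1 = most
    significant.
    """
    trios = ttest_per_gene(expr, patients, equal_var=equal_var)
    q = bh_fdr([p for _, _, p in trios])
    order = sorted(range(len(trios)), key=lambda i: (trios[i][2], trios[i][0]))
    rank = {i: r + 1 for r, i in enumerate(order)}
    return [GeneStat(g, t, p, float(q[i]), rank[i])
            for i, (g, t, p) in enumerate(trios)]


def group_mean_profiles(
    expr: ExpressionMatrix, patients: list[Patient]
) -> dict[str, pd.Series]:
    """Arithmetic mean expression per gene per phenotype group."""
    groups = patients_by_group(patients)
    cols = set(expr.patients)
    out: dict[str, pd.Series] = {}
    for group in (AFFECTED, UNAFFECTED):
        ids = [p for p in groups[group] if p in cols]
        if not ids:
            raise DataError(f"group {group!r} is empty")
        out[group] = expr.values[ids].mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# Additive genotype coding and regression scans


def additive_codes(
    matrix: GenotypeMatrix, refs: dict[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Additive 0/1/2 coding (count of non-reference alleles).

    Returns (codes, mask), both patients x SNPs; missing calls have
    code 0 and mask 0.
    """
    n, m = matrix.shape
    codes = np.zeros((n, m), dtype=float)
    mask = np.zeros((n, m), dtype=float)
    for j, snp in enumerate(matrix.snps):
        try:
            ref = refs[snp]
        except KeyError:
            raise DataError(f"no reference base for SNP {snp!r}") from None
        col = matrix.calls[snp].to_numpy(dtype=object)
        for i, call in enumerate(col):
            if call is None:
                continue
            codes[i, j] = (call[0] != ref) + (call[1] != ref)
            mask[i, j] = 1.0
    return codes, mask


def _aligned_arrays(expr: ExpressionMatrix, matrix: GenotypeMatrix,
                    refs: dict[str, str]):
    missing = [p for p in matrix.patients if p not in set(expr.patients)]
    if missing:
        raise DataError(
            f"{len(missing)} genotyped patient(s) missing from the "
            f"expression table (e.g. {missing[0]!r})"
        )
    y = expr.values[matrix.patients].to_numpy()  # genes x patients
    codes, mask = additive_codes(matrix, refs)
    return y, codes, mask


def single_locus_scan(
    expr: ExpressionMatrix,
    matrix: GenotypeMatrix,
    refs: dict[str, str],
) -> list[SingleLocusResult]:
    """Simple linear regression of each gene's expression on each SNP's
    additive code; reports the slope t-test p and the model R^2.

    Monomorphic SNPs (or any degenerate fit) yield p=1, r2=0, flagged.
    Results are ordered gene-major, matching ``for gene: for snp``.
    """
    y_all, x, m = _aligned_arrays(expr, matrix, refs)
    snps = matrix.snps
    results: list[SingleLocusResult] = []
    xm = x * m
    x2m = x * xm
    for gi, gene in enumerate(expr.genes):
        y = y_all[gi]
        n = m.sum(axis=0)
        sx = xm.sum(axis=0)
        sxx = x2m.sum(axis=0)
        sy = m.T @ y
        sxy = xm.T @ y
        syy = m.T @ (y * y)
        with np.errstate(invalid="ignore", divide="ignore"):
            sxx_c = sxx - sx * sx / n
            sxy_c = sxy - sx * sy / n
            syy_c = syy - sy * sy / n
            df = n - 2
            ok = (df >= 1) & (sxx_c > 1e-12) & (syy_c > 1e-12)
            r2 = np.where(ok, sxy_c**2 / np.where(ok, sxx_c * syy_c, 1.0), 0.0)
            r2 = np.clip(r2, 0.0, 1.0)
            t2 = np.where(ok & (r2 < 1.0), r2 * df / (1.0 - r2), np.inf)
            p = np.where(ok, 2.0 * sps.t.sf(np.sqrt(np.where(ok, t2, 0.0)),
                                            np.maximum(df, 1)), 1.0)
        p = np.clip(np.where(np.isfinite(p), p, 0.0), 0.0, 1.0)
        for j, snp in enumerate(snps):
            flagged = not bool(ok[j])
            results.append(SingleLocusResult(
                snp, gene,
                p=1.0 if flagged else float(p[j]),
                r2=0.0 if flagged else float(r2[j]),
                flagged=flagged,
            ))
    return results


def all_pairs(snps: list[str]) -> list[tuple[str, str]]:
    """All unordered SNP pairs in canonical (sorted-id) order."""
    return [tuple(sorted(pair)) for pair in itertools.combinations(snps, 2)]


def two_locus_scan(
    expr: ExpressionMatrix,
    matrix: GenotypeMatrix,
    refs: dict[str, str],
    pairs: list[tuple[str, str]] | None = None,
    chunk: int = 4096,
) -> list[PairResult]:
    """Interaction scan: expression ~ codeA + codeB + codeA*codeB per
    (SNP pair, gene); the reported p is the interaction-term t-test p.

    ``pairs=None`` scans all unordered pairs.  Collinear designs (e.g. a
    SNP paired with a duplicate of itself) are flagged with p=1.  Results
    are gene-major, then in the order of ``pairs``.
    """
    y_all, x, mask = _aligned_arrays(expr, matrix, refs)
    snps = matrix.snps
    index = {s: j for j, s in enumerate(snps)}
    if pairs is None:
        pairs = all_pairs(snps)
    for a, b in pairs:
        if a == b:
            raise DataError(f"self-pair ({a}, {b}) in scan request")
        if a not in index or b not in index:
            raise DataError(f"pair ({a}, {b}) references an unknown SNP")
    ia = np.array([index[a] for a, _ in pairs], dtype=int)
    ib = np.array([index[b] for _, b in pairs], dtype=int)

    n_pairs = len(pairs)
    genes = expr.genes
    p_out = np.ones((len(genes), n_pairs))
    flag_out = np.zeros(n_pairs, dtype=bool)

    for lo in range(0, n_pairs, chunk):
        hi = min(lo + chunk, n_pairs)
        ja, jb = ia[lo:hi], ib[lo:hi]
        mp = mask[:, ja] * mask[:, jb]              # patients x pairs
        am = x[:, ja] * mp
        bm = x[:, jb] * mp
        abm = am * x[:, jb]
        a2 = am * x[:, ja]
        b2 = bm * x[:, jb]
        n = mp.sum(axis=0)
        sa, sb, sab = am.sum(axis=0), bm.sum(axis=0), abm.sum(axis=0)
        saa, sbb = a2.sum(axis=0), b2.sum(axis=0)
        saab = (a2 * x[:, jb]).sum(axis=0)
        sabb = (abm * x[:, jb]).sum(axis=0)
        saabb = (a2 * b2).sum(axis=0)  # mp is binary, so mp^2 == mp
        gram = np.empty((hi - lo, 4, 4))
        gram[:, 0, 0] = n
        gram[:, 0, 1] = gram[:, 1, 0] = sa
        gram[:, 0, 2] = gram[:, 2, 0] = sb
        gram[:, 0, 3] = gram[:, 3, 0] = sab
        gram[:, 1, 1] = saa
        gram[:, 1, 2] = gram[:, 2, 1] = sab
        gram[:, 1, 3] = gram[:, 3, 1] = saab
        gram[:, 2, 2] = sbb
        gram[:, 2, 3] = gram[:, 3, 2] = sabb
        gram[:, 3, 3] = saabb
        df = n - 4.0
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = np.linalg.cond(gram)
        bad = (~np.isfinite(cond)) | (cond > _COND_MAX) | (df < 1)
        safe = gram.copy()
        safe[bad] = np.eye(4)
        ginv = np.linalg.inv(safe)
        flag_out[lo:hi] = bad

        for gi in range(len(genes)):
            y = y_all[gi]
            v = np.stack([mp.T @ y, am.T @ y, bm.T @ y, abm.T @ y], axis=1)
            syy = mp.T @ (y * y)
            beta = np.einsum("pij,pj->pi", ginv, v)
            rss = np.maximum(syy - np.einsum("pi,pi->p", beta, v), 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                sigma2 = rss / np.maximum(df, 1.0)
                var3 = sigma2 * ginv[:, 3, 3]
                tstat = beta[:, 3] / np.sqrt(var3)
            ok = (~bad) & np.isfinite(tstat)
            pvals = np.ones(hi - lo)
            pvals[ok] = 2.0 * sps.t.sf(np.abs(tstat[ok]),
                                       np.maximum(df[ok], 1.0))
            # an exact fit (rss == 0) is maximally significant, not degenerate
            exact = (~bad) & ~np.isfinite(tstat) & (rss <= 1e-12) \
                & (np.abs(beta[:, 3]) > 1e-12)
            pvals[exact] = 0.0
            p_out[gi, lo:hi] = np.clip(pvals, 0.0, 1.0)

    results: list[PairResult] = []
    for gi, gene in enumerate(genes):
        for k, (a, b) in enumerate(pairs):
            results.append(PairResult.make(
                a, b, gene,
                p=1.0 if flag_out[k] else float(p_out[gi, k]),
                flagged=bool(flag_out[k]),
            ))
    return results
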