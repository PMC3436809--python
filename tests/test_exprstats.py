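"""Differential-expression statistics and the regression scans."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

import eqtlnet as eq
from eqtlnet.domain import (
    AFFECTED,
    UNAFFECTED,
    ExpressionMatrix,
    GenotypeMatrix,
    Patient,
)


def make_patients(n_aff, n_unaff):
    return ([Patient(f"F{i}", f"P{i}", AFFECTED) for i in range(n_aff)]
            + [Patient(f"F{i}", f"P{i}", UNAFFECTED)
               for i in range(n_aff, n_aff + n_unaff)])


def expr_matrix(values: np.ndarray, genes=None):
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    pats = [f"P{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=pats))


class TestTTest:
    def test_identical_groups_give_t0_p1(self):
        expr = expr_matrix(np.ones((1, 8)))
        (gene, t, p), = eq.ttest_per_gene(expr, make_patients(4, 4))
        assert (t, p) == (0.0, 1.0)

    def test_huge_separation_is_certain(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 1, 50),
                               rng.normal(5, 1, 50)])[None, :]
        expr = expr_matrix(vals)
        (_, t, p), = eq.ttest_per_gene(expr, make_patients(50, 50))
        assert p < 1e-10 and t < 0

    def test_group_swap_negates_t_preserves_p(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, (3, 20))
        expr = expr_matrix(vals)
        fwd = eq.ttest_per_gene(expr, make_patients(10, 10))
        pats_swapped = [Patient(p.family_id, p.individual_id,
                                UNAFFECTED if p.group == AFFECTED else AFFECTED)
                        for p in make_patients(10, 10)]
        rev = eq.ttest_per_gene(expr, pats_swapped)
        for (g1, t1, p1), (g2, t2, p2) in zip(fwd, rev):
            assert t1 == pytest.approx(-t2)
            assert p1 == pytest.approx(p2)

    def test_shift_invariance_welch(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, (2, 30))
        pats = make_patients(15, 15)
        base = eq.ttest_per_gene(expr_matrix(vals), pats)
        shifted = eq.ttest_per_gene(expr_matrix(vals + 100.0), pats)
        for (_, t1, p1), (_, t2, p2) in zip(base, shifted):
            assert t1 == pytest.approx(t2, rel=1e-9)
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_tiny_group_rejected(self):
        expr = expr_matrix(np.ones((1, 3)))
        with pytest.raises(Exception, match="2 patients"):
            eq.ttest_per_gene(expr, make_patients(1, 2))


class TestBhFdr:
    def test_single_p_is_unchanged(self):
        assert eq.bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_applied_step_up_example(self):
        # step-up: 4*.01/1=.04, 4*.02/2=.04, 4*.03/3=.04, 4*.04/4=.04
        q = eq.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        assert eq.bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            mine = eq.bh_fdr(p)
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(mine, ref, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_qvalues_dominate_p_and_are_monotone(self, pvals):
        q = eq.bh_fdr(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        p = rng.random(25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(eq.bh_fdr(p)[perm], eq.bh_fdr(p[perm]),
                                   atol=1e-15)


class TestGeneStatsAndProfiles:
    def test_ranks_are_a_permutation_and_q_dominates_p(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, (6, 40))
        vals[0, :20] += 3.0  # make one gene clearly differential
        stats = eq.gene_stats(expr_matrix(vals), make_patients(20, 20))
        assert sorted(s.rank for s in stats) == list(range(1, 7))
        assert min(stats, key=lambda s: s.p).rank == 1
        for s in stats:
            assert s.q >= s.p - 1e-15

    def test_group_means_and_conservation(self):
        vals = np.array([[1.0, 3.0, 5.0, 7.0]])
        expr = expr_matrix(vals)
        prof = eq.group_mean_profiles(expr, make_patients(2, 2))
        assert prof[AFFECTED]["G0"] == pytest.approx(2.0)
        assert prof[UNAFFECTED]["G0"] == pytest.approx(6.0)
        # n_a*mean_a + n_u*mean_u == n*overall mean
        assert 2 * 2.0 + 2 * 6.0 == pytest.approx(4 * vals.mean())


def geno_from_codes(codes: np.ndarray):
    """Codes (patients x snps) -> genotype matrix + refs, ref allele A."""
    geno = np.empty(codes.shape, dtype=object)
    lookup = {0: "AA", 1: "AC", 2: "CC"}
    for idx, c in np.ndenumerate(codes):
        geno[idx] = None if c < 0 else lookup[int(c)]
    pats = [f"P{i}" for i in range(codes.shape[0])]
    snps = [f"s{j}" for j in range(codes.shape[1])]
    matrix = GenotypeMatrix(pd.DataFrame(geno, index=pats, columns=snps))
    return matrix, {s: "A" for s in snps}


class TestSingleLocusScan:
    def test_additive_coding_counts_non_reference_alleles(self):
        matrix, refs = geno_from_codes(np.array([[0], [1], [2], [-1]]))
        codes, mask = eq.additive_codes(matrix, refs)
        np.testing.assert_array_equal(codes[:, 0], [0, 1, 2, 0])
        np.testing.assert_array_equal(mask[:, 0], [1, 1, 1, 0])

    def test_perfect_fit(self):
        codes = np.tile([0, 1, 2, 0, 1, 2], 5)[:, None].astype(float)
        matrix, refs = geno_from_codes(codes)
        expr = expr_matrix(2.0 * codes.T)
        (res,) = eq.single_locus_scan(expr, matrix, refs)
        assert res.r2 == pytest.approx(1.0)
        assert res.p < 1e-30

    def test_monomorphic_snp_flagged(self):
        codes = np.zeros((10, 1))
        matrix, refs = geno_from_codes(codes)
        expr = expr_matrix(np.random.default_rng(0).normal(size=(1, 10)))
        (res,) = eq.single_locus_scan(expr, matrix, refs)
        assert res.flagged and res.p == 1.0 and res.r2 == 0.0

    def test_agrees_with_statsmodels_ols(self):
        rng = np.random.default_rng(6)
        codes = rng.integers(0, 3, size=(60, 5)).astype(float)
        codes[rng.random(codes.shape) < 0.1] = -1  # sprinkle missing calls
        matrix, refs = geno_from_codes(codes)
        y = rng.normal(size=60) + 0.4 * np.where(codes[:, 0] >= 0,
                                                 codes[:, 0], 0)
        expr = expr_matrix(y[None, :])
        results = eq.single_locus_scan(expr, matrix, refs)
        for j, res in enumerate(results):
            keep = codes[:, j] >= 0
            fit = sm.OLS(y[keep], sm.add_constant(codes[keep, j])).fit()
            assert res.p == pytest.approx(fit.pvalues[1], abs=1e-8)
            assert res.r2 == pytest.approx(fit.rsquared, abs=1e-8)


class TestTwoLocusScan:
    def test_pure_interaction_detected(self):
        rng = np.random.default_rng(7)
        codes = rng.integers(0, 3, size=(80, 2)).astype(float)
        matrix, refs = geno_from_codes(codes)
        y = codes[:, 0] * codes[:, 1]
        expr = expr_matrix(y[None, :])
        (res,) = eq.two_locus_scan(expr, matrix, refs, pairs=[("s0", "s1")])
        assert res.p < 1e-6 and not res.flagged

    def test_collinear_duplicate_snp_flagged(self):
        codes = np.tile([0, 1, 2, 1], 10)[:, None]
        codes = np.column_stack([codes, codes])  # identical SNPs
        matrix, refs = geno_from_codes(codes.astype(float))
        expr = expr_matrix(np.random.default_rng(1).normal(size=(1, 40)))
        (res,) = eq.two_locus_scan(expr, matrix, refs, pairs=[("s0", "s1")])
        assert res.flagged and res.p == 1.0

    def test_agrees_with_statsmodels_interaction_model(self):
        rng = np.random.default_rng(8)
        codes = rng.integers(0, 3, size=(70, 4)).astype(float)
        codes[rng.random(codes.shape) < 0.08] = -1
        matrix, refs = geno_from_codes(codes)
        y = rng.normal(size=70) + 0.5 * np.where(
            (codes[:, 0] >= 0) & (codes[:, 1] >= 0),
            codes[:, 0] * codes[:, 1], 0)
        expr = expr_matrix(y[None, :])
        pairs = [("s0", "s1"), ("s1", "s2"), ("s2", "s3"), ("s0", "s3")]
        results = eq.two_locus_scan(expr, matrix, refs, pairs=pairs)
        for res, (a, b) in zip(results, pairs):
            ja, jb = int(a[1]), int(b[1])
            keep = (codes[:, ja] >= 0) & (codes[:, jb] >= 0)
            ca, cb = codes[keep, ja], codes[keep, jb]
            X = sm.add_constant(np.column_stack([ca, cb, ca * cb]))
            fit = sm.OLS(y[keep], X).fit()
            assert res.p == pytest.approx(fit.pvalues[3], abs=1e-8)

    def test_additive_only_data_interaction_is_null(self):
        """Type-I error of the interaction test on purely additive
        expression stays near the nominal 5% level."""
        rng = np.random.default_rng(9)
        n, m = 200, 42
        codes = rng.integers(0, 3, size=(n, m)).astype(float)
        matrix, refs = geno_from_codes(codes)
        pairs = [(f"s{2 * k}", f"s{2 * k + 1}") for k in range(m // 2)]
        reps = []
        for _ in range(10):
            y = (codes[:, 0] + codes[:, 1]
                 + rng.normal(0, 0.5, size=n))
            expr = expr_matrix(y[None, :])
            res = eq.two_locus_scan(expr, matrix, refs, pairs=pairs)
            reps.extend(r.p for r in res)
        frac = np.mean(np.asarray(reps) < 0.05)
        assert 0.01 <= frac <= 0.09  # 210 tests, 95% band around 0.05
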