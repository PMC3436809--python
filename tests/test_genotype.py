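"""Genotype simplification, group consensus, relevance rule and chi2."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

import eqtlnet as eq
from eqtlnet.domain import AFFECTED, UNAFFECTED, GenotypeMatrix, Patient
from eqtlnet.genotype import (
    GroupSummary,
    SimplifiedState,
    chi2_independence,
    neg_log_p,
)

REF, HET, HOM = SimplifiedState.REF, SimplifiedState.HET, SimplifiedState.HOM


class TestSimplify:
    @pytest.mark.parametrize("call, ref, state", [
        ("AA", "A", REF),
        ("AC", "A", HET),
        ("CC", "A", HOM),
        ("CG", "A", HOM),   # both alleles non-reference, even if different
        ("AC", "C", HET),
        (None, "A", None),
    ])
    def test_state_counts_non_reference_alleles(self, call, ref, state):
        assert eq.simplify_genotype(call, ref) == state

    def test_bad_reference_rejected(self):
        with pytest.raises(Exception):
            eq.simplify_genotype("AA", "N")


def cohort(calls_by_group: dict[str, list]) -> tuple[GenotypeMatrix,
                                                     list[Patient]]:
    """One-SNP cohort from per-group call lists."""
    patients, calls = [], []
    i = 0
    for group, cc in calls_by_group.items():
        for c in cc:
            patients.append(Patient(f"F{i}", f"P{i}", group))
            calls.append(c)
            i += 1
    df = pd.DataFrame({"snp": calls},
                      index=pd.Index([p.individual_id for p in patients]))
    return GenotypeMatrix(df), patients


class TestGroupSummary:
    def test_consensus_majority_and_strength(self):
        m, pats = cohort({AFFECTED: ["AA"] * 6 + ["AC"] * 3 + ["CC"],
                          UNAFFECTED: ["AA"] * 2})
        s = eq.summarize_group(m, pats, "snp", "A")[AFFECTED]
        assert s.consensus == REF
        assert s.strength == pytest.approx(0.6)
        assert s.state_counts == {REF: 6, HET: 3, HOM: 1}
        assert s.dist == {"AA": 6, "AC": 3, "CC": 1}

    def test_all_missing_group_is_degenerate_not_an_error(self):
        m, pats = cohort({AFFECTED: [None] * 5, UNAFFECTED: ["AA"]})
        s = eq.summarize_group(m, pats, "snp", "A")[AFFECTED]
        assert s.consensus is None
        assert s.strength == 0.0
        assert s.n_missing == 5

    def test_tie_breaks_in_state_order(self):
        m, pats = cohort({AFFECTED: ["AA"] * 5 + ["AC"] * 5,
                          UNAFFECTED: ["AA"]})
        s = eq.summarize_group(m, pats, "snp", "A")[AFFECTED]
        assert s.consensus == REF and s.tie
        assert s.strength == pytest.approx(0.5)

    def test_counts_conserve_group_size(self):
        m, pats = cohort({AFFECTED: ["AA", "AC", None, "CC", None],
                          UNAFFECTED: ["AA", "GG"]})
        for group, size in ((AFFECTED, 5), (UNAFFECTED, 2)):
            s = eq.summarize_group(m, pats, "snp", "A")[group]
            assert sum(s.state_counts.values()) + s.n_missing == size
            assert sum(s.dist.values()) == sum(s.state_counts.values())

    def test_absent_snp_raises(self):
        m, pats = cohort({AFFECTED: ["AA"], UNAFFECTED: ["AA"]})
        with pytest.raises(Exception, match="nope"):
            eq.summarize_group(m, pats, "nope", "A")


def summaries(state_a, strength_a, state_u, strength_u):
    def gs(group, state, strength):
        return GroupSummary("s", group, {}, {}, state, strength, 0)
    return {"s": {AFFECTED: gs(AFFECTED, state_a, strength_a),
                  UNAFFECTED: gs(UNAFFECTED, state_u, strength_u)}}


class TestRelevanceRule:
    @pytest.mark.parametrize("sa, ta, su, tu, expect", [
        (REF, 0.9, HET, 0.9, True),    # states differ
        (REF, 0.75, REF, 0.63, True),  # 12 points >= 10
        (REF, 0.75, REF, 0.70, False),  # 5 points < 10
        (REF, 0.75, REF, 0.65, True),  # exactly 10 points (inclusive)
    ])
    def test_state_or_strength_difference(self, sa, ta, su, tu, expect):
        got = eq.detect_relevant_snps(summaries(sa, ta, su, tu))
        assert (got == {"s"}) is expect

    def test_undefined_consensus_excluded(self):
        got = eq.detect_relevant_snps(summaries(None, 0.0, REF, 0.9))
        assert got == set()

    def test_inclusive_threshold_robust_to_float_rounding(self):
        # 0.85 - 0.75 is not exactly 0.1 in binary; must still be flagged
        got = eq.detect_relevant_snps(summaries(REF, 0.85, REF, 0.75))
        assert got == {"s"}

    def test_delta_extremes_reduce_to_pure_rules(self):
        s = summaries(REF, 0.9, REF, 0.2)
        assert eq.detect_relevant_snps(s, delta=1.01) == set()
        assert eq.detect_relevant_snps(summaries(REF, 0.5, HET, 0.5),
                                       delta=1.01) == {"s"}
        assert eq.detect_relevant_snps(s, delta=0.0) == {"s"}


class TestChi2:
    def test_perfect_independence(self):
        r = chi2_independence({"AA": 10, "AC": 10}, {"AA": 10, "AC": 10})
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_hand_computed_diagonal_table(self):
        # [[20,0],[0,20]]: all expected counts are 10, so the statistic is
        # 4 * (20-10)^2/10 ... summed over the four cells = 40, df = 1
        r = chi2_independence({"AA": 20, "CC": 0}, {"AA": 0, "CC": 20})
        assert r.statistic == pytest.approx(40.0)
        assert r.df == 1
        assert r.p < 1e-9

    def test_degenerate_single_category(self):
        r = chi2_independence({"AA": 15}, {"AA": 12})
        assert r.degenerate and r.p == 1.0

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            ncols = rng.integers(2, 4)
            table = rng.integers(0, 51, size=(2, ncols))
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            cats = [f"g{k}" for k in range(ncols)]
            mine = chi2_independence(dict(zip(cats, table[0])),
                                     dict(zip(cats, table[1])))
            ref_stat, ref_p, ref_df, _ = chi2_contingency(table,
                                                          correction=False)
            assert mine.statistic == pytest.approx(ref_stat, abs=1e-10)
            assert mine.p == pytest.approx(ref_p, abs=1e-10)
            assert mine.df == ref_df

    def test_symmetry_under_group_swap(self):
        a, u = {"AA": 12, "AC": 3}, {"AA": 5, "AC": 9}
        r1 = chi2_independence(a, u)
        r2 = chi2_independence(u, a)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p == pytest.approx(r2.p)


class TestViewModel:
    def _inputs(self):
        m, pats = cohort({AFFECTED: ["AA", "AC"], UNAFFECTED: ["AA", "AA"]})
        calls = pd.DataFrame(
            {"1:300": ["AA", "AC", "AA", "AA"],
             "1:100": ["CC", "CC", "AA", "AA"],
             "1:200": ["AA", "AA", "AA", "GG"]},
            index=m.calls.index)
        matrix = GenotypeMatrix(calls)
        refs = {s: "A" for s in calls.columns}
        meta = {s: eq.SnpMeta.from_id(s) for s in calls.columns}
        single = [eq.SingleLocusResult("1:100", "G1", 0.01, 0.5),
                  eq.SingleLocusResult("1:100", "G2", 0.5, 0.1)]
        return matrix, pats, refs, meta, single

    def test_columns_sorted_by_position(self):
        matrix, pats, refs, meta, single = self._inputs()
        cols = eq.build_genotype_view_model(
            list(matrix.snps), matrix, pats, refs, meta, single, "P0")
        assert [c.snp_id for c in cols] == ["1:100", "1:200", "1:300"]

    def test_neg_log_p_uses_best_trait_and_clamps(self):
        matrix, pats, refs, meta, single = self._inputs()
        cols = eq.build_genotype_view_model(
            list(matrix.snps), matrix, pats, refs, meta, single, "P0")
        col = next(c for c in cols if c.snp_id == "1:100")
        assert col.neg_log_p == pytest.approx(2.0)  # min p = 0.01
        assert col.best_trait == "G1"
        assert neg_log_p(0.0) == pytest.approx(300.0)

    def test_focus_patient_call_recorded(self):
        matrix, pats, refs, meta, single = self._inputs()
        cols = eq.build_genotype_view_model(
            ["1:100"], matrix, pats, refs, meta, single, "P1")
        assert cols[0].individual_call == "CC"

    def test_unknown_focus_patient_raises(self):
        matrix, pats, refs, meta, single = self._inputs()
        with pytest.raises(Exception, match="focus patient"):
            eq.build_genotype_view_model(["1:100"], matrix, pats, refs, meta,
                                         single, "nobody")


@given(st.lists(st.sampled_from(["AA", "AC", "CC", "CG", None]),
                min_size=2, max_size=30),
       st.lists(st.sampled_from(["AA", "AC", "CC", "CG", None]),
                min_size=2, max_size=30))
def test_group_swap_symmetry_property(calls_a, calls_u):
    """Swapping the group labels swaps the summaries and leaves the chi2
    p-value and relevance flag unchanged."""
    m1, p1 = cohort({AFFECTED: calls_a, UNAFFECTED: calls_u})
    m2, p2 = cohort({AFFECTED: calls_u, UNAFFECTED: calls_a})
    s1 = eq.summarize_group(m1, p1, "snp", "A")
    s2 = eq.summarize_group(m2, p2, "snp", "A")
    assert s1[AFFECTED].state_counts == s2[UNAFFECTED].state_counts
    assert s1[AFFECTED].strength == s2[UNAFFECTED].strength
    r1 = chi2_independence(s1[AFFECTED].dist, s1[UNAFFECTED].dist)
    r2 = chi2_independence(s2[AFFECTED].dist, s2[UNAFFECTED].dist)
    assert r1.p == pytest.approx(r2.p)
    rel1 = eq.detect_relevant_snps({"snp": s1})
    rel2 = eq.detect_relevant_snps({"snp": s2})
    assert rel1 == rel2


@given(st.lists(st.sampled_from(["AA", "AC", "CC"]), min_size=3, max_size=60))
def test_strength_bounds_property(calls):
    """With all three states observed, 1/3 <= strength <= 1; strength is 1
    iff the group is unanimous."""
    m, pats = cohort({AFFECTED: calls + ["AA", "AC", "CC"],
                      UNAFFECTED: ["AA", "AA"]})
    s = eq.summarize_group(m, pats, "snp", "A")[AFFECTED]
    assert 1 / 3 - 1e-12 <= s.strength <= 1.0
    unanimous = len({c for c in calls + ["AA", "AC", "CC"]}) == 1
    assert (s.strength == 1.0) == unanimous
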