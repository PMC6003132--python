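import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ciascore.evaluation import (
    LabeledScores,
    auc_trapezoid,
    cohens_kappa,
    confusion_metrics,
    fisher_exact,
    mcnemar_exact,
    paired_concordance,
    roc_and_cutoff,
    roc_points,
)


def brute_force_auc(scores, is_case):
    """Concordant-pair counting with 1/2 for ties (Mann-Whitney)."""
    cases = scores[is_case]
    controls = scores[~is_case]
    total = 0.0
    for a in cases:
        for b in controls:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(cases) * len(controls))


def labeled(case_scores, control_scores):
    scores = np.r_[case_scores, control_scores]
    is_case = np.r_[np.ones(len(case_scores)), np.zeros(len(control_scores))]
    ids = [f"s{i}" for i in range(len(scores))]
    return LabeledScores(ids, scores, is_case.astype(bool))


class TestROC:
    def test_perfect_separation(self):
        report, _ = roc_and_cutoff(labeled([10, 10, 10], [0, 0]))
        assert report.auc == 1.0
        assert report.sensitivity == 1.0 and report.specificity == 1.0

    def test_random_labels_auc_near_half(self):
        rng = np.random.default_rng(2024)
        scores = rng.normal(size=2000)
        is_case = rng.random(2000) < 0.5
        ls = LabeledScores([str(i) for i in range(2000)], scores, is_case)
        report, _ = roc_and_cutoff(ls)
        assert 0.45 <= report.auc <= 0.55

    def test_auc_matches_pair_counting_with_ties(self):
        ls = labeled([30, 30, 5], [4, 3])
        report, curve = roc_and_cutoff(ls)
        assert report.auc == pytest.approx(
            brute_force_auc(ls.scores, ls.is_case))
        assert auc_trapezoid(curve) == pytest.approx(report.auc)

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_trapezoid_auc_equals_mann_whitney(self, data):
        n_case = data.draw(st.integers(1, 12))
        n_ctrl = data.draw(st.integers(1, 12))
        vals = st.integers(0, 6)  # small range forces ties
        cases = data.draw(st.lists(vals, min_size=n_case, max_size=n_case))
        ctrls = data.draw(st.lists(vals, min_size=n_ctrl, max_size=n_ctrl))
        ls = labeled(cases, ctrls)
        curve = roc_points(ls)
        assert auc_trapezoid(curve) == pytest.approx(
            brute_force_auc(ls.scores, ls.is_case))

    def test_auc_cross_checked_against_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(5)
        scores = np.round(rng.normal(size=300), 1)
        is_case = rng.random(300) < 0.4
        ls = LabeledScores([str(i) for i in range(300)], scores, is_case)
        report, _ = roc_and_cutoff(ls)
        assert report.auc == pytest.approx(roc_auc_score(is_case, scores))

    def test_youden_ties_break_toward_larger_cutoff(self):
        # thresholds 1 and 2 give identical J; the larger must win
        ls = labeled([3, 3], [1, 2])
        report, _ = roc_and_cutoff(ls)
        assert report.cutoff == 2.0
        assert report.specificity == 1.0

    def test_report_consistent_with_strict_greater_calls(self):
        rng = np.random.default_rng(6)
        ls = labeled(rng.normal(1, 1, 40), rng.normal(0, 1, 40))
        report, _ = roc_and_cutoff(ls)
        pred = ls.scores > report.cutoff
        manual = confusion_metrics(
            tp=int((pred & ls.is_case).sum()), fp=int((pred & ~ls.is_case).sum()),
            tn=int((~pred & ~ls.is_case).sum()), fn=int((~pred & ls.is_case).sum()))
        assert report.sensitivity == manual.sensitivity
        assert report.specificity == manual.specificity

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            LabeledScores(["a", "b"], [1.0, 2.0], [True, True])


class TestConfusionMetrics:
    def test_training_group_panel(self):
        """59/71 cases and 4/74 controls called positive."""
        r = confusion_metrics(tp=59, fn=12, tn=70, fp=4)
        pct = r.as_dict(percent=True)
        assert pct["sensitivity"] == "83.1%"
        assert pct["accuracy"] == "89.0%"
        assert pct["npv"] == "85.4%"
        assert pct["ppv"] == "93.7%"
        assert r.specificity == pytest.approx(70 / 74)

    def test_tissue_positive_subgroup_panel(self):
        r = confusion_metrics(tp=44, fn=5, tn=70, fp=4)
        assert f"{100 * r.sensitivity:.1f}" == "89.8"
        assert f"{100 * r.accuracy:.1f}" == "92.7"

    def test_zero_denominator_metric_absent(self):
        r = confusion_metrics(tp=0, fn=0, tn=5, fp=5)
        assert r.sensitivity is None
        assert r.as_dict(percent=True)["sensitivity"] is None
        assert r.specificity == 0.5

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(tp=-1, fn=0, tn=0, fp=0)


class TestKappa:
    def test_tissue_urine_agreement_table(self):
        """Paired CIA calls: (3, 5, 2, 44) -> 87.0% agreement, kappa 0.392."""
        res = cohens_kappa([[3, 5], [2, 44]])
        assert res.observed_agreement == pytest.approx(0.870, abs=5e-4)
        assert res.kappa == pytest.approx(0.392, abs=5e-4)

    @pytest.mark.parametrize("table,expected", [
        ([[10, 0], [0, 10]], 1.0),
        ([[25, 25], [25, 25]], 0.0),
    ])
    def test_reference_points(self, table, expected):
        assert cohens_kappa(table).kappa == pytest.approx(expected)

    def test_degenerate_marginals_absent(self):
        assert cohens_kappa([[10, 0], [0, 0]]).kappa is None

    @given(st.lists(st.integers(0, 40), min_size=4, max_size=4))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_independent_marginal_computation(self, cells):
        a, b, c, d = cells
        n = a + b + c + d
        if n == 0:
            return
        table = np.array([[a, b], [c, d]])
        po = (a + d) / n
        pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
        res = cohens_kappa(table)
        if pe == 1.0:
            assert res.kappa is None
        else:
            assert res.kappa == pytest.approx((po - pe) / (1 - pe))

    def test_cross_checked_against_sklearn(self):
        from sklearn.metrics import cohen_kappa_score
        x = [0] * 8 + [1] * 46
        y = [0] * 3 + [1] * 5 + [0] * 2 + [1] * 44
        assert cohens_kappa([[3, 5], [2, 44]]).kappa == pytest.approx(
            cohen_kappa_score(x, y))


class TestMcNemar:
    @pytest.mark.parametrize("b,c,expected", [
        (5, 2, 58 / 128),   # = 0.453 printed
        (20, 5, 0.004077),
        (0, 0, 1.0),
    ])
    def test_exact_binomial_values(self, b, c, expected):
        assert mcnemar_exact(b, c) == pytest.approx(expected, abs=5e-4)

    def test_symmetry_and_monotonicity(self):
        n = 14
        previous = 1.1
        for b in range(n // 2, -1, -1):
            c = n - b
            p = mcnemar_exact(b, c)
            assert p == mcnemar_exact(c, b)
            assert p <= previous + 1e-12
            previous = p

    def test_cross_checked_against_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
        for b, c in [(5, 2), (20, 5), (3, 3), (0, 7)]:
            sm = sm_mcnemar([[0, b], [c, 0]], exact=True).pvalue
            assert mcnemar_exact(b, c) == pytest.approx(sm)


def brute_force_fisher(table):
    """Enumerate every margin-preserving table; sum P <= P_obs."""
    table = np.asarray(table)
    rows, cols = table.sum(1), table.sum(0)
    from math import factorial, prod
    n = int(table.sum())

    def prob(t):
        num = prod(factorial(int(x)) for x in rows) * \
            prod(factorial(int(x)) for x in cols)
        den = factorial(n) * prod(factorial(int(x)) for x in np.ravel(t))
        return num / den

    p_obs = prob(table)
    total = 0.0
    r, c = table.shape
    free = [range(min(rows[i], cols[j]) + 1) for i in range(r - 1)
            for j in range(c - 1)]
    for combo in itertools.product(*free):
        t = np.zeros((r, c), dtype=int)
        t[: r - 1, : c - 1] = np.reshape(combo, (r - 1, c - 1))
        t[: r - 1, c - 1] = rows[: r - 1] - t[: r - 1, : c - 1].sum(1)
        t[r - 1, :] = cols - t[: r - 1, :].sum(0)
        if (t >= 0).all():
            p = prob(t)
            if p <= p_obs * (1 + 1e-9):
                total += p
    return total


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_diagonal_table_closed_form(self):
        from math import comb
        assert fisher_exact([[10, 0], [0, 10]]) == pytest.approx(
            2 / comb(20, 10), rel=1e-9)

    def test_2x2_matches_scipy(self):
        table = [[8, 2], [1, 5]]
        assert fisher_exact(table) == pytest.approx(
            stats.fisher_exact(table)[1])

    @pytest.mark.parametrize("table", [
        [[3, 1, 4], [2, 5, 0]],
        [[1, 2, 3], [4, 0, 2], [2, 2, 1]],
        [[6, 0], [2, 3], [1, 4]],
    ])
    def test_rxc_matches_exhaustive_enumeration(self, table):
        assert fisher_exact(table) == pytest.approx(
            brute_force_fisher(table), rel=1e-9)

    def test_monte_carlo_fallback_close_to_exact(self):
        table = [[30, 10, 20], [15, 25, 20]]
        exact = fisher_exact(table)  # total 120 <= 500: enumerated
        mc = fisher_exact(table, max_exact_total=50, seed=0)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [0, 2]])


class TestPairedConcordance:
    def test_tissue_vs_urine_summary(self):
        stats_ = paired_concordance(3, 5, 2, 44)
        assert stats_["n"] == 54
        assert stats_["observed_agreement"] == pytest.approx(0.8704, abs=1e-4)
        assert stats_["kappa"] == pytest.approx(0.392, abs=5e-4)
        assert stats_["mcnemar_p"] == pytest.approx(0.453, abs=5e-4)
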