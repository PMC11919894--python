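"""Screening statistics against closed forms and brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from pediscreen.evaluation import (ConfusionTable, PairedOutcome,
                                   confusion_table, decision_curve,
                                   matched_sensitivity_threshold, mcnemar_test,
                                   metrics, paired_outcome,
                                   per_finding_evaluation, roc_auc,
                                   youden_threshold)


class TestConfusionTable:
    def test_perfect_predictions(self):
        truth = [True] * 4 + [False] * 6
        t = confusion_table(truth, truth)
        assert (t.tp, t.tn, t.fp, t.fn) == (4, 6, 0, 0)

    def test_inverted_predictions(self):
        truth = np.array([True] * 4 + [False] * 6)
        t = confusion_table(~truth, truth)
        assert (t.tp, t.tn, t.fp, t.fn) == (0, 0, 6, 4)

    def test_matches_hand_tally(self, rng):
        pred = rng.random(200) < 0.5
        truth = rng.random(200) < 0.3
        t = confusion_table(pred, truth)
        assert t.tp == sum(p and q for p, q in zip(pred, truth))
        assert t.fp == sum(p and not q for p, q in zip(pred, truth))
        assert t.fn == sum(q and not p for p, q in zip(pred, truth))
        assert t.n == 200

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_table([True], [True, False])


class TestMetricsWorkedExamples:
    def test_conventional_algorithm_test_group(self):
        """208 of 310 flagged, 84 truly abnormal, sensitivity 0.95: the five
        statistics at two decimals."""
        r = metrics(ConfusionTable(tp=80, fp=128, fn=4, tn=98), seed=0)
        assert r.accuracy.value == pytest.approx(0.57, abs=0.005)
        assert r.sensitivity.value == pytest.approx(0.95, abs=0.005)
        assert r.specificity.value == pytest.approx(0.43, abs=0.005)
        assert r.ppv.value == pytest.approx(0.38, abs=0.005)
        assert r.npv.value == pytest.approx(0.96, abs=0.005)

    def test_model_at_youden_threshold(self):
        """102 of 310 flagged at the Youden threshold."""
        r = metrics(ConfusionTable(tp=66, fp=36, fn=18, tn=190), seed=0)
        values = [r.accuracy.value, r.sensitivity.value, r.specificity.value,
                  r.ppv.value, r.npv.value]
        assert [round(v, 2) for v in values] == [0.83, 0.79, 0.84, 0.65, 0.91]

    def test_undefined_statistic_reported_as_none(self):
        r = metrics(ConfusionTable(tp=0, fp=3, fn=0, tn=7), seed=0)
        assert r.sensitivity is None
        assert r.specificity is not None

    def test_point_estimates_inside_ci(self, rng):
        for _ in range(10):
            tp, fp, fn, tn = rng.integers(1, 40, 4)
            r = metrics(ConfusionTable(int(tp), int(fp), int(fn), int(tn)), seed=1)
            for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
                est = getattr(r, name)
                assert est.ci_low <= est.value <= est.ci_high

    def test_cis_shrink_with_n(self):
        small = metrics(ConfusionTable(10, 10, 5, 25), seed=2)
        big = metrics(ConfusionTable(1000, 1000, 500, 2500), seed=2)
        width = lambda e: e.ci_high - e.ci_low
        assert width(big.accuracy) < width(small.accuracy) / 3


class TestROC:
    def test_perfect_separation(self):
        probs = [0.9, 0.8, 0.2, 0.1]
        truth = [True, True, False, False]
        assert roc_auc(probs, truth).auc == 1.0

    def test_constant_probabilities(self):
        assert roc_auc([0.5] * 10, [True] * 4 + [False] * 6).auc == 0.5

    def test_equals_rank_sum_with_ties(self, rng):
        for _ in range(200):
            n = int(rng.integers(8, 40))
            truth = np.zeros(n, dtype=bool)
            truth[rng.choice(n, max(1, n // 3), replace=False)] = True
            if truth.all() or not truth.any():
                continue
            probs = np.round(rng.random(n), 1)       # heavy ties
            got = roc_auc(probs, truth).auc
            u = stats.mannwhitneyu(probs[truth], probs[~truth]).statistic
            expected = u / (truth.sum() * (~truth).sum())
            assert got == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [True, True])


def _scan_youden(probs, truth):
    u = np.unique(probs)
    cands = np.concatenate([[u[0] - 1], (u[:-1] + u[1:]) / 2, [u[-1] + 1]])
    best_t, best_j = None, -np.inf
    for t in cands:
        flag = probs >= t
        j = np.mean(flag[truth]) - np.mean(flag[~truth])
        if j > best_j or (j == best_j and t > best_t):
            best_j, best_t = j, t
    return best_t, best_j


class TestThresholds:
    def test_youden_perfect_separation(self):
        probs = np.array([0.9, 0.85, 0.3, 0.2])
        truth = np.array([True, True, False, False])
        t = youden_threshold(roc_auc(probs, truth))
        assert 0.3 < t < 0.85
        flag = probs >= t
        assert np.mean(flag[truth]) - np.mean(flag[~truth]) == 1.0

    def test_youden_agrees_with_exhaustive_scan(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 50))
            truth = rng.random(n) < 0.4
            if truth.all() or not truth.any():
                continue
            probs = np.round(rng.random(n), 2)
            got = youden_threshold(roc_auc(probs, truth))
            expected, _ = _scan_youden(probs, truth)
            assert got == pytest.approx(expected)

    def test_youden_constant_probs_j_zero(self):
        probs = np.full(10, 0.4)
        truth = np.array([True] * 3 + [False] * 7)
        t = youden_threshold(roc_auc(probs, truth))
        flag = probs >= t
        assert np.mean(flag[truth]) - np.mean(flag[~truth]) == 0.0

    def test_matched_sensitivity_exact_target(self):
        probs = np.array([0.9, 0.7, 0.5, 0.3, 0.2, 0.1])
        truth = np.array([True, True, True, True, False, False])
        t = matched_sensitivity_threshold(probs, truth, 0.75)
        assert t == 0.5
        assert np.mean((probs >= t)[truth]) == 0.75

    def test_matched_sensitivity_target_one(self, rng):
        truth = rng.random(30) < 0.5
        truth[0] = True
        probs = rng.random(30)
        t = matched_sensitivity_threshold(probs, truth, 1.0)
        assert t <= probs[truth].min()
        assert np.mean((probs >= t)[truth]) == 1.0

    def test_matched_sensitivity_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            truth = rng.random(n) < 0.4
            if not truth.any():
                continue
            probs = np.round(rng.random(n), 2)
            target = float(rng.uniform(0.2, 1.0))
            got = matched_sensitivity_threshold(probs, truth, target)
            # oracle: scan all observed probabilities, keep the largest
            # threshold whose sensitivity clears the target
            feasible = [t for t in np.unique(probs)
                        if np.mean((probs >= t)[truth]) >= target]
            assert got == pytest.approx(max(feasible))

    def test_matched_sensitivity_invalid_target(self):
        with pytest.raises(ValueError):
            matched_sensitivity_threshold([0.5], [True], 1.5)


class TestMcNemar:
    def test_symmetric_exact(self):
        assert mcnemar_test(PairedOutcome(5, 5)) == 1.0

    def test_one_sided_discordance_closed_form(self):
        assert mcnemar_test(PairedOutcome(0, 10)) == pytest.approx(2 * 0.5**10)

    def test_no_discordance_convention(self):
        assert mcnemar_test(PairedOutcome(0, 0, both_correct=30)) == 1.0

    def test_exact_branch_equals_binomial_tail_sums(self):
        for n in range(1, 25):
            for b in range(n + 1):
                c = n - b
                got = mcnemar_test(PairedOutcome(b, c))
                k = min(b, c)
                expected = min(1.0, 2 * stats.binom.cdf(k, n, 0.5)
                               - (stats.binom.pmf(k, n, 0.5) if b == c else 0.0))
                assert got == pytest.approx(expected)

    def test_chi_square_branch(self):
        got = mcnemar_test(PairedOutcome(25, 50))
        expected = stats.chi2.sf((abs(25 - 50) - 1) ** 2 / 75, 1)
        assert got == pytest.approx(expected)

    def test_against_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
        for b, c in [(3, 9), (10, 2), (40, 60)]:
            exact = b + c < 25
            table = [[5, b], [c, 5]]
            expected = sm_mcnemar(table, exact=exact,
                                  correction=True).pvalue
            assert mcnemar_test(PairedOutcome(b, c)) == pytest.approx(
                float(expected), rel=1e-6)

    def test_paired_outcome_counts(self):
        m = np.array([True, True, False, False])
        c = np.array([True, False, True, False])
        p = paired_outcome(m, c)
        assert (p.b, p.c, p.both_correct, p.both_wrong) == (1, 1, 1, 1)
        assert p.n == 4


class TestDecisionCurve:
    def test_treat_none_identically_zero(self, rng):
        truth = rng.random(50) < 0.3
        dc = decision_curve(rng.random(50), truth)
        np.testing.assert_array_equal(dc.net_benefit_none, 0.0)

    def test_treat_all_closed_form(self, rng):
        truth = rng.random(200) < 0.3
        prev = truth.mean()
        pts = [0.05, 0.2, 0.5]
        dc = decision_curve(rng.random(200), truth, pt_grid=pts)
        for pt, nb in zip(pts, dc.net_benefit_all):
            assert nb == pytest.approx(prev - (1 - prev) * pt / (1 - pt))

    def test_perfect_model_net_benefit_is_prevalence(self, rng):
        truth = rng.random(80) < 0.4
        dc = decision_curve(truth.astype(float), truth, pt_grid=[0.1, 0.3, 0.7])
        np.testing.assert_allclose(dc.net_benefit_model, truth.mean())

    def test_model_curve_bounded_by_prevalence(self, rng):
        truth = rng.random(100) < 0.25
        dc = decision_curve(rng.random(100), truth)
        assert np.all(dc.net_benefit_model <= dc.prevalence + 1e-12)

    def test_treat_all_zero_at_prevalence(self, rng):
        truth = np.array([True] * 25 + [False] * 75)
        dc = decision_curve(rng.random(100), truth, pt_grid=[0.25])
        assert dc.net_benefit_all[0] == pytest.approx(0.0, abs=1e-12)

    def test_invalid_grid(self, rng):
        truth = rng.random(10) < 0.5
        with pytest.raises(ValueError):
            decision_curve(rng.random(10), truth, pt_grid=[1.0])


class TestPerFinding:
    def test_comparator_flags_everything(self):
        findings = [{"st_t"}, {"crbbb"}, set(), set(), set(), {"st_t"}]
        probs = [0.9, 0.8, 0.1, 0.2, 0.3, 0.7]
        comp = [True] * 6
        report = per_finding_evaluation(probs, findings, comp,
                                        ["st_t", "crbbb"], warn=lambda m: None)
        for row in report.rows.values():
            assert row["comparator"]["sensitivity"] == 1.0
            assert row["comparator"]["specificity"] == 0.0

    def test_perfect_model_specificity_at_matched_sensitivity(self):
        findings = [{"st_t"}] * 3 + [set()] * 7
        probs = [1.0] * 3 + [0.0] * 7
        comp = [True, True, True, False, True, False, False, True, False, False]
        report = per_finding_evaluation(probs, findings, comp, ["st_t"],
                                        warn=lambda m: None)
        assert report.rows["st_t"]["model"]["sensitivity"] == 1.0
        assert report.rows["st_t"]["model"]["specificity"] == 1.0

    def test_hand_computed_small_cohort(self):
        # 12 records, two findings; negatives for F include the other finding
        findings = [{"a"}, {"a"}, {"b"}, {"b"}, {"a", "b"},
                    set(), set(), set(), set(), set(), set(), set()]
        probs = np.array([0.9, 0.6, 0.8, 0.4, 0.95,
                          0.1, 0.2, 0.3, 0.15, 0.25, 0.05, 0.35])
        comp = np.array([True, False, True, True, True,
                         False, True, False, False, True, False, False])
        report = per_finding_evaluation(probs, findings, comp, ["a", "b"],
                                        warn=lambda m: None)
        ra = report.rows["a"]
        # comparator on 'a': 2 of 3 positives flagged; FPs among 9 negatives: 4
        assert ra["comparator"]["sensitivity"] == pytest.approx(2 / 3)
        assert ra["comparator"]["specificity"] == pytest.approx(5 / 9)
        # matched sensitivity 2/3 -> threshold at 2nd-largest positive prob 0.9
        assert ra["threshold"] == pytest.approx(0.9)
        # model flags probs >= 0.9: no 'a'-negative reaches it
        assert ra["model"]["specificity"] == pytest.approx(1.0)
        assert ra["n_positive"] == 3
        rb = report.rows["b"]
        # 'b': comparator sensitivity 1 -> threshold = min positive prob 0.4;
        # the 0.9 and 0.6 'a'-only records become false positives
        assert rb["threshold"] == pytest.approx(0.4)
        assert rb["model"]["specificity"] == pytest.approx(7 / 9)

    def test_absent_finding_skipped_with_warning(self):
        warnings = []
        report = per_finding_evaluation([0.5], [set()], [False], ["wpw"],
                                        warn=warnings.append)
        assert report.rows == {}
        assert any("wpw" in w for w in warnings)
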