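"""Diagnostic metrics: identities, ROC rank-statistic equivalence, Wilson
intervals, stratification and confusion reconstruction."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from euslite import evaluate as ev
from euslite.errors import ConfigError, DataError


class TestMetricsFromConfusion:
    def test_perfect_two_by_two(self):
        m = ev.metrics_from_confusion(ev.ConfusionSummary(1, 0, 1, 0))
        assert (m.sensitivity, m.specificity, m.accuracy, m.ppv, m.npv, m.f1) == \
            (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    def test_no_positives_leaves_sensitivity_undefined(self):
        m = ev.metrics_from_confusion(ev.ConfusionSummary(0, 0, 10, 0))
        assert m.sensitivity is None and m.ppv is None
        assert m.specificity == 1.0

    def test_held_out_study_row(self):
        # 66 GIST / 43 leiomyoma images; (tp 62, tn 41)
        m = ev.metrics_from_confusion(ev.ConfusionSummary(tp=62, fp=2, tn=41, fn=4))
        pct = m.as_percent_dict()
        assert round(pct["sensitivity"], 1) == 93.9
        assert round(pct["accuracy"], 1) == 94.5
        assert round(pct["ppv"], 1) == 96.9
        assert round(pct["npv"], 1) == 91.1
        # printed specificity is 95.4 but 41/43 rounds to 95.3
        assert round(pct["specificity"], 1) == 95.3

    def test_all_zero_rejected(self):
        with pytest.raises(ConfigError):
            ev.metrics_from_confusion(ev.ConfusionSummary(0, 0, 0, 0))

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    @settings(max_examples=200, deadline=None)
    def test_metric_identities(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        c = ev.ConfusionSummary(tp, fp, tn, fn)
        m = ev.metrics_from_confusion(c, with_ci=False)
        n = c.total
        assert m.accuracy * n == pytest.approx(tp + tn)
        if m.sensitivity is not None:
            assert m.sensitivity * (tp + fn) == pytest.approx(tp)
        if m.specificity is not None:
            assert m.specificity * (tn + fp) == pytest.approx(tn)
        if m.ppv is not None:
            assert m.ppv * (tp + fp) == pytest.approx(tp)
        if m.npv is not None:
            assert m.npv * (tn + fn) == pytest.approx(tn)
        if m.f1 is not None:
            assert m.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))


class TestROC:
    def test_perfect_separation(self):
        roc = ev.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert roc.auc == 1.0

    def test_perfect_inversion(self):
        roc = ev.roc_auc([0.9, 0.8, 0.1, 0.2], [0, 0, 1, 1])
        assert roc.auc == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            ev.roc_auc([0.1, 0.9], [1, 1])

    def test_curve_is_monotone(self, rng):
        roc = ev.roc_auc(rng.random(50), rng.integers(0, 2, 50))
        assert (np.diff(roc.tpr) >= 0).all() and (np.diff(roc.fpr) >= 0).all()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_auc_equals_pairwise_concordance(self, seed):
        r = np.random.default_rng(seed)
        scores = np.round(r.random(30), 2)  # rounding forces ties
        labels = r.integers(0, 2, 30)
        if labels.min() == labels.max():
            return
        roc = ev.roc_auc(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert roc.auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)


class TestWilson:
    def test_zero_successes_touch_zero(self):
        low, high = ev.wilson_interval(0, 10)
        assert low == 0.0 and high > 0.0

    def test_half_bracket(self):
        low, high = ev.wilson_interval(5, 10)
        assert low < 0.5 < high

    def test_matches_quadratic_inversion(self):
        """The interval endpoints are the roots of the score-test quadratic
        (1 + z^2/n) p^2 - (2 phat + z^2/n) p + phat^2 = 0."""
        from scipy.stats import norm

        z = norm.ppf(0.975)
        for s, n in [(8, 10), (1, 7), (25, 40)]:
            phat = s / n
            a = 1 + z**2 / n
            b = -(2 * phat + z**2 / n)
            c = phat**2
            roots = np.sort(np.roots([a, b, c]))
            low, high = ev.wilson_interval(s, n)
            assert low == pytest.approx(roots[0], abs=1e-9)
            assert high == pytest.approx(roots[1], abs=1e-9)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for s, n in [(3, 12), (50, 60), (0, 9)]:
            lo, hi = proportion_confint(s, n, alpha=0.05, method="wilson")
            assert ev.wilson_interval(s, n) == pytest.approx((lo, hi), abs=1e-9)

    def test_zero_n_rejected(self):
        with pytest.raises(ConfigError):
            ev.wilson_interval(0, 0)


class TestStratifiedCompare:
    def test_empty_stratum_is_marked_not_zero_filled(self):
        rep = ev.stratified_compare([1, 0, 1], [5.0, 8.0, 12.0],
                                    model_predictions=[1, 0, 1])
        assert rep.strata["ge20mm"]["model"] is None
        assert rep.counts["ge20mm"] == 0

    def test_perfect_model(self):
        truth = [1, 0, 1, 0]
        rep = ev.stratified_compare(truth, [5, 10, 25, 30],
                                    model_predictions=truth)
        for stratum in ("lt20mm", "ge20mm"):
            m = rep.strata[stratum]["model"]
            assert m.accuracy == 1.0 and m.sensitivity == 1.0

    def test_always_positive_reader(self):
        rep = ev.stratified_compare([1, 0, 1, 0], [5, 6, 7, 8],
                                    reader_predictions=[1, 1, 1, 1])
        m = rep.strata["lt20mm"]["endoscopist"]
        assert m.sensitivity == 1.0 and m.specificity == 0.0

    def test_missing_sizes_listed(self):
        with pytest.raises(DataError, match=r"\[1\]"):
            ev.stratified_compare([1, 0], [5.0, np.nan], model_predictions=[1, 0])

    def test_strata_confusions_sum_to_total(self, rng):
        truth = rng.integers(0, 2, 40)
        preds = rng.integers(0, 2, 40)
        sizes = rng.uniform(5, 35, 40)
        total = ev.confusion_from_predictions(truth, preds)
        small = ev.confusion_from_predictions(truth[sizes < 20], preds[sizes < 20])
        large = ev.confusion_from_predictions(truth[sizes >= 20], preds[sizes >= 20])
        for f in ("tp", "fp", "tn", "fn"):
            assert getattr(small, f) + getattr(large, f) == getattr(total, f)


class TestReconstructConfusion:
    def test_four_metric_row_has_unique_candidate(self):
        cons, rep = ev.reconstruct_confusion(
            {"sensitivity": 93.9, "accuracy": 94.5, "ppv": 96.9, "npv": 91.1},
            n_pos=66, n_neg=43,
        )
        assert [(c.tp, c.tn) for c in cons] == [(62, 41)]
        assert rep["n_consistent"] == 1

    def test_perfect_metrics(self):
        cons, _ = ev.reconstruct_confusion(
            {"sensitivity": 100.0, "specificity": 100.0}, 5, 5
        )
        assert [(c.tp, c.tn) for c in cons] == [(5, 5)]

    def test_impossible_combination_returns_empty(self):
        cons, _ = ev.reconstruct_confusion(
            {"sensitivity": 100.0, "npv": 0.0}, 5, 5
        )
        assert cons == []
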