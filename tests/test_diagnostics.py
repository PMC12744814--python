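"""Physiology labeling, 2x2 statistics, ROC, agreement, reconstruction."""

import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from bullseye import (ConfusionTable, PhysiologyResult, bland_altman,
                      classify_physiology, cohen_kappa, confusion_table,
                      diagnostic_metrics, odds_ratio_ci, reconstruct_confusion,
                      roc_auc)
from bullseye.diagnostics import round_half_up

STUDY_TABLE = ConfusionTable(tp=93, fp=67, fn=6, tn=41)


class TestClassifyPhysiology:
    @pytest.mark.parametrize("ffr, nhpr, expected", [
        (0.76, None, "positive"),
        (None, 0.89, "positive"),       # boundary: <= is positive
        (0.80, None, "positive"),       # boundary: <= is positive
        (0.88, 0.95, "negative"),
        (0.81, None, "negative"),
        (None, 0.90, "negative"),
        (0.85, 0.85, "positive"),       # and/or: either index suffices
    ])
    def test_thresholds(self, ffr, nhpr, expected):
        assert classify_physiology(PhysiologyResult(ffr=ffr, nhpr=nhpr)) == expected

    def test_both_absent_rejected(self):
        with pytest.raises(ValueError):
            classify_physiology(PhysiologyResult())

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            PhysiologyResult(ffr=1.2)


class TestConfusionTable:
    def test_simple_tally(self):
        t = confusion_table(["+", "-"], ["+", "-"])
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 0, 0, 1)

    def test_all_positive_predictions(self):
        t = confusion_table([1, 1, 1, 1], [1, 1, 0, 0])
        assert (t.tp, t.fp, t.fn, t.tn) == (2, 2, 0, 0)

    def test_matches_hand_count_on_random_labels(self, rng):
        pred = rng.random(500) < 0.5
        true = rng.random(500) < 0.4
        t = confusion_table(pred, true)
        hand = [sum(1 for p, y in zip(pred, true) if p == pv and y == yv)
                for pv, yv in ((1, 1), (1, 0), (0, 1), (0, 0))]
        assert list(t.cells()) == hand
        assert t.n == 500

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_table([1, 0], [1])

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ConfusionTable(-1, 0, 0, 0)


class TestDiagnosticMetrics:
    def test_study_operating_point(self):
        """The reconstructed study table prints NPV 87 %, specificity 38 %."""
        s = diagnostic_metrics(STUDY_TABLE)
        assert round_half_up(100 * s.npv.point) == 87
        assert round_half_up(100 * s.specificity.point) == 38
        assert s.sensitivity.point == pytest.approx(93 / 99)
        assert s.dor.point == pytest.approx(93 * 41 / (67 * 6))

    def test_perfect_classifier_uses_haldane_for_dor(self):
        s = diagnostic_metrics(ConfusionTable(10, 0, 0, 10))
        assert s.sensitivity.point == 1.0
        assert s.specificity.point == 1.0
        # Haldane: (10.5 * 10.5) / (0.5 * 0.5); proportions are uncorrected
        assert s.dor.point == pytest.approx(441.0)

    def test_wilson_ci_brackets_point(self):
        s = diagnostic_metrics(STUDY_TABLE)
        for est in (s.sensitivity, s.specificity, s.ppv, s.npv, s.dor):
            assert est.lower <= est.point <= est.upper

    def test_empty_margin_flagged_absent(self):
        s = diagnostic_metrics(ConfusionTable(0, 3, 0, 7))  # nobody diseased
        assert s.sensitivity is None and s.npv is not None
        assert s.dor is None

    def test_dor_consistent_with_sens_spec(self, rng):
        for _ in range(20):
            t = ConfusionTable(*(int(x) for x in rng.integers(1, 80, size=4)))
            s = diagnostic_metrics(t)
            sens, spec = s.sensitivity.point, s.specificity.point
            assert s.dor.point == pytest.approx(
                (sens / (1 - sens)) / ((1 - spec) / spec))


class TestOddsRatioCI:
    def test_study_table_matches_printed_interval(self):
        lo, hi = odds_ratio_ci(STUDY_TABLE)
        assert round_half_up(lo, 2) == 3.81
        assert round_half_up(hi, 2) == 23.62

    def test_balanced_table_symmetric_about_one(self):
        lo, hi = odds_ratio_ci(ConfusionTable(10, 10, 10, 10))
        assert lo * hi == pytest.approx(1.0)

    def test_matches_closed_form(self, rng):
        for _ in range(20):
            tp, fp, fn, tn = (int(x) for x in rng.integers(1, 60, size=4))
            lo, hi = odds_ratio_ci(ConfusionTable(tp, fp, fn, tn))
            se = math.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn)
            log_or = math.log(tp * tn / (fp * fn))
            assert lo == pytest.approx(math.exp(log_or - 1.959963984540054 * se))
            assert hi == pytest.approx(math.exp(log_or + 1.959963984540054 * se))

    def test_width_shrinks_as_counts_scale(self):
        widths = []
        for k in (1, 2, 4):
            lo, hi = odds_ratio_ci(ConfusionTable(20 * k, 10 * k, 8 * k, 30 * k))
            widths.append(math.log(hi) - math.log(lo))
        assert widths[0] > widths[1] > widths[2]


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([5.0] * 10, [0, 1] * 5) == 0.5

    def test_matches_pair_counting_and_sklearn(self, rng):
        scores = rng.normal(size=40)
        scores[rng.integers(0, 40, 10)] = 0.0  # inject ties
        truth = rng.random(40) < 0.45
        wins = halves = 0
        for sp in scores[truth]:
            for sn in scores[~truth]:
                wins += sp > sn
                halves += sp == sn
        expected = (wins + halves / 2) / (truth.sum() * (~truth).sum())
        assert roc_auc(scores, truth) == pytest.approx(expected)
        assert roc_auc(scores, truth) == pytest.approx(roc_auc_score(truth, scores))

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=60)
        truth = rng.random(60) < 0.5
        a = roc_auc(scores, truth)
        assert roc_auc(np.exp(scores), truth) == pytest.approx(a)
        assert roc_auc(3 * scores - 7, truth) == pytest.approx(a)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == pytest.approx(1.0)

    def test_independent_raters(self):
        assert cohen_kappa([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(0.0)

    def test_hand_computation_on_2x2_counts(self):
        # agreement table a=8 (both +), b=1, c=1, d=10
        a_rat = [1] * 8 + [1] * 1 + [0] * 1 + [0] * 10
        b_rat = [1] * 8 + [0] * 1 + [1] * 1 + [0] * 10
        n = 20
        p_obs = 18 / n
        p_exp = (9 / n) * (9 / n) + (11 / n) * (11 / n)
        assert cohen_kappa(a_rat, b_rat) == pytest.approx((p_obs - p_exp) / (1 - p_exp))

    def test_matches_sklearn(self, rng):
        a = rng.random(50) < 0.5
        b = np.where(rng.random(50) < 0.8, a, ~a)
        assert cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cohen_kappa([1, 1, 1], [1, 1, 1])


class TestBlandAltman:
    def test_identical_series(self):
        bias, lo, hi = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (bias, lo, hi) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0])
        bias, lo, hi = bland_altman(x, x + 2.5)
        assert bias == pytest.approx(-2.5)
        assert lo == pytest.approx(-2.5) and hi == pytest.approx(-2.5)

    def test_matches_direct_recomputation(self, rng):
        x = rng.normal(-16, 3, size=30)
        y = x + rng.normal(0.2, 0.8, size=30)
        bias, lo, hi = bland_altman(x, y)
        d = x - y
        assert bias == pytest.approx(d.mean())
        assert hi - lo == pytest.approx(2 * 1.96 * d.std(ddof=1))

    def test_too_short(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestReconstruction:
    def test_study_margins_yield_unique_table(self):
        tables = reconstruct_confusion(
            99, 108, [("specificity", 38, 0), ("npv", 87, 0)])
        assert tables == [STUDY_TABLE]

    def test_adding_dor_constraint_keeps_same_table(self):
        tables = reconstruct_confusion(
            99, 108, [("specificity", 38, 0), ("npv", 87, 0), ("dor", 9.49, 2)])
        assert tables == [STUDY_TABLE]

    def test_infeasible_constraint_gives_empty_set(self):
        assert reconstruct_confusion(10, 10, [("sensitivity", 200, 0)]) == []

    def test_roundtrip_property(self, rng):
        """Every returned table re-satisfies its constraints going forward."""
        for _ in range(5):
            n_pos, n_neg = int(rng.integers(5, 25)), int(rng.integers(5, 25))
            sens = float(rng.integers(0, 101))
            cons = [("sensitivity", sens, 0)]
            for t in reconstruct_confusion(n_pos, n_neg, cons):
                assert round_half_up(100 * t.tp / t.n_pos) == sens
                assert t.n_pos == n_pos and t.n_neg == n_neg

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_confusion(5, 5, [("accuracy", 50, 0)])


class TestRounding:
    @pytest.mark.parametrize("x, d, expected", [
        (2.5, 0, 3.0), (37.963, 0, 38.0), (9.4851, 2, 9.49), (93.9394, 0, 94.0),
        (-2.5, 0, -3.0),
    ])
    def test_half_up(self, x, d, expected):
        assert round_half_up(x, d) == expected
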