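"""Dice matching, FROC/ROC analysis, bootstrap confidence intervals."""

import numpy as np
import pytest

from histoscreen.detection import LesionComponent
from histoscreen.errors import EvaluationError
from histoscreen.evaluation import (
    BootstrapSummary,
    GroundTruthLesion,
    SlideAssignment,
    auc_metric,
    bootstrap,
    bootstrap_roc_curve,
    dice,
    froc,
    match_detections,
    roc,
    specificity_at_sensitivity,
)


def _component(pixels, likelihood, comp_id=0, slide_id="s"):
    ys, xs = zip(*pixels)
    return LesionComponent(
        ys=np.array(ys),
        xs=np.array(xs),
        diameter_mm=1.0,
        median_likelihood=likelihood,
        slide_id=slide_id,
        component_id=comp_id,
    )


def _lesion(pixels, size_class="micro", lesion_id=0, slide_id="s"):
    ys, xs = zip(*pixels)
    return GroundTruthLesion(
        ys=np.array(ys), xs=np.array(xs), size_class=size_class,
        slide_id=slide_id, lesion_id=lesion_id,
    )


def _block(y0, x0, h, w):
    return [(y, x) for y in range(y0, y0 + h) for x in range(x0, x0 + w)]


class TestDice:
    def test_identical_sets(self):
        pix = _block(0, 0, 5, 5)
        assert dice(pix, pix) == 1.0

    def test_disjoint_sets(self):
        assert dice(_block(0, 0, 3, 3), _block(10, 10, 3, 3)) == 0.0

    def test_half_overlap(self):
        a = _block(0, 0, 10, 10)
        b = _block(0, 5, 10, 10)
        assert dice(a, b) == pytest.approx(2 * 50 / 200)

    def test_counted_sets(self):
        a = _block(0, 0, 10, 10)  # 100 px
        b = _block(0, 0, 5, 10) + _block(50, 50, 5, 10)  # overlap 50, size 100
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_is_an_error(self):
        with pytest.raises(EvaluationError):
            dice([], [])


class TestMatching:
    def test_perfect_segmentation(self):
        lesions = [_lesion(_block(0, 0, 4, 4), lesion_id=0),
                   _lesion(_block(10, 10, 4, 4), lesion_id=1)]
        comps = [_component(_block(0, 0, 4, 4), 0.9, 0),
                 _component(_block(10, 10, 4, 4), 0.8, 1)]
        a = match_detections(comps, lesions)
        assert a.matched_likelihood == [0.9, 0.8]
        assert a.fp_likelihoods == []

    def test_low_dice_overlap_is_a_false_positive(self):
        lesion = _lesion(_block(0, 0, 10, 10))
        comp = _component(_block(0, 8, 10, 10), 0.9)  # overlap 20 -> Dice 0.2
        a = match_detections([comp], [lesion])
        assert a.matched_likelihood == [None]
        assert a.fp_likelihoods == [0.9]

    def test_component_spanning_two_lesions_below_half_dice(self):
        lesions = [_lesion(_block(0, 0, 4, 10), lesion_id=0),
                   _lesion(_block(20, 0, 4, 10), lesion_id=1)]
        # covers both lesions plus the gap: |comp| = 24*10, Dice to each
        # lesion = 2*40/(240+40) ~ 0.29 < 0.5
        comp = _component(_block(0, 0, 24, 10), 0.7)
        a = match_detections([comp], lesions)
        assert a.matched_likelihood == [None, None]
        assert len(a.fp_likelihoods) == 1

    def test_best_dice_wins(self):
        lesion = _lesion(_block(0, 0, 10, 10))
        close = _component(_block(0, 0, 10, 9), 0.4, comp_id=0)  # Dice ~ 0.95
        exact = _component(_block(0, 0, 10, 10), 0.3, comp_id=1)  # Dice 1.0
        a = match_detections([close, exact], [lesion])
        assert a.matched_component_ids == [1]
        assert a.fp_likelihoods == [0.4]


def _toy_assignments():
    """The worked FROC instance: 4 lesions (3 detected), 2 clean-slide FPs."""
    pos1 = SlideAssignment(
        slide_id="p1",
        lesion_classes=["micro", "macro"],
        matched_likelihood=[0.9, 0.8],
        fp_likelihoods=[],
        matched_component_ids=[0, 1],
    )
    pos2 = SlideAssignment(
        slide_id="p2",
        lesion_classes=["micro", "micro"],
        matched_likelihood=[0.6, None],
        fp_likelihoods=[],
        matched_component_ids=[0, None],
    )
    neg1 = SlideAssignment("n1", [], [], [0.7], [])
    neg2 = SlideAssignment("n2", [], [], [0.5], [])
    return [pos1, pos2, neg1, neg2]


def _froc_oracle(matched, fps, n_lesions, n_neg):
    """Exhaustive threshold enumeration."""
    points = []
    for t in [np.inf] + sorted(set(matched) | set(fps), reverse=True):
        sens = sum(m >= t for m in matched) / n_lesions
        fp = sum(f >= t for f in fps) / n_neg
        points.append((fp, sens))
    return points


class TestFROC:
    def test_matches_exhaustive_enumeration(self):
        curve = froc(_toy_assignments())
        oracle = _froc_oracle([0.9, 0.8, 0.6], [0.7, 0.5], n_lesions=4, n_neg=2)
        got = list(zip(curve.fp_rates.tolist(), curve.sensitivities.tolist()))
        assert got == oracle

    def test_sensitivity_readouts_at_fp_budgets(self):
        curve = froc(_toy_assignments())
        # at <= 1 FP per negative slide: threshold 0.6 gives 3/4 with 0.5 FP
        assert curve.sensitivity_at(1.0) == pytest.approx(3 / 4)
        assert curve.sensitivity_at(0.0) == pytest.approx(2 / 4)

    def test_monotone_in_fp_budget(self):
        curve = froc(_toy_assignments())
        order = np.argsort(curve.fp_rates)
        sens = curve.sensitivities[order]
        assert all(a <= b + 1e-12 for a, b in zip(sens, sens[1:]))

    def test_excluding_itc_changes_denominator(self):
        a = _toy_assignments()
        itc_slide = SlideAssignment(
            "p3", ["ITC"], [None], [], [None]
        )
        full = froc(a + [itc_slide], included_classes=("ITC", "micro", "macro"))
        excl = froc(a + [itc_slide], included_classes=("micro", "macro"))
        assert full.n_lesions == 5
        assert excl.n_lesions == 4
        # the ITC-only slide counts as tumor-negative when ITCs are excluded
        assert excl.n_negative_slides == 3
        assert full.n_negative_slides == 2

    def test_no_negative_slides_raises(self):
        with pytest.raises(EvaluationError):
            froc([_toy_assignments()[0]])

    def test_slide_order_invariance(self):
        a = _toy_assignments()
        fwd = froc(a)
        rev = froc(a[::-1])
        assert np.array_equal(fwd.sensitivities, rev.sensitivities)
        assert np.array_equal(fwd.fp_rates, rev.fp_rates)


def _concordance_oracle(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 1.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        result = roc(scores, labels)
        assert result.auc == 1.0
        assert result.fpr[0] == 0 and result.tpr[-1] == 1

    def test_null_scores_give_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        assert roc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_trapezoid_equals_pairwise_concordance(self):
        rng = np.random.default_rng(1)
        scores = np.round(rng.random(50), 2)  # ties included
        labels = rng.integers(0, 2, 50)
        labels[:5] = 1
        labels[5:10] = 0
        assert roc(scores, labels).auc == pytest.approx(
            _concordance_oracle(scores, labels), abs=1e-12
        )

    def test_single_class_raises(self):
        with pytest.raises(EvaluationError):
            roc([0.1, 0.2], [1, 1])


class TestSpecificityAtSensitivity:
    def test_perfect_scores(self):
        result = roc([0.1, 0.2, 0.9, 1.0], [0, 0, 1, 1])
        assert specificity_at_sensitivity(result, 0.999) == 1.0

    def test_overlapping_counts(self):
        # worst positive (0.3) sits below 2 of 4 negatives
        scores = np.array([0.5, 0.6, 0.2, 0.1, 0.3, 0.9, 0.9, 0.9])
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        result = roc(scores, labels)
        assert specificity_at_sensitivity(result, 0.999) == pytest.approx(0.5)

    def test_target_zero_gives_full_specificity(self):
        result = roc([0.5, 0.6, 0.4, 0.7], [0, 1, 0, 1])
        assert specificity_at_sensitivity(result, 0.0) == 1.0


class TestBootstrap:
    def test_constant_metric_collapses_interval(self):
        summary = bootstrap(lambda c: 0.42, list(range(10)), n_samples=50, seed=0)
        assert summary.mean == pytest.approx(0.42, abs=1e-12)
        assert summary.ci_low == pytest.approx(summary.ci_high, abs=1e-12)
        assert summary.ci_low == pytest.approx(0.42, abs=1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        cohort = np.column_stack([rng.random(30), rng.integers(0, 2, 30)])
        a = bootstrap(auc_metric, cohort, n_samples=200, seed=5)
        b = bootstrap(auc_metric, cohort, n_samples=200, seed=5)
        assert (a.mean, a.ci_low, a.ci_high) == (b.mean, b.ci_low, b.ci_high)

    def test_mean_within_interval(self):
        rng = np.random.default_rng(3)
        scores = np.concatenate([rng.normal(0, 1, 30), rng.normal(1, 1, 30)])
        labels = np.array([0] * 30 + [1] * 30)
        cohort = np.column_stack([scores, labels])
        s = bootstrap(auc_metric, cohort, n_samples=500, seed=1)
        assert s.ci_low <= s.mean <= s.ci_high

    def test_roc_band_brackets_point_curve(self):
        rng = np.random.default_rng(4)
        scores = np.concatenate([rng.normal(0, 1, 40), rng.normal(1.5, 1, 40)])
        labels = np.array([0] * 40 + [1] * 40)
        band = bootstrap_roc_curve(scores, labels, n_samples=200, seed=2)
        assert (band["tpr_low"] <= band["tpr_high"]).all()
        assert band["tpr_mean"].shape == band["fpr_grid"].shape
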