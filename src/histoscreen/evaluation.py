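"""Lesion-level FROC, slide-level ROC, and bootstrap confidence intervals.

A ground-truth lesion counts as detected when some detected component's
segmentation overlaps it with a Dice coefficient of at least 0.5; each
lesion is claimed by at most the single best-overlapping component (ties
broken by higher component median likelihood, then lower component id).
Every component not matched to any lesion at Dice >= 0.5 is a false
positive, even if it partially overlaps one.

The FROC curve sweeps a threshold over component likelihoods and plots
lesion sensitivity against the mean number of false positives per
tumor-negative slide.  Analyses can include or exclude the ITC size class;
when ITCs are excluded, their lesions leave the sensitivity denominator,
components matched to them are ignored outright, and slides whose only
lesions are ITCs count as tumor-negative for the false-positive
denominator.

Slide-level ROC uses the trapezoidal AUC (identical to the Mann-Whitney
concordance probability with ties counted 1/2).  Confidence intervals come
from a slide-level percentile bootstrap (default 10,000 resamples,
equal-tailed 2.5-97.5% interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .detection import LesionComponent, max_feret_diameter_px, size_class_of_diameter
from .errors import EvaluationError

__all__ = [
    "GroundTruthLesion",
    "FROCCurve",
    "ROCResult",
    "BootstrapSummary",
    "SlideAssignment",
    "lesions_from_labeled_mask",
    "dice",
    "match_detections",
    "assign_slide",
    "froc",
    "roc",
    "specificity_at_sensitivity",
    "bootstrap",
    "bootstrap_roc_curve",
]

DICE_MATCH_THRESHOLD = 0.5
ALL_SIZE_CLASSES = ("ITC", "micro", "macro")
METASTASIS_CLASSES = ("micro", "macro")


@dataclass
class GroundTruthLesion:
    """An annotated lesion region at the analysis resolution."""

    ys: np.ndarray
    xs: np.ndarray
    size_class: str
    slide_id: str = "slide"
    lesion_id: int = 0

    def __post_init__(self) -> None:
        if len(self.ys) == 0:
            raise EvaluationError("ground-truth lesion with empty pixel set")
        if self.size_class not in ALL_SIZE_CLASSES:
            raise EvaluationError(f"unknown size class {self.size_class!r}")


def lesions_from_labeled_mask(
    labeled: np.ndarray, microns_per_pixel: float, slide_id: str = "slide"
) -> list[GroundTruthLesion]:
    """Extract per-lesion ground truth from an integer-labeled mask.

    Size classes follow the measured max Feret diameter of each component.
    """
    out = []
    for i, lbl in enumerate(np.unique(labeled)):
        if lbl == 0:
            continue
        ys, xs = np.nonzero(labeled == lbl)
        d_mm = max_feret_diameter_px(ys, xs) * microns_per_pixel / 1000.0
        out.append(
            GroundTruthLesion(
                ys=ys,
                xs=xs,
                size_class=size_class_of_diameter(d_mm),
                slide_id=slide_id,
                lesion_id=i,
            )
        )
    return out


def _flat(ys, xs, width: int) -> np.ndarray:
    return np.asarray(ys, dtype=np.int64) * width + np.asarray(xs, dtype=np.int64)


def dice(a, b) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) between two pixel sets.

    Accepts ``(ys, xs)`` pairs or anything ``set``-convertible; undefined
    (error) when both sets are empty.
    """
    sa = set(zip(*a)) if isinstance(a, tuple) else set(a)
    sb = set(zip(*b)) if isinstance(b, tuple) else set(b)
    if not sa and not sb:
        raise EvaluationError("Dice undefined for two empty sets")
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def _dice_flat(fa: np.ndarray, fb: np.ndarray) -> float:
    inter = np.intersect1d(fa, fb, assume_unique=True).size
    return 2.0 * inter / (fa.size + fb.size)


@dataclass
class SlideAssignment:
    """Per-slide matching outcome feeding the FROC analysis."""

    slide_id: str
    lesion_classes: list  # size class per ground-truth lesion
    matched_likelihood: list  # per lesion: matched component's likelihood or None
    fp_likelihoods: list  # likelihoods of unmatched components
    matched_component_ids: list  # per lesion: component id or None


def match_detections(
    components: list[LesionComponent],
    lesions: list[GroundTruthLesion],
    grid_width: int | None = None,
) -> SlideAssignment:
    """Match detected components to ground-truth lesions by Dice >= 0.5.

    Each lesion takes the component with the highest Dice (provided it
    reaches 0.5); ties break by higher median likelihood, then lower
    component id.  Components claiming no lesion are false positives.
    """
    if grid_width is None:
        all_xs = [c.xs for c in components] + [l.xs for l in lesions]
        grid_width = max((int(x.max()) for x in all_xs if len(x)), default=0) + 1
    comp_flat = [np.sort(_flat(c.ys, c.xs, grid_width)) for c in components]
    matched_ids: list = []
    matched_lik: list = []
    used_components: set[int] = set()
    for lesion in lesions:
        lf = np.sort(_flat(lesion.ys, lesion.xs, grid_width))
        best: tuple | None = None
        for comp, cf in zip(components, comp_flat):
            d = _dice_flat(lf, cf)
            if d < DICE_MATCH_THRESHOLD:
                continue
            key = (d, comp.median_likelihood, -comp.component_id)
            if best is None or key > best[0]:
                best = (key, comp)
        if best is None:
            matched_ids.append(None)
            matched_lik.append(None)
        else:
            comp = best[1]
            matched_ids.append(comp.component_id)
            matched_lik.append(comp.median_likelihood)
            used_components.add(comp.component_id)
    fp_likelihoods = [
        c.median_likelihood for c in components if c.component_id not in used_components
    ]
    slide_id = (
        components[0].slide_id
        if components
        else (lesions[0].slide_id if lesions else "slide")
    )
    return SlideAssignment(
        slide_id=slide_id,
        lesion_classes=[l.size_class for l in lesions],
        matched_likelihood=matched_lik,
        fp_likelihoods=fp_likelihoods,
        matched_component_ids=matched_ids,
    )


#: alias named for what it produces
assign_slide = match_detections


@dataclass
class FROCCurve:
    """Lesion sensitivity vs mean false positives per tumor-negative slide."""

    thresholds: np.ndarray
    fp_rates: np.ndarray
    sensitivities: np.ndarray
    included_classes: tuple
    n_lesions: int
    n_negative_slides: int

    def sensitivity_at(self, fp_budget: float) -> float:
        """Highest sensitivity among operating points with FP rate <= budget."""
        ok = self.fp_rates <= fp_budget + 1e-12
        return float(self.sensitivities[ok].max()) if ok.any() else 0.0


def froc(
    assignments: list[SlideAssignment],
    included_classes=METASTASIS_CLASSES,
) -> FROCCurve:
    """FROC analysis over per-slide matching outcomes.

    A slide is tumor-negative when it holds no lesion of an included class;
    false positives are counted on those slides only.  Components matched
    to excluded-class lesions are ignored (neither hit nor false positive).
    """
    included = tuple(included_classes)
    lesion_liks: list = []  # matched likelihood (or None) per included lesion
    fp_all: list[float] = []
    n_negative = 0
    for a in assignments:
        has_included = any(c in included for c in a.lesion_classes)
        for cls, lik in zip(a.lesion_classes, a.matched_likelihood):
            if cls in included:
                lesion_liks.append(lik)
        if not has_included:
            n_negative += 1
            fp_all.extend(a.fp_likelihoods)
    if n_negative == 0:
        raise EvaluationError("FROC needs at least one tumor-negative slide")
    if not lesion_liks:
        raise EvaluationError("FROC needs at least one lesion of an included class")

    n_lesions = len(lesion_liks)
    matched = np.array([l for l in lesion_liks if l is not None], dtype=float)
    fps = np.array(fp_all, dtype=float)
    observed = np.unique(np.concatenate([matched, fps]))[::-1]
    thresholds = np.concatenate([[np.inf], observed])
    sens = np.array([(matched >= t).sum() / n_lesions for t in thresholds])
    fp_rate = np.array([(fps >= t).sum() / n_negative for t in thresholds])
    return FROCCurve(
        thresholds=thresholds,
        fp_rates=fp_rate,
        sensitivities=sens,
        included_classes=included,
        n_lesions=n_lesions,
        n_negative_slides=n_negative,
    )


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc(scores, labels) -> ROCResult:
    """ROC curve and trapezoidal AUC over per-slide scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def specificity_at_sensitivity(result: ROCResult, target: float = 0.999) -> float:
    """Specificity at the highest threshold reaching the sensitivity target."""
    idx = int(np.argmax(result.tpr >= target))
    return float(1.0 - result.fpr[idx])


def _fast_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted 1/2 (rank statistic)."""
    from scipy.stats import rankdata

    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC needs both classes present")
    ranks = rankdata(scores)
    return (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auc_metric(cohort: np.ndarray) -> float:
    """Bootstrap-friendly AUC metric over an ``(n, 2)`` [score, label] array."""
    arr = np.asarray(cohort)
    return _fast_auc(arr[:, 0], arr[:, 1].astype(int))


@dataclass
class BootstrapSummary:
    n_samples: int
    mean: float
    ci_low: float
    ci_high: float
    seed: int
    n_redrawn: int = 0

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_samples": self.n_samples,
        }


def bootstrap(
    metric,
    cohort,
    n_samples: int = 10000,
    seed: int = 0,
    ci: float = 0.95,
) -> BootstrapSummary:
    """Slide-level percentile bootstrap of an arbitrary scalar metric.

    Slides are resampled with replacement to the cohort size.  Resamples on
    which the metric is undefined (raises :class:`EvaluationError`) are
    redrawn; if more than half of all draws fail, the metric is deemed
    undefined on this cohort.
    """
    n = len(cohort)
    if n == 0:
        raise EvaluationError("bootstrap over an empty cohort")
    is_array = isinstance(cohort, np.ndarray)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    values = np.empty(n_samples)
    n_redrawn = 0
    for b in range(n_samples):
        while True:
            idx = rng.integers(0, n, size=n)
            sub = cohort[idx] if is_array else [cohort[i] for i in idx]
            try:
                values[b] = metric(sub)
                break
            except EvaluationError:
                n_redrawn += 1
                if n_redrawn > n_samples // 2:
                    raise EvaluationError(
                        "metric undefined on more than half of the bootstrap draws"
                    )
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return BootstrapSummary(
        n_samples=n_samples,
        mean=float(values.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        seed=seed,
        n_redrawn=n_redrawn,
    )


def plot_roc(result: ROCResult, band: dict | None = None, ax=None, label=None):
    """Plot a ROC curve, optionally with a bootstrap band (needs matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(result.fpr, result.tpr, label=label or f"AUC = {result.auc:.3f}")
    if band is not None:
        ax.fill_between(
            band["fpr_grid"], band["tpr_low"], band["tpr_high"], alpha=0.3
        )
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("sensitivity")
    ax.legend()
    return ax


def plot_froc(curve: FROCCurve, ax=None, label=None):
    """Plot a FROC curve (needs matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    order = np.argsort(curve.fp_rates)
    ax.step(
        curve.fp_rates[order], curve.sensitivities[order], where="post",
        label=label or ", ".join(curve.included_classes),
    )
    ax.set_xlabel("false positives per tumor-negative slide")
    ax.set_ylabel("lesion sensitivity")
    ax.legend()
    return ax


def bootstrap_roc_curve(
    scores,
    labels,
    n_samples: int = 10000,
    seed: int = 0,
    fpr_grid: np.ndarray | None = None,
    ci: float = 0.95,
) -> dict:
    """Bootstrap ROC band by vertical averaging on a fixed FPR grid."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 1.0, 101)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(scores)
    tprs = np.empty((n_samples, len(fpr_grid)))
    b = 0
    guard = 0
    while b < n_samples:
        idx = rng.integers(0, n, size=n)
        if len(np.unique(labels[idx])) < 2:
            guard += 1
            if guard > n_samples // 2:
                raise EvaluationError("cohort too small for a two-class bootstrap")
            continue
        r = roc(scores[idx], labels[idx])
        tprs[b] = np.interp(fpr_grid, r.fpr, r.tpr)
        b += 1
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(tprs, [alpha, 1.0 - alpha], axis=0)
    return {
        "fpr_grid": fpr_grid,
        "tpr_mean": tprs.mean(axis=0),
        "tpr_low": lo,
        "tpr_high": hi,
    }
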