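"""Slide-level scoring by cumulative-histogram percentile analysis.

A normalized cumulative histogram (100 equal bins on [0, 1]) is built over
the tissue pixels of a slide's likelihood map.  For a cancer-free slide
nearly all likelihoods are small, so the cumulative curve saturates almost
immediately; in a cancerous slide mass sits in high-likelihood bins and the
curve rises slowly.  The percentile score is the likelihood (snapped to a
bin upper edge) at which the curve first reaches the chosen percentile —
higher scores mean more high-likelihood tissue.

Restricting the histogram to tissue pixels makes the score independent of
how much empty glass surrounds the specimen; background is likelihood 0 by
construction anyway.

The operating percentile can be selected on a validation cohort over the
decile grid 0.1..0.9, maximizing either ROC AUC or specificity at a fixed
sensitivity target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ScoringError
from .preprocess import BinaryMask
from .slide import LikelihoodMap

__all__ = [
    "N_BINS",
    "CumulativeHistogram",
    "PercentileScore",
    "cumulative_histogram",
    "percentile_score",
    "select_percentile",
    "DEFAULT_PERCENTILE_GRID",
]

N_BINS = 100
DEFAULT_PERCENTILE_GRID = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))


@dataclass
class CumulativeHistogram:
    """Normalized cumulative histogram of tissue-pixel likelihoods."""

    bin_edges: np.ndarray  # (101,) equally spaced on [0, 1]
    cumulative: np.ndarray  # (100,) non-decreasing, last value 1
    n_pixels: int


@dataclass
class PercentileScore:
    percentile: float
    score: float  # a bin upper edge in (0, 1]


def cumulative_histogram(
    lmap: LikelihoodMap, tissue: BinaryMask
) -> CumulativeHistogram:
    """Histogram the likelihoods of tissue pixels into 100 bins and cumulate.

    Bins are half-open ``[e_i, e_{i+1})`` with the final bin closed at 1
    (numpy's convention), normalized by the tissue pixel count.
    """
    if lmap.shape != tissue.shape:
        raise ScoringError(
            f"map {lmap.shape} and tissue mask {tissue.shape} geometry differ"
        )
    values = lmap.values[tissue.astype_bool()]
    if values.size == 0:
        raise ScoringError("empty tissue mask: no pixels to score")
    edges = np.linspace(0.0, 1.0, N_BINS + 1)
    counts, _ = np.histogram(values, bins=edges)
    cumulative = np.cumsum(counts) / values.size
    return CumulativeHistogram(
        bin_edges=edges, cumulative=cumulative, n_pixels=int(values.size)
    )


def percentile_score(hist: CumulativeHistogram, percentile: float) -> PercentileScore:
    """The upper edge of the first bin whose cumulative value reaches the percentile."""
    if not (0.0 < percentile < 1.0):
        raise ScoringError("percentile must be in (0, 1)")
    idx = int(np.argmax(hist.cumulative >= percentile))
    return PercentileScore(percentile=percentile, score=float(hist.bin_edges[idx + 1]))


def slide_percentile_score(
    lmap: LikelihoodMap, tissue: BinaryMask, percentile: float
) -> float:
    """Convenience: histogram + percentile in one call."""
    return percentile_score(cumulative_histogram(lmap, tissue), percentile).score


def select_percentile(
    maps,
    tissues,
    labels,
    criterion: str = "auc",
    grid=DEFAULT_PERCENTILE_GRID,
    sensitivity_target: float = 0.999,
) -> tuple[float, float]:
    """Pick the operating percentile on a validation cohort.

    ``criterion`` is ``"auc"`` (maximize ROC AUC) or ``"spec_at_sens"``
    (maximize specificity at ``sensitivity_target``).  Ties break toward
    the lowest percentile.  Returns ``(percentile, criterion_value)``.
    """
    from .evaluation import roc, specificity_at_sensitivity

    labels = np.asarray(labels)
    hists = [cumulative_histogram(m, t) for m, t in zip(maps, tissues)]
    best: tuple[float, float] | None = None
    for p in grid:
        scores = np.array([percentile_score(h, p).score for h in hists])
        result = roc(scores, labels)
        if criterion == "auc":
            value = result.auc
        elif criterion == "spec_at_sens":
            value = specificity_at_sensitivity(result, sensitivity_target)
        else:
            raise ScoringError(f"unknown criterion {criterion!r}")
        if best is None or value > best[1]:
            best = (float(p), float(value))
    assert best is not None
    return best
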