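"""Lesion-level detection: threshold, connected components, size filter.

The likelihood map is binarized at 0.3 to discard low-likelihood noise,
8-connected components are extracted, and components whose maximum Feret
diameter falls below 0.02 mm — one tenth of the 0.2 mm lower bound of a
micro-metastasis — are dropped as spurious (dust, deformation artifacts).
Each surviving component is scored by the median of the *original*
(pre-threshold) likelihoods over its pixels; the highest component median
serves as the slide-level score, as that is the component a pathologist
would act on.

Diameter is the maximum Feret diameter: the largest pairwise distance
between pixel centers plus one pixel extent, converted to millimetres via
the map's pixel spacing.  Small components are measured exactly; larger
ones via their convex hull, which carries the same extremes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .errors import GeometryError
from .slide import LikelihoodMap

__all__ = [
    "MICRO_METASTASIS_MIN_MM",
    "MACRO_METASTASIS_MIN_MM",
    "SPURIOUS_DIAMETER_FRACTION",
    "DetectionConfig",
    "LesionComponent",
    "detect_lesions",
    "slide_score_from_detections",
    "max_feret_diameter_px",
    "size_class_of_diameter",
]

#: Clinical size conventions: micro-metastases span 0.2-2 mm, macro > 2 mm,
#: isolated tumor cells (ITC) < 0.2 mm.
MICRO_METASTASIS_MIN_MM = 0.2
MACRO_METASTASIS_MIN_MM = 2.0
#: Components smaller than this fraction of the micro-metastasis lower
#: bound are treated as spurious detections.
SPURIOUS_DIAMETER_FRACTION = 0.1

_EXACT_FERET_MAX_PIXELS = 3000


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds for turning a likelihood map into discrete candidates."""

    likelihood_threshold: float = 0.3
    min_diameter_mm: float = SPURIOUS_DIAMETER_FRACTION * MICRO_METASTASIS_MIN_MM
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not (0.0 < self.likelihood_threshold < 1.0):
            raise GeometryError("likelihood_threshold must be in (0, 1)")
        if self.min_diameter_mm <= 0:
            raise GeometryError("min_diameter_mm must be positive")
        if self.connectivity not in (4, 8):
            raise GeometryError("connectivity must be 4 or 8")


@dataclass
class LesionComponent:
    """One detected candidate lesion."""

    ys: np.ndarray  # row indices at analysis resolution
    xs: np.ndarray  # column indices
    diameter_mm: float
    median_likelihood: float
    slide_id: str = "slide"
    component_id: int = 0

    @property
    def n_pixels(self) -> int:
        return len(self.ys)

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.xs.mean()), float(self.ys.mean())

    def pixel_set(self) -> set[tuple[int, int]]:
        return set(zip(self.xs.tolist(), self.ys.tolist()))


def max_feret_diameter_px(ys: np.ndarray, xs: np.ndarray) -> float:
    """Max pairwise pixel-center distance plus one pixel extent.

    Exact for small components; via the convex hull (which preserves the
    farthest pair) for large ones.
    """
    pts = np.column_stack([ys, xs]).astype(float)
    if len(pts) == 1:
        return 1.0
    if len(pts) > _EXACT_FERET_MAX_PIXELS:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:  # degenerate (collinear) point sets
            pass
    return float(pdist(pts).max()) + 1.0


def size_class_of_diameter(diameter_mm: float) -> str:
    """Clinical size class: ITC < 0.2 mm, micro 0.2-2 mm, macro > 2 mm."""
    if diameter_mm < MICRO_METASTASIS_MIN_MM:
        return "ITC"
    if diameter_mm <= MACRO_METASTASIS_MIN_MM:
        return "micro"
    return "macro"


def detect_lesions(
    lmap: LikelihoodMap, cfg: DetectionConfig = DetectionConfig()
) -> list[LesionComponent]:
    """Connected components of the thresholded map, size-filtered and scored.

    The threshold comparison is inclusive (``value >= threshold``); median
    likelihoods are computed on the raw map values over each component.
    """
    if not np.isfinite(lmap.microns_per_pixel) or lmap.microns_per_pixel <= 0:
        raise GeometryError("likelihood map has no valid microns_per_pixel")
    binary = lmap.values >= cfg.likelihood_threshold
    structure = np.ones((3, 3), dtype=bool) if cfg.connectivity == 8 else None
    labels, n = ndimage.label(binary, structure=structure)
    components: list[LesionComponent] = []
    mpp = lmap.microns_per_pixel
    comp_id = 0
    slices = ndimage.find_objects(labels)
    for lbl in range(1, n + 1):
        sl = slices[lbl - 1]
        ys, xs = np.nonzero(labels[sl] == lbl)
        ys = ys + sl[0].start
        xs = xs + sl[1].start
        diameter_mm = max_feret_diameter_px(ys, xs) * mpp / 1000.0
        if diameter_mm < cfg.min_diameter_mm:
            continue
        median = float(np.median(lmap.values[ys, xs]))
        components.append(
            LesionComponent(
                ys=ys,
                xs=xs,
                diameter_mm=diameter_mm,
                median_likelihood=median,
                slide_id=lmap.slide_id,
                component_id=comp_id,
            )
        )
        comp_id += 1
    return components


def slide_score_from_detections(components: list[LesionComponent]) -> float:
    """Slide-level score: the highest component median likelihood (0 if none)."""
    if not components:
        return 0.0
    return max(c.median_likelihood for c in components)
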