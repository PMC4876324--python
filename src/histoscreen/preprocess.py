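"""Slide pre-processing: optical density, tissue masks, annotation rasters.

Stained tissue absorbs light, so its optical density (OD) is well above
zero, while the glass background transmits nearly everything and sits close
to OD 0.  Per channel ``c`` with 8-bit intensity ``I``::

    OD_c = -log10(max(I, 1) / I_max),   I_max = 255

The base-10 (Beer-Lambert) convention is used, with intensity clamped to 1
so the OD stays finite.  A pixel counts as tissue when *any* channel's OD
exceeds the threshold (default 0.2), which removes near-white background
robustly.

Polygon annotations are rasterized with the even-odd fill rule using a
strict pixel-center-inside test.  Pixel centers sit at integer coordinates
(0-based, x right, y down); a center exactly on a ring edge follows the
half-open ray-casting convention.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import AnnotationError, FormatError, GeometryError
from .slide import SlideImage

__all__ = [
    "I_MAX",
    "OD_TISSUE_THRESHOLD",
    "OpticalDensityMap",
    "BinaryMask",
    "PolygonAnnotation",
    "optical_density",
    "tissue_mask",
    "rasterize_annotations",
    "read_annotation_json",
    "write_annotation_json",
    "read_imagescope_xml",
]

I_MAX = 255
#: OD threshold separating tissue from near-white background.
OD_TISSUE_THRESHOLD = 0.2


@dataclass
class OpticalDensityMap:
    """Per-pixel, per-channel optical density of an RGB slide."""

    od: np.ndarray  # (H, W, 3) float64, >= 0
    i_max: int = I_MAX
    microns_per_pixel: float = float("nan")

    @property
    def shape(self) -> tuple[int, int]:
        return self.od.shape[:2]


@dataclass
class BinaryMask:
    """A {0,1} raster sharing geometry with the analysis-resolution slide."""

    values: np.ndarray  # (H, W) uint8 in {0, 1}
    microns_per_pixel: float
    role: str  # "tissue" or "annotation"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise GeometryError("mask must be 2-D")
        self.values = (v > 0).astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def astype_bool(self) -> np.ndarray:
        return self.values.astype(bool)


@dataclass
class PolygonAnnotation:
    """Closed vertex rings outlining cancer regions, in pixel coordinates.

    Each ring is an (K, 2) array of (x, y) vertices, K >= 3.  A repeated
    closing vertex is accepted and dropped.
    """

    polygons: list = field(default_factory=list)
    label: str = "cancer"

    def __post_init__(self) -> None:
        cleaned = []
        for ring in self.polygons:
            r = np.asarray(ring, dtype=float)
            if r.ndim != 2 or r.shape[1] != 2:
                raise AnnotationError(f"ring must be (K, 2), got {r.shape}")
            if len(r) > 1 and np.array_equal(r[0], r[-1]):
                r = r[:-1]
            if len(r) < 3:
                raise AnnotationError(
                    f"ring needs at least 3 distinct vertices, got {len(r)}"
                )
            cleaned.append(r)
        self.polygons = cleaned


def optical_density(image, i_max: int = I_MAX) -> OpticalDensityMap:
    """Convert an RGB slide (or raw array) to per-channel optical density.

    Intensities are clamped to >= 1 before the log so the OD is bounded by
    ``log10(i_max)``; saturated pixels (I = i_max) map exactly to OD 0.
    """
    mpp = float("nan")
    if isinstance(image, SlideImage):
        mpp = image.microns_per_pixel
        image = image.image
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"expected an RGB (H, W, 3) image, got shape {arr.shape}")
    inten = np.clip(arr.astype(np.float64), 1.0, i_max)
    od = -np.log10(inten / i_max)
    return OpticalDensityMap(od=od, i_max=i_max, microns_per_pixel=mpp)


def tissue_mask(
    od: OpticalDensityMap,
    threshold: float = OD_TISSUE_THRESHOLD,
    microns_per_pixel: float | None = None,
) -> BinaryMask:
    """Threshold optical densities into a binary tissue mask.

    A pixel is tissue (1) iff the maximum of its three channel ODs exceeds
    ``threshold``; near-white background falls below and is labeled 0.
    """
    mpp = microns_per_pixel if microns_per_pixel is not None else od.microns_per_pixel
    values = (od.od.max(axis=2) > threshold).astype(np.uint8)
    return BinaryMask(values=values, microns_per_pixel=mpp, role="tissue")


def _even_odd_fill(rings, shape: tuple[int, int]) -> np.ndarray:
    """Vectorized even-odd ray casting over all pixel centers."""
    h, w = shape
    xs = np.arange(w, dtype=float)
    ys = np.arange(h, dtype=float)
    inside = np.zeros((h, w), dtype=bool)
    for ring in rings:
        v1 = ring
        v2 = np.roll(ring, -1, axis=0)
        parity = np.zeros((h, w), dtype=bool)
        for (x1, y1), (x2, y2) in zip(v1, v2):
            if y1 == y2:
                continue
            lo, hi = (y1, y2) if y1 < y2 else (y2, y1)
            rows = (ys >= lo) & (ys < hi)  # half-open edge span
            if not rows.any():
                continue
            yr = ys[rows]
            xint = x1 + (yr - y1) * (x2 - x1) / (y2 - y1)
            parity[rows] ^= xs[None, :] < xint[:, None]
        inside ^= parity
    return inside


def rasterize_annotations(
    ann: PolygonAnnotation,
    shape: tuple[int, int],
    microns_per_pixel: float = float("nan"),
) -> BinaryMask:
    """Rasterize polygon rings to a binary annotation mask.

    Pixel centers strictly inside an odd number of rings (even-odd rule)
    are labeled 1; rasterization is independent of ring orientation.
    """
    rings = [np.asarray(r, dtype=float) for r in ann.polygons]
    for r in rings:
        if len(r) < 3:
            raise AnnotationError("ring with fewer than 3 vertices")
    inside = _even_odd_fill(rings, shape) if rings else np.zeros(shape, dtype=bool)
    return BinaryMask(
        values=inside.astype(np.uint8),
        microns_per_pixel=microns_per_pixel,
        role="annotation",
    )


# ---------------------------------------------------------------------------
# annotation I/O


def read_annotation_json(path) -> PolygonAnnotation:
    """Read ``{"polygons": [[[x, y], ...], ...]}`` from a JSON file."""
    with open(path) as fh:
        payload = json.load(fh)
    if "polygons" not in payload:
        raise AnnotationError(f"{path}: missing 'polygons' key")
    return PolygonAnnotation(polygons=payload["polygons"])


def write_annotation_json(ann: PolygonAnnotation, path) -> None:
    payload = {"polygons": [np.asarray(r).tolist() for r in ann.polygons]}
    Path(path).write_text(json.dumps(payload))


def read_imagescope_xml(path) -> PolygonAnnotation:
    """Read an ImageScope-style annotation XML into polygon rings.

    Expects ``Annotation/Regions/Region/Vertices/Vertex`` elements with
    ``X``/``Y`` attributes, the layout produced by Aperio ImageScope's
    freehand tool.
    """
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:  # pragma: no cover - malformed file
        raise AnnotationError(f"{path}: not parseable XML: {exc}") from exc
    rings = []
    for region in root.iter("Region"):
        verts = [
            (float(v.attrib["X"]), float(v.attrib["Y"]))
            for v in region.iter("Vertex")
        ]
        if len(verts) >= 3:
            rings.append(verts)
    return PolygonAnnotation(polygons=rings)
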