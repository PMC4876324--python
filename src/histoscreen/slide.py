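"""Core raster containers shared by all stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError

__all__ = ["SlideImage", "LikelihoodMap"]


@dataclass
class SlideImage:
    """An RGB whole-slide-like raster with physical pixel spacing.

    Parameters
    ----------
    image : (H, W, 3) uint8 array
    microns_per_pixel : physical size of one pixel side, in micrometres
    slide_id : stable identifier used in manifests and reports
    """

    image: np.ndarray
    microns_per_pixel: float
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise GeometryError(
                f"slide image must be (H, W, 3) RGB, got shape {img.shape}"
            )
        if self.microns_per_pixel <= 0:
            raise GeometryError("microns_per_pixel must be positive")
        self.image = img

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


@dataclass
class LikelihoodMap:
    """Per-pixel cancer likelihood in [0, 1] at the analysis resolution.

    Background (non-tissue) pixels are zero by construction.
    """

    values: np.ndarray
    microns_per_pixel: float
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float32)
        if v.ndim != 2:
            raise GeometryError("likelihood map must be a 2-D raster")
        if self.microns_per_pixel <= 0:
            raise GeometryError("microns_per_pixel must be positive")
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape
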