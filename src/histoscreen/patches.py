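"""Balanced patch sampling, extraction, augmentation, and hard-example boosting.

Training patches are 128x128 RGB squares cut from the slide at a configured
analysis resolution.  A patch's label is the annotation-mask value at its
center pixel (the boosting rule references the center pixel, so the label
must too).  Class balance is enforced at sampling time: equal numbers of
cancer-centered and benign-centered patches, drawn uniformly without
replacement.

Augmentation applies the four axis rotations and their horizontal mirrors
(the full dihedral group of the square), multiplying the dataset by exactly
eight.

Boosting re-samples additional patches with a multiplicative weight
``boost_factor`` on candidates whose center pixel the initial model
misclassified (likelihood >= 0.5 for a benign center, < 0.5 for a cancer
center).  Boost draws are taken with replacement, so a candidate's
probability per draw is proportional to its weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, SamplingError
from .preprocess import BinaryMask
from .slide import LikelihoodMap, SlideImage

__all__ = [
    "PatchSpec",
    "LabeledPatch",
    "BoostConfig",
    "sample_patch_centers",
    "extract_patch",
    "augment_patch",
    "boost_resample",
    "resample_to_mpp",
]

MISCLASSIFICATION_CUTOFF = 0.5


@dataclass(frozen=True)
class PatchSpec:
    """Patch geometry and sampling budget.

    ``target_mpp`` is the analysis resolution in microns per pixel; it must
    be at least the native slide resolution (patches are only ever
    downsampled).
    """

    target_mpp: float
    patch_px: int = 128
    n_per_class: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_px <= 0 or self.patch_px % 2:
            raise GeometryError("patch_px must be a positive even integer")
        if self.target_mpp <= 0:
            raise GeometryError("target_mpp must be positive")
        if self.n_per_class <= 0:
            raise SamplingError("n_per_class must be positive")


@dataclass
class LabeledPatch:
    """One training patch plus its provenance."""

    pixels: np.ndarray  # (patch_px, patch_px, 3) uint8
    label: int
    slide_id: str
    center: tuple[int, int]  # (x, y) in analysis-level pixels
    rotation: int = 0  # degrees, in {0, 90, 180, 270}
    flipped: bool = False


@dataclass(frozen=True)
class BoostConfig:
    """Hard-example re-sampling parameters."""

    n_additional_per_class: int
    boost_factor: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.boost_factor) or self.boost_factor < 1:
            raise SamplingError("boost_factor must be finite and >= 1")
        if self.n_additional_per_class <= 0:
            raise SamplingError("n_additional_per_class must be positive")


def _eligible_centers(mask: np.ndarray, half: int) -> np.ndarray:
    """Indices (y, x) of mask-positive pixels whose patch fits the raster."""
    h, w = mask.shape
    ok = mask.astype(bool).copy()
    ok[:half, :] = False
    ok[:, :half] = False
    if h - half + 1 <= h:
        ok[h - half + 1 :, :] = False
        ok[:, w - half + 1 :] = False
    return np.argwhere(ok)


def sample_patch_centers(
    tissue: BinaryMask, annotation: BinaryMask, spec: PatchSpec
) -> list[tuple[tuple[int, int], int]]:
    """Draw a class-balanced set of patch centers, uniformly without replacement.

    Returns ``[(center_xy, label), ...]`` with exactly ``spec.n_per_class``
    centers per class: label 1 centers lie inside the annotation, label 0
    centers in tissue outside it.
    """
    if tissue.shape != annotation.shape:
        raise GeometryError(
            f"tissue {tissue.shape} and annotation {annotation.shape} masks differ"
        )
    half = spec.patch_px // 2
    ann = annotation.astype_bool()
    tis = tissue.astype_bool()
    pos = _eligible_centers(ann, half)
    neg = _eligible_centers(tis & ~ann, half)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    out: list[tuple[tuple[int, int], int]] = []
    for label, pool in ((1, pos), (0, neg)):
        if len(pool) < spec.n_per_class:
            raise SamplingError(
                f"class {label}: requested {spec.n_per_class} centers but only "
                f"{len(pool)} eligible"
            )
        pick = rng.choice(len(pool), size=spec.n_per_class, replace=False)
        out.extend(((int(pool[i][1]), int(pool[i][0])), label) for i in pick)
    return out


def _block_mean(img: np.ndarray, f: int) -> np.ndarray:
    h, w = img.shape[:2]
    r = img.reshape(h // f, f, w // f, f, -1).mean(axis=(1, 3))
    return r


def resample_to_mpp(image: np.ndarray, native_mpp: float, target_mpp: float) -> np.ndarray:
    """Resample an RGB raster from native to target resolution.

    Integer downsampling factors use exact area averaging (anti-aliased and
    deterministic); other ratios fall back to anti-aliased resizing.
    """
    ratio = target_mpp / native_mpp
    if abs(ratio - 1.0) < 1e-9:
        return image
    if ratio < 1.0 - 1e-9:
        raise GeometryError(
            f"target_mpp {target_mpp} finer than native {native_mpp}; upsampling unsupported"
        )
    f = int(round(ratio))
    if abs(ratio - f) < 1e-9:
        h, w = image.shape[:2]
        img = image[: (h // f) * f, : (w // f) * f]
        out = _block_mean(img.astype(np.float64), f)
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    from skimage.transform import resize

    h, w = image.shape[:2]
    out = resize(
        image,
        (max(1, int(round(h / ratio))), max(1, int(round(w / ratio)))),
        anti_aliasing=True,
        preserve_range=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def extract_patch(
    slide: SlideImage, center: tuple[int, int], spec: PatchSpec
) -> np.ndarray:
    """Cut the ``patch_px`` square centered on ``center`` at the analysis resolution.

    ``center`` is (x, y) in analysis-level pixels.  At identical native and
    target resolution this is a bit-exact crop; integer downsampling factors
    average the corresponding native-resolution block.
    """
    cx, cy = center
    half = spec.patch_px // 2
    ratio = spec.target_mpp / slide.microns_per_pixel
    if ratio < 1.0 - 1e-9:
        raise GeometryError("target_mpp finer than the native slide resolution")
    f = int(round(ratio))
    exact = abs(ratio - f) < 1e-9
    h, w = slide.shape
    if exact:
        y0, y1 = (cy - half) * f, (cy + half) * f
        x0, x1 = (cx - half) * f, (cx + half) * f
        if y0 < 0 or x0 < 0 or y1 > h or x1 > w:
            raise GeometryError(
                f"patch at center {center} exceeds slide bounds {slide.shape}"
            )
        crop = slide.image[y0:y1, x0:x1]
        if f == 1:
            return crop.copy()
        out = _block_mean(crop.astype(np.float64), f)
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    # non-integer ratio: crop generously at native scale, then resize
    y0 = int(round((cy - half) * ratio))
    y1 = int(round((cy + half) * ratio))
    x0 = int(round((cx - half) * ratio))
    x1 = int(round((cx + half) * ratio))
    if y0 < 0 or x0 < 0 or y1 > h or x1 > w:
        raise GeometryError(
            f"patch at center {center} exceeds slide bounds {slide.shape}"
        )
    from skimage.transform import resize

    out = resize(
        slide.image[y0:y1, x0:x1],
        (spec.patch_px, spec.patch_px),
        anti_aliasing=True,
        preserve_range=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def augment_patch(patch: LabeledPatch) -> list[LabeledPatch]:
    """The eight dihedral variants of a square patch (4 rotations x 2 mirrors)."""
    px = patch.pixels
    if px.shape[0] != px.shape[1]:
        raise GeometryError(f"patch must be square, got {px.shape[:2]}")
    out = []
    for k, deg in enumerate((0, 90, 180, 270)):
        rot = np.rot90(px, k)
        for flipped in (False, True):
            arr = np.fliplr(rot) if flipped else rot
            out.append(
                LabeledPatch(
                    pixels=np.ascontiguousarray(arr),
                    label=patch.label,
                    slide_id=patch.slide_id,
                    center=patch.center,
                    rotation=deg,
                    flipped=flipped,
                )
            )
    return out


def boost_resample(
    centers_with_labels: list[tuple[tuple[int, int], int]],
    initial_map: LikelihoodMap | np.ndarray,
    cfg: BoostConfig,
) -> list[tuple[tuple[int, int], int]]:
    """Draw additional per-class centers, over-weighting misclassified ones.

    A candidate whose center pixel the initial likelihood map got wrong
    (>= 0.5 for label 0, < 0.5 for label 1) carries sampling weight
    ``cfg.boost_factor`` against weight 1; draws are with replacement, so
    the per-draw probability of a candidate is weight / total weight.
    """
    values = initial_map.values if isinstance(initial_map, LikelihoodMap) else np.asarray(initial_map)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    out: list[tuple[tuple[int, int], int]] = []
    for label in (0, 1):
        cands = [(c, l) for c, l in centers_with_labels if l == label]
        if not cands:
            raise SamplingError(f"no candidate centers for class {label}")
        lik = np.array([values[cy, cx] for (cx, cy), _ in cands])
        wrong = lik >= MISCLASSIFICATION_CUTOFF if label == 0 else lik < MISCLASSIFICATION_CUTOFF
        weights = np.where(wrong, cfg.boost_factor, 1.0)
        p = weights / weights.sum()
        pick = rng.choice(len(cands), size=cfg.n_additional_per_class, replace=True, p=p)
        out.extend(cands[i] for i in pick)
    return out
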