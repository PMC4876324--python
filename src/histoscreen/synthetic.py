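"""Synthetic whole-slide-like images with ground-truth lesion masks.

The generator emulates the three tissue compartments a screening pipeline
has to tell apart:

* near-white glass background whose per-channel optical density stays
  below the tissue threshold (0.2),
* benign tissue: an eosin-pink Gaussian color distribution with spatially
  correlated noise (smoothed noise fields),
* planted "cancer" lesions: deformed ellipses whose color mean is shifted
  from the benign mean by ``texture_separation`` pooled standard
  deviations along a fixed hematoxylin-ish direction.

Lesion sizes are controlled in millimetres so the micro- (0.2-2 mm) and
macro- (>2 mm) metastasis conventions can both be exercised.  Each lesion
is a simply connected star-shaped blob with low-frequency boundary
harmonics; its maximum Feret diameter lands within +-10% of the request.
Lesions never overlap each other nor touch the image border.

Optional benign "distractor" blobs (a weak fraction of the lesion texture
shift, absent from the annotation mask) create false-positive pressure for
hard-negative boosting experiments; they are off by default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .preprocess import BinaryMask
from .slide import SlideImage

__all__ = [
    "SlideSimSpec",
    "SyntheticSlide",
    "generate_slide",
    "generate_cohort",
    "BACKGROUND_RGB",
    "BENIGN_RGB",
    "TEXTURE_NOISE_SD",
    "SEPARABILITY_THRESHOLD",
]

#: Mean background color; with noise sd 2 and a floor at 236 every
#: background channel stays >= 236 > 255 * 10**-0.2, i.e. OD < 0.2.
BACKGROUND_RGB = (245.0, 245.0, 243.0)
BACKGROUND_NOISE_SD = 2.0
BACKGROUND_FLOOR = 236

#: Benign tissue color mean (eosin-pink) and per-channel texture noise sd.
BENIGN_RGB = (185.0, 120.0, 175.0)
TEXTURE_NOISE_SD = 10.0

#: Unit shift direction for lesion texture (toward darker, bluer tissue).
#: The R component has magnitude 1, so a ``texture_separation`` of s moves
#: the red-channel mean by exactly s pooled standard deviations.
LESION_SHIFT_DIRECTION = (-1.0, -0.6, 0.25)

#: Above this ``texture_separation`` the lesion/benign class means are
#: guaranteed >= 3 pooled standard deviations apart in the red channel.
SEPARABILITY_THRESHOLD = 3.0

_BOUNDARY_AMPLITUDE = 0.15  # total harmonic amplitude of the lesion boundary


@dataclass(frozen=True)
class SlideSimSpec:
    """Simulation parameters for one synthetic slide.

    Defaults describe the study conditions used throughout the test suite:
    a 512 px square slide at 8 um/px (a 4.1 mm field of view), 55% tissue,
    and two micro-metastasis-sized lesions with a strongly separable
    texture.
    """

    width_px: int = 512
    height_px: int = 512
    microns_per_pixel: float = 8.0
    n_lesions: int = 2
    lesion_diameters_mm: tuple = (0.6, 1.2)
    tissue_fraction: float = 0.55
    texture_separation: float = 4.0
    n_distractors: int = 0
    distractor_diameter_mm: float = 0.4
    distractor_separation_frac: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ConfigurationError("slide dimensions must be positive")
        if self.microns_per_pixel <= 0:
            raise ConfigurationError("microns_per_pixel must be positive")
        if not (0.0 < self.tissue_fraction <= 1.0):
            raise ConfigurationError("tissue_fraction must be in (0, 1]")
        if self.texture_separation < 0:
            raise ConfigurationError("texture_separation must be >= 0")
        if self.n_lesions < 0 or self.n_distractors < 0:
            raise ConfigurationError("lesion/distractor counts must be >= 0")
        diams = tuple(float(d) for d in self.lesion_diameters_mm)
        if len(diams) != self.n_lesions:
            raise ConfigurationError(
                f"n_lesions={self.n_lesions} but {len(diams)} diameters given"
            )
        if any(d <= 0 for d in diams):
            raise ConfigurationError("lesion diameters must be positive")
        object.__setattr__(self, "lesion_diameters_mm", diams)


@dataclass
class SyntheticSlide:
    """A generated slide, its ground truth, and the spec that produced it."""

    image: np.ndarray  # (H, W, 3) uint8
    annotation_mask: np.ndarray  # (H, W) uint8, 1 = lesion
    lesion_labels: np.ndarray  # (H, W) int32, 0 background, 1..n per lesion
    slide_label: int
    spec: SlideSimSpec
    slide_id: str = "slide"
    tissue_truth: np.ndarray | None = None  # (H, W) bool, planted tissue layout
    planted_diameters_mm: tuple = ()

    def as_slide_image(self) -> SlideImage:
        return SlideImage(
            image=self.image,
            microns_per_pixel=self.spec.microns_per_pixel,
            slide_id=self.slide_id,
        )

    def annotation_binary_mask(self) -> BinaryMask:
        return BinaryMask(
            values=self.annotation_mask,
            microns_per_pixel=self.spec.microns_per_pixel,
            role="annotation",
        )


def _correlated_noise(rng, shape, sigma: float) -> np.ndarray:
    """Smoothed white noise rescaled to unit pixel variance."""
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    sd = raw.std()
    return raw / sd if sd > 0 else raw


def _tissue_region(rng, spec: SlideSimSpec) -> np.ndarray:
    """A connected blobby region holding exactly the requested pixel count."""
    h, w = spec.height_px, spec.width_px
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot((xx - cx) / (w / 2.0), (yy - cy) / (h / 2.0))
    field_ = r + 0.25 * _correlated_noise(rng, (h, w), sigma=max(2.0, min(h, w) / 8))
    border = 4
    if h > 2 * border and w > 2 * border:
        field_[:border, :] = np.inf
        field_[-border:, :] = np.inf
        field_[:, :border] = np.inf
        field_[:, -border:] = np.inf
    n_target = int(round(spec.tissue_fraction * h * w))
    n_target = min(n_target, int(np.isfinite(field_).sum()))
    flat = field_.ravel()
    kth = np.partition(flat, n_target - 1)[n_target - 1]
    return field_ <= kth


def _lesion_blob(rng, diameter_px: float, center, shape) -> np.ndarray:
    """Rasterize one star-shaped blob with low-frequency boundary noise.

    The blob's maximum through-center width equals ``diameter_px``; for the
    mild harmonic amplitudes used the max Feret diameter coincides with it.
    """
    thetas = np.linspace(0.0, 2 * np.pi, 721)
    radius = np.ones_like(thetas)
    amps = rng.uniform(0, 1, size=4)
    amps *= _BOUNDARY_AMPLITUDE / max(amps.sum(), 1e-9) * rng.uniform(0.5, 1.0)
    for k, a in zip(range(2, 6), amps):
        radius += a * np.cos(k * thetas + rng.uniform(0, 2 * np.pi))
    width = radius + np.interp(
        (thetas + np.pi) % (2 * np.pi), thetas, radius
    )
    scale = diameter_px / width.max()
    radius *= scale

    cy, cx = center
    rmax = int(np.ceil(radius.max())) + 1
    y0, y1 = max(0, cy - rmax), min(shape[0], cy + rmax + 1)
    x0, x1 = max(0, cx - rmax), min(shape[1], cx + rmax + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
    rho = np.hypot(yy - cy, xx - cx)
    ang = np.arctan2(yy - cy, xx - cx) % (2 * np.pi)
    rb = np.interp(ang, thetas, radius)
    blob = np.zeros(shape, dtype=bool)
    blob[y0:y1, x0:x1] = rho <= rb
    return blob


def _place_blobs(rng, tissue, diameters_px, spec, taken):
    """Choose non-overlapping centers deep enough inside the tissue.

    Returns a list of (center, blob_mask).  Raises ConfigurationError
    naming the first diameter that cannot be placed.
    """
    dist = ndimage.distance_transform_edt(tissue)
    placed = []
    order = np.argsort(diameters_px)[::-1]  # biggest first
    centers: list[tuple[int, int]] = [c for c, _ in taken]
    radii: list[float] = [r for _, r in taken]
    for idx in order:
        d_px = diameters_px[idx]
        margin = 0.68 * d_px + 4
        eligible = np.argwhere(dist >= margin)
        if len(eligible) == 0:
            mm = d_px * spec.microns_per_pixel / 1000.0
            raise ConfigurationError(
                f"lesion diameter {mm:.3g} mm ({d_px:.0f} px) does not fit "
                f"inside the tissue region"
            )
        ok = None
        for _ in range(300):
            cy, cx = eligible[rng.integers(len(eligible))]
            if all(
                np.hypot(cy - py, cx - px) >= 0.68 * d_px + r + 6
                for (py, px), r in zip(centers, radii)
            ):
                ok = (int(cy), int(cx))
                break
        if ok is None:
            mm = d_px * spec.microns_per_pixel / 1000.0
            raise ConfigurationError(
                f"could not place lesion of diameter {mm:.3g} mm without "
                f"overlap; reduce counts or diameters"
            )
        blob = _lesion_blob(rng, d_px, ok, tissue.shape)
        placed.append((idx, ok, blob))
        centers.append(ok)
        radii.append(0.68 * d_px)
    placed.sort(key=lambda t: t[0])  # restore requested order
    return [(c, b) for _, c, b in placed]


def generate_slide(spec: SlideSimSpec, slide_id: str = "slide") -> SyntheticSlide:
    """Generate one synthetic slide; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    h, w = spec.height_px, spec.width_px
    tissue = _tissue_region(rng, spec)

    diameters_px = [
        d * 1000.0 / spec.microns_per_pixel for d in spec.lesion_diameters_mm
    ]
    lesions = _place_blobs(rng, tissue, diameters_px, spec, taken=[]) if diameters_px else []

    lesion_labels = np.zeros((h, w), dtype=np.int32)
    for i, (_, blob) in enumerate(lesions, start=1):
        lesion_labels[blob] = i
    annotation = (lesion_labels > 0).astype(np.uint8)

    taken = [(c, 0.68 * d) for (c, _), d in zip(lesions, diameters_px)]
    distractor_mask = np.zeros((h, w), dtype=bool)
    if spec.n_distractors > 0:
        d_px = [spec.distractor_diameter_mm * 1000.0 / spec.microns_per_pixel] * spec.n_distractors
        for _, blob in _place_blobs(rng, tissue, d_px, spec, taken=taken):
            distractor_mask |= blob

    shift = np.array(LESION_SHIFT_DIRECTION) * spec.texture_separation * TEXTURE_NOISE_SD
    mean = np.empty((h, w, 3))
    sd = np.empty((h, w, 3))
    mean[:] = BACKGROUND_RGB
    sd[:] = BACKGROUND_NOISE_SD
    mean[tissue] = BENIGN_RGB
    sd[tissue] = TEXTURE_NOISE_SD
    mean[annotation > 0] = np.array(BENIGN_RGB) + shift
    if spec.n_distractors > 0:
        mean[distractor_mask] = (
            np.array(BENIGN_RGB) + shift * spec.distractor_separation_frac
        )

    noise = np.stack(
        [_correlated_noise(rng, (h, w), sigma=2.0) for _ in range(3)], axis=2
    )
    img = mean + sd * noise
    bg = ~tissue
    img[bg] = np.clip(img[bg], BACKGROUND_FLOOR, 255)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return SyntheticSlide(
        image=img,
        annotation_mask=annotation,
        lesion_labels=lesion_labels,
        slide_label=int(spec.n_lesions > 0),
        spec=spec,
        slide_id=slide_id,
        tissue_truth=tissue,
        planted_diameters_mm=spec.lesion_diameters_mm,
    )


def generate_cohort(
    n_positive: int, n_negative: int, template: SlideSimSpec
) -> list[SyntheticSlide]:
    """Generate a cohort of slides from one template spec.

    Positive slides reuse the template's lesion layout parameters; negative
    slides carry no lesions.  Per-slide seeds are derived deterministically
    from ``template.seed`` so identical calls yield bit-identical cohorts.
    """
    if n_positive < 0 or n_negative < 0:
        raise ConfigurationError("cohort counts must be >= 0")
    if n_positive > 0 and template.n_lesions < 1:
        raise ConfigurationError(
            "template must plant at least one lesion for positive slides"
        )
    children = np.random.SeedSequence(template.seed).spawn(n_positive + n_negative)
    slides = []
    for i in range(n_positive):
        seed_i = int(children[i].generate_state(1)[0] % (2**31))
        spec_i = dataclasses.replace(template, seed=seed_i)
        slides.append(generate_slide(spec_i, slide_id=f"pos_{i:03d}"))
    for j in range(n_negative):
        seed_j = int(children[n_positive + j].generate_state(1)[0] % (2**31))
        spec_j = dataclasses.replace(
            template, seed=seed_j, n_lesions=0, lesion_diameters_mm=()
        )
        slides.append(generate_slide(spec_j, slide_id=f"neg_{j:03d}"))
    return slides
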