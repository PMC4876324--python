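"""Disk formats: slides and masks as PNG/TIFF with JSON sidecars.

Layout for one slide ``<id>`` inside a cohort directory::

    <id>.png         RGB slide raster
    <id>_mask.png    annotation mask, 0/255 single channel (optional)
    <id>.json        {"slide_id", "microns_per_pixel", "label",
                      "lesion_diameters_mm"}

Likelihood maps are float32 TIFFs next to a ``<id>_map.json`` sidecar.
Binary masks are stored 0/255 on disk and mapped back to {0, 1} on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .errors import FormatError
from .preprocess import BinaryMask
from .slide import LikelihoodMap, SlideImage
from .synthetic import SyntheticSlide

__all__ = [
    "save_synthetic_slide",
    "load_slide",
    "save_mask",
    "load_mask",
    "save_likelihood_map",
    "load_likelihood_map",
    "read_image",
]


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return np.asarray(tifffile.imread(path))
    return np.asarray(Image.open(path))


def _write_image(arr: np.ndarray, path: Path) -> None:
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def save_synthetic_slide(slide: SyntheticSlide, out_dir) -> dict:
    """Write image, annotation mask and sidecar; returns the paths used."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_path = out / f"{slide.slide_id}.png"
    _write_image(slide.image, img_path)
    paths = {"image": str(img_path)}
    mask_path = out / f"{slide.slide_id}_mask.png"
    _write_image((slide.annotation_mask * 255).astype(np.uint8), mask_path)
    paths["mask"] = str(mask_path)
    sidecar = {
        "slide_id": slide.slide_id,
        "microns_per_pixel": slide.spec.microns_per_pixel,
        "label": int(slide.slide_label),
        "lesion_diameters_mm": list(slide.planted_diameters_mm),
    }
    sc_path = out / f"{slide.slide_id}.json"
    sc_path.write_text(json.dumps(sidecar, indent=1))
    paths["sidecar"] = str(sc_path)
    return paths


def load_slide(cohort_dir, slide_id: str):
    """Read one slide back: ``(SlideImage, annotation BinaryMask | None, label)``."""
    d = Path(cohort_dir)
    sc_path = d / f"{slide_id}.json"
    if not sc_path.exists():
        raise FormatError(f"missing sidecar {sc_path}")
    meta = json.loads(sc_path.read_text())
    mpp = float(meta["microns_per_pixel"])
    img = read_image(d / f"{slide_id}.png")
    slide = SlideImage(image=img, microns_per_pixel=mpp, slide_id=slide_id)
    mask = None
    mask_path = d / f"{slide_id}_mask.png"
    if mask_path.exists():
        mask = BinaryMask(
            values=(read_image(mask_path) > 127).astype(np.uint8),
            microns_per_pixel=mpp,
            role="annotation",
        )
    return slide, mask, int(meta.get("label", 0))


def save_mask(mask: BinaryMask, path) -> None:
    _write_image((mask.values * 255).astype(np.uint8), Path(path))


def load_mask(path, microns_per_pixel: float, role: str) -> BinaryMask:
    return BinaryMask(
        values=(read_image(path) > 127).astype(np.uint8),
        microns_per_pixel=microns_per_pixel,
        role=role,
    )


def save_likelihood_map(lmap: LikelihoodMap, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, lmap.values.astype(np.float32))
    sidecar = {"slide_id": lmap.slide_id, "microns_per_pixel": lmap.microns_per_pixel}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_likelihood_map(path) -> LikelihoodMap:
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=np.float32)
    sc_path = path.with_suffix(".json")
    if not sc_path.exists():
        raise FormatError(f"missing likelihood-map sidecar {sc_path}")
    meta = json.loads(sc_path.read_text())
    return LikelihoodMap(
        values=values,
        microns_per_pixel=float(meta["microns_per_pixel"]),
        slide_id=meta.get("slide_id", path.stem),
    )
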