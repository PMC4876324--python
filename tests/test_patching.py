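"""Patch sampling, extraction, dihedral augmentation, and boosting."""

import numpy as np
import pytest

from histoscreen.errors import GeometryError, SamplingError
from histoscreen.patches import (
    BoostConfig,
    LabeledPatch,
    PatchSpec,
    augment_patch,
    boost_resample,
    extract_patch,
    sample_patch_centers,
)
from histoscreen.preprocess import BinaryMask
from histoscreen.slide import SlideImage

MPP = 8.0


def _mask(values, role):
    return BinaryMask(values=np.asarray(values, np.uint8), microns_per_pixel=MPP, role=role)


def _split_masks(n=64, patch_px=16):
    """Tissue everywhere, annotation covering the left half."""
    tissue = np.ones((n, n), np.uint8)
    ann = np.zeros((n, n), np.uint8)
    ann[:, : n // 2] = 1
    return _mask(tissue, "tissue"), _mask(ann, "annotation")


class TestSampling:
    def test_balanced_and_inside_masks(self):
        tissue, ann = _split_masks()
        spec = PatchSpec(target_mpp=MPP, patch_px=16, n_per_class=50, seed=3)
        centers = sample_patch_centers(tissue, ann, spec)
        pos = [(c, l) for c, l in centers if l == 1]
        neg = [(c, l) for c, l in centers if l == 0]
        assert len(pos) == len(neg) == 50
        ann_b = ann.astype_bool()
        assert all(ann_b[cy, cx] for (cx, cy), _ in pos)
        assert all(not ann_b[cy, cx] for (cx, cy), _ in neg)
        assert len({c for c, _ in centers}) == 100  # without replacement

    def test_impossible_request_raises(self):
        tissue, _ = _split_masks()
        empty = _mask(np.zeros((64, 64)), "annotation")
        spec = PatchSpec(target_mpp=MPP, patch_px=16, n_per_class=10, seed=0)
        with pytest.raises(SamplingError, match="class 1"):
            sample_patch_centers(tissue, empty, spec)

    def test_determinism(self):
        tissue, ann = _split_masks()
        spec = PatchSpec(target_mpp=MPP, patch_px=16, n_per_class=20, seed=9)
        assert sample_patch_centers(tissue, ann, spec) == sample_patch_centers(
            tissue, ann, spec
        )


class TestExtraction:
    def test_constant_slide_gives_constant_patch(self):
        img = np.full((64, 64, 3), 123, np.uint8)
        slide = SlideImage(image=img, microns_per_pixel=MPP)
        patch = extract_patch(slide, (32, 32), PatchSpec(target_mpp=MPP, patch_px=16))
        assert (patch == 123).all()

    def test_identity_resolution_is_bit_exact_crop(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        slide = SlideImage(image=img, microns_per_pixel=MPP)
        patch = extract_patch(slide, (20, 30), PatchSpec(target_mpp=MPP, patch_px=16))
        assert np.array_equal(patch, img[22:38, 12:28])

    def test_factor_two_matches_area_average_oracle(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, (128, 128, 3), dtype=np.uint8)
        slide = SlideImage(image=img, microns_per_pixel=MPP)
        spec = PatchSpec(target_mpp=2 * MPP, patch_px=16)
        patch = extract_patch(slide, (20, 24), spec)
        crop = img[2 * (24 - 8) : 2 * (24 + 8), 2 * (20 - 8) : 2 * (20 + 8)].astype(float)
        oracle = crop.reshape(16, 2, 16, 2, 3).mean(axis=(1, 3))
        assert np.array_equal(patch, np.clip(np.rint(oracle), 0, 255).astype(np.uint8))

    def test_out_of_bounds_center_raises(self):
        img = np.zeros((32, 32, 3), np.uint8)
        slide = SlideImage(image=img, microns_per_pixel=MPP)
        with pytest.raises(GeometryError):
            extract_patch(slide, (2, 2), PatchSpec(target_mpp=MPP, patch_px=16))


def _patch(pixels, label=1):
    return LabeledPatch(
        pixels=np.asarray(pixels, np.uint8), label=label, slide_id="s", center=(0, 0)
    )


def _dihedral_orbit(arr):
    out = []
    for k in range(4):
        rot = np.rot90(arr, k)
        out.append(rot)
        out.append(np.fliplr(rot))
    return out


class TestAugmentation:
    def test_asymmetric_patch_yields_eight_distinct_variants(self):
        rng = np.random.default_rng(2)
        patch = _patch(rng.integers(0, 256, (8, 8, 3)))
        variants = augment_patch(patch)
        assert len(variants) == 8
        assert len({v.pixels.tobytes() for v in variants}) == 8
        assert all(v.label == patch.label for v in variants)

    def test_uniform_patch_yields_identical_variants(self):
        variants = augment_patch(_patch(np.full((8, 8, 3), 7)))
        assert len(variants) == 8
        assert len({v.pixels.tobytes() for v in variants}) == 1

    def test_dihedral_closure(self):
        rng = np.random.default_rng(3)
        patch = _patch(rng.integers(0, 256, (8, 8, 3)))
        pooled = set()
        for v in augment_patch(patch):
            for w in augment_patch(v):
                pooled.add(w.pixels.tobytes())
        orbit = {np.ascontiguousarray(a).tobytes() for a in _dihedral_orbit(patch.pixels)}
        assert pooled == orbit
        assert len(pooled) <= 8

    def test_non_square_patch_rejected(self):
        with pytest.raises(GeometryError):
            augment_patch(_patch(np.zeros((8, 10, 3))))


class TestBoosting:
    def _candidates(self, n_wrong, n_right):
        """Label-0 candidates; the first ``n_wrong`` sit on map value 0.9."""
        lmap = np.zeros((1, n_wrong + n_right), dtype=np.float32)
        lmap[0, :n_wrong] = 0.9
        cands = [((x, 0), 0) for x in range(n_wrong + n_right)]
        # one class-1 candidate on a correctly classified pixel keeps the
        # two-class contract satisfied
        lmap2 = np.vstack([lmap, np.ones((1, n_wrong + n_right), np.float32)])
        cands.append(((0, 1), 1))
        return cands, lmap2

    def test_boost_share_matches_weighted_expectation(self):
        cands, lmap = self._candidates(10, 90)
        cfg = BoostConfig(n_additional_per_class=10000, boost_factor=5.0, seed=1)
        out = boost_resample(cands, lmap, cfg)
        zero_draws = [c for c, l in out if l == 0]
        share = np.mean([c[0] < 10 for c in zero_draws])
        assert share == pytest.approx(50 / 140, abs=0.02)

    def test_boost_factor_one_is_uniform(self):
        cands, lmap = self._candidates(10, 90)
        cfg = BoostConfig(n_additional_per_class=20000, boost_factor=1.0, seed=2)
        out = boost_resample(cands, lmap, cfg)
        counts = np.bincount(
            [c[0] for c, l in out if l == 0], minlength=100
        )
        expected = counts.sum() / 100
        chi2 = ((counts - expected) ** 2 / expected).sum()
        # chi-square with 99 dof: far tail bound, catches any weighting
        assert chi2 < 160

    def test_all_correct_reduces_to_uniform_weights(self):
        cands, lmap = self._candidates(0, 50)
        cfg = BoostConfig(n_additional_per_class=100, boost_factor=7.0, seed=3)
        out = boost_resample(cands, lmap, cfg)
        assert len([1 for _, l in out if l == 0]) == 100

    def test_missing_class_raises(self):
        lmap = np.zeros((1, 4), np.float32)
        cands = [((x, 0), 0) for x in range(4)]
        with pytest.raises(SamplingError):
            boost_resample(cands, lmap, BoostConfig(n_additional_per_class=5, seed=0))

    def test_boosted_centers_stay_within_candidates(self):
        cands, lmap = self._candidates(5, 20)
        cfg = BoostConfig(n_additional_per_class=200, boost_factor=5.0, seed=4)
        out = boost_resample(cands, lmap, cfg)
        assert set(out) <= set(cands)
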