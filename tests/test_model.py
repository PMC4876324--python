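"""CNN construction, early stopping, FCN equivalence, dense inference."""

import dataclasses

import numpy as np
import pytest

from histoscreen.errors import ConfigurationError, GeometryError
from histoscreen.model import (
    CNNConfig,
    build_cnn,
    infer_likelihood_map,
    simulate_early_stopping,
    to_fully_convolutional,
    train,
)
from histoscreen.pipeline import _preprocess
from histoscreen.preprocess import BinaryMask
from histoscreen.slide import SlideImage


class TestBuild:
    def test_output_is_a_probability_vector(self, tiny_cnn_config):
        net = build_cnn(tiny_cnn_config)
        x = np.random.default_rng(0).integers(0, 256, (5, 28, 28, 3), dtype=np.uint8)
        probs = net.predict_proba(x)
        assert probs.shape == (5, 2)
        assert (probs >= 0).all() and (probs <= 1).all()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_spatial_underflow_raises(self):
        with pytest.raises(ConfigurationError, match="block"):
            CNNConfig(
                conv_blocks=((8, 3, True),) * 5, fc_sizes=(16, 8, 2), input_px=16
            )

    def test_same_seed_same_outputs(self, tiny_cnn_config):
        x = np.random.default_rng(1).integers(0, 256, (3, 28, 28, 3), dtype=np.uint8)
        a = build_cnn(tiny_cnn_config).predict_proba(x)
        b = build_cnn(tiny_cnn_config).predict_proba(x)
        assert np.array_equal(a, b)


class TestEarlyStopping:
    def test_patience_five_reference_sequence(self):
        seq = [0.4, 0.3, 0.31, 0.32, 0.33, 0.34, 0.35]
        assert simulate_early_stopping(seq, patience=5) == (7, 2)

    def test_improvement_resets_patience(self):
        seq = [0.4, 0.35, 0.36, 0.30, 0.31, 0.32, 0.33, 0.34, 0.35]
        stopped, best = simulate_early_stopping(seq, patience=5)
        assert (stopped, best) == (9, 4)

    def test_runs_to_end_without_stop(self):
        stopped, best = simulate_early_stopping([0.5, 0.4, 0.3], patience=5)
        assert (stopped, best) == (3, 3)

    def test_max_epochs_one_trains_single_epoch(self, tiny_cnn_config):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 256, (16, 28, 28, 3), dtype=np.uint8)
        y = np.tile([0, 1], 8)
        cfg = dataclasses.replace(tiny_cnn_config, max_epochs=1)
        tm = train(build_cnn(cfg), (X, y), (X, y), cfg)
        assert tm.stopped_epoch == 1
        assert len(tm.history["val_error"]) == 1

    def test_returned_weights_match_best_epoch(self, trained_small_model):
        trained, _, _ = trained_small_model
        hist = trained.history["val_error"]
        assert hist[trained.best_epoch - 1] == min(hist)
        # weights restored from the best epoch: re-evaluating reproduces it
        assert trained.best_epoch <= trained.stopped_epoch


class TestFCNEquivalence:
    def test_single_position(self, tiny_cnn_config):
        net = build_cnn(tiny_cnn_config)
        dense = to_fully_convolutional(net)
        x = np.random.default_rng(3).integers(0, 256, (28, 28, 3), dtype=np.uint8)
        grid = dense.forward(x / 255.0)
        assert grid.shape == (1, 1)
        assert abs(grid[0, 0] - net.predict_proba(x[None])[0, 1]) < 1e-5

    def test_grid_against_patchwise_oracle(self, tiny_cnn_config):
        net = build_cnn(tiny_cnn_config)
        dense = to_fully_convolutional(net)
        s, p = dense.stride, dense.input_px
        x = np.random.default_rng(4).integers(0, 256, (44, 60, 3), dtype=np.uint8)
        grid = dense.forward(x / 255.0)
        for i in range(grid.shape[0]):
            for j in range(grid.shape[1]):
                patch = x[i * s : i * s + p, j * s : j * s + p]
                want = net.predict_proba(patch[None])[0, 1]
                assert abs(grid[i, j] - want) < 1e-5

    def test_default_topology_grid_size(self):
        # four conv/pool blocks give stride 16: a 160 px input yields 3x3
        net = build_cnn(CNNConfig(seed=5))
        dense = to_fully_convolutional(net)
        x = np.random.default_rng(5).random((160, 160, 3))
        assert dense.stride == 16
        assert dense.forward(x).shape == (3, 3)


class TestInference:
    def _tissue(self, h, w, mpp=8.0):
        return BinaryMask(np.ones((h, w), np.uint8), microns_per_pixel=mpp, role="tissue")

    def test_constant_model_paints_tissue_only(self, tiny_cnn_config):
        net = build_cnn(tiny_cnn_config)
        for layer in net.layers:  # zero weights -> logits 0 -> p = 0.5
            for p in layer.params():
                p[...] = 0
        dense = to_fully_convolutional(net)
        img = np.random.default_rng(6).integers(0, 256, (40, 40, 3), dtype=np.uint8)
        tissue = np.zeros((40, 40), np.uint8)
        tissue[10:30, 5:25] = 1
        mask = BinaryMask(tissue, microns_per_pixel=8.0, role="tissue")
        slide = SlideImage(image=img, microns_per_pixel=8.0)
        lmap = infer_likelihood_map(dense, slide, mask, target_mpp=8.0)
        assert np.allclose(lmap.values[tissue.astype(bool)], 0.5, atol=1e-6)
        assert (lmap.values[~tissue.astype(bool)] == 0).all()

    def test_geometry_mismatch_raises(self, tiny_cnn_config):
        dense = to_fully_convolutional(build_cnn(tiny_cnn_config))
        slide = SlideImage(np.zeros((40, 40, 3), np.uint8), microns_per_pixel=8.0)
        with pytest.raises(GeometryError):
            infer_likelihood_map(dense, slide, self._tissue(20, 20), target_mpp=8.0)

    def test_padding_with_background_is_invariant(self, tiny_cnn_config):
        net = build_cnn(tiny_cnn_config)
        dense = to_fully_convolutional(net)
        rng = np.random.default_rng(7)
        img = rng.integers(0, 256, (48, 48, 3), dtype=np.uint8)
        tissue = np.ones((48, 48), np.uint8)
        base = infer_likelihood_map(
            dense,
            SlideImage(img, microns_per_pixel=8.0),
            BinaryMask(tissue, 8.0, "tissue"),
            8.0,
        )
        pad = 2 * dense.stride  # background frame aligned with the stride grid
        big_img = np.full((48 + 2 * pad, 48 + 2 * pad, 3), 255, np.uint8)
        big_img[pad : pad + 48, pad : pad + 48] = img
        big_tissue = np.zeros((48 + 2 * pad, 48 + 2 * pad), np.uint8)
        big_tissue[pad : pad + 48, pad : pad + 48] = 1
        padded = infer_likelihood_map(
            dense,
            SlideImage(big_img, microns_per_pixel=8.0),
            BinaryMask(big_tissue, 8.0, "tissue"),
            8.0,
        )
        inner = padded.values[pad : pad + 48, pad : pad + 48]
        assert np.allclose(inner, base.values, atol=1e-6)


class TestEndToEndLearning:
    def test_validation_error_drops_below_ten_percent(self, trained_small_model):
        trained, _, _ = trained_small_model
        assert min(trained.history["val_error"]) < 0.1

    def test_lesion_region_scores_above_benign(
        self, trained_small_model, dense_small_model
    ):
        _, slides, masks = trained_small_model
        positive = next(s for s in slides if s.slide_label == 1)
        tissue, _ = masks[positive.slide_id]
        lmap = infer_likelihood_map(
            dense_small_model, positive.as_slide_image(), tissue, 8.0
        )
        lesion = positive.annotation_mask.astype(bool)
        benign = tissue.astype_bool() & ~lesion
        assert lmap.values[lesion].mean() > lmap.values[benign].mean()
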