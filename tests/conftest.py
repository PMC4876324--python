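"""Shared fixtures: small synthetic slides and a cheaply trained CNN."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from histoscreen.model import CNNConfig, build_cnn, to_fully_convolutional, train
from histoscreen.pipeline import _gather_patches, _preprocess
from histoscreen.synthetic import SlideSimSpec, generate_cohort, generate_slide

SMALL_MPP = 8.0


@pytest.fixture(scope="session")
def small_template() -> SlideSimSpec:
    """A 256 px slide at 8 um/px with one strongly separable 0.5 mm lesion."""
    return SlideSimSpec(
        width_px=256,
        height_px=256,
        microns_per_pixel=SMALL_MPP,
        n_lesions=1,
        lesion_diameters_mm=(0.5,),
        tissue_fraction=0.6,
        texture_separation=4.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_slide(small_template):
    return generate_slide(small_template)


@pytest.fixture(scope="session")
def tiny_cnn_config() -> CNNConfig:
    """A 28 px three-layer network used for fast equivalence checks."""
    return CNNConfig(
        conv_blocks=((8, 3, True), (16, 3, True)),
        fc_sizes=(32, 16, 2),
        input_px=28,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_cnn_config() -> CNNConfig:
    """A 64 px network small enough to train in seconds on a CPU."""
    return CNNConfig(
        conv_blocks=((8, 3, True), (16, 3, True), (32, 3, True)),
        fc_sizes=(64, 32, 2),
        input_px=64,
        max_epochs=15,
        batch_size=64,
        seed=0,
    )


@pytest.fixture(scope="session")
def trained_small_model(small_template, small_cnn_config):
    """A CNN trained end to end on a small synthetic cohort.

    Returns ``(TrainedModel, train_slides, masks)``; several model and
    pipeline tests share this to keep the suite fast.
    """
    slides = generate_cohort(6, 6, small_template)
    masks = {s.slide_id: _preprocess(s, SMALL_MPP) for s in slides}
    X, y = _gather_patches(slides, masks, SMALL_MPP, 64, 16, seed=5, augment=True)
    val_slides = generate_cohort(3, 3, dataclasses.replace(small_template, seed=77))
    vmasks = {s.slide_id: _preprocess(s, SMALL_MPP) for s in val_slides}
    Xv, yv = _gather_patches(val_slides, vmasks, SMALL_MPP, 64, 10, seed=6, augment=False)
    trained = train(build_cnn(small_cnn_config), (X, y), (Xv, yv), small_cnn_config)
    return trained, slides, masks


@pytest.fixture(scope="session")
def dense_small_model(trained_small_model):
    trained, _, _ = trained_small_model
    return to_fully_convolutional(trained)
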