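"""Shared fixtures: one small separable scene and a classifier trained on it.

Everything is generated programmatically and seeded; nothing is read from
disk. The trained model is session-scoped because training, while fast, is
the most expensive fixture and several detection tests reuse it.
"""

from __future__ import annotations

import numpy as np
import pytest

from hetrack import classifier as clf
from hetrack import synthetic as syn
from hetrack.config import Config

BOX = 21


@pytest.fixture(scope="session")
def small_scene() -> syn.SyntheticScene:
    return syn.SyntheticScene(width=640, height=480, n_animals=5, n_frames=30,
                              animal_radius=6.0, seed=7)


@pytest.fixture(scope="session")
def rendered(small_scene):
    """(frames, jitter-compensated ground truth) for the small scene."""
    records = syn.generate_trajectories(small_scene)
    return syn.render_video(small_scene, records)


@pytest.fixture(scope="session")
def crop_set():
    """300 balanced labelled crops from an independent training scene."""
    scene = syn.SyntheticScene(width=640, height=480, n_animals=5, n_frames=60,
                               animal_radius=6.0, seed=5)
    frames, gt = syn.render_video(scene, syn.generate_trajectories(scene))
    return syn.generate_crop_dataset(frames, gt, BOX, n_yes=150, n_no=150,
                                     min_distance=25.0, seed=5)


@pytest.fixture(scope="session")
def trained_model(crop_set):
    """Compact CNN trained to (near-)perfection on the separable crops."""
    model = clf.build_model(clf.ModelSpec(input_side=BOX), seed=0)
    train_set, val_set = clf.split_dataset(crop_set, 0.2, seed=0)
    model, report = clf.train(model, train_set, val_set, epochs=5, seed=0)
    assert report.validation_accuracy >= 0.9  # sanity for dependent tests
    return model


@pytest.fixture()
def base_config(small_scene) -> Config:
    lo, hi = small_scene.threshold_band()
    return Config(box_size=BOX, threshold_low=int(lo), threshold_high=int(hi),
                  frame_rate=30.0)
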