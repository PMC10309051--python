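"""End-to-end benchmark experiments on synthetic footage.

Two standard experiments exercise the whole pipeline under controlled,
seeded conditions:

* :func:`run_detection_benchmark` — render a 30 s, 30 fps clip of five
  animals over a heterogeneous background with camera jitter, train the
  compact CNN on crops from an independent clip, run detection on every
  frame, and score per-frame true/false-positive percentages against
  ground truth at a one-second stride.
* :func:`run_saturation_benchmark` — train on a 20% subsample of a
  balanced 4000-crop dataset and report validation accuracy on a common
  held-out split, across several training seeds.

Both derive every random stream from a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import classifier as clf
from . import detection as det
from . import evaluation as ev
from . import synthetic as syn
from .config import Config

__all__ = ["BenchmarkScene", "benchmark_scene", "benchmark_config",
           "make_training_crops", "run_detection_benchmark",
           "run_saturation_benchmark"]

#: box side (px) used for all benchmark crops: encapsulates the ~12 px
#: animals with margin and leaves a 10x10 map after the first pooling
BOX_SIZE = 21

FRAME_RATE = 30


def _subseeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(0, 2 ** 31 - 1, n)]


def benchmark_scene(seed: int, n_frames: int = 900) -> syn.SyntheticScene:
    """The scored clip: 1280x720, 5 animals, patchy background, 1 px jitter."""
    return syn.SyntheticScene(
        width=1280, height=720, n_animals=5, n_frames=n_frames,
        animal_radius=6.0, animal_intensity_range=(30.0, 80.0),
        background_intensity_range=(120.0, 230.0), background_patch_scale=80.0,
        speed=2.0, turn_sd=0.3, jitter_sd=1.0, noise_sd=3.0, seed=seed,
    )


def benchmark_config(scene: syn.SyntheticScene) -> Config:
    lo, hi = scene.threshold_band()
    return Config(box_size=BOX_SIZE, threshold_low=int(lo), threshold_high=int(hi),
                  prob_threshold=0.5, frame_rate=FRAME_RATE, seed=scene.seed)


def make_training_crops(seed: int, n_yes: int = 2000, n_no: int = 2000,
                        n_frames: int = 450) -> list:
    """Balanced crop dataset from an independent (held-out) rendered clip."""
    scene = benchmark_scene(seed, n_frames=n_frames)
    records = syn.generate_trajectories(scene)
    frames, truth = syn.render_video(scene, records)
    return syn.generate_crop_dataset(
        frames, truth, BOX_SIZE, n_yes=n_yes, n_no=n_no,
        min_distance=1.5 * BOX_SIZE, seed=seed)


@dataclass
class DetectionBenchmarkResult:
    tp_percent: float
    fp_percent: float
    fn_percent: float
    n_frames_scored: int
    validation_accuracy: float
    n_detections: int


def run_detection_benchmark(seed: int, crops: list | None = None,
                            epochs: int = 10,
                            n_frames: int = 900) -> DetectionBenchmarkResult:
    """Full-pipeline detection score on the standard synthetic clip.

    Trains on crops from a clip with a different seed than the scored clip,
    detects on every frame (streamed, constant memory), and scores TP%/FP%
    at a one-second frame stride with match radius box_size / 2.
    """
    video_seed, crop_seed, train_seed = _subseeds(seed, 3)
    if crops is None:
        crops = make_training_crops(crop_seed)
    model = clf.build_model(clf.ModelSpec(input_side=BOX_SIZE), seed=train_seed)
    train_set, val_set = clf.split_dataset(crops, 0.2, seed=train_seed)
    model, report = clf.train(model, train_set, val_set, epochs=epochs,
                              seed=train_seed)

    scene = benchmark_scene(video_seed, n_frames=n_frames)
    config = benchmark_config(scene)
    records = syn.generate_trajectories(scene)
    truth = syn.rendered_ground_truth(scene, records)
    table = det.detect_video(syn.iter_rendered_frames(scene, records),
                             model, config)
    metrics = ev.match_detections(table, truth, config.match_radius,
                                  stride=FRAME_RATE)
    return DetectionBenchmarkResult(
        tp_percent=metrics.tp_percent,
        fp_percent=metrics.fp_percent,
        fn_percent=metrics.fn_percent,
        n_frames_scored=metrics.n_frames_scored,
        validation_accuracy=report.validation_accuracy,
        n_detections=len(table),
    )


def run_saturation_benchmark(seed: int, crops: list | None = None,
                             train_fraction: float = 0.2, epochs: int = 10,
                             n_seeds: int = 3) -> list[float]:
    """Validation accuracies when training on a fraction of the data.

    The dataset is split 80/20 once; each run subsamples
    ``train_fraction`` of the training split with its own seed (which also
    seeds initialization and shuffling) and is evaluated on the common
    validation split.
    """
    crop_seed, split_seed, *run_seeds = _subseeds(seed, 2 + n_seeds)
    if crops is None:
        crops = make_training_crops(crop_seed)
    train_all, val_set = clf.split_dataset(crops, 0.2, seed=split_seed)
    accs = []
    for run_seed in run_seeds:
        rng = np.random.default_rng(run_seed)
        n = int(round(train_fraction * len(train_all)))
        pick = rng.permutation(len(train_all))[:n]
        subset = [train_all[i] for i in pick]
        model = clf.build_model(clf.ModelSpec(input_side=BOX_SIZE), seed=run_seed)
        _, report = clf.train(model, subset, val_set, epochs=epochs,
                              seed=run_seed)
        accs.append(report.validation_accuracy)
    return accs
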