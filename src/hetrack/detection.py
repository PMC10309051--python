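"""Per-frame detection: grayscale-threshold region proposal, CNN
classification of each candidate, and duplicate suppression.

Localization is deliberately biased toward recall: the threshold band
should be chosen so that every animal produces at least one candidate blob,
even at the cost of many background candidates — the classifier's job is to
reject those. Thresholding restricts classification to a handful of
candidate positions per frame instead of a sliding window over the image.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from skimage import measure

from . import io as hio
from .annotation import extract_crop
from .classifier import ClassifierModel, predict_batch
from .config import Config

__all__ = ["Keypoint", "Detection", "localize_keypoints", "classify_keypoints",
           "suppress_duplicates", "detect_video"]


class Keypoint(NamedTuple):
    """Centroid of one candidate blob (x = column, y = row, sub-pixel)."""

    x: float
    y: float
    area: int


class Detection(NamedTuple):
    """A candidate accepted by the classifier."""

    frame: int
    x: float
    y: float
    prob: float


def localize_keypoints(frame: np.ndarray, threshold_low: float,
                       threshold_high: float, min_blob_area: int = 4) -> list[Keypoint]:
    """Candidate positions: centroids of in-band connected components.

    Pixels with intensity in [threshold_low, threshold_high] form a binary
    mask; 8-connected components with area >= ``min_blob_area`` become
    keypoints at their intensity-agnostic centroids, sorted by (y, x).
    An empty list is a valid result.
    """
    if threshold_low >= threshold_high:
        raise ValueError("threshold_low must be < threshold_high")
    gray = hio.to_grayscale(frame)
    mask = (gray >= threshold_low) & (gray <= threshold_high)
    labels = measure.label(mask, connectivity=2)
    keypoints = []
    for region in measure.regionprops(labels):
        if region.area < min_blob_area:
            continue
        cy, cx = region.centroid
        keypoints.append(Keypoint(float(cx), float(cy), int(region.area)))
    keypoints.sort(key=lambda k: (k.y, k.x))
    return keypoints


def classify_keypoints(frame: np.ndarray, keypoints: Sequence[Keypoint],
                       model: ClassifierModel, box_size: int,
                       prob_threshold: float,
                       frame_index: int = 0) -> list[Detection]:
    """Crop a box around each keypoint, classify, keep confident animals.

    The reported position is the keypoint centroid itself, not the centre
    of the (possibly edge-clamped) crop.
    """
    if model.input_side != box_size:
        raise ValueError(
            f"model expects {model.input_side}px crops but box_size is {box_size}"
        )
    if not keypoints:
        return []
    gray = hio.to_grayscale(frame) if model.channels == 1 else frame
    crops = np.empty((len(keypoints), box_size, box_size, model.channels),
                     dtype=np.float32)
    for i, kp in enumerate(keypoints):
        crop, _ = extract_crop(gray, (kp.x, kp.y), box_size)
        crops[i] = crop[..., None] if crop.ndim == 2 else crop
    probs = predict_batch(model, crops)
    return [
        Detection(frame_index, kp.x, kp.y, float(p[1]))
        for kp, p in zip(keypoints, probs)
        if p[1] >= prob_threshold
    ]


def suppress_duplicates(detections: Sequence[Detection],
                        radius: float) -> list[Detection]:
    """Greedy radius-based suppression within one frame.

    Repeatedly keep the highest-probability detection (ties broken by
    smaller y then smaller x) and drop every other detection within
    ``radius`` of it; idempotent. Output is ordered by (y, x).
    """
    if not detections:
        return []
    frames = {d.frame for d in detections}
    if len(frames) > 1:
        raise ValueError(f"detections span multiple frames: {sorted(frames)}")
    pending = sorted(detections, key=lambda d: (-d.prob, d.y, d.x))
    kept: list[Detection] = []
    while pending:
        best = pending.pop(0)
        kept.append(best)
        pending = [d for d in pending
                   if np.hypot(d.x - best.x, d.y - best.y) > radius]
    kept.sort(key=lambda d: (d.y, d.x))
    return kept


def detect_video(frames: Iterable[np.ndarray], model: ClassifierModel,
                 config: Config, out_csv: str | Path | None = None,
                 verbose: bool = False) -> pd.DataFrame:
    """Run the full localize -> classify -> suppress pipeline over a video.

    Returns (and optionally writes) the detection table ``frame,x,y,prob``.
    Deterministic: identical frames + model + config give identical CSV
    bytes.
    """
    rows = []
    for f, frame in enumerate(frames):
        if frame is None:
            raise IOError(f"unreadable frame at index {f}")
        keypoints = localize_keypoints(frame, config.threshold_low,
                                       config.threshold_high,
                                       config.min_blob_area)
        detections = classify_keypoints(frame, keypoints, model,
                                        config.box_size,
                                        config.prob_threshold, f)
        detections = suppress_duplicates(detections, config.nms_radius)
        if verbose:
            print(f"frame {f}: {len(keypoints)} keypoints, "
                  f"{len(detections)} detections")
        rows += [d._asdict() for d in detections]
    table = pd.DataFrame(rows, columns=hio.DETECTION_COLUMNS)
    if out_csv is not None:
        hio.write_detections(table, out_csv)
    return table
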