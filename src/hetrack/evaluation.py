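"""Detection and tracking metrics against ground truth.

Detection scoring follows the per-frame convention used for field
validation: TP% is the percentage of ground-truth individuals correctly
detected in a frame (averaged over scored frames), FP% the number of
spurious detections expressed as a percentage of the ground-truth count in
the same frame, and FN% = 100 - TP% by construction. Frames are scored at a
configurable stride (e.g. one frame per second of video).

Track persistence uses the one-switch-allowed rule: for each true
individual the duration of its first tracker id is recorded, then of the
second id after one switch; a second switch marks the track as lost.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

import numpy as np
import pandas as pd

__all__ = ["DetectionMetrics", "TrackLengthRecord", "match_detections",
           "precision_recall_sweep", "track_length_metrics"]


@dataclass
class DetectionMetrics:
    tp_percent: float
    fp_percent: float
    fn_percent: float
    n_frames_scored: int
    match_radius: float


@dataclass
class TrackLengthRecord:
    """Persistence of tracker identity for one true individual."""

    animal_id: int
    first_id: int | None
    first_id_duration: float          # seconds
    second_id: int | None = None
    second_id_duration: float | None = None
    lost: bool = False                # True after a second id change


def _greedy_match(det_xy: np.ndarray, truth_xy: np.ndarray,
                  radius: float) -> list[tuple[int, int]]:
    """One-to-one greedy nearest matching within ``radius``.

    Candidate pairs are taken in order of (distance, detection index,
    truth index), so the result is deterministic and independent of any
    prior ordering of equal-distance pairs.
    """
    if len(det_xy) == 0 or len(truth_xy) == 0:
        return []
    d = np.linalg.norm(det_xy[:, None, :] - truth_xy[None, :, :], axis=2)
    cand = [(d[i, j], i, j)
            for i in range(len(det_xy)) for j in range(len(truth_xy))
            if d[i, j] <= radius]
    cand.sort()
    used_det: set[int] = set()
    used_truth: set[int] = set()
    pairs = []
    for _, i, j in cand:
        if i in used_det or j in used_truth:
            continue
        pairs.append((i, j))
        used_det.add(i)
        used_truth.add(j)
    return pairs


def _scored_frames(gt: pd.DataFrame, stride: int) -> list[int]:
    first, last = int(gt["frame"].min()), int(gt["frame"].max())
    return list(range(first, last + 1, stride))


def match_detections(detections: pd.DataFrame, ground_truth: pd.DataFrame,
                     match_radius: float, stride: int = 1) -> DetectionMetrics:
    """Per-frame TP/FP/FN percentages averaged over frames scored at ``stride``.

    Frames with no ground-truth individuals are skipped (their percentages
    are undefined); if every scored frame is empty an error is raised.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    det_by_frame = dict(tuple(detections.groupby("frame"))) if len(detections) else {}
    gt_by_frame = dict(tuple(ground_truth.groupby("frame"))) if len(ground_truth) else {}
    tp_rates, fp_rates = [], []
    for f in _scored_frames(ground_truth, stride) if len(ground_truth) else []:
        truth = gt_by_frame.get(f)
        if truth is None or len(truth) == 0:
            continue
        dets = det_by_frame.get(f)
        det_xy = dets[["x", "y"]].to_numpy() if dets is not None else np.zeros((0, 2))
        truth_xy = truth[["x", "y"]].to_numpy()
        matched = len(_greedy_match(det_xy, truth_xy, match_radius))
        n_truth = len(truth_xy)
        tp_rates.append(100.0 * matched / n_truth)
        fp_rates.append(100.0 * (len(det_xy) - matched) / n_truth)
    if not tp_rates:
        raise ValueError("no scored frame contains ground-truth animals")
    tp = float(np.mean(tp_rates))
    return DetectionMetrics(
        tp_percent=tp,
        fp_percent=float(np.mean(fp_rates)),
        fn_percent=100.0 - tp,
        n_frames_scored=len(tp_rates),
        match_radius=match_radius,
    )


def precision_recall_sweep(detections: pd.DataFrame, ground_truth: pd.DataFrame,
                           match_radius: float, thresholds: list[float],
                           stride: int = 1) -> pd.DataFrame:
    """Precision and recall of the detection table across probability cuts.

    Counts are aggregated over the scored frames. With zero detections
    precision is reported as 1 by convention. Returns a table with columns
    ``threshold, precision, recall``.
    """
    if not thresholds:
        raise ValueError("threshold list must be non-empty")
    if "prob" not in detections.columns:
        raise ValueError("detections must carry a 'prob' column")
    gt_by_frame = dict(tuple(ground_truth.groupby("frame"))) if len(ground_truth) else {}
    frames = _scored_frames(ground_truth, stride) if len(ground_truth) else []
    rows = []
    for thr in thresholds:
        kept = detections[detections["prob"] >= thr]
        det_by_frame = dict(tuple(kept.groupby("frame"))) if len(kept) else {}
        tp = fp = fn = 0
        for f in frames:
            truth = gt_by_frame.get(f)
            if truth is None or len(truth) == 0:
                continue
            dets = det_by_frame.get(f)
            det_xy = dets[["x", "y"]].to_numpy() if dets is not None else np.zeros((0, 2))
            truth_xy = truth[["x", "y"]].to_numpy()
            m = len(_greedy_match(det_xy, truth_xy, match_radius))
            tp += m
            fp += len(det_xy) - m
            fn += len(truth_xy) - m
        precision = tp / (tp + fp) if (tp + fp) > 0 else 1.0
        recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
        rows.append({"threshold": thr, "precision": precision, "recall": recall})
    return pd.DataFrame(rows)


def _mode(values: list[float]) -> float | None:
    if not values:
        return None
    rounded = np.round(np.asarray(values), 3)
    uniq, counts = np.unique(rounded, return_counts=True)
    return float(uniq[counts.argmax()])


def track_length_metrics(track_table: pd.DataFrame, ground_truth: pd.DataFrame,
                         match_radius: float, frame_rate: float
                         ) -> tuple[list[TrackLengthRecord], dict]:
    """Identity-persistence records per true individual, plus a summary.

    Per frame, tracker rows are matched one-to-one to true positions
    (greedy nearest within ``match_radius``). For each individual the
    tracker id at its first matched frame is followed until it changes;
    the duration in seconds of the first id, then of the second id, is
    recorded, and a second change flags the individual as lost (the
    one-switch-allowed rule). The summary reports median and mode of the
    first/second-id durations over individuals.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    trk_by_frame = dict(tuple(track_table.groupby("frame"))) if len(track_table) else {}
    gt_by_frame = dict(tuple(ground_truth.groupby("frame")))

    # per animal: ordered list of (frame, matched tracker id)
    seq: dict[int, list[tuple[int, int]]] = {
        int(a): [] for a in ground_truth["id"].unique()
    }
    for f, truth in sorted(gt_by_frame.items()):
        trk = trk_by_frame.get(f)
        if trk is None or len(trk) == 0:
            continue
        pairs = _greedy_match(trk[["x", "y"]].to_numpy(),
                              truth[["x", "y"]].to_numpy(), match_radius)
        trk_ids = trk["id"].to_numpy()
        truth_ids = truth["id"].to_numpy()
        for i, j in pairs:
            seq[int(truth_ids[j])].append((int(f), int(trk_ids[i])))

    end_frame = int(ground_truth["frame"].max()) + 1
    records = []
    for animal_id, matches in sorted(seq.items()):
        if not matches:
            records.append(TrackLengthRecord(animal_id, None, 0.0))
            continue
        first_frame, first_id = matches[0]
        change1 = next(((f, i) for f, i in matches if i != first_id), None)
        if change1 is None:
            records.append(TrackLengthRecord(
                animal_id, first_id, (end_frame - first_frame) / frame_rate))
            continue
        c1_frame, second_id = change1
        change2 = next(((f, i) for f, i in matches
                        if f >= c1_frame and i not in (first_id, second_id)), None)
        # a return to first_id after the switch also counts as a second change
        revert = next(((f, i) for f, i in matches
                       if f > c1_frame and i == first_id), None)
        if change2 is not None and revert is not None:
            change2 = min(change2, revert)
        elif change2 is None:
            change2 = revert
        second_end = change2[0] if change2 is not None else end_frame
        records.append(TrackLengthRecord(
            animal_id=animal_id,
            first_id=first_id,
            first_id_duration=(c1_frame - first_frame) / frame_rate,
            second_id=second_id,
            second_id_duration=(second_end - c1_frame) / frame_rate,
            lost=change2 is not None,
        ))

    firsts = [r.first_id_duration for r in records]
    seconds = [r.second_id_duration for r in records
               if r.second_id_duration is not None]
    summary = {
        "median_first_id_duration": float(median(firsts)) if firsts else None,
        "mode_first_id_duration": _mode(firsts),
        "median_second_id_duration": float(median(seconds)) if seconds else None,
        "mode_second_id_duration": _mode(seconds),
        "n_lost": sum(r.lost for r in records),
        "n_individuals": len(records),
    }
    return records, summary
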