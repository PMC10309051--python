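"""Track linking: constant-velocity Kalman prediction plus Hungarian
assignment of detections to tracks, with birth/death management.

Each live track carries a 4-state (x, y, vx, vy) Kalman filter observed in
position only (dt = 1 frame). Per frame, every live track is propagated one
step, predicted positions are matched to the frame's detections by
minimum-total-Euclidean-distance assignment with a hard distance gate,
matched tracks are corrected, unmatched tracks coast on their prediction
until they have missed ``max_skipped`` consecutive frames, and every
unmatched detection starts a new track. No appearance information enters
the cost, so identity switches between animals closer than about one body
length are expected behaviour.
"""

from __future__ import annotations

import colorsys
import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from . import io as hio
from .config import Config
from .detection import Detection

__all__ = ["TrackState", "kalman_init", "kalman_predict", "kalman_update",
           "build_cost_matrix", "hungarian_assign", "link_tracks",
           "render_overlay"]

# constant-velocity transition and position-only observation, dt = 1
_F = np.array([[1., 0., 1., 0.],
               [0., 1., 0., 1.],
               [0., 0., 1., 0.],
               [0., 0., 0., 1.]])
_H = np.array([[1., 0., 0., 0.],
               [0., 1., 0., 0.]])

#: discrete white-acceleration process noise for dt = 1, unit intensity
_Q_UNIT = np.array([[0.25, 0., 0.5, 0.],
                    [0., 0.25, 0., 0.5],
                    [0.5, 0., 1., 0.],
                    [0., 0.5, 0., 1.]])

_id_source = itertools.count(1)


@dataclass
class TrackState:
    """One tracked individual: Kalman state, covariance, bookkeeping."""

    id: int
    state: np.ndarray            # (x, y, vx, vy)
    covariance: np.ndarray       # 4x4 symmetric PSD
    skipped: int = 0
    history: list[tuple[int, float, float]] = field(default_factory=list)

    @property
    def position(self) -> np.ndarray:
        return self.state[:2]


def kalman_init(detection: Detection, initial_pos_var: float = 10.0,
                initial_vel_var: float = 100.0,
                track_id: int | None = None) -> TrackState:
    """Fresh track at the detection with zero velocity and diagonal covariance."""
    if initial_pos_var < 0 or initial_vel_var < 0:
        raise ValueError("initial variances must be non-negative")
    state = np.array([detection.x, detection.y, 0.0, 0.0])
    cov = np.diag([initial_pos_var, initial_pos_var,
                   initial_vel_var, initial_vel_var]).astype(float)
    return TrackState(id=track_id if track_id is not None else next(_id_source),
                      state=state, covariance=cov)


def kalman_predict(track: TrackState, process_noise_q: float = 1.0) -> TrackState:
    """One constant-velocity step: x -> Fx, P -> FPF' + qQ."""
    state = _F @ track.state
    cov = _F @ track.covariance @ _F.T + process_noise_q * _Q_UNIT
    cov = (cov + cov.T) / 2.0
    return replace(track, state=state, covariance=cov)


def kalman_update(track: TrackState, measurement: Sequence[float],
                  measurement_noise_r: float = 1.0) -> TrackState:
    """Position-only correction (Joseph-form covariance, PSD-preserving).

    With r -> 0 the posterior position equals the measurement; with
    r -> inf the measurement is ignored.
    """
    if measurement_noise_r < 0:
        raise ValueError("measurement noise must be non-negative")
    z = np.asarray(measurement, dtype=float)
    p = track.covariance
    r_mat = measurement_noise_r * np.eye(2)
    s = _H @ p @ _H.T + r_mat
    # pinv instead of solve: with exact measurements the covariance can
    # collapse to zero, making S singular with the correct gain K = 0
    k = p @ _H.T @ np.linalg.pinv(s)
    innovation = z - _H @ track.state
    state = track.state + k @ innovation
    ikh = np.eye(4) - k @ _H
    cov = ikh @ p @ ikh.T + k @ r_mat @ k.T
    cov = (cov + cov.T) / 2.0
    return replace(track, state=state, covariance=cov)


def build_cost_matrix(predicted: Sequence[Sequence[float]],
                      detections: Sequence[Sequence[float]]) -> np.ndarray:
    """Euclidean distances, tracks along rows, detections along columns."""
    if len(predicted) == 0 or len(detections) == 0:
        return np.zeros((len(predicted), len(detections)))
    return cdist(np.asarray(predicted, dtype=float),
                 np.asarray(detections, dtype=float))


def hungarian_assign(cost: np.ndarray, gate: float = np.inf
                     ) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Minimum-total-cost one-to-one assignment with a hard distance gate.

    Rectangular matrices are allowed. Any matched pair whose cost exceeds
    ``gate`` is demoted to unmatched on both sides. Among equal-cost optima
    a tiny lexicographic perturbation (low row index prefers low column
    index) makes the result deterministic.
    """
    cost = np.asarray(cost, dtype=float)
    n_rows, n_cols = cost.shape
    if n_rows == 0 or n_cols == 0:
        return [], list(range(n_rows)), list(range(n_cols))
    eps = 1e-9 * max(1.0, float(cost.max()))
    # row 0 prefers the lowest column, then row 1, ... (geometric weights)
    tie = np.outer(0.5 ** np.arange(n_rows), np.arange(n_cols))
    rows, cols = linear_sum_assignment(cost + eps * tie)
    pairs, um_rows, um_cols = [], set(range(n_rows)), set(range(n_cols))
    for r, c in zip(rows, cols):
        if cost[r, c] <= gate:
            pairs.append((int(r), int(c)))
            um_rows.discard(int(r))
            um_cols.discard(int(c))
    return pairs, sorted(um_rows), sorted(um_cols)


def link_tracks(detections: pd.DataFrame, config: Config) -> pd.DataFrame:
    """Associate a detection table into identity-labelled trajectories.

    Input must be sorted by frame. Output rows (``frame,id,x,y``) are
    emitted only for frames in which a track was matched to a detection —
    coasted (predicted-only) positions are not written, so every output row
    is backed by evidence. Tracks that die with fewer than
    ``config.min_track_length`` rows are dropped; IDs are assigned in birth
    order starting at 1 and never reused.
    """
    frames_col = detections["frame"].to_numpy()
    if len(frames_col) and np.any(np.diff(frames_col) < 0):
        raise ValueError("detection table must be sorted by frame")

    ids = itertools.count(1)
    live: list[TrackState] = []
    finished_rows: list[tuple[int, int, float, float]] = []
    rows_by_id: dict[int, list[tuple[int, int, float, float]]] = {}

    if len(detections) == 0:
        return pd.DataFrame(columns=hio.TRACK_COLUMNS)

    by_frame = dict(tuple(detections.groupby("frame")))
    first, last = int(frames_col.min()), int(frames_col.max())
    for f in range(first, last + 1):
        group = by_frame.get(f)
        dets = (group[["x", "y"]].to_numpy()
                if group is not None else np.zeros((0, 2)))

        live = [kalman_predict(t, config.process_noise_q) for t in live]
        cost = build_cost_matrix([t.position for t in live], dets)
        pairs, um_tracks, um_dets = hungarian_assign(cost, config.max_gate)

        survivors: list[TrackState] = []
        for ti, di in pairs:
            t = kalman_update(live[ti], dets[di], config.measurement_noise_r)
            t.skipped = 0
            t.history.append((f, float(dets[di][0]), float(dets[di][1])))
            rows_by_id.setdefault(t.id, []).append(
                (f, t.id, float(dets[di][0]), float(dets[di][1])))
            survivors.append(t)
        for ti in um_tracks:
            t = live[ti]
            t.skipped += 1
            if t.skipped <= config.max_skipped:
                survivors.append(t)  # coasts on its prediction
        for di in um_dets:
            d = Detection(f, float(dets[di][0]), float(dets[di][1]), 1.0)
            t = kalman_init(d, config.initial_pos_var,
                            config.initial_vel_var, track_id=next(ids))
            t.history.append((f, d.x, d.y))
            rows_by_id.setdefault(t.id, []).append((f, t.id, d.x, d.y))
            survivors.append(t)
        live = survivors

    for tid, rows in rows_by_id.items():
        if len(rows) >= config.min_track_length:
            finished_rows += rows
    finished_rows.sort(key=lambda r: (r[0], r[1]))
    return pd.DataFrame(finished_rows, columns=hio.TRACK_COLUMNS)


def id_color(track_id: int) -> tuple[int, int, int]:
    """Deterministic saturated RGB colour for a track id (golden-angle hue)."""
    hue = (track_id * 0.61803398875) % 1.0
    r, g, b = colorsys.hsv_to_rgb(hue, 0.9, 1.0)
    return int(r * 255), int(g * 255), int(b * 255)


def render_overlay(frames: Iterable[np.ndarray], track_table: pd.DataFrame,
                   box_size: int) -> list[np.ndarray]:
    """Draw an id-labelled box of side ``box_size`` on each tracked animal.

    Box colour is a deterministic function of the id, so an individual
    keeps its colour across frames. Returns RGB frames.
    """
    from PIL import Image, ImageDraw

    frames = list(frames)
    if len(track_table) and int(track_table["frame"].max()) >= len(frames):
        raise ValueError("track table refers to frames beyond the video")
    by_frame = dict(tuple(track_table.groupby("frame"))) if len(track_table) else {}
    half = box_size // 2
    out = []
    for f, frame in enumerate(frames):
        arr = np.asarray(frame)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        img = Image.fromarray(arr.astype(np.uint8))
        draw = ImageDraw.Draw(img)
        group = by_frame.get(f)
        if group is not None:
            for _, row in group.iterrows():
                x, y, tid = row["x"], row["y"], int(row["id"])
                color = id_color(tid)
                draw.rectangle([x - half, y - half, x + half, y + half],
                               outline=color, width=1)
                draw.text((x - half, y - half - 10), str(tid), fill=color)
        out.append(np.asarray(img))
    return out
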