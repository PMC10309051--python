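"""Seeded synthetic aerial footage: blob-like animals moving over patchy
heterogeneous backgrounds, with exact per-frame ground truth.

The generator emulates the conditions that make field footage hard for
classical segmentation — spatially correlated background clutter, camera
jitter, pixel noise — while keeping ground truth exact, so the detection,
classification and tracking stages can all be scored without real videos.
Animals are rendered as anti-aliased disks: that preserves the classifier's
job (discriminating patch intensity/texture) while keeping true positions
unambiguous.

Every operation is deterministic given ``scene.seed``; independent
sub-streams per operation mean e.g. trajectories do not change when only
the rendering options change.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize

from .annotation import LabelledCrop, extract_crop, save_crop
from . import io as hio

__all__ = [
    "SyntheticScene",
    "generate_background",
    "generate_trajectories",
    "generate_separated_trajectories",
    "render_video",
    "iter_rendered_frames",
    "rendered_ground_truth",
    "generate_crop_dataset",
]

# rng sub-stream tags so each operation has an independent, stable stream
_BG, _TRAJ, _RENDER, _NOISE = 1, 2, 3, 4


@dataclass
class SyntheticScene:
    """Parameters of one synthetic recording.

    Defaults describe a 1280-wide aerial view: animals ~12 px across
    (a ~35 px body at 4K scaled to this width), dark animals on a brighter
    patchy background with a comfortable intensity gap so a valid grayscale
    threshold band exists (``separable``).
    """

    width: int = 640
    height: int = 480
    n_animals: int = 5
    n_frames: int = 100
    animal_radius: float = 6.0
    animal_intensity_range: tuple[float, float] = (30.0, 80.0)
    background_intensity_range: tuple[float, float] = (120.0, 230.0)
    background_patch_scale: float = 40.0
    speed: float = 2.0
    turn_sd: float = 0.3
    jitter_sd: float = 0.0
    noise_sd: float = 3.0
    separable: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.n_frames <= 0:
            raise ValueError("scene dimensions and frame count must be positive")
        if self.n_animals < 0:
            raise ValueError("n_animals must be >= 0")
        if self.background_patch_scale <= 0 or self.animal_radius <= 0:
            raise ValueError("patch scale and animal radius must be positive")
        a_lo, a_hi = self.animal_intensity_range
        b_lo, b_hi = self.background_intensity_range
        if a_lo > a_hi or b_lo > b_hi:
            raise ValueError("intensity ranges must be (low, high)")
        if self.separable and not (a_hi < b_lo or b_hi < a_lo):
            raise ValueError(
                "separable scene requires disjoint animal/background "
                f"intensity ranges, got {self.animal_intensity_range} vs "
                f"{self.background_intensity_range}"
            )

    def threshold_band(self, noise_margin: float = 4.0) -> tuple[float, float]:
        """A grayscale band containing animal pixels and no background.

        Widens the animal intensity range by ``noise_margin`` standard
        deviations of the pixel noise, clipped so it still excludes the
        background range (only defined for separable scenes).
        """
        if not self.separable:
            raise ValueError("threshold band is only defined for separable scenes")
        a_lo, a_hi = self.animal_intensity_range
        b_lo, b_hi = self.background_intensity_range
        pad = noise_margin * self.noise_sd
        if a_hi < b_lo:  # dark animals on light background
            return max(0.0, a_lo - pad), min(a_hi + pad, (a_hi + b_lo) / 2)
        return max(a_lo - pad, (b_hi + a_lo) / 2), min(255.0, a_hi + pad)


def _rng(scene: SyntheticScene, *tags: int) -> np.random.Generator:
    return np.random.default_rng([scene.seed, *tags])


def generate_background(scene: SyntheticScene) -> np.ndarray:
    """Patchy background: coarse value noise linearly upsampled to frame size.

    A grid of independent uniform intensities at spacing
    ``background_patch_scale`` is bilinearly interpolated up to the frame,
    so the image is spatially correlated at the patch scale and every pixel
    stays inside ``background_intensity_range`` (linear interpolation cannot
    overshoot). A patch scale at or beyond the frame size degenerates to a
    constant image.
    """
    rng = _rng(scene, _BG)
    lo, hi = scene.background_intensity_range
    gh = max(1, int(np.ceil(scene.height / scene.background_patch_scale)))
    gw = max(1, int(np.ceil(scene.width / scene.background_patch_scale)))
    grid = rng.uniform(lo, hi, size=(gh, gw))
    if gh == 1 and gw == 1:
        return np.full((scene.height, scene.width), grid[0, 0])
    return resize(grid, (scene.height, scene.width), order=1,
                  anti_aliasing=False, preserve_range=True)


def _walk(rng: np.random.Generator, n_frames: int, speed: float, turn_sd: float,
          bounds: tuple[float, float, float, float],
          start: tuple[float, float] | None = None,
          heading: float | None = None) -> np.ndarray:
    """Correlated random walk with reflecting borders inside ``bounds``.

    bounds = (xmin, xmax, ymin, ymax). Step length is exactly ``speed``
    every frame; the heading is perturbed by Normal(0, turn_sd) per frame.
    """
    xmin, xmax, ymin, ymax = bounds
    if start is None:
        start = (rng.uniform(xmin, xmax), rng.uniform(ymin, ymax))
    if heading is None:
        heading = rng.uniform(0.0, 2.0 * np.pi)
    pos = np.empty((n_frames, 2))
    x, y = start
    pos[0] = (x, y)
    for t in range(1, n_frames):
        heading += rng.normal(0.0, turn_sd) if turn_sd > 0 else 0.0
        x += speed * np.cos(heading)
        y += speed * np.sin(heading)
        # reflect at borders (repeat in case a step crosses twice)
        for _ in range(4):
            if x < xmin:
                x = 2 * xmin - x
                heading = np.pi - heading
            elif x > xmax:
                x = 2 * xmax - x
                heading = np.pi - heading
            elif y < ymin:
                y = 2 * ymin - y
                heading = -heading
            elif y > ymax:
                y = 2 * ymax - y
                heading = -heading
            else:
                break
        pos[t] = (x, y)
    return pos


def _records_frame(trajectories: list[np.ndarray], n_frames: int) -> pd.DataFrame:
    rows = {
        "frame": np.repeat(np.arange(n_frames), len(trajectories)),
        "id": np.tile(np.arange(len(trajectories)), n_frames),
        "x": np.stack([t[:, 0] for t in trajectories], axis=1).ravel()
        if trajectories else np.array([]),
        "y": np.stack([t[:, 1] for t in trajectories], axis=1).ravel()
        if trajectories else np.array([]),
    }
    if not trajectories:
        return pd.DataFrame(columns=["frame", "id", "x", "y"])
    return pd.DataFrame(rows)


def generate_trajectories(
    scene: SyntheticScene,
    start_positions: Sequence[tuple[float, float]] | None = None,
    start_headings: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Correlated random walks for every animal, reflected at frame borders.

    Returns a ground-truth table ``frame,id,x,y`` (one row per animal per
    frame, sub-pixel positions, origin at the top-left, x = column).
    Optional fixed starts/headings make degenerate cases (straight lines,
    stationary animals) exactly reproducible.
    """
    rng = _rng(scene, _TRAJ)
    margin = scene.animal_radius
    bounds = (margin, scene.width - 1 - margin, margin, scene.height - 1 - margin)
    trajectories = []
    for a in range(scene.n_animals):
        start = tuple(start_positions[a]) if start_positions is not None else None
        heading = start_headings[a] if start_headings is not None else None
        trajectories.append(_walk(rng, scene.n_frames, scene.speed,
                                  scene.turn_sd, bounds, start, heading))
    return _records_frame(trajectories, scene.n_frames)


def generate_separated_trajectories(scene: SyntheticScene,
                                    min_gap: float) -> pd.DataFrame:
    """Like :func:`generate_trajectories` but with guaranteed separation.

    The frame is tiled into one cell per animal and each walk is confined
    to its cell shrunk by ``min_gap / 2`` on every side, so any two animals
    are always at least ``min_gap`` apart — the regime in which track
    linking is expected to be exact (the method does not resolve
    individuals closer than about one body length).
    """
    rng = _rng(scene, _TRAJ)
    n = scene.n_animals
    if n == 0:
        return _records_frame([], scene.n_frames)
    ncols = int(np.ceil(np.sqrt(n * scene.width / scene.height)))
    nrows = int(np.ceil(n / ncols))
    cw, ch = scene.width / ncols, scene.height / nrows
    pad = min_gap / 2 + scene.animal_radius
    trajectories = []
    for a in range(n):
        r, c = divmod(a, ncols)
        bounds = (c * cw + pad, (c + 1) * cw - 1 - pad,
                  r * ch + pad, (r + 1) * ch - 1 - pad)
        if bounds[0] >= bounds[1] or bounds[2] >= bounds[3]:
            raise ValueError(
                f"cannot fit {n} animals with min_gap {min_gap} in a "
                f"{scene.width}x{scene.height} frame"
            )
        trajectories.append(_walk(rng, scene.n_frames, scene.speed,
                                  scene.turn_sd, bounds))
    return _records_frame(trajectories, scene.n_frames)


def _render_setup(scene: SyntheticScene,
                  records: pd.DataFrame) -> tuple[dict[int, float], np.ndarray]:
    """Per-animal intensities (drawn once) and the per-frame jitter sequence."""
    rng = _rng(scene, _RENDER)
    lo, hi = scene.animal_intensity_range
    ids = sorted(records["id"].unique()) if len(records) else []
    intensities = {int(i): float(rng.uniform(lo, hi)) for i in ids}
    jitter = rng.normal(0.0, scene.jitter_sd, size=(scene.n_frames, 2)) \
        if scene.jitter_sd > 0 else np.zeros((scene.n_frames, 2))
    return intensities, jitter


def _draw_disk(canvas: np.ndarray, x: float, y: float, radius: float,
               intensity: float) -> None:
    """Alpha-blend an anti-aliased disk onto the canvas in place."""
    h, w = canvas.shape
    x0, x1 = int(np.floor(x - radius - 1)), int(np.ceil(x + radius + 1)) + 1
    y0, y1 = int(np.floor(y - radius - 1)), int(np.ceil(y + radius + 1)) + 1
    x0, x1 = max(0, x0), min(w, x1)
    y0, y1 = max(0, y0), min(h, y1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - x, yy - y)
    alpha = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    canvas[y0:y1, x0:x1] = canvas[y0:y1, x0:x1] * (1 - alpha) + intensity * alpha


def rendered_ground_truth(scene: SyntheticScene,
                          records: pd.DataFrame) -> pd.DataFrame:
    """Ground truth as it appears in the rendered frames.

    Camera jitter shifts the whole frame, so the emitted positions are the
    jittered ones (metrics then score the pipeline, not the simulator).
    Positions pushed outside the frame are clamped and flagged.
    """
    _, jitter = _render_setup(scene, records)
    out = records.copy()
    f = out["frame"].to_numpy(dtype=int)
    out["x"] = out["x"].to_numpy() + jitter[f, 0]
    out["y"] = out["y"].to_numpy() + jitter[f, 1]
    cx = out["x"].clip(0, scene.width - 1)
    cy = out["y"].clip(0, scene.height - 1)
    out["clamped"] = ((cx != out["x"]) | (cy != out["y"])).astype(int)
    out["x"], out["y"] = cx, cy
    return out


def iter_rendered_frames(scene: SyntheticScene,
                         records: pd.DataFrame) -> Iterator[np.ndarray]:
    """Yield rendered uint8 grayscale frames one at a time (constant memory).

    frame = jittered background + anti-aliased animal disks at their
    jittered positions + Gaussian pixel noise, clipped to [0, 255]. Noise
    uses a per-frame sub-stream, so any frame can be regenerated
    independently and bit-identically.
    """
    background = generate_background(scene)
    intensities, jitter = _render_setup(scene, records)
    by_frame = dict(tuple(records.groupby("frame"))) if len(records) else {}
    for f in range(scene.n_frames):
        dx, dy = jitter[f]
        if dx != 0.0 or dy != 0.0:
            canvas = ndimage.shift(background, (dy, dx), order=1, mode="nearest")
        else:
            canvas = background.copy()
        group = by_frame.get(f)
        if group is not None:
            for _, row in group.iterrows():
                _draw_disk(canvas, row["x"] + dx, row["y"] + dy,
                           scene.animal_radius, intensities[int(row["id"])])
        if scene.noise_sd > 0:
            noise_rng = np.random.default_rng([scene.seed, _NOISE, f])
            canvas = canvas + noise_rng.normal(0.0, scene.noise_sd, canvas.shape)
        yield np.clip(np.round(canvas), 0, 255).astype(np.uint8)


def render_video(
    scene: SyntheticScene,
    records: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Render all frames plus the jitter-compensated ground-truth table.

    When ``out_dir`` is given the frames are also written as a zero-padded
    PNG sequence with the ground truth alongside as ``ground_truth.csv``.
    """
    if records is None:
        records = generate_trajectories(scene)
    frames = list(iter_rendered_frames(scene, records))
    truth = rendered_ground_truth(scene, records)
    if out_dir is not None:
        out = Path(out_dir)
        hio.write_frames(frames, out)
        hio.write_ground_truth(truth, out / "ground_truth.csv")
    return frames, truth


def generate_crop_dataset(
    frames: Sequence[np.ndarray],
    ground_truth: pd.DataFrame,
    box_size: int,
    n_yes: int,
    n_no: int,
    min_distance: float,
    seed: int,
    out_dir: str | Path | None = None,
    max_tries_per_crop: int = 200,
) -> list[LabelledCrop]:
    """Build a balanced labelled crop set from rendered frames + ground truth.

    "yes" crops are centred on sampled ground-truth positions; "no" crops
    are centred at uniform positions at least ``min_distance`` from every
    animal in their frame. Placement failure after bounded retries reports
    how many background crops were achievable.
    """
    rng = np.random.default_rng(seed)
    frames = list(frames)
    n_available = len(ground_truth)
    if n_yes > n_available:
        raise ValueError(
            f"requested {n_yes} animal crops but only {n_available} "
            "ground-truth instances are available"
        )
    h, w = frames[0].shape[:2]
    crops: list[LabelledCrop] = []

    pick = rng.permutation(n_available)[:n_yes]
    for idx in pick:
        row = ground_truth.iloc[int(idx)]
        f = int(row["frame"])
        pixels, center = extract_crop(frames[f], (row["x"], row["y"]), box_size)
        crops.append(LabelledCrop(pixels, "yes", f, center))

    by_frame = dict(tuple(ground_truth.groupby("frame"))) if len(ground_truth) else {}
    placed = 0
    tries = 0
    budget = max_tries_per_crop * max(1, n_no)
    while placed < n_no and tries < budget:
        tries += 1
        f = int(rng.integers(0, len(frames)))
        x = rng.uniform(0, w - 1)
        y = rng.uniform(0, h - 1)
        group = by_frame.get(f)
        if group is not None and len(group):
            d = np.hypot(group["x"].to_numpy() - x, group["y"].to_numpy() - y)
            if d.min() < min_distance:
                continue
        pixels, center = extract_crop(frames[f], (x, y), box_size)
        crops.append(LabelledCrop(pixels, "no", f, center))
        placed += 1
    if placed < n_no:
        raise RuntimeError(
            f"could only place {placed} of {n_no} background crops at "
            f"min_distance {min_distance} after {tries} tries"
        )
    if out_dir is not None:
        for crop in crops:
            save_crop(crop, out_dir)
    return crops
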