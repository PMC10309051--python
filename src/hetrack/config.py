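"""Pipeline configuration: one object carries every tunable parameter.

All stages (annotation, training, detection, tracking, evaluation) read
their parameters from a single :class:`Config` that round-trips to a flat
YAML file, so a run is fully described by one file plus the input video.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """A configuration field violates its documented constraint."""


def _normalize_box_size(box_size: int) -> int:
    """Round ``box_size`` up to the next odd integer (minimum 3).

    Crops and bounding boxes are squares with an exact centre pixel, so the
    side must be odd; detections are reported at crop centres.
    """
    box = int(box_size)
    if box < 3:
        raise ConfigError(f"box_size must be >= 3, got {box}")
    return box if box % 2 == 1 else box + 1


@dataclass
class Config:
    """All user-tunable parameters of the detection/tracking pipeline.

    Parameters
    ----------
    box_size
        Side (pixels) of the square crop / bounding box; normalized to the
        next odd integer so each crop has a centre pixel. Choose it large
        enough to encapsulate the biggest animal.
    threshold_low, threshold_high
        Grayscale band [low, high] in [0, 255] used for region proposal:
        pixels inside the band are candidate animal pixels. Two-sided so
        both dark-on-light and light-on-dark animals work.
    min_blob_area
        Minimum connected-component area (px^2) kept as a candidate.
    prob_threshold
        Classifier probability above which a candidate is accepted.
    nms_radius
        Duplicate-suppression radius (px); defaults to box_size / 2.
    max_gate
        Assignment gating distance (px); defaults to 2 * box_size.
    max_skipped
        Consecutive missed frames after which a track is terminated.
    min_track_length
        Tracks with fewer emitted rows are discarded as spurious.
    frame_rate
        Video frame rate (frames/second), used to convert track durations
        to seconds.
    """

    box_size: int = 21
    threshold_low: int = 0
    threshold_high: int = 100
    min_blob_area: int = 4
    prob_threshold: float = 0.5
    nms_radius: float | None = None
    max_gate: float | None = None
    max_skipped: int = 10
    min_track_length: int = 3
    frame_rate: float = 30.0
    seed: int = 0

    # classifier training
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    val_fraction: float = 0.2
    grayscale: bool = True

    # Kalman filter noise (process / measurement) and initial variances
    process_noise_q: float = 1.0
    measurement_noise_r: float = 1.0
    initial_pos_var: float = 10.0
    initial_vel_var: float = 100.0

    # paths (optional; CLI fills them from flags when absent)
    video_path: str = ""
    dataset_root: str = ""
    model_path: str = ""
    output_dir: str = ""

    def __post_init__(self) -> None:
        self.box_size = _normalize_box_size(self.box_size)
        if not (0 <= self.threshold_low < self.threshold_high <= 255):
            raise ConfigError(
                "threshold band must satisfy 0 <= threshold_low < "
                f"threshold_high <= 255, got [{self.threshold_low}, "
                f"{self.threshold_high}]"
            )
        if not (0.0 <= self.prob_threshold <= 1.0):
            raise ConfigError(
                f"prob_threshold must be in [0, 1], got {self.prob_threshold}"
            )
        if self.max_skipped < 0:
            raise ConfigError(f"max_skipped must be >= 0, got {self.max_skipped}")
        if self.frame_rate <= 0:
            raise ConfigError(f"frame_rate must be > 0, got {self.frame_rate}")
        if self.min_blob_area < 1:
            raise ConfigError(f"min_blob_area must be >= 1, got {self.min_blob_area}")
        if self.nms_radius is None:
            self.nms_radius = self.box_size / 2
        if self.max_gate is None:
            self.max_gate = 2.0 * self.box_size

    @property
    def match_radius(self) -> float:
        """Spatial tolerance for scoring a detection against ground truth."""
        return self.box_size / 2


def load_config(path: str | Path) -> Config:
    """Load and validate a :class:`Config` from a flat YAML mapping.

    Missing keys take their documented defaults; unknown keys raise
    :class:`ConfigError` so typos do not silently fall back to defaults.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file must be a flat mapping: {path}")
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return Config(**raw)


def save_config(config: Config, path: str | Path) -> Path:
    """Write ``config`` as YAML such that :func:`load_config` inverts it."""
    path = Path(path)
    data = dataclasses.asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path
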