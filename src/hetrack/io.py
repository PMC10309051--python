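"""Frame and table I/O: PNG frame sequences, detection/track/ground-truth CSVs.

A "video" is a directory of zero-padded PNG frames (or an in-memory list of
arrays); compressed container formats are not read or written.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

#: ITU-R BT.709-style luminance weights used by scikit-image's rgb2gray.
_LUMA = np.array([0.2125, 0.7154, 0.0721])

DETECTION_COLUMNS = ["frame", "x", "y", "prob"]
TRACK_COLUMNS = ["frame", "id", "x", "y"]
GROUND_TRUTH_COLUMNS = ["frame", "id", "x", "y"]


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) frame to single-channel luminance in [0, 255]."""
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        return frame[..., :3].astype(np.float64) @ _LUMA
    raise ValueError(f"unsupported frame shape {frame.shape}")


def read_frames(source: str | Path | Sequence[np.ndarray]) -> list[np.ndarray]:
    """Load frames from a directory of PNGs (sorted by name) or pass arrays through."""
    if not isinstance(source, (str, Path)):
        return list(source)
    path = Path(source)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise IOError(f"no PNG frames found in {path}")
        return [iio.imread(f) for f in files]
    if path.is_file():
        return [iio.imread(path)]
    raise IOError(f"frame source not found: {path}")


def write_frames(frames: Iterable[np.ndarray], out_dir: str | Path,
                 prefix: str = "frame") -> list[Path]:
    """Write frames as ``<prefix>_000000.png`` ... under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out / f"{prefix}_{i:06d}.png"
        iio.imwrite(p, np.asarray(frame))
        paths.append(p)
    return paths


def _write_table(df: pd.DataFrame, path: str | Path, columns: list[str]) -> Path:
    path = Path(path)
    df = df[columns] if not df.empty else pd.DataFrame(columns=columns)
    with open(path, "w", newline="\n") as fh:
        df.to_csv(fh, index=False, float_format="%.6f", lineterminator="\n")
    return path


def write_detections(df: pd.DataFrame, path: str | Path) -> Path:
    """Detection table CSV: ``frame,x,y,prob`` with fixed float formatting."""
    return _write_table(df, path, DETECTION_COLUMNS)


def read_detections(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detection CSV missing columns {sorted(missing)}")
    return df


def write_tracks(df: pd.DataFrame, path: str | Path) -> Path:
    """Track table CSV: ``frame,id,x,y``."""
    return _write_table(df, path, TRACK_COLUMNS)


def read_tracks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns {sorted(missing)}")
    return df


def write_ground_truth(df: pd.DataFrame, path: str | Path) -> Path:
    cols = GROUND_TRUTH_COLUMNS + (["clamped"] if "clamped" in df.columns else [])
    return _write_table(df, path, cols)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(GROUND_TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ground-truth CSV missing columns {sorted(missing)}")
    return df
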