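"""Training-data extraction: fixed-size crops labelled animal ("yes") or
background ("no"), stored as PNGs under two category folders.

Classification is strictly two-category; crops are squares of the configured
box size so every crop has an exact centre pixel. Crops whose box would cross
a frame edge are clamped inward (not padded), so training crops and
detection-time crops come from the same distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

LABELS = ("yes", "no")


@dataclass
class LabelledCrop:
    """A box_size x box_size patch with its binary label and provenance."""

    pixels: np.ndarray
    label: str          # "yes" = animal, "no" = background
    frame_index: int = 0
    center: tuple[int, int] = (0, 0)  # effective (x, y) after clamping

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        h, w = self.pixels.shape[:2]
        if h != w:
            raise ValueError(f"crop must be square, got {self.pixels.shape}")


def sample_frames(frames: Sequence[np.ndarray], stride: int) -> list[np.ndarray]:
    """Every ``stride``-th frame starting at index 0 (ceil(n/stride) frames)."""
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    return list(frames[::stride])


def extract_crop(frame: np.ndarray, center: tuple[float, float],
                 box_size: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Cut a ``box_size`` square around ``center`` = (x, y).

    The centre is rounded to the nearest pixel and clamped inward so the
    crop always lies fully inside the frame; the effective centre actually
    used is returned alongside the pixels.
    """
    if box_size % 2 != 1:
        raise ValueError(f"box_size must be odd, got {box_size}")
    h, w = frame.shape[:2]
    if h < box_size or w < box_size:
        raise ValueError(
            f"frame {w}x{h} smaller than box_size {box_size}"
        )
    half = box_size // 2
    cx = int(np.clip(round(float(center[0])), half, w - 1 - half))
    cy = int(np.clip(round(float(center[1])), half, h - 1 - half))
    crop = frame[cy - half:cy + half + 1, cx - half:cx + half + 1].copy()
    return crop, (cx, cy)


def save_crop(crop: LabelledCrop, dataset_root: str | Path) -> Path:
    """Write the crop as a lossless PNG under ``<root>/<label>/``.

    Filenames encode provenance; an integer suffix keeps repeated saves of
    the same frame/centre collision-free.
    """
    root = Path(dataset_root) / crop.label
    root.mkdir(parents=True, exist_ok=True)
    stem = f"f{crop.frame_index:06d}_x{crop.center[0]}_y{crop.center[1]}"
    path = root / f"{stem}.png"
    k = 1
    while path.exists():
        path = root / f"{stem}_{k}.png"
        k += 1
    pixels = crop.pixels
    if pixels.dtype != np.uint8:
        pixels = np.clip(np.round(pixels), 0, 255).astype(np.uint8)
    iio.imwrite(path, pixels)
    return path


def load_crop_dataset(dataset_root: str | Path) -> list[LabelledCrop]:
    """Read back a ``yes/``+``no/`` folder pair (sorted, deterministic order)."""
    root = Path(dataset_root)
    crops = []
    for label in LABELS:
        folder = root / label
        if not folder.is_dir():
            continue
        for path in sorted(folder.glob("*.png")):
            crops.append(LabelledCrop(pixels=iio.imread(path), label=label))
    if not crops:
        raise IOError(f"no crops found under {root}")
    return crops
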