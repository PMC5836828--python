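"""Image I/O and coordinate conventions.

A *GrayImage* is a 2-D float64 numpy array of intensities on the 0-255
scale (fractional values appear after smoothing); a *LabelMask* is a 2-D
integer array with 0 = background and labels 1..n for objects.  Coordinates
are 0-based (row, col); bounding boxes are half-open on their max edges;
the "x" axis of all comet formulas is the column index.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

LUMINANCE_WEIGHTS = np.array([0.299, 0.587, 0.114])

_CHANNEL_INDEX = {"r": 0, "g": 1, "b": 2}


def load_image(path: str | Path, channel: str = "luminance") -> np.ndarray:
    """Load an 8-bit PNG/TIFF micrograph as a float64 grayscale image.

    RGB input is reduced either by standard luminance weighting
    (0.299R + 0.587G + 0.114B) or, since fluorescence images are
    effectively monochrome, by selecting a single channel
    (``channel`` in ``{"r","g","b"}``).
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - decoder errors vary by plugin
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype not in (np.uint8, np.int16, np.uint16):
        raise ValueError(f"unsupported bit depth {arr.dtype} in {path}; expected 8-bit")
    if arr.dtype != np.uint8:
        # 16-bit grayscale label masks are legal to write but not analysis input
        raise ValueError(f"unsupported bit depth {arr.dtype} in {path}; expected 8-bit")
    if arr.ndim == 2:
        return arr.astype(np.float64)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        if channel == "luminance":
            return rgb @ LUMINANCE_WEIGHTS
        if channel in _CHANNEL_INDEX:
            return rgb[..., _CHANNEL_INDEX[channel]]
        raise ValueError(f"unknown channel selector: {channel!r}")
    raise ValueError(f"unsupported image layout {arr.shape} in {path}")


def save_image(img: np.ndarray, path: str | Path) -> None:
    """Write a grayscale image as 8-bit PNG (values clipped to [0, 255])."""
    arr = np.clip(np.asarray(img, dtype=np.float64), 0, 255)
    iio.imwrite(Path(path), np.round(arr).astype(np.uint8))


def save_label_mask(labels: np.ndarray, path: str | Path) -> None:
    """Write a label mask as 16-bit PNG (supports up to 65535 objects)."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels out of 16-bit range")
    iio.imwrite(Path(path), labels.astype(np.uint16))


def load_label_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"label mask must be single-channel: {path}")
    return arr.astype(np.int32)


def bbox_of(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Half-open bounding box (row_min, col_min, row_max, col_max) of a
    boolean mask."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty mask has no bounding box")
    return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1


def crop_comet(img: np.ndarray, labels: np.ndarray, comet_id: int) -> np.ndarray:
    """Bounding-box crop of one comet with non-member pixels zeroed."""
    member = labels == comet_id
    if not member.any():
        raise KeyError(f"label {comet_id} not present in mask")
    r0, c0, r1, c1 = bbox_of(member)
    crop = np.where(member[r0:r1, c0:c1], img[r0:r1, c0:c1], 0.0)
    return crop.astype(np.float64)
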