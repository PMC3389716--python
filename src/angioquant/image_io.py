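"""Reading and writing grayscale images, binary masks and metric tables.

Grayscale images are returned as 2-D float64 arrays normalized to [0, 1] by
the format's full-scale value (255 for 8-bit, 65535 for 16-bit), so that
intensity thresholds are comparable across images.  Masks are 2-D boolean
arrays saved as 8-bit PNG/TIFF with foreground = 255; the write/read
round-trip is lossless.
"""

from __future__ import annotations

import os
import warnings

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "load_gray",
    "load_mask",
    "save_gray",
    "save_mask",
    "save_metrics_csv",
]

_FULL_SCALE = {
    np.dtype(np.uint8): 255.0,
    np.dtype(np.int16): 32767.0,
    np.dtype(np.uint16): 65535.0,
    np.dtype(np.uint32): 4294967295.0,
}


def _collapse_channels(arr: np.ndarray) -> np.ndarray:
    """Collapse a multi-channel raster to a single channel by averaging.

    Angiography projections are inherently single-channel; color inputs are
    display artifacts, so a plain channel average suffices.  An alpha channel
    (4th channel) is dropped before averaging.
    """
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (2, 3, 4):
        if arr.shape[2] in (2, 4):  # gray+alpha or RGBA: drop alpha
            arr = arr[..., :-1]
        return arr.mean(axis=2)
    raise ValueError(f"cannot interpret raster of shape {arr.shape} as a 2-D image")


def load_gray(path: str | os.PathLike) -> np.ndarray:
    """Load a raster image as a float64 grayscale array in [0, 1].

    Integer images are divided by the dtype's full-scale value (255, 65535);
    float images are assumed to already be on [0, 1] and are validated.
    Multi-channel inputs are collapsed by channel averaging.

    Raises
    ------
    ValueError
        If the image has zero size or float values outside [0, 1].
    """
    arr = np.asarray(iio.imread(path))
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path}")
    dtype = arr.dtype  # full-scale determined before channel collapse
    arr = _collapse_channels(arr)
    if dtype in _FULL_SCALE:
        out = arr.astype(np.float64) / _FULL_SCALE[dtype]
    elif np.issubdtype(dtype, np.floating):
        out = arr.astype(np.float64)
        if out.min() < 0 or out.max() > 1:
            raise ValueError("float image values must lie in [0, 1]")
    elif np.issubdtype(dtype, np.bool_):
        out = arr.astype(np.float64)
    else:
        raise ValueError(f"unsupported image dtype {dtype}")
    return np.clip(out, 0.0, 1.0)


def load_mask(path: str | os.PathLike, threshold: float | None = None) -> np.ndarray:
    """Load a binary mask; foreground is the larger of the two pixel values.

    The raster must contain at most two distinct values; otherwise a
    normalized-intensity ``threshold`` must be supplied, and pixels strictly
    above it become foreground.
    """
    arr = np.asarray(iio.imread(path))
    if arr.size == 0:
        raise ValueError(f"zero-size mask: {path}")
    arr = _collapse_channels(arr)
    values = np.unique(arr)
    if values.size <= 2:
        return arr == values.max() if values.size == 2 else np.zeros(arr.shape, bool) | (arr > 0)
    if threshold is None:
        raise ValueError(
            f"mask has {values.size} distinct values; pass an explicit threshold"
        )
    if arr.dtype in _FULL_SCALE:
        arr = arr.astype(np.float64) / _FULL_SCALE[arr.dtype]
    return arr > threshold


def save_gray(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write a [0, 1] grayscale array as an 8-bit raster."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale array")
    if img.min() < 0 or img.max() > 1:
        warnings.warn("image values outside [0, 1] are clipped on save")
        img = np.clip(img, 0.0, 1.0)
    iio.imwrite(path, np.rint(img * 255).astype(np.uint8))


def save_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a boolean mask as an 8-bit raster with foreground = 255.

    ``load_mask(save_mask(m))`` round-trips bit-exactly.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.dtype != np.bool_:
        raise ValueError("expected a 2-D boolean mask")
    iio.imwrite(path, np.where(mask, 255, 0).astype(np.uint8))


def save_metrics_csv(rows: list[dict], path: str | os.PathLike) -> None:
    """Write per-image metrics as CSV with header ``image,fd,vlf,vad``."""
    df = pd.DataFrame(rows, columns=["image", "fd", "vlf", "vad"])
    df.to_csv(path, index=False)
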