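"""Three-step vessel segmentation with contrast pre-adjustment.

The binarization pipeline is: (0) contrast stretch saturating a small
fraction of pixels at intensities 0 and 1; (1) a morphological low-pass step
with a disk structuring element of radius V1 that suppresses elements
smaller than the disk; (2) a global threshold V2 zeroing all pixels below
it; (3) a local adaptive threshold that marks a pixel as vessel when it
strictly exceeds the mean of its V3 x V3 neighborhood.

The low-pass step is a "top hat filter" built from erosion followed by
dilation: the image minus its grayscale opening (white-tophat).  This keeps
bright elements narrower than the disk -- the vessels -- while removing the
slowly varying background; it is the only reading under which the reference
radius V1 = 15 is compatible with vessels up to ~13 px wide, since a plain
opening with a 31 px diameter disk would erase them outright.  The raw
opening is still available via ``mode="opening"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.morphology import disk
from skimage.morphology import opening as _gray_opening

#: numerical tie tolerance for the strict local-mean comparison: a pixel must
#: exceed its neighborhood mean by more than this to count as vessel.  Keeps
#: exactly-flat regions background despite float residue in the sliding-sum
#: filter (well below the 1/255 quantization of 8-bit input).
TIE_TOLERANCE = 1e-9

__all__ = [
    "SegParams",
    "adjust_contrast",
    "lowpass_tophat",
    "global_threshold",
    "adaptive_threshold",
    "segment",
    "coerce_window",
]


@dataclass(frozen=True)
class SegParams:
    """Segmentation parameters (V1, V2, V3).

    Defaults are the reference optimum (15, 0.15, 10) found by a
    sensitivity/specificity sweep against a manually segmented gold
    standard.  ``v3_window`` is coerced to the nearest odd integer >= 3 so a
    center pixel exists (10 becomes 11 internally).
    """

    v1_radius: int = 15
    v2_global: float = 0.15
    v3_window: int = 10
    saturation_frac: float = 0.01  # per tail
    lowpass_mode: str = "white-tophat"

    def __post_init__(self) -> None:
        if self.v1_radius < 1:
            raise ValueError("v1_radius must be >= 1")
        if not 0.0 <= self.v2_global <= 1.0:
            raise ValueError("v2_global must lie in [0, 1]")
        if self.v3_window < 3:
            raise ValueError("v3_window must be >= 3")
        if not 0.0 <= self.saturation_frac < 0.5:
            raise ValueError("saturation_frac must lie in [0, 0.5)")
        if self.lowpass_mode not in ("opening", "white-tophat"):
            raise ValueError("lowpass_mode must be 'opening' or 'white-tophat'")


def coerce_window(window: int) -> int:
    """Round a window side up to the nearest odd integer >= 3."""
    window = max(int(window), 3)
    return window if window % 2 == 1 else window + 1


def _as_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale array")
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    return img


def adjust_contrast(img: np.ndarray, saturation_frac: float = 0.01) -> np.ndarray:
    """Linearly stretch intensities, saturating ``saturation_frac`` per tail.

    Values at or below the lower percentile map to 0, at or above the upper
    percentile map to 1, linear in between.  A constant image (degenerate
    percentiles) returns all zeros with a warning.
    """
    img = _as_image(img)
    lo = float(np.quantile(img, saturation_frac))
    hi = float(np.quantile(img, 1.0 - saturation_frac))
    if hi <= lo:
        warnings.warn("degenerate intensity range; contrast adjustment returns zeros")
        return np.zeros_like(img)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def lowpass_tophat(img: np.ndarray, v1_radius: int, mode: str = "opening") -> np.ndarray:
    """Morphological low-pass: grayscale opening (or white-tophat) with a disk.

    Opening (erosion then dilation with a Euclidean disk of radius
    ``v1_radius``) removes bright elements smaller than the disk; the
    white-tophat is the image minus its opening.  Output is clamped to
    [0, 1].
    """
    img = _as_image(img)
    if v1_radius >= min(img.shape) / 2:
        raise ValueError("v1_radius must be smaller than half the smaller image side")
    opened = _gray_opening(img, footprint=disk(v1_radius))
    if mode == "white-tophat":
        out = img - opened
    elif mode == "opening":
        out = opened
    else:
        raise ValueError("mode must be 'opening' or 'white-tophat'")
    return np.clip(out, 0.0, 1.0)


def global_threshold(img: np.ndarray, v2: float) -> np.ndarray:
    """Zero all pixels strictly below ``v2``; pixels at or above it pass through."""
    img = _as_image(img)
    if not 0.0 <= v2 <= 1.0:
        raise ValueError("v2 must lie in [0, 1]")
    return np.where(img < v2, 0.0, img)


def adaptive_threshold(img: np.ndarray, v3_window: int) -> np.ndarray:
    """Binarize: foreground where a pixel strictly exceeds its local mean.

    The local mean is taken over a ``v3_window`` x ``v3_window`` sliding
    neighborhood with mirror padding at the borders (window sides are
    coerced to odd so a center pixel exists).  The strict inequality makes
    constant regions background.  If the window exceeds the image, the
    global mean is used instead, with a warning.
    """
    img = _as_image(img)
    win = coerce_window(v3_window)
    if win > min(img.shape):
        warnings.warn("adaptive window exceeds image; falling back to global mean")
        return (img - img.mean()) > TIE_TOLERANCE
    local_mean = uniform_filter(img, size=win, mode="mirror")
    return (img - local_mean) > TIE_TOLERANCE


def segment(img: np.ndarray, params: SegParams = SegParams()) -> np.ndarray:
    """Full segmentation: contrast stretch, low-pass, global then adaptive threshold."""
    out = adjust_contrast(img, params.saturation_frac)
    out = lowpass_tophat(out, params.v1_radius, params.lowpass_mode)
    out = global_threshold(out, params.v2_global)
    return adaptive_threshold(out, params.v3_window)
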