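"""Synthetic fixtures: the pentaflake quasi-fractal and vessel phantoms.

The pentaflake is the standard self-similar figure obtained by replacing a
regular pentagon with six copies scaled by 1/(1+phi) (phi the golden ratio):
five copies tucked into the corners plus one center copy rotated by pi.  Its
similarity dimension log(6)/log(1+phi) ~= 1.8617 is known in closed form,
which makes it the calibration object for the box-counting estimator.

Vessel phantoms emulate the appearance statistics of en-face angiography
projections -- bright tortuous vessels of varying width on a noisy dark
background -- with an exact ground-truth mask, so segmentation and the
downstream metrics can be scored without real acquisition data.  They do not
model flow-signal physics (speckle decorrelation, shadowing).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as _draw_disk
from skimage.draw import polygon as _draw_polygon
from skimage.draw import polygon_perimeter as _draw_polygon_perimeter

__all__ = [
    "PentaflakeSpec",
    "VesselPhantomSpec",
    "generate_pentaflake",
    "generate_vessel_phantom",
]

_PHI = (1.0 + math.sqrt(5.0)) / 2.0
#: linear scale factor between successive pentaflake generations
_SCALE = 1.0 / (1.0 + _PHI)


@dataclass(frozen=True)
class PentaflakeSpec:
    """Parameters of the rasterized pentaflake.

    Attributes
    ----------
    iteration : int
        Construction depth; iteration 0 is a single pentagon.  The fifth
        iteration is the standard quasi-fractal calibration image.
    raster_size : int
        Side of the square output raster in pixels (>= 64).
    fill : str
        ``"filled"`` rasterizes pentagon interiors (default); ``"outline"``
        rasterizes only their perimeters.
    """

    iteration: int = 5
    raster_size: int = 1024
    fill: str = "filled"

    def __post_init__(self) -> None:
        if self.iteration < 0:
            raise ValueError("iteration must be >= 0")
        if self.raster_size < 64:
            raise ValueError("raster_size must be >= 64")
        if self.fill not in ("filled", "outline"):
            raise ValueError("fill must be 'filled' or 'outline'")


def _pentagon_vertices(cx: float, cy: float, radius: float, rotation: float) -> tuple[np.ndarray, np.ndarray]:
    """Row/col vertex coordinates of a regular pentagon (point-up at rotation 0)."""
    angles = rotation + np.deg2rad(90.0 + 72.0 * np.arange(5))
    cols = cx + radius * np.cos(angles)
    rows = cy - radius * np.sin(angles)  # raster rows grow downward
    return rows, cols


def generate_pentaflake(spec: PentaflakeSpec = PentaflakeSpec()) -> np.ndarray:
    """Rasterize the n-th iteration pentaflake as a boolean mask.

    The base pentagon is point-up and centered in the raster.  Each
    generation replaces a pentagon of circumradius R with six pentagons of
    circumradius R/(1+phi): five centered at distance R*(1 - 1/(1+phi))
    toward each vertex (same orientation) and one concentric copy rotated by
    pi.  Generation is fully deterministic.
    """
    size = spec.raster_size
    base_radius = 0.48 * size
    # (center_col, center_row, radius, rotation) per pentagon of the current generation
    pentagons = [(size / 2.0, size / 2.0, base_radius, 0.0)]
    for _ in range(spec.iteration):
        nxt = []
        for cx, cy, r, rot in pentagons:
            child_r = r * _SCALE
            offset = r - child_r
            angles = rot + np.deg2rad(90.0 + 72.0 * np.arange(5))
            for a in angles:
                nxt.append((cx + offset * math.cos(a), cy - offset * math.sin(a), child_r, rot))
            nxt.append((cx, cy, child_r, rot + math.pi))
        pentagons = nxt

    if pentagons and pentagons[0][2] < 2.0:
        warnings.warn(
            f"smallest pentagon circumradius {pentagons[0][2]:.2f} px is below 2 px; "
            "raster may not resolve the finest generation"
        )

    out = np.zeros((size, size), dtype=bool)
    for cx, cy, r, rot in pentagons:
        rows, cols = _pentagon_vertices(cx, cy, r, rot)
        if spec.fill == "filled":
            rr, cc = _draw_polygon(rows, cols, shape=out.shape)
        else:
            rr, cc = _draw_polygon_perimeter(rows, cols, shape=out.shape, clip=True)
        out[rr, cc] = True
    return out


@dataclass(frozen=True)
class VesselPhantomSpec:
    """Parameters of the random vessel-network phantom.

    Defaults emulate a high-contrast en-face projection at ~8 um/px: vessel
    widths up to ~13 px (~100 um), moderate tortuosity, dim background with
    additive Gaussian noise and slight optical blur.
    """

    raster_size: int = 256
    n_main_vessels: int = 5
    branch_prob: float = 0.01  # per walk step
    width_range: tuple[int, int] = (3, 13)  # px, min/max dilated vessel width
    tortuosity: float = 0.15  # std of per-step heading change, radians
    vessel_intensity: float = 0.8
    background_level: float = 0.08
    noise_sigma: float = 0.05
    blur_sigma: float = 1.0  # px
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.width_range
        if not (1 <= lo <= hi <= self.raster_size / 4):
            raise ValueError("width_range must satisfy 1 <= min <= max <= raster_size/4")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must be a probability")
        for name in ("vessel_intensity", "background_level"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def _walk_vessel(
    mask: np.ndarray,
    rng: np.random.Generator,
    start: tuple[float, float],
    heading: float,
    width: float,
    spec: VesselPhantomSpec,
    depth: int,
) -> None:
    """Stamp one random-walk vessel (and recursive branches) into ``mask``."""
    size = spec.raster_size
    r, c = start
    radius = max(width / 2.0, 0.5)
    max_steps = size
    for _ in range(max_steps):
        rr, cc = _draw_disk((r, c), radius, shape=mask.shape)
        mask[rr, cc] = True
        heading += rng.normal(0.0, spec.tortuosity)
        r += math.sin(heading)
        c += math.cos(heading)
        if not (0 <= r < size and 0 <= c < size):
            return
        if depth < 2 and rng.random() < spec.branch_prob:
            branch_heading = heading + rng.choice([-1.0, 1.0]) * rng.uniform(0.4, 1.1)
            _walk_vessel(mask, rng, (r, c), branch_heading, width * 0.7, spec, depth + 1)


def generate_vessel_phantom(spec: VesselPhantomSpec = VesselPhantomSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Generate a (grayscale image, ground-truth mask) phantom pair.

    Vessels are random-walk polylines dilated to per-vessel widths drawn from
    ``width_range``, branching with probability ``branch_prob`` per step.  The
    image is ``background_level + vessel_intensity * mask`` blurred by
    ``blur_sigma`` and corrupted with additive Gaussian noise, clamped to
    [0, 1].  The returned mask is the exact pre-blur, pre-noise vessel
    support; identical specs (including seed) give bit-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.raster_size
    mask = np.zeros((size, size), dtype=bool)
    for _ in range(spec.n_main_vessels):
        edge = rng.integers(4)
        t = rng.uniform(0.1, 0.9) * size
        if edge == 0:  # left edge, heading right-ish
            start, heading = (t, 0.0), rng.uniform(-0.6, 0.6)
        elif edge == 1:  # right edge
            start, heading = (t, size - 1.0), math.pi + rng.uniform(-0.6, 0.6)
        elif edge == 2:  # top edge (row 0), heading downward
            start, heading = (0.0, t), math.pi / 2 + rng.uniform(-0.6, 0.6)
        else:  # bottom edge
            start, heading = (size - 1.0, t), -math.pi / 2 + rng.uniform(-0.6, 0.6)
        width = float(rng.uniform(*spec.width_range))
        _walk_vessel(mask, rng, start, heading, width, spec, depth=0)

    img = spec.background_level + spec.vessel_intensity * mask.astype(np.float64)
    if spec.blur_sigma > 0:
        img = gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0), mask
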