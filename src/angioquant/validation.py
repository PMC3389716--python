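"""Scoring computer segmentations against gold standards and parameter sweeps.

A computer-segmented (CS) mask is overlaid on a manually segmented gold
standard (GS): per-pixel categories are true positive (both), false negative
(GS only), false positive (CS only) and true negative (neither), rendered
yellow/green/red/black in the overlay raster.  Sensitivity and specificity
are Se = TP/(TP+FN) and Sp = TN/(TN+FP); a parameter sweep scores every
(V1, V2, V3) combination by the arithmetic mean (Se+Sp)/2 and reports the
full scatter (an ROC cloud) plus the argmax.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .metrics import VesselMetrics
from .segmentation import (
    SegParams,
    adaptive_threshold,
    adjust_contrast,
    global_threshold,
    lowpass_tophat,
)

__all__ = [
    "ConfusionCounts",
    "SweepRow",
    "SweepResult",
    "confusion_overlay",
    "sensitivity_specificity",
    "parameter_sweep",
    "percent_variation",
    "default_sweep_grid",
]

#: overlay colors, Fig.-style convention: TP yellow, FN green, FP red, TN black
_OVERLAY_COLORS = {
    "tp": (255, 255, 0),
    "fn": (0, 255, 0),
    "fp": (255, 0, 0),
    "tn": (0, 0, 0),
}


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixelwise confusion counts of a CS mask against a GS mask."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def se(self) -> float | None:
        """Sensitivity TP/(TP+FN); ``None`` when the gold foreground is empty."""
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def sp(self) -> float | None:
        """Specificity TN/(TN+FP); ``None`` when the gold background is empty."""
        denom = self.tn + self.fp
        return self.tn / denom if denom else None


@dataclass(frozen=True)
class SweepRow:
    params: SegParams
    se: float | None
    sp: float | None
    score: float | None  # (se + sp) / 2


@dataclass
class SweepResult:
    rows: list[SweepRow]
    best: SweepRow


def confusion_overlay(cs: np.ndarray, gs: np.ndarray) -> tuple[ConfusionCounts, np.ndarray]:
    """Overlay a computer segmentation on a gold standard.

    Returns the confusion counts and an RGB uint8 raster coding TP/FN/FP/TN
    as yellow/green/red/black.
    """
    cs = np.asarray(cs, dtype=bool)
    gs = np.asarray(gs, dtype=bool)
    if cs.shape != gs.shape:
        raise ValueError(f"shape mismatch: CS {cs.shape} vs GS {gs.shape}")
    tp = cs & gs
    fn = ~cs & gs
    fp = cs & ~gs
    counts = ConfusionCounts(
        tp=int(tp.sum()),
        fn=int(fn.sum()),
        fp=int(fp.sum()),
        tn=int(cs.size - tp.sum() - fn.sum() - fp.sum()),
    )
    overlay = np.zeros(cs.shape + (3,), dtype=np.uint8)
    overlay[tp] = _OVERLAY_COLORS["tp"]
    overlay[fn] = _OVERLAY_COLORS["fn"]
    overlay[fp] = _OVERLAY_COLORS["fp"]
    return counts, overlay


def sensitivity_specificity(counts: ConfusionCounts) -> tuple[float | None, float | None]:
    """Return (Se, Sp); an undefined ratio is ``None`` and warned about."""
    if counts.se is None:
        warnings.warn("gold standard has no foreground: sensitivity undefined")
    if counts.sp is None:
        warnings.warn("gold standard complement is empty: specificity undefined")
    return counts.se, counts.sp


def default_sweep_grid() -> list[SegParams]:
    """The shipped 10 x 10 x 10 sweep grid: V1 in [3, 30], V2 in [0.05, 0.5], V3 odd in [5, 41]."""
    v1s = np.unique(np.round(np.linspace(3, 30, 10)).astype(int))
    v2s = np.round(np.linspace(0.05, 0.5, 10), 3)
    v3s = np.round(np.linspace(5, 41, 10)).astype(int)
    v3s = np.unique(v3s + (1 - v3s % 2))  # force odd
    return [
        SegParams(v1_radius=int(a), v2_global=float(b), v3_window=int(c))
        for a, b, c in itertools.product(v1s, v2s, v3s)
    ]


def parameter_sweep(
    img: np.ndarray, gs: np.ndarray, grid: list[SegParams] | None = None
) -> SweepResult:
    """Segment ``img`` under every parameter combination and score against ``gs``.

    Each row carries (Se + Sp)/2; a failing combination is recorded with a
    missing score rather than aborting the sweep.  The best row maximizes
    the score, ties broken by smaller (V1, V2, V3).  Intermediate stage
    outputs are cached per (saturation, mode, V1) and per V2, so large grids
    cost roughly one opening per distinct V1.
    """
    if grid is None:
        grid = default_sweep_grid()
    if not grid:
        raise ValueError("sweep grid is empty")
    gs = np.asarray(gs, dtype=bool)

    contrast_cache: dict[float, np.ndarray] = {}
    lowpass_cache: dict[tuple[float, str, int], np.ndarray] = {}
    thresh_cache: dict[tuple[float, str, int, float], np.ndarray] = {}
    rows: list[SweepRow] = []
    for p in grid:
        try:
            ckey = p.saturation_frac
            if ckey not in contrast_cache:
                contrast_cache[ckey] = adjust_contrast(img, p.saturation_frac)
            lkey = (ckey, p.lowpass_mode, p.v1_radius)
            if lkey not in lowpass_cache:
                lowpass_cache[lkey] = lowpass_tophat(
                    contrast_cache[ckey], p.v1_radius, p.lowpass_mode
                )
            tkey = lkey + (p.v2_global,)
            if tkey not in thresh_cache:
                thresh_cache[tkey] = global_threshold(lowpass_cache[lkey], p.v2_global)
            cs = adaptive_threshold(thresh_cache[tkey], p.v3_window)
            counts, _ = confusion_overlay(cs, gs)
            se, sp = counts.se, counts.sp
            score = (se + sp) / 2.0 if se is not None and sp is not None else None
        except ValueError:
            se = sp = score = None
        rows.append(SweepRow(params=p, se=se, sp=sp, score=score))

    scored = [r for r in rows if r.score is not None]
    if not scored:
        raise ValueError("no parameter combination produced a valid score")
    best = min(
        scored,
        key=lambda r: (-r.score, r.params.v1_radius, r.params.v2_global, r.params.v3_window),
    )
    return SweepResult(rows=rows, best=best)


def percent_variation(
    manual: VesselMetrics, auto: VesselMetrics
) -> tuple[float | None, float | None, float | None]:
    """Percent variation 100*|manual - auto|/manual per metric (fd, vlf, vad).

    The manual (gold-standard) value is the denominator.  A metric whose
    manual value is zero or undefined yields ``None`` with a warning.
    """
    out = []
    for name in ("fd", "vlf", "vad"):
        m = getattr(manual, name)
        a = getattr(auto, name)
        if m is None or a is None or m == 0:
            warnings.warn(f"percent variation undefined for {name}")
            out.append(None)
        else:
            out.append(100.0 * abs(m - a) / m)
    return tuple(out)
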