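"""Topology-preserving skeletonization of vessel masks.

Reduces every 8-connected foreground segment to a unit-width centerline by
iterative boundary deletion, preserving connectivity (8-connected foreground,
4-connected background).  The two-subiteration thinning scheme of Zhang &
Suen, as implemented in scikit-image, is used with its fixed scan order, so
results are deterministic.  Isolated single pixels are retained as length-1
segments: deleting them would silently change the vessel length fraction.
No spur pruning is applied.
"""

from __future__ import annotations

import numpy as np
from skimage.morphology import skeletonize as _skimage_skeletonize

__all__ = ["skeletonize"]


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Thin a boolean mask to unit-width centerlines.

    The result is a subset of the input, preserves the number of 8-connected
    components, and is idempotent.  Empty masks are allowed.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("expected a 2-D mask")
    if mask.dtype != np.bool_:
        if not np.isin(mask, (0, 1)).all():
            raise ValueError("mask values must be in {0, 1}")
        mask = mask.astype(bool)
    return _skimage_skeletonize(mask, method="zhang")
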