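"""Pipeline configuration: YAML loading and defaults.

Defaults reproduce the reference configuration: segmentation parameters
(V1, V2, V3) = (15, 0.15, 10) and a 32 px sliding window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .segmentation import SegParams

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    seg: SegParams = field(default_factory=SegParams)
    window: int = 32
    map_stride: int = 1
    box_lengths: tuple[int, ...] | None = None
    sweep_grid: dict[str, list] | None = None  # per-variable value lists
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["seg"] = asdict(self.seg)
        return d


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Build a config from an optional YAML file plus flat overrides.

    YAML layout mirrors the dataclass: a ``seg`` mapping with ``v1_radius``,
    ``v2_global``, ``v3_window``, ``saturation_frac``, ``lowpass_mode``, and
    top-level ``window``, ``map_stride``, ``box_lengths``, ``sweep_grid``,
    ``seed``, ``log_level``.  CLI flags override file values.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        seg_over = {k: v for k, v in overrides.items()
                    if k in ("v1_radius", "v2_global", "v3_window",
                             "saturation_frac", "lowpass_mode") and v is not None}
        data.setdefault("seg", {})
        data["seg"].update(seg_over)
        for k, v in overrides.items():
            if k not in seg_over and v is not None:
                data[k] = v
    seg = SegParams(**data.pop("seg", {}))
    if "box_lengths" in data and data["box_lengths"] is not None:
        data["box_lengths"] = tuple(int(x) for x in data["box_lengths"])
    return PipelineConfig(seg=seg, **data)
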