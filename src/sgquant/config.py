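"""Run configuration: every tunable of every stage with documented
defaults, strict (unknown-key-rejecting) YAML loading, and a stable
config hash embedded in all outputs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Optional

import yaml


@dataclass
class SegmentationConfig:
    membrane_channel: str = "WGA"
    smoothing_sigma: float = 1.5
    ridge_threshold: Optional[float] = None   # Otsu when None
    min_area_px: int = 500


@dataclass
class SurfaceConfig:
    sgii_channel: str = "SgII"
    width_each_side: int = 3


@dataclass
class CorticalConfig:
    shell_thickness_nm: float = 500.0
    welch: bool = False


@dataclass
class TrackingConfig:
    sigma_px: float = 1.3
    threshold: float = 15.0
    max_disp_px: float = 8.0
    straightness_threshold: float = 0.8
    min_directed_detections: int = 4
    coloc_radius_px: float = 2.0


@dataclass
class SimulateConfig:
    """Optional simulation block: generate the inputs instead of reading
    them. ``kind`` is one of fluor / em / tracks; ``overrides`` are applied
    on top of the preset."""

    kind: str = "fluor"
    preset: Optional[str] = None
    overrides: dict[str, Any] = field(default_factory=dict)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results"
    inputs: dict[str, str] = field(default_factory=dict)
    simulate: Optional[SimulateConfig] = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    surface: SurfaceConfig = field(default_factory=SurfaceConfig)
    cortical: CorticalConfig = field(default_factory=CorticalConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        # the hash fingerprints the analysis, not where it is written
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


_SECTION_TYPES = {
    "simulate": SimulateConfig,
    "segmentation": SegmentationConfig,
    "surface": SurfaceConfig,
    "cortical": CorticalConfig,
    "tracking": TrackingConfig,
}


def _build(cls, data: dict, path: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s) under {path!r}: {sorted(unknown)}")
    return cls(**data)


def load_config(source: str | Path | dict) -> RunConfig:
    """Load a run configuration from YAML (path or mapping), rejecting any
    key that no stage defines."""
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text()) or {}
    else:
        data = dict(source)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _SECTION_TYPES and value is not None:
            kwargs[key] = _build(_SECTION_TYPES[key], dict(value), key)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)
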