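"""Flat pipeline configuration with strict key checking.

Every tunable named across the pipeline lives here so a single snapshot
fully determines a run; the snapshot is embedded in output artifacts for
provenance. Unknown keys in a config file are rejected rather than
ignored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # pre-processing
    bone_threshold_hu: float = 300.0
    roi_depth_mm: float = 32.0
    # superpixels
    slic_target_size_px: int = 64
    slic_compactness: float = 0.1
    positive_fraction: float = 0.5
    # cross-validation / classifier
    n_folds: int = 2
    n_trees: int = 200
    seed: int = 0
    prob_threshold: float = 0.5
    # deep features (optional)
    use_deep_features: bool = False
    unet_epochs: int = 4
    unet_patch_size: int = 32
    # post-processing
    # ~2 superpixels: an isolated single-superpixel detection is sparse noise
    min_area_px: int = 128
    fill_radius_px: int = 2
    fill_max_hole_px: int = 200
    min_slices: int = 2
    # in-plane drift (mm) tolerated between adjacent slices when judging
    # 3D continuity; compensates the 5 mm slice anisotropy
    continuity_drift_mm: float = 4.0
    smooth_sigma_mm: float = 1.0
    # None = volume-preserving re-binarization after smoothing
    smooth_threshold: float | None = None
    # severity
    severity_threshold_cc: float = 25.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a flat mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
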