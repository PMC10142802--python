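"""Run configuration for the semi-quantification pipeline.

All tunables of the automated procedure live here with their published
defaults: the parcellation budget, the two cubic-window half-sizes (reference
filter and maxima extraction), the quantile-histogram resolution, the
conformity threshold on the Y statistic, and the mask-combination rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import yaml


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Parameters
    ----------
    k_districts:
        Target number of parcellation districts per FLAIR scan (~300).
    l_ref:
        Half-size (voxels) of the cubic sliding window of the conformity
        filter; the window spans ``(2*l_ref + 1)**3`` voxels.
    l_max:
        Half-size of the cubic window used for the local-mean maxima.
    quantile_bins:
        Number K of quantile bins describing a reference region's intensity
        distribution.
    y_threshold:
        Fixed acceptance threshold on the Y statistic (used when
        ``y_threshold_mode == "fixed"``).
    y_threshold_mode:
        ``"calibrated"`` derives the threshold per reference histogram as the
        95th percentile of Y under multinomial sampling at the window size
        (seeded simulation); ``"fixed"`` uses ``y_threshold`` as published.
    mask_combination_threshold:
        A voxel joins the normal-tissue mask M_n when the mean of its five
        per-lobe indicators reaches this fraction (0.5 = majority, >= 3/5).
    rho_grow:
        Region-growing admission factor for the ipsilateral striatal mask:
        a neighbor joins when its activity >= rho_grow * current region mean.
    grow_max_iter:
        Iteration cap of the striatal region growing.
    infiltration_assumed:
        Whether striatal infiltration by the tumor is taken as established,
        which lets the in-striatum maximum represent the lesion.
    per_lobe_search:
        Restrict each lobe's conformity filter to its own lobe instead of
        the whole brain.
    seed:
        Seed for every stochastic component (parcellation sampling, class
        balancing, threshold calibration).
    """

    k_districts: int = 300
    l_ref: int = 3
    l_max: int = 2
    quantile_bins: int = 10
    y_threshold: float = 1e-3
    y_threshold_mode: Literal["calibrated", "fixed"] = "calibrated"
    mask_combination_threshold: float = 0.5
    rho_grow: float = 0.8
    grow_max_iter: int = 50
    infiltration_assumed: bool = False
    per_lobe_search: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.quantile_bins < 2:
            raise ValueError("quantile_bins must be >= 2")
        if self.l_ref < 1 or self.l_max < 1:
            raise ValueError("window half-sizes must be >= 1")
        if not self.y_threshold > 0:
            raise ValueError("y_threshold must be > 0")
        if not 0 < self.mask_combination_threshold <= 1:
            raise ValueError("mask_combination_threshold must be in (0, 1]")
        if self.y_threshold_mode not in ("calibrated", "fixed"):
            raise ValueError("y_threshold_mode must be 'calibrated' or 'fixed'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat key-value YAML config; unknown keys are rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a flat mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
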