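"""Pipeline configuration: every tunable of the classifier-development procedure."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunables of the pipeline with the study's operating defaults.

    Attributes
    ----------
    cv_folds : int
        K for the stratified K-fold cross-validation inside marker
        selection (default 5).
    rfe_reps : int
        Number of repeated cross-validation repetitions for recursive
        feature elimination (default 100).
    resamples : int
        Number of independent stratified train/test resamples of the
        final classifier (default 100).
    train_fraction : float
        Fraction of each stratum assigned to training (default 2/3).
    pauc_spec_lo, pauc_spec_hi : float
        Specificity band over which partial AUC is computed (defaults
        0.75 and 1.00), emphasising the low-false-positive regime.
    target_specificity : float
        Specificity anchor for per-split threshold calibration
        (default 0.99, i.e. ">99%" with 61 test controls).
    bootstrap_B : int
        Bootstrap replicates for the bias-corrected AUC interval
        (default 2000).
    ci_level : float
        Two-sided confidence level for all intervals (default 0.95).
    marker_missing_max_frac : float
        Markers with at least this fraction of values missing or below
        the LOD are excluded (default 0.5; retention requires < 50%).
    seed : int
        Root seed; every random draw in the pipeline descends from it.
    include_age : bool
        Whether age enters the model as a covariate alongside the
        selected markers (default True).
    average_replicates : bool
        Whether replicate measurement rows per subject are averaged on
        read (default True).
    """

    cv_folds: int = 5
    rfe_reps: int = 100
    resamples: int = 100
    train_fraction: float = 2.0 / 3.0
    pauc_spec_lo: float = 0.75
    pauc_spec_hi: float = 1.00
    target_specificity: float = 0.99
    bootstrap_B: int = 2000
    ci_level: float = 0.95
    marker_missing_max_frac: float = 0.5
    seed: int = 0
    include_age: bool = True
    average_replicates: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if not (0.0 <= self.pauc_spec_lo < self.pauc_spec_hi <= 1.0):
            raise ValueError(
                f"invalid pAUC specificity band [{self.pauc_spec_lo}, {self.pauc_spec_hi}]"
            )
        if self.cv_folds < 2:
            raise ValueError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if not (0.0 < self.target_specificity <= 1.0):
            raise ValueError("target_specificity must be in (0, 1]")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0, 1)")
        for name in ("rfe_reps", "resamples", "bootstrap_B"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
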