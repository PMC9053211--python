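"""Core domain types for the EV-protein MCED classifier pipeline.

A :class:`Cohort` bundles subject metadata (case/control group, stage, age,
sex), marker metadata (name, limit of detection, units) and the raw
subject-by-marker concentration matrix.  Missing measurements are carried
as ``NaN``; values below a marker's LOD are carried as-is and handled by
the preprocessing stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

GROUPS = ("control", "pancreatic", "ovarian", "bladder")
CANCERS = ("pancreatic", "ovarian", "bladder")
STAGES = ("I", "II")


class CohortValidationError(ValueError):
    """Raised when cohort data violates a structural invariant."""


@dataclass(frozen=True)
class MarkerMeta:
    """Assay metadata for one protein marker.

    Parameters
    ----------
    name : str
        Unique marker identifier.
    lod : float
        Limit of detection in assay units; must be positive so that
        ``log2(lod)`` is finite.
    units : str
        Concentration units, e.g. ``pg/mL``.
    panel : str
        Immunoassay panel label.
    """

    name: str
    lod: float
    units: str = "pg/mL"
    panel: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise CohortValidationError("marker name must be non-empty")
        if not np.isfinite(self.lod) or self.lod <= 0:
            raise CohortValidationError(
                f"marker {self.name!r}: LOD must be positive and finite, got {self.lod}"
            )


@dataclass
class Subject:
    """One study subject: controls carry no stage; cases must carry one."""

    id: str
    group: str
    age: float
    sex: str = "unknown"
    stage: Optional[str] = None
    substage: Optional[str] = None
    histology: Optional[str] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortValidationError(
                f"subject {self.id!r}: unknown group {self.group!r}; expected one of {GROUPS}"
            )
        if self.group == "control":
            if self.stage is not None:
                raise CohortValidationError(
                    f"control subject {self.id!r} must not carry a stage, got {self.stage!r}"
                )
        else:
            if self.stage not in STAGES:
                raise CohortValidationError(
                    f"case subject {self.id!r} must carry stage I or II, got {self.stage!r}"
                )
            if self.substage is not None and not self.substage.startswith(self.stage):
                raise CohortValidationError(
                    f"subject {self.id!r}: sub-stage {self.substage!r} inconsistent "
                    f"with stage {self.stage!r}"
                )

    @property
    def is_case(self) -> bool:
        return self.group != "control"


@dataclass
class Cohort:
    """Subjects x markers measurement table with metadata.

    ``values[i, j]`` is the measured concentration of marker ``j`` for
    subject ``i``; ``NaN`` marks a missing measurement.  Replicate wells
    are averaged upstream (see :func:`evmced.io.read_cohort`), so rows are
    one-per-subject here.
    """

    subjects: list[Subject]
    markers: list[MarkerMeta]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = len(self.subjects), len(self.markers)
        if self.values.shape != (n, m):
            raise CohortValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{n} subjects x {m} markers"
            )
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != n:
            raise CohortValidationError("subject ids are not unique")
        names = [mk.name for mk in self.markers]
        if len(set(names)) != m:
            raise CohortValidationError("marker names are not unique")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                i, j = np.argwhere(self.values < 0)[0]
                raise CohortValidationError(
                    f"negative measurement for subject {ids[i]!r}, marker {names[j]!r}"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def lods(self) -> np.ndarray:
        return np.array([m.lod for m in self.markers])

    @property
    def labels(self) -> np.ndarray:
        """Binary case/control labels: 1 = cancer case, 0 = control."""
        return np.array([int(s.is_case) for s in self.subjects])

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.subjects], dtype=float)

    def marker_index(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise KeyError(f"unknown marker {name!r}") from None


@dataclass
class FeatureMatrix:
    """Model-ready feature table on the log2 scale (age untransformed).

    ``imputed[i, j]`` flags cells whose value was set to the marker's LOD
    because the measurement was missing or below it.  The age column, when
    present, is never imputed.
    """

    subject_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = len(self.subject_ids), len(self.feature_names)
        if self.values.shape != (n, m):
            raise CohortValidationError(
                f"feature matrix shape {self.values.shape} != ({n}, {m})"
            )
        if self.imputed is None:
            self.imputed = np.zeros((n, m), dtype=bool)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        if self.imputed.shape != self.values.shape:
            raise CohortValidationError("provenance mask shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise CohortValidationError("feature matrix contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        """Column subset preserving the requested order."""
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            subject_ids=list(self.subject_ids),
            feature_names=list(names),
            values=self.values[:, idx].copy(),
            imputed=self.imputed[:, idx].copy(),
        )
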