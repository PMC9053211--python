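"""Synthetic case-control cohorts with the statistical structure of
EV-protein screening data.

The generator draws marker concentrations as ``2**z`` with ``z``
multivariate normal on the log2 scale (so the pipeline's log2 transform
is variance-stabilising by construction), with

* block-equicorrelated markers (assay-panel style correlation),
* per-cancer mean shifts on overlapping subsets of informative markers,
* per-marker limits of detection placed at a quantile of the control
  distribution (left-censoring is applied downstream, not here),
* measurements missing completely at random, and
* an age covariate with cases a few years older than controls.

It emulates structure, not the real per-marker concentrations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .datamodel import CANCERS, Cohort, MarkerMeta, Subject

# Mean log2 shifts for informative markers, per cancer.  Calibrated once
# so the pooled classifier operates in the regime reported for EV-protein
# MCED panels (overall AUC ~0.95, sensitivity ~0.7 at ~99% specificity):
# strong pancreatic markers (CA19-9-like, orders-of-magnitude elevations),
# intermediate ovarian (CA125-like), weak bladder markers.
DEFAULT_EFFECT_SCALES = {"pancreatic": 5.5, "ovarian": 3.0, "bladder": 1.8}

# Per-marker multiplier applied to a cancer's effect scale: informative
# markers within a cancer are not equally informative.
_EFFECT_PROFILE_RANGE = (1.6, 0.4)


def _effect_profile(n: int, scale: float) -> np.ndarray:
    return scale * np.linspace(*_EFFECT_PROFILE_RANGE, n)


@dataclass
class AgeParams:
    """Age draw: normal around the group median, clipped to the range."""

    control_median: float = 57.0
    control_range: tuple[float, float] = (40.0, 71.0)
    case_median: float = 60.0
    case_range: tuple[float, float] = (21.0, 76.0)
    sd: float = 8.0


@dataclass
class SimSpec:
    """Full parameterisation of a synthetic cohort draw.

    ``effect_sizes`` maps each cancer to the per-informative-marker log2
    shifts (length ``n_informative_per_cancer``); scalars are expanded
    through a decaying profile.  ``lod_quantile`` (scalar or per-marker)
    is the control-distribution quantile at which each marker's LOD is
    placed, i.e. the expected censored fraction among controls.
    """

    n_controls: int = 184
    n_per_cancer: tuple[int, int, int] = (47, 44, 48)  # pancreatic, ovarian, bladder
    n_markers: int = 42
    n_informative_per_cancer: int = 7
    effect_sizes: dict[str, np.ndarray] = field(default_factory=dict)
    base_log2_mean: Optional[np.ndarray] = None  # default: spread over [2, 12]
    base_log2_sd: float | np.ndarray = 1.5
    block_size: int = 7
    block_rho: float = 0.3
    correlation_matrix: Optional[np.ndarray] = None  # overrides block structure
    lod_quantile: float | np.ndarray = 0.15
    missing_rate: float = 0.02
    age_params: AgeParams = field(default_factory=AgeParams)
    stage_fraction_I: float = 0.633
    stage_plan: Optional[dict[str, list[tuple[str, Optional[str], Optional[str]]]]] = None
    informative_markers: Optional[dict[str, list[int]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        q = np.atleast_1d(np.asarray(self.lod_quantile, dtype=float))
        if np.any(q <= 0) or np.any(q >= 1):
            raise ValueError("lod_quantile must lie in (0, 1)")
        for c in CANCERS:
            eff = self.effect_sizes.get(c, DEFAULT_EFFECT_SCALES[c])
            eff = (
                _effect_profile(self.n_informative_per_cancer, float(eff))
                if np.ndim(eff) == 0
                else np.asarray(eff, dtype=float)
            )
            if eff.shape != (self.n_informative_per_cancer,):
                raise ValueError(
                    f"effect_sizes[{c!r}] must have length {self.n_informative_per_cancer}"
                )
            if not np.all(np.isfinite(eff)):
                raise ValueError(f"effect_sizes[{c!r}] must be finite")
            self.effect_sizes[c] = eff

    # -- derived structure -------------------------------------------------

    @property
    def n_cases(self) -> int:
        return int(sum(self.n_per_cancer))

    @property
    def n_subjects(self) -> int:
        return self.n_controls + self.n_cases

    def marker_names(self) -> list[str]:
        return [f"EVP{j + 1:02d}" for j in range(self.n_markers)]

    def informative_index(self) -> dict[str, list[int]]:
        """Per-cancer informative marker indices; overlapping by default.

        With the default stride ``(n_inf - 1) // 2`` and three cancers the
        union has ``n_inf + 2 * stride`` markers (13 for n_inf = 7).
        """
        if self.informative_markers is not None:
            return {c: list(v) for c, v in self.informative_markers.items()}
        n_inf = self.n_informative_per_cancer
        stride = max(1, (n_inf - 1) // 2)
        out = {}
        for k, c in enumerate(CANCERS):
            idx = list(range(k * stride, k * stride + n_inf))
            if idx[-1] >= self.n_markers:
                raise ValueError("informative markers exceed n_markers")
            out[c] = idx
        return out

    def correlation(self) -> np.ndarray:
        """Marker-marker correlation: explicit matrix or equicorrelated blocks."""
        p = self.n_markers
        if self.correlation_matrix is not None:
            R = np.asarray(self.correlation_matrix, dtype=float)
            if R.shape != (p, p) or not np.allclose(R, R.T, atol=1e-12):
                raise ValueError("correlation matrix must be symmetric p x p")
            if np.min(np.linalg.eigvalsh(R)) < -1e-10:
                raise ValueError("correlation matrix is not positive semi-definite")
            return R
        R = np.eye(p)
        for start in range(0, p, self.block_size):
            stop = min(start + self.block_size, p)
            R[start:stop, start:stop] = self.block_rho
        np.fill_diagonal(R, 1.0)
        return R

    def log2_means_sds(self) -> tuple[np.ndarray, np.ndarray]:
        mu = (
            np.linspace(2.0, 12.0, self.n_markers)
            if self.base_log2_mean is None
            else np.asarray(self.base_log2_mean, dtype=float)
        )
        sd = np.broadcast_to(
            np.asarray(self.base_log2_sd, dtype=float), (self.n_markers,)
        ).copy()
        if mu.shape != (self.n_markers,) or np.any(sd <= 0):
            raise ValueError("invalid base log2 mean/sd")
        return mu, sd

    def lods(self) -> np.ndarray:
        """LOD per marker: the lod_quantile point of the control log2-normal."""
        mu, sd = self.log2_means_sds()
        q = np.broadcast_to(
            np.asarray(self.lod_quantile, dtype=float), (self.n_markers,)
        )
        return np.exp2(mu + sd * norm.ppf(q))

    def replace(self, **kwargs) -> "SimSpec":
        return dataclasses.replace(self, **kwargs)


def _draw_ages(rng: np.random.Generator, n: int, median: float, lo_hi, sd: float) -> np.ndarray:
    ages = rng.normal(median, sd, size=n)
    return np.clip(np.round(ages, 1), *lo_hi)


def _stage_descriptors(spec: SimSpec, cancer: str, n: int):
    if spec.stage_plan is not None and cancer in spec.stage_plan:
        plan = spec.stage_plan[cancer]
        if len(plan) != n:
            raise ValueError(f"stage plan for {cancer} has {len(plan)} entries, need {n}")
        return list(plan)
    n_I = int(round(spec.stage_fraction_I * n))
    return [("I", None, None)] * n_I + [("II", None, None)] * (n - n_I)


def simulate_cohort(spec: SimSpec) -> tuple[Cohort, dict[str, set[str]]]:
    """Draw one cohort; returns it with the informative-marker ground truth.

    Pure function of ``spec`` (including ``spec.seed``): the same spec
    yields an identical cohort.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_markers
    names = spec.marker_names()
    mu, sd = spec.log2_means_sds()
    R = spec.correlation()
    # eigh-based factor tolerates semi-definite R (cholesky would not)
    w, V = np.linalg.eigh(R)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    informative = spec.informative_index()

    group_sizes = [("control", spec.n_controls)] + list(zip(CANCERS, spec.n_per_cancer))
    prefix = {"control": "C", "pancreatic": "P", "ovarian": "O", "bladder": "B"}

    subjects: list[Subject] = []
    blocks: list[np.ndarray] = []
    ap = spec.age_params
    for group, n in group_sizes:
        z = rng.standard_normal((n, p)) @ L.T
        shift = np.zeros(p)
        if group != "control":
            shift[informative[group]] = spec.effect_sizes[group]
        blocks.append(np.exp2(mu + shift + sd * z))
        if group == "control":
            ages = _draw_ages(rng, n, ap.control_median, ap.control_range, ap.sd)
            sexes = rng.choice(["male", "female"], size=n)
            descs = [(None, None, None)] * n
        else:
            ages = _draw_ages(rng, n, ap.case_median, ap.case_range, ap.sd)
            sexes = rng.choice(["male", "female"], size=n, p=[0.4, 0.6])
            descs = _stage_descriptors(spec, group, n)
        for i in range(n):
            stage, substage, histology = descs[i]
            subjects.append(
                Subject(
                    id=f"{prefix[group]}{i + 1:03d}",
                    group=group,
                    age=float(ages[i]),
                    sex=str(sexes[i]),
                    stage=stage,
                    substage=substage,
                    histology=histology,
                )
            )

    values = np.vstack(blocks)
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = values.copy()
        values[mask] = np.nan

    markers = [
        MarkerMeta(name=names[j], lod=float(lod_j), units="pg/mL", panel="synthetic")
        for j, lod_j in enumerate(spec.lods())
    ]
    cohort = Cohort(subjects=subjects, markers=markers, values=values)
    truth = {c: {names[j] for j in idx} for c, idx in informative.items()}
    return cohort, truth


def study_like_spec(seed: int = 12) -> SimSpec:
    """Preset mirroring the study cohort's shape.

    184 controls and 47/44/48 pancreatic/ovarian/bladder stage I-II cases
    (323 subjects), 42 markers of which 13 are informative for at least
    one cancer, 8 heavily censored markers destined to fail the <50%
    missing/below-LOD filter (34 retained), and the study's stage
    composition including ovarian sub-stage IA and serous histology.
    """
    spec = SimSpec(seed=seed)
    # the last 8 markers are non-informative and heavily left-censored
    q = np.full(spec.n_markers, 0.15)
    q[-8:] = 0.65
    # ovarian: 39 stage I (26 of them IA) and 5 stage II; 22 serous overall
    ovarian = []
    for i in range(44):
        if i < 39:
            stage, substage = "I", ("IA" if i < 26 else "IB")
        else:
            stage, substage = "II", None
        histology = "serous" if (i < 17 or i >= 39) else "other"
        ovarian.append((stage, substage, histology))
    plan = {
        "pancreatic": [("I", None, None)] * 22 + [("II", None, None)] * 25,
        "ovarian": ovarian,
        "bladder": [("I", None, None)] * 27 + [("II", None, None)] * 21,
    }
    return spec.replace(lod_quantile=q, stage_plan=plan)
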