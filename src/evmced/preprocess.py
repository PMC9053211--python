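"""Marker prevalence filtering, LOD imputation and log2 transformation.

The rules, in pipeline order:

1. Markers with >= ``max_frac`` (default 50%) of values missing or
   strictly below their limit of detection are excluded, fractions
   computed over the pooled cohort (cases and controls together).
2. Remaining missing or below-LOD cells are set to the marker's LOD
   (left-censored imputation).
3. All marker values are log2-transformed; age, when appended as a
   covariate, stays on its natural scale.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datamodel import Cohort, FeatureMatrix

AGE_FEATURE = "age"


def below_lod_or_missing(cohort: Cohort) -> np.ndarray:
    """Boolean subjects x markers mask: cell missing or strictly below LOD.

    A value exactly equal to the LOD counts as observed.
    """
    with np.errstate(invalid="ignore"):
        below = cohort.values < cohort.lods[None, :]
    return np.isnan(cohort.values) | below


def filter_markers(cohort: Cohort, max_frac: float = 0.5) -> list[str]:
    """Markers whose missing-or-below-LOD fraction is strictly under ``max_frac``."""
    frac = below_lod_or_missing(cohort).mean(axis=0)
    retained = [name for name, f in zip(cohort.marker_names, frac) if f < max_frac]
    if not retained:
        warnings.warn("no markers pass the missing/below-LOD filter", stacklevel=2)
    return retained


def impute_and_log2(
    cohort: Cohort, retained: list[str], include_age: bool = True
) -> FeatureMatrix:
    """Left-censored LOD imputation followed by log2, for the retained markers.

    Every missing or below-LOD cell becomes ``log2(LOD)`` and is flagged
    ``imputed``; observed cells become ``log2(value)``.  Idempotent: the
    imputation step is the identity on an already-imputed matrix.
    """
    unknown = set(retained) - set(cohort.marker_names)
    if unknown:
        raise KeyError(f"markers not in cohort: {sorted(unknown)}")
    idx = [cohort.marker_index(name) for name in retained]
    vals = cohort.values[:, idx].copy()
    lods = cohort.lods[idx]
    mask = below_lod_or_missing(cohort)[:, idx]
    vals[mask] = np.broadcast_to(lods, vals.shape)[mask]
    if np.any(vals <= 0):
        raise ValueError("non-positive value after imputation; check LODs")
    out = np.log2(vals)
    names = list(retained)
    imputed = mask
    if include_age:
        out = np.column_stack([out, cohort.ages])
        imputed = np.column_stack([mask, np.zeros(cohort.n_subjects, dtype=bool)])
        names = names + [AGE_FEATURE]
    return FeatureMatrix(
        subject_ids=cohort.subject_ids,
        feature_names=names,
        values=out,
        imputed=imputed,
    )


def correlation_matrix(fm: FeatureMatrix) -> np.ndarray:
    """Pearson correlations among features (multicollinearity screen).

    Zero-variance features yield NaN rows/columns with a warning rather
    than an error; the diagonal is exactly 1 for non-degenerate features.
    """
    if fm.n_subjects < 3:
        raise ValueError("need at least 3 subjects for correlations")
    sd = fm.values.std(axis=0)
    degenerate = sd == 0
    if np.any(degenerate):
        warnings.warn(
            f"zero-variance features: {[n for n, d in zip(fm.feature_names, degenerate) if d]}",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        R = np.corrcoef(fm.values, rowvar=False)
    R = np.atleast_2d(R)
    np.fill_diagonal(R, np.where(degenerate, np.nan, 1.0))
    return np.clip(R, -1.0, 1.0)
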