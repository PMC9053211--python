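"""Delimited-text readers and writers for cohorts and feature matrices.

File dialect (CSV with header; TSV auto-detected by extension):

``subjects``      id, group, stage, substage, histology, age, sex
``markers``       name, lod, units, panel
``measurements``  subject_id followed by one column per marker; several
                  rows with the same subject_id are replicate wells and
                  are averaged per marker on read (non-missing values
                  only).  Empty fields and the literal ``NA`` denote
                  missing measurements.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import Cohort, CohortValidationError, FeatureMatrix, MarkerMeta, Subject

_NA = ["", "NA"]


def _sep(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep(path), na_values=_NA, keep_default_na=False)


def read_cohort(
    measurements_path: str | Path,
    subjects_path: str | Path,
    markers_path: str | Path,
    average_replicates: bool = True,
) -> Cohort:
    """Read and validate the three cohort files.

    Replicate measurement rows per subject are reduced to the arithmetic
    mean of non-missing values per marker (before any LOD comparison)
    unless ``average_replicates`` is False, in which case replicate rows
    are rejected.
    """
    subj_df = _read_table(subjects_path)
    marker_df = _read_table(markers_path)
    meas_df = _read_table(measurements_path)

    required = {"id", "group", "age"}
    if not required.issubset(subj_df.columns):
        raise CohortValidationError(
            f"subjects file must contain columns {sorted(required)}"
        )
    if not {"name", "lod"}.issubset(marker_df.columns):
        raise CohortValidationError("markers file must contain columns ['name', 'lod']")
    if "subject_id" not in meas_df.columns:
        raise CohortValidationError("measurements file must contain a 'subject_id' column")

    markers = []
    for _, row in marker_df.iterrows():
        lod = row["lod"]
        if pd.isna(lod):
            raise CohortValidationError(f"marker {row['name']!r} has no LOD")
        markers.append(
            MarkerMeta(
                name=str(row["name"]),
                lod=float(lod),
                units=str(row.get("units", "")) if pd.notna(row.get("units", "")) else "",
                panel=str(row.get("panel", "")) if pd.notna(row.get("panel", "")) else "",
            )
        )
    if not markers:
        raise CohortValidationError("markers file is empty")
    marker_names = [m.name for m in markers]

    def _opt(row, key):
        v = row.get(key)
        return None if (v is None or pd.isna(v) or v == "") else str(v)

    subjects = []
    for _, row in subj_df.iterrows():
        subjects.append(
            Subject(
                id=str(row["id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                sex=_opt(row, "sex") or "unknown",
                stage=_opt(row, "stage"),
                substage=_opt(row, "substage"),
                histology=_opt(row, "histology"),
            )
        )
    subject_ids = [s.id for s in subjects]

    missing_cols = [m for m in marker_names if m not in meas_df.columns]
    if missing_cols:
        raise CohortValidationError(
            f"measurements file lacks columns for markers {missing_cols}"
        )
    meas_df = meas_df.copy()
    meas_df["subject_id"] = meas_df["subject_id"].astype(str)
    unknown = set(meas_df["subject_id"]) - set(subject_ids)
    if unknown:
        raise CohortValidationError(
            f"measurement rows for subjects absent from subjects file: {sorted(unknown)[:5]}"
        )
    if meas_df["subject_id"].duplicated().any() and not average_replicates:
        raise CohortValidationError(
            "replicate measurement rows present but replicate averaging is disabled"
        )
    # mean() skips NaN: a subject-marker cell is missing only if missing in
    # every replicate well.
    wide = meas_df.groupby("subject_id", sort=False)[marker_names].mean()
    absent = set(subject_ids) - set(wide.index)
    if absent:
        raise CohortValidationError(
            f"subjects with no measurement row: {sorted(absent)[:5]}"
        )
    values = wide.reindex(subject_ids).to_numpy(dtype=float)
    return Cohort(subjects=subjects, markers=markers, values=values)


def write_cohort(cohort: Cohort, directory: str | Path, sep: str = ",") -> dict[str, Path]:
    """Write the three cohort files in the dialect :func:`read_cohort` accepts."""
    if not cohort.markers:
        raise CohortValidationError("cannot write a cohort with no markers")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = "tsv" if sep == "\t" else "csv"
    paths = {
        "subjects": directory / f"subjects.{ext}",
        "markers": directory / f"markers.{ext}",
        "measurements": directory / f"measurements.{ext}",
    }
    subj_df = pd.DataFrame(
        {
            "id": [s.id for s in cohort.subjects],
            "group": [s.group for s in cohort.subjects],
            "stage": [s.stage for s in cohort.subjects],
            "substage": [s.substage for s in cohort.subjects],
            "histology": [s.histology for s in cohort.subjects],
            "age": [s.age for s in cohort.subjects],
            "sex": [s.sex for s in cohort.subjects],
        }
    )
    subj_df.to_csv(paths["subjects"], sep=sep, index=False, na_rep="NA")
    marker_df = pd.DataFrame(
        {
            "name": [m.name for m in cohort.markers],
            "lod": [repr(m.lod) for m in cohort.markers],
            "units": [m.units for m in cohort.markers],
            "panel": [m.panel for m in cohort.markers],
        }
    )
    marker_df.to_csv(paths["markers"], sep=sep, index=False, na_rep="NA")
    meas_df = pd.DataFrame(cohort.values, columns=cohort.marker_names)
    # repr round-trips float64 exactly through text
    meas_df = meas_df.map(lambda v: "NA" if np.isnan(v) else repr(v))
    meas_df.insert(0, "subject_id", cohort.subject_ids)
    meas_df.to_csv(paths["measurements"], sep=sep, index=False)
    return paths


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> Path:
    """Feature matrix to CSV with a sidecar ``.provenance.csv`` 0/1 mask."""
    path = Path(path)
    df = pd.DataFrame(fm.values, columns=fm.feature_names)
    df.insert(0, "subject_id", fm.subject_ids)
    df.to_csv(path, index=False)
    mask = pd.DataFrame(fm.imputed.astype(int), columns=fm.feature_names)
    mask.insert(0, "subject_id", fm.subject_ids)
    mask.to_csv(path.with_suffix(".provenance.csv"), index=False)
    return path


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    ids = df["subject_id"].astype(str).tolist()
    names = [c for c in df.columns if c != "subject_id"]
    values = df[names].to_numpy(dtype=float)
    prov_path = path.with_suffix(".provenance.csv")
    imputed = None
    if prov_path.exists():
        mdf = pd.read_csv(prov_path)
        imputed = mdf[names].to_numpy(dtype=int).astype(bool)
    return FeatureMatrix(subject_ids=ids, feature_names=names, values=values, imputed=imputed)


def subjects_from_cohort(cohort: Cohort, ids: Sequence[str]) -> list[Subject]:
    """Subjects re-ordered to match ``ids`` (e.g. a feature matrix's rows)."""
    by_id = {s.id: s for s in cohort.subjects}
    return [by_id[i] for i in ids]
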