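"""End-to-end orchestration: simulate/ingest -> preprocess -> select ->
resample -> evaluate, with a run manifest for reproducibility.

Every intermediate artifact is plain CSV/JSON so any stage can be
inspected or replaced independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as evio
from .config import PipelineConfig
from .datamodel import Cohort
from .preprocess import AGE_FEATURE, correlation_matrix, filter_markers, impute_and_log2
from .resample import evaluate, resample_fit
from .rfe import rfe_select
from .simulate import SimSpec, simulate_cohort, study_like_spec

log = logging.getLogger("evmced")


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-exactly."""

    config: dict
    seed: int
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    outputs: list[str] = field(default_factory=list)
    timings_s: dict[str, float] = field(default_factory=dict)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    cohort: Optional[Cohort] = None,
    cohort_paths: Optional[dict[str, str]] = None,
    sim_spec: Optional[SimSpec] = None,
    simulate: bool = False,
) -> Path:
    """Execute the full classifier-development procedure.

    Exactly one input source: an in-memory ``cohort``, the three
    ``cohort_paths`` (measurements/subjects/markers), or synthetic data
    (``simulate=True`` uses the study-shaped preset unless ``sim_spec``
    is given).  Writes the report tables, ROC and importance CSVs, all
    intermediate artifacts, and a manifest into ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    t0 = time.perf_counter()

    if sum(x is not None for x in (cohort, cohort_paths)) + int(simulate or sim_spec is not None) != 1:
        raise ValueError("provide exactly one of cohort, cohort_paths, or simulate/sim_spec")

    if cohort_paths is not None:
        for p in cohort_paths.values():
            manifest.inputs[str(p)] = _sha256(Path(p))
        cohort = evio.read_cohort(
            cohort_paths["measurements"],
            cohort_paths["subjects"],
            cohort_paths["markers"],
            average_replicates=config.average_replicates,
        )
    elif cohort is None:
        spec = sim_spec if sim_spec is not None else study_like_spec(seed=config.seed)
        cohort, truth = simulate_cohort(spec)
        (outdir / "ground_truth.json").write_text(
            json.dumps({c: sorted(m) for c, m in truth.items()}, indent=2)
        )
        evio.write_cohort(cohort, outdir / "cohort")
    manifest.timings_s["ingest"] = time.perf_counter() - t0

    # -- preprocess --------------------------------------------------------
    t = time.perf_counter()
    retained = filter_markers(cohort, config.marker_missing_max_frac)
    if not retained:
        raise ValueError("preprocess: no markers pass the missing/below-LOD filter")
    log.info("preprocess: retained %d/%d markers", len(retained), len(cohort.markers))
    fm = impute_and_log2(cohort, retained, include_age=config.include_age)
    evio.write_feature_matrix(fm, outdir / "features.csv")
    corr = correlation_matrix(fm)
    pd.DataFrame(corr, index=fm.feature_names, columns=fm.feature_names).to_csv(
        outdir / "feature_correlations.csv"
    )
    manifest.timings_s["preprocess"] = time.perf_counter() - t

    labels = cohort.labels
    strata = cohort.groups

    # -- marker selection --------------------------------------------------
    t = time.perf_counter()
    rfe = rfe_select(fm, labels, config, strata=strata)
    log.info(
        "select: %d markers at mean pAUC %.4f: %s",
        rfe.selected_size,
        rfe.mean_pauc[rfe.selected_size - 1],
        ", ".join(rfe.selected_markers),
    )
    rfe.size_table().to_csv(outdir / "rfe_size_pauc.csv", index=False)
    (outdir / "selected_markers.json").write_text(json.dumps(rfe.to_json_dict(), indent=2))
    manifest.timings_s["select"] = time.perf_counter() - t

    # -- resample + evaluate ----------------------------------------------
    t = time.perf_counter()
    features = rfe.selected_markers + ([AGE_FEATURE] if config.include_age else [])
    fm_sel = fm.select(features)
    result = resample_fit(fm_sel, labels, strata, config)
    sizes = {len(s.train_idx) for s in result.splits}
    log.info("resample: %d splits, train sizes %s, tau_bar=%.6f",
             len(result.splits), sorted(sizes), result.tau_bar)
    result.per_subject_frame().to_csv(outdir / "subject_mean_scores.csv", index=False)
    result.thresholds_frame().to_csv(outdir / "split_thresholds.csv", index=False)
    report = evaluate(result, cohort.subjects, config)
    report.to_frame().to_csv(outdir / "performance_report.csv", index=False)
    report.mean_roc.to_csv(outdir / "mean_roc.csv", index=False)
    pd.Series(report.importance, name="importance").rename_axis("feature").sort_values(
        ascending=False
    ).to_csv(outdir / "importance.csv")
    (outdir / "summary.json").write_text(
        json.dumps(
            {
                "auc": report.auc,
                "auc_ci": list(report.auc_ci),
                "tau_bar": report.tau_bar,
                "selected_markers": rfe.selected_markers,
                "rows": [dataclasses.asdict(r) for r in report.rows],
            },
            indent=2,
        )
    )
    manifest.timings_s["resample_evaluate"] = time.perf_counter() - t

    manifest.outputs = sorted(str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file())
    manifest.save(outdir / "manifest.json")
    return outdir
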