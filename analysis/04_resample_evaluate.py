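#!/usr/bin/env python
"""Fit and evaluate the final classifier: 100 stratified 2/3-1/3
train/test resamples of the logistic model on the selected panel (+
age), per-subject averaged held-out scores, threshold calibration at
>99% specificity on the 61 test controls per split, and the performance
table with Wilson and bias-corrected-bootstrap intervals.

Writes the Table-1-style report, per-subject mean scores, per-split
thresholds, mean ROC and importance table under results/.
"""

import json
from pathlib import Path

import pandas as pd

from evmced import PipelineConfig, evaluate, read_feature_matrix, resample_fit
from evmced.datamodel import Subject
from evmced.preprocess import AGE_FEATURE

ROOT = Path(__file__).resolve().parent.parent / "results"


def _subjects(path, order):
    df = pd.read_csv(path, na_values=["", "NA"], keep_default_na=False)
    opt = lambda v: None if pd.isna(v) or v == "" else str(v)
    by_id = {
        str(r["id"]): Subject(
            id=str(r["id"]), group=str(r["group"]), age=float(r["age"]),
            sex=opt(r.get("sex")) or "unknown", stage=opt(r.get("stage")),
            substage=opt(r.get("substage")), histology=opt(r.get("histology")),
        )
        for _, r in df.iterrows()
    }
    return [by_id[i] for i in order]


def main(seed: int = 12) -> None:
    cfg = PipelineConfig(seed=seed)
    fm = read_feature_matrix(ROOT / "features.csv")
    subjects = _subjects(ROOT / "cohort" / "subjects.csv", fm.subject_ids)
    labels = pd.Series([int(s.is_case) for s in subjects]).to_numpy()
    strata = pd.Series([s.group for s in subjects]).to_numpy()
    panel = json.loads((ROOT / "selected_markers.json").read_text())["selected_markers"]
    fm_sel = fm.select(panel + ([AGE_FEATURE] if cfg.include_age else []))

    result = resample_fit(fm_sel, labels, strata, cfg)
    report = evaluate(result, subjects, cfg)

    report.to_frame().to_csv(ROOT / "performance_report.csv", index=False)
    result.per_subject_frame().to_csv(ROOT / "subject_mean_scores.csv", index=False)
    result.thresholds_frame().to_csv(ROOT / "split_thresholds.csv", index=False)
    report.mean_roc.to_csv(ROOT / "mean_roc.csv", index=False)
    pd.Series(report.importance, name="importance").rename_axis("feature").sort_values(
        ascending=False
    ).to_csv(ROOT / "importance.csv")

    print(f"{cfg.resamples} resamples of {len(panel)} markers + age; "
          f"average threshold {report.tau_bar:.4f}")
    print(f"AUC of per-subject mean scores: {report.auc:.3f} "
          f"(95% BC bootstrap {report.auc_ci[0]:.3f}-{report.auc_ci[1]:.3f})")
    df = report.to_frame()
    print(df.to_string(index=False,
                       formatters={c: "{:.1f}".format for c in df.columns if c.endswith("pct")}))


if __name__ == "__main__":
    main()
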