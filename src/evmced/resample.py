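"""Repeated stratified train/test resampling of the final classifier.

The engine draws R (default 100) independent 2/3-1/3 splits stratified
by cancer type, fits the logistic model on each training set, scores the
held-out subjects, and calibrates a per-split threshold at the target
specificity on the held-out controls.  Each subject's held-out
probabilities are averaged across the splits in which it was tested
("average fit"); the per-split thresholds are averaged into a global
threshold; the final call for a subject is mean score > mean threshold.
Performance (sensitivity per case sub-cohort, specificity on controls,
AUC of the mean scores) is then reported with Wilson and bias-corrected
bootstrap intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datamodel import FeatureMatrix, Subject
from .logistic import LogisticFit, fit_logistic, predict_prob, standardized_importance
from .roc import (
    auc,
    bootstrap_auc_ci,
    roc_curve,
    threshold_at_specificity,
    wilson_ci,
)

_MAX_COVERAGE_RETRIES = 5


@dataclass
class SplitResult:
    """One train/test resample: membership, fit, held-out scores, threshold."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    fit: LogisticFit
    test_probs: np.ndarray
    threshold: float


@dataclass
class ResampleResult:
    """All R splits plus the per-subject averages and final calls."""

    subject_ids: list[str]
    feature_names: list[str]
    splits: list[SplitResult]
    mean_score: np.ndarray  # NaN for subjects never held out
    n_tested: np.ndarray
    tau_bar: float

    @property
    def calls(self) -> np.ndarray:
        """Final positive call: mean held-out score above the mean threshold."""
        with np.errstate(invalid="ignore"):
            return self.mean_score > self.tau_bar

    @property
    def has_call(self) -> np.ndarray:
        return self.n_tested > 0

    def per_subject_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "n_tested": self.n_tested,
                "mean_score": self.mean_score,
                "call": self.calls,
            }
        )

    def thresholds_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "split": np.arange(len(self.splits)),
                "threshold": [s.threshold for s in self.splits],
            }
        )


@dataclass
class ReportRow:
    category: str
    n: int
    metric: str  # "sensitivity" | "specificity"
    k: int
    estimate: float
    ci_lower: float
    ci_upper: float


@dataclass
class PerformanceReport:
    """Table-style cohort/sub-cohort performance with all intervals."""

    rows: list[ReportRow]
    auc: float
    auc_ci: tuple[float, float]
    tau_bar: float
    importance: dict[str, float]
    mean_roc: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "category": r.category,
                    "n_subjects": r.n,
                    "metric": r.metric,
                    "k": r.k,
                    "estimate_pct": 100.0 * r.estimate,
                    "ci_lower_pct": 100.0 * r.ci_lower,
                    "ci_upper_pct": 100.0 * r.ci_upper,
                }
                for r in self.rows
            ]
        )

    def row(self, category: str) -> ReportRow:
        for r in self.rows:
            if r.category == category:
                return r
        raise KeyError(category)


def stratified_split(
    strata: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-stratum nearest-integer split: round(n_s * fraction) train.

    With 184 controls at fraction 2/3 this yields 123 train / 61 test.
    """
    strata = np.asarray(strata)
    train, test = [], []
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        n_train = int(np.floor(idx.size * train_fraction + 0.5))
        if n_train == 0 or n_train == idx.size:
            raise ValueError(f"stratum {s!r} too small to split (n={idx.size})")
        perm = rng.permutation(idx)
        train.append(perm[:n_train])
        test.append(perm[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def _rows(fm: FeatureMatrix, idx: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        subject_ids=[fm.subject_ids[i] for i in idx],
        feature_names=fm.feature_names,
        values=fm.values[idx],
        imputed=fm.imputed[idx],
    )


def resample_fit(
    fm: FeatureMatrix,
    labels: np.ndarray,
    strata: np.ndarray,
    config: PipelineConfig,
    seed: Optional[int] = None,
) -> ResampleResult:
    """Run the R-split resampling engine on a fixed feature set.

    ``strata`` are the cancer-type labels (controls being their own
    stratum).  If any subject is never held out across the R splits —
    possible only at very small R — the whole split sequence is redrawn
    from a fresh substream.
    """
    y = np.asarray(labels, dtype=float)
    n = fm.n_subjects
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    for attempt in range(_MAX_COVERAGE_RETRIES):
        stream = root.spawn(1)[0] if attempt else root
        split_seqs = stream.spawn(config.resamples)
        splits: list[SplitResult] = []
        prob_sum = np.zeros(n)
        n_tested = np.zeros(n, dtype=int)
        for seq in split_seqs:
            rng = np.random.default_rng(seq)
            tr, te = stratified_split(strata, config.train_fraction, rng)
            fit = fit_logistic(_rows(fm, tr), y[tr])
            probs = predict_prob(fit, _rows(fm, te))
            ctrl_probs = probs[y[te] == 0]
            tau = threshold_at_specificity(ctrl_probs, config.target_specificity)
            splits.append(
                SplitResult(train_idx=tr, test_idx=te, fit=fit, test_probs=probs, threshold=tau)
            )
            prob_sum[te] += probs
            n_tested[te] += 1
        if np.all(n_tested > 0):
            break
        root = stream
        warnings.warn(
            "some subjects never appeared in a test set; redrawing splits", stacklevel=2
        )
    else:
        warnings.warn(
            "subjects never held out after retries are excluded from metrics", stacklevel=2
        )
    with np.errstate(invalid="ignore"):
        mean_score = np.where(n_tested > 0, prob_sum / np.maximum(n_tested, 1), np.nan)
    tau_bar = float(np.mean([s.threshold for s in splits]))
    return ResampleResult(
        subject_ids=list(fm.subject_ids),
        feature_names=list(fm.feature_names),
        splits=splits,
        mean_score=mean_score,
        n_tested=n_tested,
        tau_bar=tau_bar,
    )


def _mean_roc(result: ResampleResult, labels: np.ndarray, grid_size: int = 101) -> pd.DataFrame:
    """Average held-out ROC across splits on a common FPR grid."""
    y = np.asarray(labels)
    grid = np.linspace(0.0, 1.0, grid_size)
    tprs = []
    for s in result.splits:
        y_te = y[s.test_idx]
        if len(np.unique(y_te)) < 2:
            continue
        roc = roc_curve(s.test_probs, y_te)
        tprs.append(np.interp(grid, roc.fpr, roc.tpr))
    return pd.DataFrame({"fpr": grid, "mean_tpr": np.mean(tprs, axis=0)})


def _subcohorts(subjects: Sequence[Subject]) -> list[tuple[str, str, np.ndarray]]:
    """(category, metric, member mask) rows in Table-1 order."""
    groups = np.array([s.group for s in subjects])
    stages = np.array([s.stage or "" for s in subjects])
    is_case = groups != "control"
    rows = [
        ("Controls", "specificity", ~is_case),
        ("All cancer cases", "sensitivity", is_case),
        ("Stage I", "sensitivity", is_case & (stages == "I")),
        ("Stage II", "sensitivity", is_case & (stages == "II")),
    ]
    for cancer in ("pancreatic", "ovarian", "bladder"):
        in_cancer = groups == cancer
        if not in_cancer.any():
            continue
        label = f"{cancer.capitalize()} cancer"
        rows.append((label, "sensitivity", in_cancer))
        for stage in ("I", "II"):
            mask = in_cancer & (stages == stage)
            if mask.any():
                rows.append((f"{label}, stage {stage}", "sensitivity", mask))
        substages = np.array([s.substage or "" for s in subjects])
        for sub in sorted({s.substage for s, m in zip(subjects, in_cancer) if m and s.substage}):
            rows.append((f"{label}, stage {sub}", "sensitivity", in_cancer & (substages == sub)))
        hists = np.array([s.histology or "" for s in subjects])
        for h in sorted({s.histology for s, m in zip(subjects, in_cancer) if m and s.histology}):
            rows.append((f"{label}, {h} histology", "sensitivity", in_cancer & (hists == h)))
    return rows


def evaluate(
    result: ResampleResult,
    subjects: Sequence[Subject],
    config: PipelineConfig,
    seed: Optional[int] = None,
) -> PerformanceReport:
    """Final calls at the average threshold, per-sub-cohort performance
    with Wilson intervals, and AUC of the mean scores with a BC
    bootstrap interval."""
    subjects = list(subjects)
    if [s.id for s in subjects] != result.subject_ids:
        raise ValueError("subject order does not match the resample result")
    labels = np.array([int(s.is_case) for s in subjects])
    usable = result.has_call
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} subjects without held-out scores excluded", stacklevel=2
        )
    calls = result.calls
    rows: list[ReportRow] = []
    for category, metric, mask in _subcohorts(subjects):
        mask = mask & usable
        n_sub = int(mask.sum())
        if n_sub == 0:
            warnings.warn(f"empty sub-cohort {category!r} omitted", stacklevel=2)
            continue
        correct = calls[mask] if metric == "sensitivity" else ~calls[mask]
        k = int(correct.sum())
        ci = wilson_ci(k, n_sub, config.ci_level)
        rows.append(
            ReportRow(
                category=category,
                n=n_sub,
                metric=metric,
                k=k,
                estimate=k / n_sub,
                ci_lower=ci.lower,
                ci_upper=ci.upper,
            )
        )
    scores = result.mean_score[usable]
    y = labels[usable]
    overall_auc = auc(roc_curve(scores, y))
    boot_seed = np.random.SeedSequence(
        [config.seed if seed is None else seed, 0xB00])
    auc_ci = bootstrap_auc_ci(
        scores, y, B=config.bootstrap_B, level=config.ci_level, seed=boot_seed
    )
    importance = standardized_importance([s.fit for s in result.splits])
    return PerformanceReport(
        rows=rows,
        auc=float(overall_auc),
        auc_ci=auc_ci,
        tau_bar=result.tau_bar,
        importance=importance,
        mean_roc=_mean_roc(result, labels),
    )


def compare_feature_sets(
    fm_a: FeatureMatrix,
    fm_b: FeatureMatrix,
    labels: np.ndarray,
    strata: np.ndarray,
    config: PipelineConfig,
    seed: Optional[int] = None,
) -> dict:
    """Resample both feature tables with identical split sequences and
    report the two AUCs side by side (e.g. EV proteins vs free proteins)."""
    if fm_a.subject_ids != fm_b.subject_ids:
        raise ValueError("feature matrices must cover the same subjects in order")
    res_a = resample_fit(fm_a, labels, strata, config, seed=seed)
    res_b = resample_fit(fm_b, labels, strata, config, seed=seed)
    y = np.asarray(labels)
    out = {}
    for tag, res in (("a", res_a), ("b", res_b)):
        usable = res.has_call
        s, yy = res.mean_score[usable], y[usable]
        out[f"auc_{tag}"] = auc(roc_curve(s, yy))
        out[f"auc_ci_{tag}"] = bootstrap_auc_ci(
            s, yy, B=config.bootstrap_B, level=config.ci_level,
            seed=np.random.SeedSequence([config.seed if seed is None else seed, 0xC0, ord(tag)]),
        )
        out[f"result_{tag}"] = res
    return out
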