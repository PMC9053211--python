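"""ROC machinery: curves, AUC, partial AUC over a specificity band,
specificity-anchored thresholds, Wilson intervals, and bias-corrected
bootstrap AUC intervals.

Conventions
-----------
* Higher score means more case-like; a subject is called positive when
  its score is strictly greater than the threshold (ties at the
  threshold are negative calls).
* Partial AUC is the raw (unnormalised) trapezoidal area of TPR over
  the FPR interval implied by the specificity band, with linear
  interpolation at the band edges; its maximum is the band width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint


@dataclass
class RocCurve:
    """Ordered (fpr, tpr, threshold) points from (0,0) to (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC points must be non-decreasing")
        if not (self.fpr[0] == 0 and self.tpr[0] == 0 and self.fpr[-1] == 1 and self.tpr[-1] == 1):
            raise ValueError("ROC curve must run from (0,0) to (1,1)")


@dataclass
class BinomialCI:
    """A binomial proportion with its two-sided Wilson score interval."""

    k: int
    n: int
    level: float
    lower: float
    upper: float

    @property
    def estimate(self) -> float:
        return self.k / self.n


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """Empirical ROC curve; tied scores collapse into a single step."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, n_pos=n_pos, n_neg=n_neg)


def auc(roc: RocCurve) -> float:
    """Trapezoidal area; equals the tie-corrected Mann-Whitney probability."""
    return float(np.trapezoid(roc.tpr, roc.fpr))


def partial_auc(roc: RocCurve, spec_lo: float, spec_hi: float) -> float:
    """Raw area of TPR over FPR in [1 - spec_hi, 1 - spec_lo].

    Additive over adjoining bands; over [0, 1] it equals :func:`auc`.
    The chance diagonal over the band [0.75, 1.00] yields 0.03125.
    """
    if not (0.0 <= spec_lo < spec_hi <= 1.0):
        raise ValueError(f"invalid specificity band [{spec_lo}, {spec_hi}]")
    f_lo, f_hi = 1.0 - spec_hi, 1.0 - spec_lo
    f, t = roc.fpr, roc.tpr
    area = 0.0
    for i in range(len(f) - 1):
        x0, x1 = f[i], f[i + 1]
        if x1 <= f_lo or x0 >= f_hi or x1 == x0:
            continue
        xa, xb = max(x0, f_lo), min(x1, f_hi)
        slope = (t[i + 1] - t[i]) / (x1 - x0)
        ya = t[i] + slope * (xa - x0)
        yb = t[i] + slope * (xb - x0)
        area += (xb - xa) * (ya + yb) / 2.0
    return float(area)


def threshold_at_specificity(control_scores: np.ndarray, target: float) -> float:
    """Smallest threshold calling at most a (1 - target) fraction of
    controls positive under the strict ``score > threshold`` rule.

    With n controls this permits ``floor(n * (1 - target))`` positive
    calls; with 61 controls and target 0.99 that is zero, so the
    threshold is the maximum control score and all 61 are called
    negative.
    """
    s = np.sort(np.asarray(control_scores, dtype=float))[::-1]
    n = s.size
    if n == 0:
        raise ValueError("control scores must be non-empty")
    if not (0.0 < target <= 1.0):
        raise ValueError("target specificity must be in (0, 1]")
    # tolerance so e.g. n=10, target=0.9 yields exactly 1 permitted positive
    # despite 1 - 0.9 rounding below 0.1 in binary floating point
    m = min(int(np.floor(n * (1.0 - target) + 1e-9)), n - 1)
    return float(s[m])


def sensitivity_specificity(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[float, float]:
    """(sensitivity, specificity) of the strict ``> threshold`` rule."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores > threshold
    sens = float(np.mean(pos[labels == 1])) if np.any(labels == 1) else np.nan
    spec = float(np.mean(~pos[labels == 0])) if np.any(labels == 0) else np.nan
    return sens, spec


def wilson_ci(k: int, n: int, level: float = 0.95) -> BinomialCI:
    """Two-sided Wilson score interval for k successes in n trials."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    lower, upper = proportion_confint(k, n, alpha=1.0 - level, method="wilson")
    return BinomialCI(k=int(k), n=int(n), level=level, lower=float(lower), upper=float(upper))


def _auc_fast(case_scores: np.ndarray, control_scores: np.ndarray) -> float:
    """Tie-corrected Mann-Whitney AUC via ranks (used inside the bootstrap)."""
    from scipy.stats import rankdata

    n1, n0 = case_scores.size, control_scores.size
    ranks = rankdata(np.concatenate([case_scores, control_scores]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _bootstrap_aucs(
    case: np.ndarray, ctrl: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    """Stratified-bootstrap AUC replicates, vectorised over B.

    A with-replacement resample of each class is equivalent to drawing
    multinomial counts over the original observations; the replicate AUC
    is then a bilinear form in those counts against the pairwise
    win/tie matrix.
    """
    n1, n0 = case.size, ctrl.size
    # pairwise comparison matrix: 1 win, 0.5 tie (n1 x n0)
    M = (case[:, None] > ctrl[None, :]) + 0.5 * (case[:, None] == ctrl[None, :])
    C1 = rng.multinomial(n1, np.full(n1, 1.0 / n1), size=B).astype(float)
    C0 = rng.multinomial(n0, np.full(n0, 1.0 / n0), size=B).astype(float)
    return np.einsum("bi,bi->b", C1, C0 @ M.T) / (n1 * n0)


def bootstrap_auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    B: int = 2000,
    level: float = 0.95,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, float]:
    """Bias-corrected (BC) percentile bootstrap interval for the AUC.

    Cases and controls are resampled separately (stratified, preserving
    class counts).  The median-bias correction is
    ``z0 = Phi^-1(frac of bootstrap AUCs below the observed AUC)``; no
    acceleration term.  Deterministic given ``seed``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    case = scores[labels == 1]
    ctrl = scores[labels == 0]
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    obs = _auc_fast(case, ctrl)
    boot = _bootstrap_aucs(case, ctrl, B, rng)
    if boot.min() == boot.max():
        warnings.warn("degenerate bootstrap distribution; point interval", stacklevel=2)
        return float(boot[0]), float(boot[0])
    frac_below = np.clip(np.mean(boot < obs), 1.0 / (B + 1), B / (B + 1.0))
    z0 = norm.ppf(frac_below)
    z = norm.ppf(0.5 + level / 2.0)
    a_lo = norm.cdf(2.0 * z0 - z)
    a_hi = norm.cdf(2.0 * z0 + z)
    lower, upper = np.quantile(boot, [a_lo, a_hi])
    return float(lower), float(upper)
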