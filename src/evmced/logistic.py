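"""Unpenalized binomial logistic regression via IRLS, with
standardized-coefficient importance.

The fitter is deliberately plain maximum likelihood: penalties would
distort the standardized coefficients used for marker importance and
for the elimination ranking.  Near-separable training splits (routine in
a >99%-specificity regime) are handled by capping linear predictors at
+/-30 and flagging the fit as non-converged instead of aborting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .datamodel import FeatureMatrix

_ETA_CAP = 30.0
_MAX_ITER = 100
_SCORE_TOL = 1e-8


@dataclass
class LogisticFit:
    """Fitted coefficients plus the training moments used for standardization."""

    feature_names: list[str]
    coef: np.ndarray
    intercept: float
    converged: bool
    n_iter: int
    feature_means: np.ndarray
    feature_sds: np.ndarray

    def __post_init__(self) -> None:
        if len(self.feature_names) != self.coef.size:
            raise ValueError("coefficient count must equal feature count")
        if self.converged and not np.all(np.isfinite(self.coef)):
            raise ValueError("converged fit has non-finite coefficients")

    def standardized_coef(self) -> np.ndarray:
        """beta_j * sd_j: coefficient per standard deviation of feature j."""
        return self.coef * self.feature_sds

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.coef


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    beta0: Optional[np.ndarray] = None,
    max_iter: int = _MAX_ITER,
    tol: float = _SCORE_TOL,
) -> tuple[np.ndarray, bool, int]:
    """Newton-Raphson / IRLS on the design with intercept column prepended.

    Convergence when the score (log-likelihood gradient) has max
    absolute entry below ``tol``.  Linear predictors are capped at
    +/-30 inside the weight computation; a fit whose predictors sit at
    the cap is flagged non-converged (quasi-separation).
    """
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1) if beta0 is None else beta0.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(Xd @ beta, -_ETA_CAP, _ETA_CAP)
        mu = expit(eta)
        score = Xd.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        H = (Xd * w[:, None]).T @ Xd
        H[np.diag_indices_from(H)] += 1e-12  # numerical safeguard
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        beta = beta + step
    if converged:
        eta = np.clip(Xd @ beta, -_ETA_CAP, _ETA_CAP)
        # a vanishing score with every training point fitted to within
        # 1e-6 of its label means separation, not a finite MLE
        if np.max(np.abs(y - expit(eta))) < 1e-6 or np.max(np.abs(Xd @ beta)) >= _ETA_CAP:
            converged = False
    return beta, converged, it


def fit_logistic(
    fm: FeatureMatrix,
    labels: np.ndarray,
    warm_start: Optional[LogisticFit] = None,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of case/control labels on ``fm``.

    Constant features are dropped (with a warning) and given a zero
    coefficient in the returned fit so the feature surface is preserved.
    """
    y = np.asarray(labels, dtype=float)
    if y.size != fm.n_subjects:
        raise ValueError("label length must match subject count")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    X = fm.values
    sds = X.std(axis=0, ddof=0)
    means = X.mean(axis=0)
    keep = sds > 0
    if not np.all(keep):
        dropped = [n for n, k in zip(fm.feature_names, keep) if not k]
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
    beta0 = None
    if warm_start is not None:
        # match by name so a superset fit can seed a reduced model (RFE path)
        lookup = dict(zip(warm_start.feature_names, warm_start.coef))
        seed_coef = np.array([lookup.get(n, 0.0) for n in fm.feature_names])
        if np.all(np.isfinite(seed_coef)) and np.isfinite(warm_start.intercept):
            beta0 = np.concatenate([[warm_start.intercept], seed_coef[keep]])
    beta, converged, n_iter = _irls(X[:, keep], y, beta0=beta0)
    coef = np.zeros(X.shape[1])
    coef[keep] = beta[1:]
    return LogisticFit(
        feature_names=list(fm.feature_names),
        coef=coef,
        intercept=float(beta[0]),
        converged=converged,
        n_iter=n_iter,
        feature_means=means,
        feature_sds=sds,
    )


def predict_prob(fit: LogisticFit, fm: FeatureMatrix) -> np.ndarray:
    """P(case) per subject; linear predictors capped as in fitting."""
    if fit.feature_names != fm.feature_names:
        raise ValueError(
            f"feature mismatch: fit has {fit.feature_names}, matrix has {fm.feature_names}"
        )
    eta = np.clip(fit.linear_predictor(fm.values), -_ETA_CAP, _ETA_CAP)
    return expit(eta)


def log_likelihood(fit: LogisticFit, fm: FeatureMatrix, labels: np.ndarray) -> float:
    y = np.asarray(labels, dtype=float)
    eta = np.clip(fit.linear_predictor(fm.values), -_ETA_CAP, _ETA_CAP)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def standardized_importance(fits: Sequence[LogisticFit]) -> dict[str, float]:
    """Mean absolute standardized coefficient per feature, rescaled to max 100.

    The rescaling is presentational; the relative ordering is the
    contract.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("need at least one fit")
    names = fits[0].feature_names
    for f in fits[1:]:
        if f.feature_names != names:
            raise ValueError("fits do not share a feature set")
    raw = np.mean([np.abs(f.standardized_coef()) for f in fits], axis=0)
    top = raw.max()
    scaled = raw * (100.0 / top) if top > 0 else raw
    return dict(zip(names, scaled.astype(float)))
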