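"""Recursive feature elimination with repeated stratified K-fold
cross-validation, selecting the marker subset that maximizes held-out
partial AUC over the configured specificity band.

Within every repetition a fresh class-stratified K-fold partition is
drawn.  For each held-out fold, a full logistic model is fitted on the
remaining folds and markers are removed one at a time — weakest first by
absolute standardized coefficient, re-fitting after every removal (true
stepwise backwards elimination) — recording the marker set of every
size and its partial AUC on the held-out fold.  The selected size is
the one maximizing the mean held-out pAUC across all repetitions and
folds (ties to the smaller panel); the selected markers are the
top-ranked ones at that size under mean elimination-order rank.

Age, when present in the feature matrix, sits in every model and is
exempt from elimination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .config import PipelineConfig
from .datamodel import FeatureMatrix
from .logistic import _ETA_CAP, _irls
from .preprocess import AGE_FEATURE
from .roc import partial_auc, roc_curve
from scipy.special import expit


@dataclass
class RfeResult:
    """Aggregated elimination traces across all repetitions and folds.

    ``pauc[r, f, s-1]`` is the held-out pAUC of the size-``s`` model in
    repetition ``r``, fold ``f``.  ``mean_rank`` maps each marker to its
    mean elimination-order rank (1 = last survivor, higher = eliminated
    earlier); the selected set is the ``selected_size`` best-ranked
    markers.
    """

    marker_names: list[str]
    sizes: np.ndarray
    pauc: np.ndarray  # (reps, folds, n_sizes)
    mean_pauc: np.ndarray  # per size
    selected_size: int
    selected_markers: list[str]
    mean_rank: dict[str, float]
    folds: list[list[tuple[np.ndarray, np.ndarray]]]

    def size_table(self) -> pd.DataFrame:
        return pd.DataFrame({"size": self.sizes, "mean_pauc": self.mean_pauc})

    def to_json_dict(self) -> dict:
        return {
            "selected_size": int(self.selected_size),
            "selected_markers": list(self.selected_markers),
            "mean_rank": {k: float(v) for k, v in self.mean_rank.items()},
            "mean_pauc_by_size": {
                int(s): float(p) for s, p in zip(self.sizes, self.mean_pauc)
            },
        }


def _elimination_path(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    y_te: np.ndarray,
    n_markers: int,
    n_fixed: int,
    spec_lo: float,
    spec_hi: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One backwards-elimination pass on a single train/test fold.

    Marker columns come first, fixed covariates (age) last.  Returns
    (pauc_by_size[size-1], elimination_rank per marker) where the rank
    equals the size of the model the marker was eliminated from.
    """
    sds = X_tr.std(axis=0)
    active = list(range(n_markers))
    fixed = list(range(n_markers, n_markers + n_fixed))
    beta = None  # [intercept, coefs aligned to active + fixed]
    pauc_by_size = np.full(n_markers, np.nan)
    rank = np.zeros(n_markers, dtype=float)
    while active:
        cols = active + fixed
        beta, _, _ = _irls(X_tr[:, cols], y_tr, beta0=beta)
        eta = np.clip(beta[0] + X_te[:, cols] @ beta[1:], -_ETA_CAP, _ETA_CAP)
        size = len(active)
        pauc_by_size[size - 1] = partial_auc(
            roc_curve(expit(eta), y_te), spec_lo, spec_hi
        )
        # weakest marker by |standardized coefficient|; ties by column index
        std = np.abs(beta[1 : 1 + size]) * sds[active]
        weakest_pos = int(np.argmin(std))
        rank[active[weakest_pos]] = size
        del active[weakest_pos]
        beta = np.delete(beta, 1 + weakest_pos)
    return pauc_by_size, rank


def rfe_select(
    fm: FeatureMatrix,
    labels: np.ndarray,
    config: PipelineConfig,
    seed: Optional[int] = None,
    strata: Optional[np.ndarray] = None,
) -> RfeResult:
    """Run the repeated-CV recursive elimination and pick the marker panel.

    ``strata`` (e.g. cancer-type labels) refines the case/control fold
    stratification when given.  Deterministic given the seed: each
    repetition draws its fold partition from an independent substream of
    the root seed.
    """
    y = np.asarray(labels, dtype=float)
    markers = [n for n in fm.feature_names if n != AGE_FEATURE]
    if len(markers) < 2:
        raise ValueError("need at least 2 markers for elimination")
    fixed = [n for n in fm.feature_names if n == AGE_FEATURE]
    X = fm.select(markers + fixed).values
    n_markers, n_fixed = len(markers), len(fixed)
    strat_labels = np.asarray(strata) if strata is not None else y
    _, strat_counts = np.unique(strat_labels, return_counts=True)
    if np.min(strat_counts) < config.cv_folds:
        raise ValueError(
            f"smallest stratum ({np.min(strat_counts)}) is below cv_folds={config.cv_folds}"
        )

    root = np.random.SeedSequence(config.seed if seed is None else seed)
    rep_seqs = root.spawn(config.rfe_reps)
    pauc = np.full((config.rfe_reps, config.cv_folds, n_markers), np.nan)
    rank_sum = np.zeros(n_markers)
    folds_record: list[list[tuple[np.ndarray, np.ndarray]]] = []
    for r, seq in enumerate(rep_seqs):
        skf = StratifiedKFold(
            n_splits=config.cv_folds,
            shuffle=True,
            random_state=int(seq.generate_state(1)[0] % (2**32 - 1)),
        )
        rep_folds = []
        for f, (tr, te) in enumerate(skf.split(X, strat_labels)):
            pauc[r, f], rank = _elimination_path(
                X[tr], y[tr], X[te], y[te], n_markers, n_fixed,
                config.pauc_spec_lo, config.pauc_spec_hi,
            )
            rank_sum += rank
            rep_folds.append((tr, te))
        folds_record.append(rep_folds)

    mean_pauc = pauc.mean(axis=(0, 1))
    sizes = np.arange(1, n_markers + 1)
    # argmax with ties resolved toward the smaller panel
    best = sizes[np.flatnonzero(mean_pauc == mean_pauc.max())[0]]
    mean_rank = rank_sum / (config.rfe_reps * config.cv_folds)
    order = sorted(range(n_markers), key=lambda j: (mean_rank[j], markers[j]))
    selected = sorted(markers[j] for j in order[: int(best)])
    return RfeResult(
        marker_names=markers,
        sizes=sizes,
        pauc=pauc,
        mean_pauc=mean_pauc,
        selected_size=int(best),
        selected_markers=selected,
        mean_rank={markers[j]: float(mean_rank[j]) for j in range(n_markers)},
        folds=folds_record,
    )
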