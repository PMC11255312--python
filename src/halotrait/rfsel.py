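"""Random-forest ranking of pathways against salinity and cross-validated
biomarker-count selection.

Forests predict EC from pathway abundances (the direction compatible with
feature importance); the iteration/aggregation loop and the CV count rule
live here while tree fitting is delegated to scikit-learn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

logger = logging.getLogger("halotrait")


@dataclass
class BiomarkerResult:
    group: str
    importances: pd.DataFrame  # pathway, mean_importance (sorted descending)
    per_iteration: np.ndarray | None = None  # iterations x pathways
    cv_error: list[float] = field(default_factory=list)
    cv_se: list[float] = field(default_factory=list)
    selected_count: int | None = None
    seed: int | None = None

    @property
    def ranked_pathways(self) -> list[str]:
        return self.importances["pathway"].tolist()

    def selected_pathways(self) -> list[str]:
        if self.selected_count is None:
            raise ValueError("run cv_select_count first")
        return self.ranked_pathways[: self.selected_count]


def _iteration_seed(seed: int, iteration: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(iteration,))
    return int(ss.generate_state(1)[0])


def rf_rank(
    pathway_matrix: pd.DataFrame,
    ec: np.ndarray,
    n_trees: int = 1000,
    iterations: int = 100,
    seed: int = 0,
    group: str = "",
) -> BiomarkerResult:
    """Rank pathways by mean impurity-decrease importance over repeated
    forest fits (distinct derived seed per iteration)."""
    ec = np.asarray(ec, dtype=float)
    if len(pathway_matrix) < 10:
        raise ValueError("need >= 10 samples")
    if pathway_matrix.shape[1] < 2:
        raise ValueError("need >= 2 pathways")
    if np.ptp(ec) == 0:
        raise ValueError("EC is constant")
    # canonical column order so input column permutations cannot affect
    # the fitted forests (sklearn tree draws depend on feature order)
    pathway_matrix = pathway_matrix[sorted(pathway_matrix.columns)]
    X = pathway_matrix.to_numpy(dtype=float)
    variances = X.var(axis=0)
    keep = variances > 0
    if not keep.all():
        dropped = pathway_matrix.columns[~keep].tolist()
        logger.warning("dropping %d zero-variance pathway(s): %s",
                       len(dropped), dropped[:5])
        X = X[:, keep]
    cols = pathway_matrix.columns[keep].tolist()
    per_iter = np.zeros((iterations, len(cols)))
    for it in range(iterations):
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            random_state=_iteration_seed(seed, it),
            n_jobs=1,
        )
        rf.fit(X, ec)
        per_iter[it] = rf.feature_importances_
    mean_imp = per_iter.mean(axis=0)
    imp = (
        pd.DataFrame({"pathway": cols, "mean_importance": mean_imp})
        .sort_values(
            ["mean_importance", "pathway"], ascending=[False, True]
        )
        .reset_index(drop=True)
    )
    return BiomarkerResult(group=group, importances=imp,
                           per_iteration=per_iter, seed=seed)


def cv_select_count(
    result: BiomarkerResult,
    pathway_matrix: pd.DataFrame,
    ec: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    n_trees: int = 100,
    k_max: int | None = None,
    rule: str = "1se",
) -> BiomarkerResult:
    """Cross-validated MSE for forests on the top-k ranked pathways,
    k = 1..k_max; selected_count by the 1-SE rule (or the plain minimum)."""
    ec = np.asarray(ec, dtype=float)
    n = len(pathway_matrix)
    if folds > n:
        raise ValueError(f"folds ({folds}) > samples ({n})")
    ranked = result.ranked_pathways
    k_max = min(k_max or len(ranked), len(ranked))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed % (2**32))
    splits = list(kf.split(pathway_matrix))
    curve, ses = [], []
    for k in range(1, k_max + 1):
        X = pathway_matrix[ranked[:k]].to_numpy(dtype=float)
        fold_mse = []
        for f, (tr, te) in enumerate(splits):
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                random_state=_iteration_seed(seed, 10_000 + k * 100 + f),
                n_jobs=1,
            )
            rf.fit(X[tr], ec[tr])
            pred = rf.predict(X[te])
            fold_mse.append(float(np.mean((pred - ec[te]) ** 2)))
        curve.append(float(np.mean(fold_mse)))
        ses.append(float(np.std(fold_mse, ddof=1) / np.sqrt(len(fold_mse))))
    best = int(np.argmin(curve))
    if rule == "min":
        selected = best + 1
    elif rule == "1se":
        threshold = curve[best] + ses[best]
        selected = next(
            k + 1 for k, e in enumerate(curve) if e <= threshold
        )
    else:
        raise ValueError(f"unknown rule: {rule}")
    result.cv_error = curve
    result.cv_se = ses
    result.selected_count = selected
    return result
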