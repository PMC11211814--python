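"""Variable selection: attribution prefilter, greedy forward selection, and
permutation variable importance (PVIM), with cross-split consensus.

Attributions come from LightGBM's exact per-sample tree-SHAP
(``pred_contrib``). Importances of every engineered feature derived from a
variable are aggregated (summed) before ranking, since selection acts on
clinical variables, not on individual feature columns. PVIM permutes all
feature columns of a variable jointly within the validation split and
measures the drop in sample-level average precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from .grid_features import FeatureMatrix
from .models import FittedModel, GBDTParams, StackedModel, fit_variant

__all__ = [
    "ImportanceRanking", "attribution_rank", "greedy_forward_select",
    "pvim", "consensus",
]


@dataclass
class ImportanceRanking:
    """Per-variable importance scores, sorted descending."""

    table: pd.DataFrame  # columns: variable, score, rank

    @property
    def variables(self) -> list[str]:
        return list(self.table["variable"])

    def top(self, k: int) -> set[str]:
        return set(self.table["variable"].head(k))


def _contributions(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    contrib = model.booster.booster_.predict(X[model.feature_cols],
                                             pred_contrib=True)
    return contrib[:, :-1]  # drop the expected-value column


def attribution_rank(model: FittedModel, X_val: pd.DataFrame,
                     manifest: dict[str, str], k: int | None = None) -> ImportanceRanking:
    """Rank variables by mean absolute per-sample attribution, summed over
    all feature columns derived from each variable."""
    contrib = np.abs(_contributions(model, X_val)).mean(axis=0)
    scores: dict[str, float] = {}
    for col, c in zip(model.feature_cols, contrib):
        var = manifest.get(col, col)
        scores[var] = scores.get(var, 0.0) + float(c)
    table = (pd.DataFrame({"variable": list(scores), "score": list(scores.values())})
             .sort_values("score", ascending=False, kind="stable")
             .reset_index(drop=True))
    table["rank"] = np.arange(1, len(table) + 1)
    if k is not None:
        table = table.head(min(k, len(table)))
    return ImportanceRanking(table)


def _cols_of(variables, manifest: dict[str, str], all_cols) -> list[str]:
    vars_set = set(variables)
    return [c for c in all_cols if manifest.get(c, c) in vars_set]


def greedy_forward_select(fm: FeatureMatrix, train_ids, val_ids, candidates,
                          params: GBDTParams | None = None, variant: str = "snapshot",
                          tolerance: float = 0.01) -> tuple[list[str], pd.DataFrame]:
    """Greedy forward selection over candidate variables, guided by
    validation-set average precision.

    Iteratively adds the candidate maximizing validation AP; returns the
    shortest prefix whose AP is within ``tolerance`` of the best AP over all
    prefix lengths, together with the full selection trajectory.
    """
    if not candidates:
        raise ValueError("no candidate variables")
    p = params or GBDTParams()
    f = fm.frame
    usable = f[f["valid"]]
    val = usable[usable["stay_id"].isin(set(val_ids))]
    y_val = val["label"].to_numpy()

    selected: list[str] = []
    remaining = list(candidates)
    trajectory = []
    while remaining:
        best_var, best_ap = None, -np.inf
        for var in remaining:
            cols = _cols_of(selected + [var], fm.manifest, fm.feature_cols(variant))
            sub = _SubsetMatrix(fm, cols)
            model = fit_variant(sub, train_ids, val_ids, "snapshot", p, calibrate=False)
            ap = average_precision_score(y_val, model.raw_scores(val))
            if ap > best_ap:
                best_var, best_ap = var, ap
        selected.append(best_var)
        remaining.remove(best_var)
        trajectory.append({"variable": best_var, "val_ap": best_ap})
    traj = pd.DataFrame(trajectory)
    best = traj["val_ap"].max()
    enough = traj["val_ap"] >= (1.0 - tolerance) * best
    k = int(np.argmax(enough.to_numpy())) + 1
    return list(traj["variable"].head(k)), traj


class _SubsetMatrix(FeatureMatrix):
    """Feature-matrix view restricted to a column subset."""

    def __init__(self, fm: FeatureMatrix, cols: list[str]):
        super().__init__(fm.frame, cols, [], fm.manifest, fm.label_horizon_h)


def pvim(model: FittedModel | StackedModel, X_val: pd.DataFrame, y_val,
         manifest: dict[str, str], n_repeats: int = 5, seed: int = 0) -> ImportanceRanking:
    """Permutation variable importance: mean drop in validation average
    precision when all feature columns of a variable are permuted jointly
    (one shared row permutation per repeat)."""
    rng = np.random.default_rng(seed)
    y_val = np.asarray(y_val)
    base = average_precision_score(y_val, model.raw_scores(X_val))
    variables = sorted({manifest.get(c, c) for c in model.feature_cols})
    rows = []
    for var in variables:
        cols = _cols_of([var], manifest, model.feature_cols)
        drops = []
        for _ in range(n_repeats):
            perm = rng.permutation(len(X_val))
            X_perm = X_val.copy()
            X_perm[cols] = X_val[cols].to_numpy()[perm]
            drops.append(base - average_precision_score(y_val, model.raw_scores(X_perm)))
        rows.append({"variable": var, "score": float(np.mean(drops)),
                     "se": float(np.std(drops, ddof=1) / np.sqrt(n_repeats))
                     if n_repeats > 1 else np.nan})
    table = (pd.DataFrame(rows).sort_values("score", ascending=False, kind="stable")
             .reset_index(drop=True))
    table["rank"] = np.arange(1, len(table) + 1)
    return ImportanceRanking(table)


def consensus(sets, mode: str = "intersect") -> set:
    """Cross-split consensus of variable sets."""
    sets = [set(s) for s in sets]
    if not sets:
        raise ValueError("need at least one set")
    if mode == "intersect":
        return set.intersection(*sets)
    if mode == "union":
        return set.union(*sets)
    raise ValueError(f"unknown consensus mode {mode!r}")
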