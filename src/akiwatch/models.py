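"""Gradient-boosted AKI risk models.

Three variants are supported:

* ``snapshot`` — the current patient state only (partially imputed current
  values, demographics, time since admission),
* ``history`` — snapshot plus multi-scale summary statistics and
  measurement-history features,
* either of the above *time-stacked*: 49 sub-models, one per full hour of
  the first 48 h since admission plus one for all later time points, each
  trained only on samples from its bucket, then jointly calibrated with a
  single pooled isotonic map fitted on the validation set. Stacking
  conditions the task on the phase of the ICU stay, which matters because
  the feature-outcome relationship shifts with time since admission.

All boosters are LightGBM with early stopping on validation-set AUPRC.
Training rows are subsampled to one grid point per 30 min (stride 6) to
limit the near-duplicate 5-min rows; prediction always runs on the full
grid. The LSTM-style sequence models from the literature are out of scope,
but anything implementing ``predict_frame`` plugs into the evaluation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .grid_features import FeatureMatrix

__all__ = [
    "N_BUCKETS", "GBDTParams", "FittedModel", "StackedModel",
    "assign_bucket", "fit_isotonic", "fit_variant", "fit_time_stacked",
    "predict_risk", "risk_by_stay", "save_model", "load_model",
]

N_BUCKETS = 49  # one per hour 0..47, plus one for >= 48 h


@dataclass(frozen=True)
class GBDTParams:
    num_leaves: int = 7
    n_estimators: int = 300
    learning_rate: float = 0.08
    min_child_samples: int = 40
    early_stopping_rounds: int = 30
    bucket_overlap_h: float = 2.0     # sub-models train on bucket +/- overlap
    min_bucket_samples: int = 8000    # sparse buckets borrow further neighbors
    min_bucket_positives: int = 500   # ... and need this many positive rows
    bucket_n_estimators: int = 150    # sub-models use a fixed booster size
    train_stride: int = 6             # keep every 6th grid row (30 min)
    stacked_train_stride: int = 1     # sub-models use all rows of their bucket
    risk_smooth_h: float = 2.0        # trailing-mean smoothing of risk
    seed: int = 0

    def lgbm_kwargs(self) -> dict:
        return dict(
            num_leaves=self.num_leaves,
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            min_child_samples=self.min_child_samples,
            random_state=self.seed,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            verbosity=-1,
        )


def assign_bucket(time_since_admission) -> np.ndarray | int:
    """Hourly bucket index: floor(hours) below 48 h, else 48."""
    t = np.asarray(time_since_admission, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since admission must be non-negative")
    b = np.minimum(np.floor(t).astype(int), N_BUCKETS - 1)
    return int(b) if b.ndim == 0 else b


def fit_isotonic(raw_scores, labels) -> IsotonicRegression:
    """Least-squares monotone step function (pool-adjacent-violators)."""
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(np.asarray(raw_scores, dtype=float), np.asarray(labels, dtype=float))
    return iso


@dataclass
class FittedModel:
    """Single (joint) booster with an isotonic calibration map."""

    booster: lgb.LGBMClassifier
    feature_cols: list[str]
    variant: str
    calibrator: IsotonicRegression | None = None
    params: GBDTParams = field(default_factory=GBDTParams)

    def raw_scores(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_cols if c not in X.columns]
        if missing:
            raise ValueError(f"feature manifest mismatch; missing columns: {missing}")
        return self.booster.predict_proba(X[self.feature_cols])[:, 1]

    def predict_frame(self, fm: FeatureMatrix) -> pd.DataFrame:
        return predict_risk(self, fm)


@dataclass
class StackedModel:
    """49 time-bucket sub-models plus one shared isotonic calibration map."""

    models: dict[int, lgb.LGBMClassifier]
    feature_cols: list[str]
    variant: str
    calibrator: IsotonicRegression | None = None
    params: GBDTParams = field(default_factory=GBDTParams)

    def raw_scores(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_cols if c not in X.columns]
        if missing:
            raise ValueError(f"feature manifest mismatch; missing columns: {missing}")
        buckets = assign_bucket(X["time_since_admission"].to_numpy())
        out = np.full(len(X), np.nan)
        for b, model in self.models.items():
            mask = buckets == b
            if mask.any():
                out[mask] = model.predict_proba(X.loc[mask, self.feature_cols])[:, 1]
        return out

    def predict_frame(self, fm: FeatureMatrix) -> pd.DataFrame:
        return predict_risk(self, fm)


def _strided(frame: pd.DataFrame, stride: int) -> pd.DataFrame:
    if stride <= 1:
        return frame
    pos = frame.groupby("stay_id").cumcount()
    return frame[pos % stride == 0]


def _split_frames(fm: FeatureMatrix, train_ids, val_ids,
                  stride: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    f = fm.frame
    usable = f[f["valid"]]
    train = _strided(usable[usable["stay_id"].isin(set(train_ids))], stride)
    val = _strided(usable[usable["stay_id"].isin(set(val_ids))], stride)
    return train, val


def _fit_booster(X_tr, y_tr, X_val, y_val, params: GBDTParams) -> lgb.LGBMClassifier:
    clf = lgb.LGBMClassifier(**params.lgbm_kwargs())
    if y_val is not None and len(np.unique(y_val)) > 1:
        clf.fit(X_tr, y_tr, eval_set=[(X_val, y_val)],
                eval_metric="average_precision",
                callbacks=[lgb.early_stopping(params.early_stopping_rounds, verbose=False),
                           lgb.log_evaluation(0)])
    else:
        clf.fit(X_tr, y_tr)
    return clf


def fit_variant(fm: FeatureMatrix, train_ids, val_ids, variant: str = "snapshot",
                params: GBDTParams | None = None, calibrate: bool = True) -> FittedModel:
    """Single booster over all time points (the 'joint' model)."""
    p = params or GBDTParams()
    cols = fm.feature_cols(variant)
    train, val = _split_frames(fm, train_ids, val_ids, p.train_stride)
    y_tr = train["label"].to_numpy()
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training labels are single-class; cannot fit")
    clf = _fit_booster(train[cols], y_tr, val[cols], val["label"].to_numpy(), p)
    model = FittedModel(clf, cols, variant, None, p)
    if calibrate and len(val):
        model.calibrator = fit_isotonic(model.raw_scores(val), val["label"].to_numpy())
    return model


def _bucket_window(frame: pd.DataFrame, bucket: int, widen: float) -> pd.DataFrame:
    t = frame["time_since_admission"].to_numpy()
    if bucket == N_BUCKETS - 1:
        lo, hi = 48.0 - widen, np.inf
    else:
        lo, hi = bucket - widen, bucket + 1 + widen
    return frame[(t >= lo) & (t < hi)]


def fit_time_stacked(fm: FeatureMatrix, train_ids, val_ids, variant: str = "snapshot",
                     params: GBDTParams | None = None) -> StackedModel:
    """49 sub-models, each specialized on one time-since-admission bucket,
    jointly calibrated with a pooled isotonic map on the validation set.

    Each sub-model trains on its bucket extended by ``bucket_overlap_h``
    neighboring hours (which regularizes adjacent sub-models toward each
    other) and keeps widening symmetrically when the window holds fewer than
    ``min_bucket_samples`` rows or ``min_bucket_positives`` positive rows.
    Sub-models use a fixed booster size rather than per-bucket early
    stopping: uniform sharpness keeps scores comparable across buckets when
    a single global alarm threshold is applied. A bucket that stays
    single-class even over the whole stay range raises an error naming the
    bucket.
    """
    p = params or GBDTParams()
    cols = fm.feature_cols(variant)
    train, val = _split_frames(fm, train_ids, val_ids, p.stacked_train_stride)
    models: dict[int, lgb.LGBMClassifier] = {}
    for b in range(N_BUCKETS):
        widen = p.bucket_overlap_h
        sub = _bucket_window(train, b, widen)
        while (len(sub) < p.min_bucket_samples
               or sub["label"].sum() < p.min_bucket_positives
               or len(np.unique(sub["label"])) < 2) and widen < 400:
            widen = widen * 2 if widen else 1.0
            sub = _bucket_window(train, b, widen)
        if len(sub) == 0 or len(np.unique(sub["label"])) < 2:
            raise ValueError(f"bucket {b} has no two-class training data even after fallback")
        clf = lgb.LGBMClassifier(**{**p.lgbm_kwargs(),
                                    "n_estimators": p.bucket_n_estimators})
        clf.fit(sub[cols], sub["label"].to_numpy())
        models[b] = clf
    model = StackedModel(models, cols, variant, None, p)
    if len(val):
        model.calibrator = fit_isotonic(model.raw_scores(val),
                                        val["label"].to_numpy())
    return model


def predict_risk(model: FittedModel | StackedModel, fm: FeatureMatrix,
                 smooth_h: float | None = None) -> pd.DataFrame:
    """Calibrated risk in [0, 1] per valid grid point; NaN at invalid points.

    The calibrated trajectory is smoothed with a causal trailing mean over
    ``smooth_h`` hours (default from the model's params; 0 disables), which
    suppresses isolated noise spikes before alarm thresholding without
    looking ahead. Returns a frame with columns ``stay_id, time_h, risk``.
    """
    f = fm.frame
    risk = np.full(len(f), np.nan)
    valid = f["valid"].to_numpy()
    if valid.any():
        raw = model.raw_scores(f[valid])
        if model.calibrator is not None:
            raw = model.calibrator.predict(raw)
        risk[valid] = np.clip(raw, 0.0, 1.0)
    out = pd.DataFrame({"stay_id": f["stay_id"], "time_h": f["time_h"], "risk": risk})
    if smooth_h is None:
        smooth_h = model.params.risk_smooth_h
    if smooth_h:
        window = max(1, int(round(smooth_h * 12)))
        smoothed = (out.groupby("stay_id", sort=False)["risk"]
                    .transform(lambda s: s.rolling(window, min_periods=1).mean()))
        out["risk"] = np.where(np.isnan(risk), np.nan, smoothed)
    return out


def risk_by_stay(risk_frame: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-stay (times, risk) arrays, for the event-based evaluation."""
    out = {}
    for sid, grp in risk_frame.groupby("stay_id", sort=False):
        out[str(sid)] = (grp["time_h"].to_numpy(), grp["risk"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# persistence: directory bundle of model files + calibration + manifest
# ---------------------------------------------------------------------------

def save_model(model: FittedModel | StackedModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stacked = isinstance(model, StackedModel)
    manifest = {
        "stacked": stacked,
        "variant": model.variant,
        "feature_cols": model.feature_cols,
        "params": asdict(model.params),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    boosters = model.models if stacked else {0: model.booster}
    for b, clf in boosters.items():
        clf.booster_.save_model(str(directory / f"bucket_{b:02d}.txt"))
    if model.calibrator is not None:
        np.savez(directory / "calibration.npz",
                 x=model.calibrator.X_thresholds_, y=model.calibrator.y_thresholds_)


class _LoadedBooster:
    """predict_proba adapter around a raw LightGBM booster file."""

    def __init__(self, booster: lgb.Booster):
        self.booster_ = booster

    def predict_proba(self, X):
        p = self.booster_.predict(X)
        return np.column_stack([1 - p, p])


def load_model(directory: str | Path) -> FittedModel | StackedModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    params = GBDTParams(**manifest["params"])
    calibrator = None
    calib_path = directory / "calibration.npz"
    if calib_path.exists():
        arr = np.load(calib_path)
        calibrator = fit_isotonic(arr["x"], arr["y"])
    boosters = {}
    for p in sorted(directory.glob("bucket_*.txt")):
        b = int(p.stem.split("_")[1])
        boosters[b] = _LoadedBooster(lgb.Booster(model_file=str(p)))
    if manifest["stacked"]:
        return StackedModel(boosters, manifest["feature_cols"], manifest["variant"],
                            calibrator, params)
    return FittedModel(boosters[0], manifest["feature_cols"], manifest["variant"],
                       calibrator, params)
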