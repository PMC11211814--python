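"""5-minute prediction grid, partial imputation and feature engineering.

The grid spans the first to the last heart-rate observation of a stay in
exact 5-minute steps. Each variable is forward-filled only within its
clinically plausible "active period"; beyond that horizon (or before the
first measurement) values stay missing. Three feature classes are computed:

* current (partially imputed) values, including time-since-admission and
  static demographics,
* multi-scale history: median / standard deviation / least-squares trend of
  the gridded series over trailing horizons of 10, 26, 53 and 156 h,
* measurement history: how often a variable has been measured so far and how
  long ago the last measurement was.

Labels mark grid points from which an AKI event onset follows within the
label horizon; points inside an event or within 12 h after an event end are
excluded (``valid = False``), mirroring the alarm-suppression zones of the
event-based evaluation so that training and evaluation distributions match.
All features at time t depend only on data observed at or before t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kdigo import AKIEvent, StayAnnotation
from .synthetic_cohort import Cohort, PatientStay

__all__ = [
    "GRID_STEP_H", "DEFAULT_ACTIVE_PERIODS", "FeatureConfig", "FeatureMatrix",
    "build_grid", "partial_impute", "multiscale_history", "measurement_history",
    "make_labels", "featurize_stay", "featurize_cohort",
]

GRID_STEP_H = 5.0 / 60.0

#: forward-fill horizons (hours) per variable; vitals are trusted briefly,
#: labs for up to a day
DEFAULT_ACTIVE_PERIODS: dict[str, float] = {
    "hr": 1.0, "map": 1.0, "spo2": 1.0, "temp": 2.0,
    "lactate": 6.0, "potassium": 12.0, "crp": 24.0,
    "creatinine": 24.0, "urine": 3.0,
    "fluid_bolus": 6.0, "furosemide": 6.0,
}

DEFAULT_HORIZONS_H = (10.0, 26.0, 53.0, 156.0)


class GridError(ValueError):
    """Stay unusable for prediction (no heart-rate observations)."""


@dataclass(frozen=True)
class FeatureConfig:
    active_periods: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVE_PERIODS))
    horizons_h: tuple[float, ...] = DEFAULT_HORIZONS_H
    label_horizon_h: float = 24.0
    post_event_exclusion_h: float = 12.0
    with_history: bool = False
    include_treatments: bool = False
    history_variables: tuple[str, ...] = ("creatinine", "urine", "lactate", "map")


@dataclass
class FeatureMatrix:
    """One row per stay x grid point, with labels and a validity mask."""

    frame: pd.DataFrame
    snapshot_cols: list[str]
    history_cols: list[str]
    manifest: dict[str, str]          # feature column -> source variable
    label_horizon_h: float

    def feature_cols(self, variant: str) -> list[str]:
        if variant == "snapshot":
            return list(self.snapshot_cols)
        if variant == "history":
            return list(self.snapshot_cols) + list(self.history_cols)
        raise ValueError(f"unknown variant {variant!r}")

    def subset(self, stay_ids) -> "FeatureMatrix":
        keep = self.frame["stay_id"].isin(set(stay_ids))
        return FeatureMatrix(self.frame[keep].reset_index(drop=True),
                             self.snapshot_cols, self.history_cols,
                             self.manifest, self.label_horizon_h)


def build_grid(stay: PatientStay) -> np.ndarray:
    """Grid timestamps (hours since admission) at exact 5-min spacing from
    the first to the last heart-rate observation."""
    hr = stay.variable("hr")["time_h"].to_numpy()
    if hr.size == 0:
        raise GridError(f"stay {stay.stay_id} has no heart-rate observations")
    t0, t1 = float(hr[0]), float(hr[-1])
    n = int(np.floor((t1 - t0) / GRID_STEP_H + 1e-9)) + 1
    return t0 + GRID_STEP_H * np.arange(n)


def partial_impute(times: np.ndarray, values: np.ndarray, grid: np.ndarray,
                   active_period_h: float) -> np.ndarray:
    """Last observation carried forward, but only within the active period;
    missing (NaN) before the first observation or beyond the horizon."""
    if active_period_h <= 0:
        raise ValueError("active period must be positive")
    out = np.full(grid.size, np.nan)
    if times.size == 0:
        return out
    idx = np.searchsorted(times, grid + 1e-12, side="right") - 1
    ok = idx >= 0
    age = np.where(ok, grid - times[np.clip(idx, 0, None)], np.inf)
    ok &= age <= active_period_h + 1e-9
    out[ok] = values[idx[ok]]
    return out


def _rolling_trend(y: pd.Series, x: np.ndarray, window: int) -> np.ndarray:
    """Least-squares slope (per hour) over the trailing window, skipping
    missing values; NaN with fewer than 2 values."""
    mask = y.notna().to_numpy()
    yv = np.where(mask, y.to_numpy(), 0.0)
    xv = np.where(mask, x, 0.0)
    n = pd.Series(mask.astype(float)).rolling(window, min_periods=1).sum().to_numpy()
    sy = pd.Series(yv).rolling(window, min_periods=1).sum().to_numpy()
    sx = pd.Series(xv).rolling(window, min_periods=1).sum().to_numpy()
    sxy = pd.Series(xv * yv).rolling(window, min_periods=1).sum().to_numpy()
    sxx = pd.Series(xv * xv).rolling(window, min_periods=1).sum().to_numpy()
    denom = n * sxx - sx * sx
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (n * sxy - sx * sy) / denom
    slope[(n < 2) | (np.abs(denom) < 1e-12)] = np.nan
    return slope


def multiscale_history(gridded: np.ndarray, grid: np.ndarray,
                       horizons_h=DEFAULT_HORIZONS_H) -> dict[str, np.ndarray]:
    """Median / std / trend of the gridded series over each trailing horizon
    (t - H, t]. Median needs >= 1 value; std and trend need >= 2."""
    out: dict[str, np.ndarray] = {}
    s = pd.Series(gridded)
    for h in horizons_h:
        w = int(round(h / GRID_STEP_H))
        tag = f"{h:g}h"
        out[f"med_{tag}"] = s.rolling(w, min_periods=1).median().to_numpy()
        out[f"std_{tag}"] = s.rolling(w, min_periods=2).std().to_numpy()
        out[f"trend_{tag}"] = _rolling_trend(s, grid, w)
    return out


def measurement_history(times: np.ndarray, grid: np.ndarray) -> dict[str, np.ndarray]:
    """Cumulative measurement count and hours since the last measurement
    (NaN before the first one)."""
    count = np.searchsorted(times, grid + 1e-12, side="right").astype(float)
    since = np.full(grid.size, np.nan)
    has = count > 0
    if times.size:
        since[has] = grid[has] - times[count[has].astype(int) - 1]
    return {"n_meas": count, "h_since_meas": since}


def make_labels(grid: np.ndarray, events: list[AKIEvent], horizon_h: float,
                post_event_exclusion_h: float = 12.0) -> tuple[np.ndarray, np.ndarray]:
    """(label, valid) per grid point: label 1 iff an event onset falls in
    (t, t + horizon]; points inside an event or within the post-event
    exclusion zone are invalid."""
    onsets = np.array(sorted(e.start_hour for e in events))
    if onsets.size:
        lo = np.searchsorted(onsets, grid, side="right")
        hi = np.searchsorted(onsets, grid + horizon_h, side="right")
        label = (hi > lo).astype(int)
    else:
        label = np.zeros(grid.size, dtype=int)
    valid = np.ones(grid.size, dtype=bool)
    for ev in events:
        valid &= ~((grid >= ev.start_hour) & (grid < ev.end_hour + post_event_exclusion_h))
    return label, valid


def featurize_stay(stay: PatientStay, annotation: StayAnnotation,
                   config: FeatureConfig | None = None) -> tuple[pd.DataFrame, dict[str, str]]:
    cfg = config or FeatureConfig()
    grid = build_grid(stay)
    cols: dict[str, np.ndarray] = {}
    manifest: dict[str, str] = {}

    obs = stay.observations
    variables = list(dict.fromkeys(obs["variable_id"]))
    series = {v: (obs_v["time_h"].to_numpy(), obs_v["value"].to_numpy())
              for v in variables
              for obs_v in (obs[obs["variable_id"] == v],)}
    if cfg.include_treatments and len(stay.treatments):
        for drug, grp in stay.treatments.groupby("treatment_id"):
            g = grp.sort_values("time_h")
            series[drug] = (g["time_h"].to_numpy(), g["amount"].to_numpy())
            variables.append(drug)

    for v in variables:
        t_v, val_v = series[v]
        ap = cfg.active_periods.get(v, 6.0)
        cols[v] = partial_impute(t_v, val_v, grid, ap)
        manifest[v] = v

    cols["time_since_admission"] = grid
    manifest["time_since_admission"] = "time_since_admission"
    for name, value in (("age", stay.age), ("weight", stay.weight),
                        ("gender_num", 1.0 if stay.gender == "M" else 0.0)):
        cols[name] = np.full(grid.size, value)
        manifest[name] = name
    snapshot_cols = list(cols)

    history_cols: list[str] = []
    if cfg.with_history:
        for v in variables:
            if cfg.history_variables and v not in cfg.history_variables:
                continue
            t_v, _ = series[v]
            for tag, arr in multiscale_history(cols[v], grid, cfg.horizons_h).items():
                name = f"{v}__{tag}"
                cols[name] = arr
                manifest[name] = v
                history_cols.append(name)
            for tag, arr in measurement_history(t_v, grid).items():
                name = f"{v}__{tag}"
                cols[name] = arr
                manifest[name] = v
                history_cols.append(name)

    label, valid = make_labels(grid, annotation.events, cfg.label_horizon_h,
                               cfg.post_event_exclusion_h)
    frame = pd.DataFrame({"stay_id": stay.stay_id, "time_h": grid, **cols,
                          "label": label, "valid": valid})
    frame.attrs["snapshot_cols"] = snapshot_cols
    frame.attrs["history_cols"] = history_cols
    return frame, manifest


def featurize_cohort(cohort: Cohort, annotations: dict[str, StayAnnotation],
                     config: FeatureConfig | None = None) -> FeatureMatrix:
    """Feature matrix over all usable stays. Stays flagged excluded by the
    annotator or lacking heart rate are skipped."""
    cfg = config or FeatureConfig()
    frames, manifest = [], {}
    snapshot_cols: list[str] = []
    history_cols: list[str] = []
    for stay in cohort:
        ann = annotations.get(stay.stay_id)
        if ann is None or ann.excluded:
            continue
        try:
            frame, mani = featurize_stay(stay, ann, cfg)
        except GridError:
            continue
        frames.append(frame)
        manifest.update(mani)
        for c in frame.attrs["snapshot_cols"]:
            if c not in snapshot_cols:
                snapshot_cols.append(c)
        for c in frame.attrs["history_cols"]:
            if c not in history_cols:
                history_cols.append(c)
    if not frames:
        raise ValueError("no usable stays to featurize")
    frame = pd.concat(frames, ignore_index=True)
    return FeatureMatrix(frame, snapshot_cols, history_cols, manifest,
                         cfg.label_horizon_h)
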