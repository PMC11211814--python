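"""Seeded synthetic ICU cohorts with known ground-truth AKI onsets.

The generator emulates the structure of multi-variate ICU time series at the
fidelity the downstream pipeline needs, without attempting organ-system
simulation:

* irregular per-variable sampling (heart rate every 2-5 min, labs every
  6-24 h, urine charted hourly),
* a discrete-time (per hour) AKI hazard driven by a slowly mixing latent
  severity process, so covariates carry signal *before* onsets,
* a deterministic pre-onset "deterioration ramp" imposed on covariates over a
  configurable lead time, whose sign pattern switches across
  time-since-admission regimes (this is what makes time-stacked models pay
  off),
* creatinine drift and depressed urine output around each onset, so a
  KDIGO annotator run blind on the observations recovers the injected events,
* optionally a confounded-but-protective treatment policy: doses are given
  preferentially at high latent severity (confounding) while multiplying the
  hazard by a ratio in (0, 1] (causal benefit).

Ground-truth onsets are stored on the stay, separate from the observation
stream, so annotation is always tested blind.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VariableSpec",
    "CohortConfig",
    "TreatmentPolicy",
    "PatientStay",
    "Cohort",
    "generate_cohort",
    "apply_treatment_policy",
    "export_cohort",
    "import_cohort",
    "cohort_tables",
    "hourly_urine",
]

#: mg/dl -> umol/l conversion for serum creatinine.
UMOL_PER_MGDL = 88.4

DIAGNOSTIC_GROUPS = ("cardiovascular", "neurologic", "respiratory", "sepsis", "surgical")
#: mild per-group hazard multipliers; produce realistic prevalence spread
#: across sub-cohorts (used by the fairness analyses).
DIAG_HAZARD_MULT = {
    "cardiovascular": 1.0,
    "neurologic": 0.8,
    "respiratory": 1.0,
    "sepsis": 1.35,
    "surgical": 0.9,
}


@dataclass(frozen=True)
class VariableSpec:
    """Measurement-interval distribution and noise model of one channel.

    ``value = base + scale * (signal_coef * sign(regime) * ramp
    + severity_coef * severity + noise_coef * eps)`` with per-observation
    standard-normal ``eps``; the regime sign only applies when
    ``regime_flip`` is set.
    """

    interval_h: tuple[float, float]
    base: float
    scale: float
    signal_coef: float = 0.8
    severity_coef: float = 0.35
    noise_coef: float = 0.5
    clip: tuple[float, float] = (-np.inf, np.inf)
    regime_flip: bool = True


def default_manifest() -> dict[str, VariableSpec]:
    """Covariate channels shipped with the generator (besides heart rate,
    creatinine and urine, which have dedicated dynamics)."""
    return {
        "map": VariableSpec((0.25, 0.5), 78.0, 9.0, signal_coef=-0.9,
                            severity_coef=-0.35, noise_coef=0.4, clip=(35.0, 140.0)),
        "spo2": VariableSpec((0.25, 0.5), 96.5, 1.8, signal_coef=-0.8,
                             severity_coef=-0.2, clip=(70.0, 100.0)),
        "temp": VariableSpec((1.0, 2.0), 37.0, 0.5, signal_coef=0.8,
                             severity_coef=0.2, clip=(34.0, 41.5)),
        "lactate": VariableSpec((2.0, 4.0), 1.8, 0.8, signal_coef=0.9,
                                severity_coef=0.3, clip=(0.3, 15.0)),
        "potassium": VariableSpec((6.0, 12.0), 4.2, 0.45, signal_coef=0.8,
                                  severity_coef=0.2, clip=(2.5, 7.5)),
        "crp": VariableSpec((12.0, 24.0), 60.0, 30.0, signal_coef=0.8,
                            severity_coef=0.3, clip=(1.0, 400.0)),
    }


@dataclass(frozen=True)
class TreatmentPolicy:
    """Risk-dependent administration policy.

    Per AKI-free hour, a dose is drawn with probability
    ``sigmoid(intercept + slope * severity)`` provided the last dose is more
    than ``washout_h`` ago. ``slope > 0`` confounds treatment with latent
    severity; ``base_prob`` short-circuits the logistic model when set to 0.
    """

    intercept: float = -3.0
    slope: float = 2.0
    washout_h: float = 6.0
    effect_window_h: float = 24.0
    enabled: bool = True

    def prob(self, severity: float) -> float:
        if not self.enabled:
            return 0.0
        return 1.0 / (1.0 + math.exp(-(self.intercept + self.slope * severity)))


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 200
    stay_length_mean_h: float = 36.0
    stay_length_sd_h: float = 12.0
    stay_length_range_h: tuple[float, float] = (20.0, 60.0)
    baseline_aki_hazard: float = 0.006
    hazard_severity_coef: float = 1.4
    ar_phi: float = 0.93
    regime_boundaries: tuple[float, ...] = (8.0, 16.0, 24.0, 32.0, 40.0, 48.0)
    signal_rotation_period_h: float | None = 24.0
    pre_onset_lead: float = 24.0
    treatment_effect: float = 1.0
    dip_rate_per_h: float = 0.03
    dip_depth: float = 0.32
    event_duration_mean_h: float = 20.0
    event_duration_range_h: tuple[float, float] = (6.0, 60.0)
    refractory_h: float = 48.0
    rrt_fraction: float = 0.08
    urine_missing_prob: float = 0.02
    gender_specific_signal: bool = False
    variable_manifest: dict[str, VariableSpec] = field(default_factory=default_manifest)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.baseline_aki_hazard <= 1.0:
            raise ValueError("baseline_aki_hazard must be a per-hour probability in [0, 1]")
        if not 0.0 < self.treatment_effect <= 1.0:
            raise ValueError("treatment_effect must be a hazard ratio in (0, 1]")
        bounds = np.asarray(self.regime_boundaries, dtype=float)
        if bounds.size and not np.all(np.diff(bounds) > 0):
            raise ValueError("regime_boundaries must be strictly increasing")
        if self.stay_length_mean_h <= 0 or self.stay_length_sd_h <= 0:
            raise ValueError("stay length distribution parameters must be positive")
        if self.pre_onset_lead <= 0:
            raise ValueError("pre_onset_lead must be positive")


@dataclass
class PatientStay:
    """One ICU admission: static attributes plus irregular observation and
    treatment streams. ``truth_onsets``/``truth_events`` are simulation
    ground truth and never visible to the annotator."""

    stay_id: str
    admission_time: pd.Timestamp
    age: float
    gender: str
    weight: float
    diagnostic_group: str
    discharge_h: float
    observations: pd.DataFrame  # columns: variable_id, time_h, value
    treatments: pd.DataFrame    # columns: treatment_id, time_h, amount
    rrt_intervals: list[tuple[float, float]] = field(default_factory=list)
    truth_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    truth_events: list[tuple[float, float]] = field(default_factory=list)
    latent: dict | None = None

    @property
    def n_hours(self) -> int:
        return int(math.ceil(self.discharge_h))

    def variable(self, variable_id: str) -> pd.DataFrame:
        obs = self.observations
        return obs[obs["variable_id"] == variable_id]


class Cohort(Sequence):
    """Sequence of :class:`PatientStay` that remembers its generating config."""

    def __init__(self, stays: list[PatientStay], config: CohortConfig | None = None):
        self.stays = list(stays)
        self.config = config

    def __len__(self) -> int:
        return len(self.stays)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Cohort(self.stays[i], self.config)
        return self.stays[i]

    def by_id(self, stay_id: str) -> PatientStay:
        for s in self.stays:
            if s.stay_id == stay_id:
                return s
        raise KeyError(stay_id)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _regime_index(t: np.ndarray, boundaries: tuple[float, ...]) -> np.ndarray:
    return np.searchsorted(np.asarray(boundaries, dtype=float), t, side="right")


def _signal_weight(var_idx: int, n_vars: int, t: np.ndarray,
                   rotation_period_h: float | None) -> np.ndarray:
    """Time-since-admission-dependent weight of the deterioration signal in
    covariate ``var_idx``.

    The encoding rotates smoothly across the channels with admission-phase
    (period ``rotation_period_h``): at any instant the signal is recoverable
    from a local linear combination of channels, but the combination itself
    drifts with time since admission. ``None`` disables the rotation
    (homogeneous encoding)."""
    if not rotation_period_h:
        return np.ones_like(t)
    phase = 2.0 * math.pi * var_idx / max(n_vars, 1)
    return np.cos(2.0 * math.pi * t / rotation_period_h + phase)


def _regime_hazard_coef(base_coef: float, regime: np.ndarray) -> np.ndarray:
    # hazard-on-severity coefficient switches across regime windows
    return base_coef * np.where(regime % 2 == 0, 0.8, 1.3)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - 0.5 * sigma2, math.sqrt(sigma2)


def _simulate_events(
    cfg: CohortConfig,
    hazard_base: np.ndarray,
    severity: np.ndarray,
    rng_events: np.random.Generator,
    rng_treat: np.random.Generator,
    policy: TreatmentPolicy | None,
    effect: float,
) -> tuple[list[tuple[float, float]], list[dict]]:
    """Hour-by-hour discrete-time simulation of onsets and doses."""
    n_hours = hazard_base.size
    events: list[tuple[float, float]] = []
    doses: list[dict] = []
    mu_d, sig_d = _lognormal_params(cfg.event_duration_mean_h, 0.5 * cfg.event_duration_mean_h)
    current_event_end = -np.inf
    blocked_until = 0.0
    last_dose = -np.inf
    effect_until = -np.inf
    for t in range(n_hours):
        in_event = t < current_event_end
        if policy is not None and not in_event:
            if t - last_dose >= policy.washout_h and rng_treat.uniform() < policy.prob(severity[t]):
                drug = "fluid_bolus" if rng_treat.uniform() < 0.5 else "furosemide"
                amount = float(rng_treat.uniform(250, 500)) if drug == "fluid_bolus" else float(
                    rng_treat.uniform(20, 40))
                dose_time = t + float(rng_treat.uniform(0.0, 1.0))
                doses.append({"treatment_id": drug, "time_h": dose_time, "amount": amount})
                last_dose = t
                effect_until = dose_time + policy.effect_window_h
        elif policy is not None:
            # keep the treatment stream aligned regardless of event history
            rng_treat.uniform()
        if in_event or t < blocked_until:
            continue
        if n_hours - t < 6:
            continue  # no room for a >= 4 h event before discharge
        h = hazard_base[t]
        if policy is not None and t < effect_until:
            h = h * effect
        if rng_events.uniform() < h:
            duration = float(np.clip(rng_events.lognormal(mu_d, sig_d),
                                     *cfg.event_duration_range_h))
            end = min(float(t) + duration, float(n_hours))
            events.append((float(t), end))
            current_event_end = end
            blocked_until = end + cfg.refractory_h
    return events, doses


def _ramp_signal(n_hours: int, events: list[tuple[float, float]], lead: float) -> np.ndarray:
    """Deterministic pre-onset deterioration ramp on the hourly grid:
    0 far from events, rising linearly to 1 over the lead window, 1 inside
    the event."""
    hours = np.arange(n_hours, dtype=float)
    s = np.zeros(n_hours)
    for onset, end in events:
        ramp = np.clip((hours - (onset - lead)) / lead, 0.0, 1.0)
        ramp[hours >= end] = 0.0
        s = np.maximum(s, ramp)
    return s


def _creatinine_curve(cfg: CohortConfig, n_hours: int, baseline: float,
                      events: list[tuple[float, float]]) -> np.ndarray:
    hours = np.arange(n_hours, dtype=float)
    c = np.full(n_hours, baseline)
    for onset, end in events:
        # creatinine lags renal injury: flat until shortly before onset,
        # then a steep rise that crosses the 0.3 mg/dl delta around onset
        rise = np.clip((hours - (onset - 4.0)) / 4.0, 0.0, 1.0) * 0.35
        in_event = (hours >= onset) & (hours < end)
        plateau = np.where(in_event, 0.35 + np.clip((hours - onset) / 12.0, 0.0, 1.0) * 0.35, 0.0)
        post = np.where(hours >= end, 0.70 * np.exp(-(hours - end) / 12.0), 0.0)
        bump = np.maximum(np.where(hours < onset, rise, 0.0), np.maximum(plateau, post))
        c = np.maximum(c, baseline + bump)
    return c


def _simulate_stay(cfg: CohortConfig, idx: int,
                   policy: TreatmentPolicy | None) -> PatientStay:
    rng_stat = np.random.default_rng([cfg.seed, idx, 0])
    rng_events = np.random.default_rng([cfg.seed, idx, 1])
    rng_obs = np.random.default_rng([cfg.seed, idx, 2])
    rng_treat = np.random.default_rng([cfg.seed, idx, 3])

    mu_l, sig_l = _lognormal_params(cfg.stay_length_mean_h, cfg.stay_length_sd_h)
    length = float(np.clip(rng_stat.lognormal(mu_l, sig_l), *cfg.stay_length_range_h))
    n_hours = int(math.ceil(length))
    hours = np.arange(n_hours, dtype=float)

    age = float(rng_stat.uniform(16, 90))
    gender = "F" if rng_stat.uniform() < 0.45 else "M"
    weight = float(np.clip(rng_stat.normal(75, 15), 40, 140))
    diag = DIAGNOSTIC_GROUPS[int(rng_stat.integers(len(DIAGNOSTIC_GROUPS)))]
    admission = pd.Timestamp("2020-01-01") + pd.Timedelta(
        minutes=int(rng_stat.integers(0, 365 * 24 * 60)))

    # latent severity: AR(1), stationary N(0, 1)
    phi = cfg.ar_phi
    innov = rng_events.normal(0.0, math.sqrt(1 - phi * phi), n_hours)
    severity = np.empty(n_hours)
    severity[0] = rng_events.normal()
    for t in range(1, n_hours):
        severity[t] = phi * severity[t - 1] + innov[t]

    coef = _regime_hazard_coef(cfg.hazard_severity_coef,
                               _regime_index(hours, cfg.regime_boundaries))
    hazard_base = np.clip(
        cfg.baseline_aki_hazard * DIAG_HAZARD_MULT[diag]
        * np.exp(coef * severity),
        0.0, 0.3)

    effect = cfg.treatment_effect
    events, doses = _simulate_events(cfg, hazard_base, severity, rng_events,
                                     rng_treat, policy, effect)
    onsets = np.array([e[0] for e in events])
    signal = _ramp_signal(n_hours, events, cfg.pre_onset_lead)
    regime = _regime_index(hours, cfg.regime_boundaries)

    frames: list[pd.DataFrame] = []

    def emit(var: str, times: np.ndarray, values: np.ndarray) -> None:
        frames.append(pd.DataFrame({"variable_id": var, "time_h": times, "value": values}))

    def irregular_times(lo: float, hi: float, start_jitter: float = 0.0) -> np.ndarray:
        n_max = int(length / lo) + 2
        gaps = rng_obs.uniform(lo, hi, n_max)
        t = np.cumsum(gaps) - gaps[0] + rng_obs.uniform(0.0, start_jitter + 1e-9)
        return t[t <= length]

    def interp(hourly: np.ndarray, t: np.ndarray) -> np.ndarray:
        return np.interp(t, hours, hourly)

    # heart rate: defines the prediction grid, 2-5 min sampling
    t_hr = irregular_times(2.0 / 60.0, 5.0 / 60.0)
    hr = (82.0 + 9.0 * (0.25 * interp(severity, t_hr) + 0.15 * interp(signal, t_hr))
          + rng_obs.normal(0, 2.5, t_hr.size))
    emit("hr", t_hr, np.clip(hr, 30, 200))

    # covariate channels with admission-phase-rotating signal encoding
    gender_flip = -1.0 if (cfg.gender_specific_signal and gender == "F") else 1.0
    n_vars = len(cfg.variable_manifest)
    for j, (var, vs) in enumerate(cfg.variable_manifest.items()):
        t_v = irregular_times(*vs.interval_h, start_jitter=vs.interval_h[0])
        if t_v.size == 0:
            continue
        sign = (_signal_weight(j, n_vars, t_v, cfg.signal_rotation_period_h)
                if vs.regime_flip else 1.0)
        contrib = (vs.signal_coef * gender_flip * sign * interp(signal, t_v)
                   + vs.severity_coef * interp(severity, t_v)
                   + vs.noise_coef * rng_obs.normal(0, 1, t_v.size))
        emit(var, t_v, np.clip(vs.base + vs.scale * contrib, *vs.clip))

    # creatinine: irregular 6-18 h sampling around the true curve (mg/dl)
    baseline_creat = float(np.clip(rng_stat.normal(0.88, 0.12), 0.55, 1.4))
    curve = _creatinine_curve(cfg, n_hours, baseline_creat, events)
    t_cr = irregular_times(6.0, 18.0, start_jitter=4.0)
    if t_cr.size == 0:
        t_cr = np.array([min(1.0, length / 2)])
    creat = np.clip(interp(curve, t_cr) + rng_obs.normal(0, 0.03, t_cr.size), 0.3, None)
    emit("creatinine", t_cr, creat)

    # urine: hourly documented volumes (ml), charted at end of hour
    rate = 1.05 * rng_obs.lognormal(0.0, 0.22, n_hours)
    depressed = np.zeros(n_hours, dtype=bool)
    for onset, end in events:
        depressed |= (hours >= onset - 6.0) & (hours < end)
    rate[depressed] = 0.30 * rng_obs.lognormal(0.0, 0.20, int(depressed.sum()))
    # short benign oliguria dips: instantaneously look like pre-onset urine
    # depression, but are too brief to satisfy the 6-h KDIGO criterion and
    # carry no deterioration signal in the covariates
    near_event = np.zeros(n_hours, dtype=bool)
    for onset, end in events:
        near_event |= (hours >= onset - 9.0) & (hours < end + 3.0)
    t = 0
    while t < n_hours:
        if not near_event[t] and rng_obs.uniform() < cfg.dip_rate_per_h:
            dur = int(rng_obs.integers(2, 4))
            sl = slice(t, min(t + dur, n_hours))
            free = ~near_event[sl]
            vals = cfg.dip_depth * rng_obs.lognormal(0.0, 0.20, sl.stop - sl.start)
            rate[sl] = np.where(free, vals, rate[sl])
            t += dur + 3
        else:
            t += 1
    volume = rate * weight
    documented = rng_obs.uniform(size=n_hours) >= cfg.urine_missing_prob
    emit("urine", hours[documented] + 1.0, volume[documented])

    # renal replacement therapy for a fraction of long events
    rrt_intervals: list[tuple[float, float]] = []
    for onset, end in events:
        if end - onset >= 18.0 and rng_events.uniform() < cfg.rrt_fraction / 0.5:
            rrt_intervals.append((onset + 4.0, min(end, onset + 28.0)))

    observations = (pd.concat(frames, ignore_index=True)
                    .sort_values(["variable_id", "time_h"], kind="stable")
                    .reset_index(drop=True))
    treatments = pd.DataFrame(doses, columns=["treatment_id", "time_h", "amount"])

    return PatientStay(
        stay_id=f"stay_{idx:05d}",
        admission_time=admission,
        age=age,
        gender=gender,
        weight=weight,
        diagnostic_group=diag,
        discharge_h=length,
        observations=observations,
        treatments=treatments,
        rrt_intervals=rrt_intervals,
        truth_onsets=onsets,
        truth_events=events,
        latent={"severity": severity, "signal": signal, "hazard": hazard_base},
    )


def generate_cohort(config: CohortConfig, policy: TreatmentPolicy | None = None) -> Cohort:
    """Generate a seeded cohort; reproducible given ``config.seed``."""
    stays = [_simulate_stay(config, i, policy) for i in range(config.n_patients)]
    return Cohort(stays, config)


def apply_treatment_policy(cohort: Cohort, policy: TreatmentPolicy,
                           effect: float | None = None) -> Cohort:
    """Re-simulate the cohort with a risk-dependent treatment policy.

    Doses are assigned preferentially at high latent severity (confounding)
    while each dose multiplies the AKI hazard by ``effect`` for the policy's
    effect window (causal protection). Event-dependent observation streams
    are regenerated consistently with the new onset sequence.
    """
    if cohort.config is None:
        raise ValueError("cohort carries no generating config; regenerate with generate_cohort")
    effect = cohort.config.treatment_effect if effect is None else effect
    if not 0.0 < effect <= 1.0:
        raise ValueError("treatment effect must be a hazard ratio in (0, 1]")
    cfg = replace(cohort.config, treatment_effect=effect)
    return generate_cohort(cfg, policy=policy)


def hourly_urine(stay: PatientStay) -> np.ndarray:
    """Documented urine volume (ml) per hour-since-admission; NaN where the
    hour is undocumented. Volumes are charted at end of hour."""
    vols = np.full(stay.n_hours, np.nan)
    urine = stay.variable("urine")
    idx = np.round(urine["time_h"].to_numpy()).astype(int) - 1
    ok = (idx >= 0) & (idx < stay.n_hours)
    vols[idx[ok]] = urine["value"].to_numpy()[ok]
    return vols


# ---------------------------------------------------------------------------
# delimited-text round trip
# ---------------------------------------------------------------------------

def cohort_tables(cohort: Cohort) -> dict[str, pd.DataFrame]:
    """Long-format tables: observations / static / treatments / truth.
    Timestamps are minutes-from-admission (column name declares the unit)."""
    obs, stat, treat, truth = [], [], [], []
    for s in cohort:
        o = s.observations.copy()
        o.insert(0, "stay_id", s.stay_id)
        o["time_min"] = o.pop("time_h") * 60.0
        obs.append(o[["stay_id", "variable_id", "time_min", "value"]])
        stat.append({
            "stay_id": s.stay_id, "admission_time": s.admission_time.isoformat(),
            "age": s.age, "gender": s.gender, "weight": s.weight,
            "diagnostic_group": s.diagnostic_group, "discharge_min": s.discharge_h * 60.0,
        })
        t = s.treatments.copy()
        if len(t):
            t.insert(0, "stay_id", s.stay_id)
            t["time_min"] = t.pop("time_h") * 60.0
            treat.append(t[["stay_id", "treatment_id", "time_min", "amount"]])
        for start, end in s.rrt_intervals:
            treat.append(pd.DataFrame([{"stay_id": s.stay_id, "treatment_id": "rrt",
                                        "time_min": start * 60.0,
                                        "amount": (end - start) * 60.0}]))
        for start, end in s.truth_events:
            truth.append({"stay_id": s.stay_id, "onset_min": start * 60.0,
                          "end_min": end * 60.0})
    cols_obs = ["stay_id", "variable_id", "time_min", "value"]
    cols_tr = ["stay_id", "treatment_id", "time_min", "amount"]
    return {
        "observations": (pd.concat(obs, ignore_index=True) if obs
                         else pd.DataFrame(columns=cols_obs)),
        "static": pd.DataFrame(stat, columns=["stay_id", "admission_time", "age", "gender",
                                              "weight", "diagnostic_group", "discharge_min"]),
        "treatments": (pd.concat(treat, ignore_index=True) if treat
                       else pd.DataFrame(columns=cols_tr)),
        "truth": pd.DataFrame(truth, columns=["stay_id", "onset_min", "end_min"]),
    }


def export_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort as CSV tables; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in cohort_tables(cohort).items():
        p = directory / f"{name}.csv"
        table.to_csv(p, index=False)
        paths[name] = p
    return paths


def import_cohort(directory: str | Path) -> Cohort:
    """Read back a cohort written by :func:`export_cohort`.

    Simulation-internal state (latent processes) is not serialized; the
    returned stays carry ``latent=None``.
    """
    directory = Path(directory)
    obs = pd.read_csv(directory / "observations.csv")
    stat = pd.read_csv(directory / "static.csv")
    treat = pd.read_csv(directory / "treatments.csv")
    truth_p = directory / "truth.csv"
    truth = pd.read_csv(truth_p) if truth_p.exists() else pd.DataFrame(
        columns=["stay_id", "onset_min", "end_min"])
    stays = []
    for _, row in stat.iterrows():
        sid = row["stay_id"]
        o = obs[obs["stay_id"] == sid].copy()
        o["time_h"] = o.pop("time_min") / 60.0
        o = (o[["variable_id", "time_h", "value"]]
             .sort_values(["variable_id", "time_h"], kind="stable").reset_index(drop=True))
        t_all = treat[treat["stay_id"] == sid].copy()
        rrt = [(r["time_min"] / 60.0, (r["time_min"] + r["amount"]) / 60.0)
               for _, r in t_all[t_all["treatment_id"] == "rrt"].iterrows()]
        t = t_all[t_all["treatment_id"] != "rrt"].copy()
        t["time_h"] = t.pop("time_min") / 60.0
        t = t[["treatment_id", "time_h", "amount"]].reset_index(drop=True)
        ev = truth[truth["stay_id"] == sid]
        truth_events = [(r["onset_min"] / 60.0, r["end_min"] / 60.0) for _, r in ev.iterrows()]
        stays.append(PatientStay(
            stay_id=sid,
            admission_time=pd.Timestamp(row["admission_time"]),
            age=float(row["age"]), gender=str(row["gender"]), weight=float(row["weight"]),
            diagnostic_group=str(row["diagnostic_group"]),
            discharge_h=float(row["discharge_min"]) / 60.0,
            observations=o, treatments=t, rrt_intervals=rrt,
            truth_onsets=np.array([e[0] for e in truth_events]),
            truth_events=truth_events, latent=None,
        ))
    return Cohort(stays, None)
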