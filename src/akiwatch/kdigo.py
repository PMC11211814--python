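"""Hourly AKI status and event list under the complete KDIGO definition.

Four criteria mark an hour as AKI stage >= 1:

* creatinine rise >= 0.3 mg/dl relative to the trailing 48-h minimum,
* creatinine >= 1.5x the stay baseline (lowest value of the whole stay,
  including pre-ICU values), with the current elevation episode having begun
  within the trailing 7 days,
* urine output < 0.5 ml/kg/h sustained over 6 fully documented hours,
* active renal replacement therapy.

The hourly status is ``aki`` when any criterion is met, ``stable`` when no
criterion is met and at least one of the creatinine/urine criteria was
evaluable, and ``unknown`` otherwise. The absence of dialysis records alone
never certifies stability. Raw AKI runs are post-processed by bridging gaps
of up to 24 h and dropping events shorter than 4 h.

Undocumented urine hours are treated as unknown, never as zero output, so
charting gaps cannot create spurious oliguria.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .synthetic_cohort import UMOL_PER_MGDL, Cohort, PatientStay, hourly_urine

__all__ = [
    "STABLE", "AKI", "UNKNOWN",
    "AnnotatorParams", "AKIEvent", "StayAnnotation",
    "compute_baseline_creatinine", "creatinine_criteria_at", "urine_criterion_at",
    "rrt_criterion_at", "annotate_stay", "bridge_and_filter_events", "annotate_cohort",
]

STABLE, AKI, UNKNOWN = 0, 1, 2
MET, NOT_MET = "met", "not_met"
UNKNOWN_STR = "unknown"


@dataclass(frozen=True)
class AnnotatorParams:
    """Tunable thresholds; defaults implement KDIGO stage >= 1 detection."""

    creat_abs_delta: float = 0.3          # mg/dl within the trailing window
    creat_abs_window_h: float = 48.0
    creat_rel_ratio: float = 1.5          # x baseline
    creat_rel_window_h: float = 168.0     # 7 days
    creat_validity_h: float = 30.0        # how long a creatinine value governs
    urine_rate_thresh: float = 0.5        # ml/kg/h
    urine_window_h: int = 6
    bridge_gap_h: float = 24.0
    min_event_h: float = 4.0
    rrt_mode: str = "active"              # "active" or "initiation"


@dataclass(frozen=True)
class AKIEvent:
    start_hour: float
    end_hour: float                       # half-open [start, end)
    criteria: frozenset = field(default_factory=frozenset)

    @property
    def duration(self) -> float:
        return self.end_hour - self.start_hour


class StayAnnotation(NamedTuple):
    status: np.ndarray                    # one entry per hour: STABLE/AKI/UNKNOWN
    events: list
    excluded: bool                        # True when no hour was evaluable


def compute_baseline_creatinine(values) -> float | None:
    """Baseline = lowest creatinine of the entire stay, including any
    supplied pre-ICU values; ``None`` when no value exists (creatinine
    criteria not evaluable)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return None
    return float(values.min())


def _as_mgdl(values: np.ndarray, unit: str) -> np.ndarray:
    if unit == "mg/dl":
        return values
    if unit in ("umol/l", "µmol/l"):
        return values / UMOL_PER_MGDL
    raise ValueError(f"unknown creatinine unit: {unit!r}")


def _run_starts(times: np.ndarray, elevated: np.ndarray) -> np.ndarray:
    """Start time of the consecutive elevated run each observation belongs to."""
    starts = np.full(times.size, np.nan)
    current = np.nan
    for i in range(times.size):
        if elevated[i]:
            if np.isnan(current):
                current = times[i]
            starts[i] = current
        else:
            current = np.nan
    return starts


def _creatinine_flags(times: np.ndarray, values: np.ndarray, baseline: float,
                      n_hours: int, p: AnnotatorParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-hour (abs_met, rel_met, evaluable) arrays."""
    abs_met = np.zeros(n_hours, dtype=bool)
    rel_met = np.zeros(n_hours, dtype=bool)
    evaluable = np.zeros(n_hours, dtype=bool)
    if times.size == 0 or baseline is None:
        return abs_met, rel_met, evaluable
    elevated = values >= p.creat_rel_ratio * baseline
    starts = _run_starts(times, elevated)
    for h in range(n_hours):
        j = int(np.searchsorted(times, h, side="right")) - 1
        if j < 0 or h - times[j] > p.creat_validity_h:
            continue
        evaluable[h] = True
        gov = values[j]
        in_win = (times >= h - p.creat_abs_window_h) & (times <= h)
        ref = values[in_win].min() if in_win.any() else gov
        if gov - min(ref, gov) >= p.creat_abs_delta:
            abs_met[h] = True
        if elevated[j] and h - starts[j] <= p.creat_rel_window_h:
            rel_met[h] = True
    return abs_met, rel_met, evaluable


def creatinine_criteria_at(times, values, baseline: float | None, t: int,
                           params: AnnotatorParams | None = None,
                           unit: str = "mg/dl") -> str:
    """Evaluate both creatinine criteria at hour ``t``; returns ``met`` /
    ``not_met`` / ``unknown`` (no value governs hour ``t``)."""
    p = params or AnnotatorParams()
    if baseline is None:
        return UNKNOWN_STR
    times = np.asarray(times, dtype=float)
    values = _as_mgdl(np.asarray(values, dtype=float), unit)
    abs_met, rel_met, evaluable = _creatinine_flags(times, values, baseline, t + 1, p)
    if not evaluable[t]:
        return UNKNOWN_STR
    return MET if (abs_met[t] or rel_met[t]) else NOT_MET


def _urine_flags(volumes: np.ndarray, weight: float | None,
                 p: AnnotatorParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-hour (met, evaluable); hour t looks at the w consecutive hours
    ending at t, all of which must be documented."""
    n = volumes.size
    met = np.zeros(n, dtype=bool)
    evaluable = np.zeros(n, dtype=bool)
    if weight is None or not weight > 0:
        return met, evaluable
    w = p.urine_window_h
    doc = ~np.isnan(volumes)
    for t in range(w - 1, n):
        win = volumes[t - w + 1: t + 1]
        if doc[t - w + 1: t + 1].all():
            evaluable[t] = True
            met[t] = win.sum() / (weight * w) < p.urine_rate_thresh
    return met, evaluable


def urine_criterion_at(volumes, weight: float | None, t: int,
                       params: AnnotatorParams | None = None) -> str:
    p = params or AnnotatorParams()
    volumes = np.asarray(volumes, dtype=float)
    met, evaluable = _urine_flags(volumes, weight, p)
    if t >= volumes.size or not evaluable[t]:
        return UNKNOWN_STR
    return MET if met[t] else NOT_MET


def _rrt_flags(intervals, n_hours: int, p: AnnotatorParams) -> np.ndarray:
    met = np.zeros(n_hours, dtype=bool)
    hours = np.arange(n_hours, dtype=float)
    for start, end in intervals:
        if p.rrt_mode == "active":
            met |= (hours >= start) & (hours <= end)
        else:  # initiation only: AKI from first initiation onwards
            met |= hours >= start
    return met


def rrt_criterion_at(intervals, t: int, params: AnnotatorParams | None = None) -> str:
    p = params or AnnotatorParams()
    met = _rrt_flags(intervals, t + 1, p)
    return MET if met[t] else NOT_MET


def bridge_and_filter_events(events: list[AKIEvent],
                             params: AnnotatorParams | None = None) -> list[AKIEvent]:
    """Merge consecutive events separated by <= 24 h (bridged hours count as
    AKI), then drop events shorter than 4 h. Idempotent."""
    p = params or AnnotatorParams()
    events = sorted(events, key=lambda e: e.start_hour)
    merged: list[AKIEvent] = []
    for ev in events:
        if merged and ev.start_hour - merged[-1].end_hour <= p.bridge_gap_h:
            prev = merged[-1]
            merged[-1] = AKIEvent(prev.start_hour, max(prev.end_hour, ev.end_hour),
                                  prev.criteria | ev.criteria)
        else:
            merged.append(ev)
    return [e for e in merged if e.duration >= p.min_event_h]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as half-open index intervals."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, mask.size))
    return out


def annotate_stay(stay: PatientStay,
                  params: AnnotatorParams | None = None) -> StayAnnotation:
    """Hourly {stable, aki, unknown} trajectory and post-processed events."""
    p = params or AnnotatorParams()
    n_hours = stay.n_hours
    if n_hours <= 0:
        return StayAnnotation(np.empty(0, dtype=int), [], True)

    creat = stay.variable("creatinine")
    t_c = creat["time_h"].to_numpy()
    v_c = creat["value"].to_numpy()
    baseline = compute_baseline_creatinine(v_c) if t_c.size else None
    abs_met, rel_met, creat_eval = _creatinine_flags(t_c, v_c, baseline, n_hours, p)

    volumes = hourly_urine(stay)
    urine_met, urine_eval = _urine_flags(volumes, stay.weight, p)
    rrt_met = _rrt_flags(stay.rrt_intervals, n_hours, p)

    any_met = abs_met | rel_met | urine_met | rrt_met
    evaluable = creat_eval | urine_eval
    status = np.where(any_met, AKI, np.where(evaluable, STABLE, UNKNOWN))

    raw = []
    for i0, i1 in _runs(status == AKI):
        crit = set()
        if abs_met[i0:i1].any():
            crit.add("creat_abs")
        if rel_met[i0:i1].any():
            crit.add("creat_rel")
        if urine_met[i0:i1].any():
            crit.add("urine")
        if rrt_met[i0:i1].any():
            crit.add("rrt")
        raw.append(AKIEvent(float(i0), float(i1), frozenset(crit)))

    events = bridge_and_filter_events(raw, p)
    excluded = not (evaluable.any() or any_met.any())
    return StayAnnotation(status, events, excluded)


def annotate_cohort(cohort: Cohort,
                    params: AnnotatorParams | None = None) -> dict[str, StayAnnotation]:
    return {stay.stay_id: annotate_stay(stay, params) for stay in cohort}
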