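"""Event-based alarm evaluation, alarm-load accounting and prevalence
correction.

Alarms fire when the 5-min risk trajectory exceeds a threshold, are silenced
for 8 h after every alarm, and are never produced inside an AKI event or
within 12 h after an event ends. An event counts as caught when at least one
alarm fired in the 24 h before its onset (event recall); an alarm counts as
true when an event onset follows within 24 h (alarm precision). Sweeping the
threshold yields an alarm-precision / event-recall curve; its area (over the
attained recall range, extended left at constant precision) is the
event-based AUPRC.

For sub-cohort comparisons at different AKI prevalences, false alarms are
rescaled by lambda = prev_sub (1 - prev_ref) / (prev_ref (1 - prev_sub)) so
precisions are comparable at a common reference prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .kdigo import AKIEvent

__all__ = [
    "AlarmCounts", "PRCurve", "generate_alarms", "score_alarms_events",
    "pr_curve", "precision_at_recall", "prevalence_corrected_precision",
    "calendar_day_alarm_load",
]


class AlarmCounts(NamedTuple):
    tp: int        # true alarms
    fp: int        # false alarms
    caught: int    # events with >= 1 alarm in the 24 h before onset
    missed: int


@dataclass
class PRCurve:
    thresholds: np.ndarray
    recalls: np.ndarray
    precisions: np.ndarray
    auprc: float
    n_events: int
    tps: np.ndarray | None = None
    fps: np.ndarray | None = None

    def operating_point(self, recall_level: float = 0.8) -> int | None:
        """Index of the highest threshold attaining the requested recall."""
        attained = np.flatnonzero(self.recalls >= recall_level - 1e-12)
        if attained.size == 0:
            return None
        return int(attained[np.argmax(self.thresholds[attained])])


def _allowed_mask(times: np.ndarray, events: list[AKIEvent],
                  post_event_h: float) -> np.ndarray:
    ok = np.ones(times.size, dtype=bool)
    for ev in events:
        ok &= ~((times >= ev.start_hour) & (times < ev.end_hour + post_event_h))
    return ok


def generate_alarms(times: np.ndarray, risk: np.ndarray, threshold: float,
                    events: list[AKIEvent] | None = None, silence_h: float = 8.0,
                    post_event_h: float = 12.0) -> np.ndarray:
    """Alarm timestamps: scan the grid in time order, alarm on risk >
    threshold unless silenced (8 h after an alarm) or suppressed (inside an
    event or within 12 h after its end)."""
    events = events or []
    with np.errstate(invalid="ignore"):
        above = risk > threshold
    cand = times[above & _allowed_mask(times, events, post_event_h)]
    alarms = []
    i = 0
    while i < cand.size:
        t = cand[i]
        alarms.append(t)
        # next alarm allowed once the full silencing period has elapsed
        i = int(np.searchsorted(cand, t + silence_h - 1e-9, side="left"))
    return np.asarray(alarms)


def score_alarms_events(alarms: np.ndarray, events: list[AKIEvent],
                        window_h: float = 24.0) -> AlarmCounts:
    """Window conventions: event caught iff an alarm lies in
    [onset - window, onset); alarm true iff an onset lies in
    (alarm, alarm + window]."""
    alarms = np.asarray(alarms, dtype=float)
    onsets = np.array(sorted(e.start_hour for e in events))
    if onsets.size:
        lo = np.searchsorted(onsets, alarms, side="right")
        hi = np.searchsorted(onsets, alarms + window_h, side="right")
        true_alarm = hi > lo
    else:
        true_alarm = np.zeros(alarms.size, dtype=bool)
    caught = 0
    for o in onsets:
        in_win = (alarms >= o - window_h) & (alarms < o)
        caught += int(in_win.any())
    return AlarmCounts(int(true_alarm.sum()), int((~true_alarm).sum()),
                       caught, int(onsets.size) - caught)


def _pooled_counts(risk_by_stay: dict, events_by_stay: dict, threshold: float,
                   window_h: float, silence_h: float, post_event_h: float) -> AlarmCounts:
    tp = fp = caught = missed = 0
    for sid, (times, risk) in risk_by_stay.items():
        events = events_by_stay.get(sid, [])
        alarms = generate_alarms(times, risk, threshold, events, silence_h, post_event_h)
        c = score_alarms_events(alarms, events, window_h)
        tp += c.tp
        fp += c.fp
        caught += c.caught
        missed += c.missed
    return AlarmCounts(tp, fp, caught, missed)


def pr_curve(risk_by_stay: dict, events_by_stay: dict, thresholds=None,
             n_thresholds: int = 60, window_h: float = 24.0, silence_h: float = 8.0,
             post_event_h: float = 12.0) -> PRCurve:
    """Alarm-precision / event-recall curve pooled across stays.

    Thresholds default to quantiles of the pooled risk values. The area is
    the trapezoidal integral of precision over the attained recall range,
    extended to recall 0 at the precision of the lowest attained recall.
    """
    n_events = sum(len(v) for v in events_by_stay.values())
    if n_events == 0:
        raise ValueError("event-based PR curve undefined without events")
    if thresholds is None:
        pooled = np.concatenate([r[np.isfinite(r)] for _, r in risk_by_stay.values()])
        qs = np.unique(np.quantile(pooled, np.linspace(0.0, 1.0, n_thresholds)))
        thresholds = np.concatenate([[qs[0] - 1.0], qs])
    thresholds = np.asarray(sorted(thresholds))

    recalls, precisions, tps, fps = [], [], [], []
    for thr in thresholds:
        c = _pooled_counts(risk_by_stay, events_by_stay, thr, window_h,
                           silence_h, post_event_h)
        n_alarms = c.tp + c.fp
        recalls.append(c.caught / n_events)
        precisions.append(c.tp / n_alarms if n_alarms else np.nan)
        tps.append(c.tp)
        fps.append(c.fp)

    recalls = np.asarray(recalls)
    precisions = np.asarray(precisions)
    ok = ~np.isnan(precisions)
    r, p = recalls[ok], precisions[ok]
    order = np.argsort(r, kind="stable")
    r, p = r[order], p[order]
    if r.size == 0:
        auprc = np.nan
    else:
        # collapse duplicate recalls to their best precision, extend left
        uniq_r, inv = np.unique(r, return_inverse=True)
        best_p = np.full(uniq_r.size, -np.inf)
        for i, pi in zip(inv, p):
            best_p[i] = max(best_p[i], pi)
        rr = np.concatenate([[0.0], uniq_r]) if uniq_r[0] > 0 else uniq_r
        pp = np.concatenate([[best_p[0]], best_p]) if uniq_r[0] > 0 else best_p
        auprc = float(np.trapezoid(pp, rr))
    return PRCurve(thresholds, recalls, precisions, auprc, n_events,
                   np.asarray(tps), np.asarray(fps))


def precision_at_recall(curve: PRCurve, recall_level: float = 0.8) -> float:
    """Precision at the smallest attained recall >= the requested level
    (NaN when that recall is never attained)."""
    ok = ~np.isnan(curve.precisions)
    r, p = curve.recalls[ok], curve.precisions[ok]
    attained = r >= recall_level - 1e-12
    if not attained.any():
        return float("nan")
    # among thresholds attaining the recall, report the best precision
    return float(p[attained].max())


def prevalence_corrected_precision(tp: float, fp: float, prev_sub: float,
                                   prev_ref: float) -> float:
    """Rescale false alarms so a sub-cohort's precision is comparable at the
    reference prevalence: precision' = TP / (TP + lambda FP) with
    lambda = prev_sub (1 - prev_ref) / (prev_ref (1 - prev_sub))."""
    for prev in (prev_sub, prev_ref):
        if not 0.0 < prev < 1.0:
            raise ValueError("prevalences must lie strictly inside (0, 1)")
    lam = (prev_sub * (1.0 - prev_ref)) / (prev_ref * (1.0 - prev_sub))
    if tp == 0 and fp == 0:
        return float("nan")
    return tp / (tp + lam * fp)


class AlarmLoad(NamedTuple):
    mean_alarms_event_days: float      # days with an AKI event within 48 h
    mean_alarms_quiet_days: float      # days without
    false_alarm_frequency: float       # alarms per event-free patient day
    n_event_days: int
    n_quiet_days: int


def calendar_day_alarm_load(alarms_by_stay: dict, events_by_stay: dict,
                            stay_hours: dict, lookahead_h: float = 48.0) -> AlarmLoad:
    """Alarm counts per patient calendar day, grouped by whether an AKI
    event onset occurs in the day or within the next 48 h. Days are
    admission-relative 24-h blocks (absolute dates are typically stripped
    from ICU datasets)."""
    ev_alarms = quiet_alarms = ev_days = quiet_days = 0
    for sid, n_hours in stay_hours.items():
        onsets = np.array(sorted(e.start_hour for e in events_by_stay.get(sid, [])))
        alarms = np.asarray(alarms_by_stay.get(sid, np.empty(0)), dtype=float)
        for d in range(int(np.ceil(n_hours / 24.0))):
            d0 = 24.0 * d
            has_event = bool(((onsets >= d0) & (onsets < d0 + 24.0 + lookahead_h)).any())
            n_alarms = int(((alarms >= d0) & (alarms < d0 + 24.0)).sum())
            if has_event:
                ev_days += 1
                ev_alarms += n_alarms
            else:
                quiet_days += 1
                quiet_alarms += n_alarms
    return AlarmLoad(
        ev_alarms / ev_days if ev_days else float("nan"),
        quiet_alarms / quiet_days if quiet_days else float("nan"),
        quiet_alarms / quiet_days if quiet_days else float("nan"),
        ev_days, quiet_days,
    )
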