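"""Independent brute-force oracles used to validate the annotator and the
event-based metrics. These deliberately re-derive every rule hour by hour /
pair by pair, sharing no code with the package implementation."""

import numpy as np

STABLE, AKI, UNKNOWN = 0, 1, 2


def oracle_annotate(creat, urine, weight, rrt, n_hours,
                    validity_h=30.0, abs_delta=0.3, abs_win=48.0,
                    ratio=1.5, rel_win=168.0, urine_thresh=0.5, urine_win=6,
                    bridge_h=24.0, min_h=4.0):
    """Per-hour direct evaluation of all KDIGO criteria plus explicit
    merge/drop enumeration. ``creat`` is a list of (t, value); ``urine`` an
    hourly array with NaN for undocumented hours."""
    creat = sorted(creat)
    times = [t for t, _ in creat]
    vals = [v for _, v in creat]
    baseline = min(vals) if vals else None

    status = []
    crit = []
    for h in range(n_hours):
        met = set()
        evaluable = set()
        # creatinine criteria
        gov_idx = None
        for i, t in enumerate(times):
            if t <= h:
                gov_idx = i
        if gov_idx is not None and h - times[gov_idx] <= validity_h:
            evaluable.add("creat")
            gov = vals[gov_idx]
            window_vals = [v for t, v in creat if h - abs_win <= t <= h]
            if window_vals and gov - min(min(window_vals), gov) >= abs_delta:
                met.add("creat_abs")
            if gov >= ratio * baseline:
                j = gov_idx
                while j - 1 >= 0 and vals[j - 1] >= ratio * baseline:
                    j -= 1
                if h - times[j] <= rel_win:
                    met.add("creat_rel")
        # urine criterion
        if weight is not None and weight > 0 and h >= urine_win - 1:
            win = [urine[k] for k in range(h - urine_win + 1, h + 1)]
            if all(not np.isnan(v) for v in win):
                evaluable.add("urine")
                if sum(win) / (weight * urine_win) < urine_thresh:
                    met.add("urine")
        # renal replacement therapy
        for start, end in rrt:
            if start <= h <= end:
                met.add("rrt")
        if met:
            status.append(AKI)
        elif evaluable:
            status.append(STABLE)
        else:
            status.append(UNKNOWN)
        crit.append(met)

    # maximal aki runs
    events = []
    h = 0
    while h < n_hours:
        if status[h] == AKI:
            start = h
            while h < n_hours and status[h] == AKI:
                h += 1
            criteria = set()
            for k in range(start, h):
                criteria |= crit[k]
            events.append([float(start), float(h), criteria])
        else:
            h += 1

    # iterative bridging of gaps <= bridge_h, then drop short events
    changed = True
    while changed:
        changed = False
        for i in range(len(events) - 1):
            if events[i + 1][0] - events[i][1] <= bridge_h:
                a, b = events[i], events[i + 1]
                events[i] = [a[0], max(a[1], b[1]), a[2] | b[2]]
                del events[i + 1]
                changed = True
                break
    events = [e for e in events if e[1] - e[0] >= min_h]
    return np.array(status), events


def oracle_alarms(times, risk, threshold, events, silence_h=8.0, post_h=12.0):
    """Sequential scan with explicit state."""
    alarms = []
    last_alarm = -np.inf
    for t, r in zip(times, risk):
        if not (r > threshold):
            continue
        if t - last_alarm < silence_h - 1e-9:
            continue
        suppressed = False
        for start, end in events:
            if start <= t < end + post_h:
                suppressed = True
        if suppressed:
            continue
        alarms.append(t)
        last_alarm = t
    return alarms


def oracle_score(alarms, onsets, window=24.0):
    """Exhaustive pairwise window enumeration."""
    tp = 0
    for a in alarms:
        if any(a < o <= a + window for o in onsets):
            tp += 1
    caught = 0
    for o in onsets:
        if any(o - window <= a < o for a in alarms):
            caught += 1
    return tp, len(alarms) - tp, caught, len(onsets) - caught
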