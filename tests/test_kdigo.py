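"""KDIGO annotator: rule-level examples, properties, and equivalence with a
brute-force per-hour oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from akiwatch import kdigo
from akiwatch.kdigo import (AKI, STABLE, UNKNOWN, AKIEvent, AnnotatorParams,
                            annotate_stay, bridge_and_filter_events,
                            compute_baseline_creatinine, creatinine_criteria_at,
                            rrt_criterion_at, urine_criterion_at)
from akiwatch.synthetic_cohort import UMOL_PER_MGDL

from .conftest import make_stay
from .oracles import oracle_annotate


class TestBaseline:
    def test_minimum_over_stay(self):
        assert compute_baseline_creatinine([1.2, 0.8, 1.5]) == 0.8

    def test_single_value(self):
        assert compute_baseline_creatinine([1.0]) == 1.0

    def test_pre_icu_values_included(self):
        # pre-ICU 0.6 with in-ICU minimum 0.9
        assert compute_baseline_creatinine([0.6, 0.9, 1.1]) == 0.6

    def test_empty_series_undefined(self):
        assert compute_baseline_creatinine([]) is None


class TestCreatinineCriteria:
    def test_absolute_delta_within_48h(self):
        # 1.0 at t=0 rising to 1.35 at t=40: delta 0.35 >= 0.3
        res = creatinine_criteria_at([0.0, 40.0], [1.0, 1.35], 1.0, 40)
        assert res == "met"

    def test_relative_ratio(self):
        # 1.25 / 0.8 = 1.5625 >= 1.5
        res = creatinine_criteria_at([0.0, 10.0], [0.8, 1.25], 0.8, 10)
        assert res == "met"

    def test_constant_series_never_met(self):
        times = [0.0, 20.0, 40.0]
        for t in range(41):
            assert creatinine_criteria_at(times, [1.0] * 3, 1.0, t) == "not_met"

    def test_no_governing_value_unknown(self):
        assert creatinine_criteria_at([40.0], [1.0], 1.0, 5) == "unknown"
        # beyond the validity window the last value no longer governs
        assert creatinine_criteria_at([0.0], [1.0], 1.0, 35) == "unknown"


class TestUrineCriterion:
    def test_oliguria_met(self):
        # 35 ml/h at 80 kg = 0.4375 ml/kg/h < 0.5
        vols = [35.0] * 6
        assert urine_criterion_at(vols, 80.0, 5) == "met"

    def test_normal_output_not_met(self):
        # 45 ml/h at 80 kg = 0.5625 ml/kg/h
        assert urine_criterion_at([45.0] * 6, 80.0, 5) == "not_met"

    def test_missing_hour_unknown(self):
        vols = [35.0, 35.0, np.nan, 35.0, 35.0, 35.0]
        assert urine_criterion_at(vols, 80.0, 5) == "unknown"

    def test_missing_weight_unknown(self):
        assert urine_criterion_at([35.0] * 6, None, 5) == "unknown"


class TestRRT:
    def test_active_interval(self):
        for t, expected in [(9, "not_met"), (10, "met"), (30, "met"), (31, "not_met")]:
            assert rrt_criterion_at([(10, 30)], t) == expected

    def test_no_records(self):
        assert rrt_criterion_at([], 5) == "not_met"

    def test_disjoint_union(self):
        ivs = [(2, 4), (10, 12)]
        met_hours = {t for t in range(15) if rrt_criterion_at(ivs, t) == "met"}
        assert met_hours == {2, 3, 4, 10, 11, 12}


class TestBridgeAndFilter:
    def test_gap_within_24h_bridged(self):
        events = [AKIEvent(10, 20), AKIEvent(40, 50)]
        out = bridge_and_filter_events(events)
        assert [(e.start_hour, e.end_hour) for e in out] == [(10, 50)]

    def test_gap_beyond_24h_kept_apart(self):
        events = [AKIEvent(10, 20), AKIEvent(46, 50)]
        out = bridge_and_filter_events(events)
        assert [(e.start_hour, e.end_hour) for e in out] == [(10, 20), (46, 50)]

    def test_short_event_dropped(self):
        assert bridge_and_filter_events([AKIEvent(10, 13)]) == []

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            starts = np.sort(rng.uniform(0, 200, 6))
            events = [AKIEvent(float(s), float(s + rng.uniform(1, 30)))
                      for s in starts]
            events = [e for i, e in enumerate(events)
                      if i == 0 or e.start_hour > events[i - 1].end_hour]
            once = bridge_and_filter_events(events)
            twice = bridge_and_filter_events(once)
            assert once == twice


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.tuples(st.floats(0.1, 60.0), st.floats(0.5, 40.0)),
                min_size=0, max_size=8))
def test_bridge_filter_idempotent_and_well_formed(gaps_durations):
    """For arbitrary non-overlapping raw events, post-processing is
    idempotent and returns sorted, non-overlapping events of duration >= 4 h
    separated by > 24 h."""
    t = 0.0
    events = []
    for gap, dur in gaps_durations:
        start = t + gap
        events.append(AKIEvent(start, start + dur))
        t = start + dur
    once = bridge_and_filter_events(events)
    assert once == bridge_and_filter_events(once)
    for i, e in enumerate(once):
        assert e.duration >= 4.0
        if i:
            assert e.start_hour - once[i - 1].end_hour > 24.0


class TestAnnotateStay:
    def test_all_stable_no_events(self):
        stay = make_stay(n_hours=48, creat=[(0, 1.0), (24, 1.0)],
                         urine=[80.0] * 48)
        ann = annotate_stay(stay)
        assert ann.events == [] and not ann.excluded
        assert (ann.status != AKI).all()

    def test_rrt_from_hour_5_single_event(self):
        stay = make_stay(n_hours=30, creat=[(0, 1.0)], urine=[80.0] * 30,
                         rrt=[(5.0, 30.0)])
        ann = annotate_stay(stay)
        assert len(ann.events) == 1
        assert ann.events[0].start_hour == 5.0
        assert "rrt" in ann.events[0].criteria

    def test_no_data_stay_excluded(self):
        stay = make_stay(n_hours=24, creat=[], urine=[np.nan] * 24)
        ann = annotate_stay(stay)
        assert ann.excluded

    def test_unit_safety_umol_equals_mgdl(self):
        """Annotating umol/l inputs converted at 88.4 equals mg/dl."""
        times = [0.0, 20.0, 40.0]
        vals = [0.9, 1.1, 1.4]
        base = compute_baseline_creatinine(vals)
        for t in (20, 40):
            mgdl = creatinine_criteria_at(times, vals, base, t)
            umol = creatinine_criteria_at(times, [v * UMOL_PER_MGDL for v in vals],
                                          base, t, unit="umol/l")
            assert mgdl == umol

    def test_injected_onset_recovered(self):
        """Generator round trip: one injected onset yields one overlapping
        annotated event."""
        from akiwatch import CohortConfig, generate_cohort

        cfg = CohortConfig(n_patients=30, seed=123, urine_missing_prob=0.0,
                           dip_rate_per_h=0.0)
        cohort = generate_cohort(cfg)
        checked = 0
        for stay in cohort:
            if len(stay.truth_events) != 1:
                continue
            onset, _ = stay.truth_events[0]
            ann = annotate_stay(stay)
            assert len(ann.events) == 1
            ev = ann.events[0]
            assert ev.start_hour <= onset + 1 and onset < ev.end_hour
            checked += 1
        assert checked >= 3


class TestUrineThresholdMonotonicity:
    def test_lower_threshold_never_more_aki(self, small_cohort):
        for stay in small_cohort[:10]:
            strict = annotate_stay(stay, AnnotatorParams(urine_rate_thresh=0.3))
            default = annotate_stay(stay, AnnotatorParams())
            assert (strict.status == AKI).sum() <= (default.status == AKI).sum()


def _random_fixture(rng):
    n_hours = int(rng.integers(12, 100))
    n_creat = int(rng.integers(0, 8))
    creat = sorted((float(rng.uniform(0, n_hours)),
                    float(rng.uniform(0.5, 2.5))) for _ in range(n_creat))
    urine = rng.uniform(10, 90, n_hours)
    urine[rng.uniform(size=n_hours) < 0.15] = np.nan
    weight = float(rng.uniform(45, 120))
    rrt = []
    if rng.uniform() < 0.3:
        s = float(rng.uniform(0, n_hours - 2))
        rrt.append((s, min(float(n_hours), s + float(rng.uniform(1, 20)))))
    return n_hours, creat, list(urine), weight, rrt


@pytest.mark.parametrize("block", range(4))
def test_oracle_equivalence_random_fixtures(block):
    """Hourly statuses and post-processed event lists match an independent
    per-hour brute-force evaluation exactly, on random small stays."""
    rng = np.random.default_rng(1000 + block)
    for _ in range(50):
        n_hours, creat, urine, weight, rrt = _random_fixture(rng)
        stay = make_stay(n_hours=n_hours, creat=creat, urine=urine,
                         weight=weight, rrt=rrt)
        ann = annotate_stay(stay)
        status_o, events_o = oracle_annotate(creat, urine, weight, rrt, n_hours)
        assert np.array_equal(ann.status, status_o)
        got = [(e.start_hour, e.end_hour, set(e.criteria)) for e in ann.events]
        exp = [(s, e, c) for s, e, c in events_o]
        assert got == exp
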