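"""Propensity matching, Kaplan-Meier freedom-from-AKI curves, stratified
false-alarm rates and attribution profiles."""

import numpy as np
import pandas as pd
import pytest

from akiwatch.kdigo import AKIEvent
from akiwatch.treatment_effect import (attribution_profile, km_freedom_curves,
                                       naive_outcome_rates, propensity_match,
                                       select_index_points,
                                       treated_cohort_false_alarm_rates)


def _points(treated_props, control_props, outcomes=None):
    rows = []
    for i, p in enumerate(treated_props):
        rows.append({"stay_id": f"t{i}", "time_h": float(i), "treated": True,
                     "propensity": p, "outcome_time": 60.0, "event_observed": False})
    for i, p in enumerate(control_props):
        rows.append({"stay_id": f"c{i}", "time_h": float(i), "treated": False,
                     "propensity": p, "outcome_time": 60.0, "event_observed": False})
    return pd.DataFrame(rows)


class TestPropensityMatch:
    def test_identical_distributions_all_matched(self):
        pts = _points([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        matched = propensity_match(pts, caliper=0.02)
        assert matched["pair"].nunique() == 3
        assert matched.attrs["n_unmatched"] == 0

    def test_caliper_excludes_distant_controls(self):
        # treated {0.30, 0.80}, controls {0.31, 0.50}: only (0.30, 0.31) pairs
        pts = _points([0.30, 0.80], [0.31, 0.50])
        matched = propensity_match(pts, caliper=0.05)
        assert matched["pair"].nunique() == 1
        pair = matched.sort_values("treated")["propensity"].tolist()
        assert pair == [0.31, 0.30]
        assert matched.attrs["n_unmatched"] == 1

    def test_no_controls_within_caliper_raises(self):
        pts = _points([0.2], [0.9])
        with pytest.raises(ValueError):
            propensity_match(pts, caliper=0.05)

    def test_without_replacement(self):
        pts = _points([0.50, 0.51], [0.505])
        matched = propensity_match(pts, caliper=0.05)
        assert matched["pair"].nunique() == 1


class TestKMFreedomCurves:
    def test_hand_computed_product_limit(self):
        # 4 subjects, onsets at 2 h and 4 h, no censoring
        rows = []
        for i, (t, obs) in enumerate([(2.0, True), (4.0, True),
                                      (60.0, False), (60.0, False)]):
            rows.append({"treated": i % 2 == 0, "outcome_time": t,
                         "event_observed": obs, "pair": i // 2})
        # single-arm check via the treated arm only
        arm = pd.DataFrame([r for r in rows] * 1)
        arm["treated"] = True
        arm = pd.concat([arm, arm.assign(treated=False)], ignore_index=True)
        km = km_freedom_curves(arm, horizon_h=60.0)
        assert float(km["treated"].predict(2.0)) == pytest.approx(0.75)
        assert float(km["treated"].predict(4.0)) == pytest.approx(0.5)

    def test_no_events_flat_curves(self):
        matched = _points([0.5] * 3, [0.5] * 3)
        matched["pair"] = [0, 1, 2, 0, 1, 2]
        km = km_freedom_curves(matched)
        assert km["survival_at_horizon"]["treated"] == pytest.approx(1.0)
        assert km["risk_difference"] == pytest.approx(0.0)

    def test_censoring_removes_from_risk_set_only(self):
        rows = [
            {"treated": True, "outcome_time": 1.0, "event_observed": False, "pair": 0},
            {"treated": True, "outcome_time": 5.0, "event_observed": True, "pair": 1},
            {"treated": False, "outcome_time": 60.0, "event_observed": False, "pair": 0},
            {"treated": False, "outcome_time": 60.0, "event_observed": False, "pair": 1},
        ]
        km = km_freedom_curves(pd.DataFrame(rows))
        # one of two at risk fails at t=5 (the censored subject already left)
        assert float(km["treated"].predict(5.0)) == pytest.approx(0.0)


@pytest.fixture(scope="module")
def study():
    from akiwatch import (TreatmentPolicy, annotate_cohort,
                          apply_treatment_policy, generate_cohort)
    from akiwatch.treatment_effect import treatment_study_config

    cfg, policy = treatment_study_config(n_patients=60, seed=21)
    cohort = apply_treatment_policy(generate_cohort(cfg), policy, 0.5)
    ann = annotate_cohort(cohort)
    risk = {}
    for s in cohort:
        t = np.arange(0.0, s.discharge_h, 5 / 60)
        sev = np.interp(t, np.arange(s.n_hours), s.latent["severity"])
        risk[s.stay_id] = (t, 1 / (1 + np.exp(-sev)))
    return cohort, ann, risk


class TestSelectIndexPoints:
    def test_invariants(self, study):
        cohort, ann, risk = study
        pts = select_index_points(cohort, ann, risk, seed=0)
        assert (pts["outcome_time"] >= 0).all()
        assert pts["propensity"].between(0, 1).all()
        assert pts["treated"].any() and (~pts["treated"]).any()
        # index points are AKI-free: no point lies inside an annotated event
        by_stay = {sid: ann[sid].events for sid in ann}
        for row in pts.itertuples():
            assert not any(e.start_hour <= row.time_h < e.end_hour
                           for e in by_stay[row.stay_id])

    def test_outcome_and_censoring(self, study):
        cohort, ann, risk = study
        pts = select_index_points(cohort, ann, risk, seed=0, horizon_h=60.0)
        discharge = {s.stay_id: s.discharge_h for s in cohort}
        for row in pts.itertuples():
            limit = min(60.0, discharge[row.stay_id] - row.time_h)
            assert row.outcome_time <= limit + 1e-9
            if not row.event_observed:
                assert row.outcome_time == pytest.approx(max(limit, 0.0))

    def test_no_treated_points_raises(self, study):
        cohort, ann, risk = study
        import copy
        bare = []
        for s in cohort[:5]:
            s2 = copy.copy(s)
            s2.treatments = s.treatments.iloc[0:0]
            bare.append(s2)
        from akiwatch.synthetic_cohort import Cohort
        with pytest.raises(ValueError):
            select_index_points(Cohort(bare, None), ann, risk, seed=0)


class TestFalseAlarmStratification:
    def test_no_treatments_single_partition_matches_global(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 48, 5 / 60)
        risk = {f"s{i}": (t, rng.uniform(size=t.size)) for i in range(10)}
        events = {f"s{i}": ([AKIEvent(30.0, 40.0)] if i < 5 else [])
                  for i in range(10)}
        table = treated_cohort_false_alarm_rates(risk, events, set(), 0.8)
        row = table.set_index("partition")
        assert row.loc["treated", "n_stays"] == 0
        assert row.loc["untreated", "n_stays"] == 10

    def test_identical_partitions_similar_rates(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 48, 5 / 60)
        risk, events = {}, {}
        for i in range(60):
            sid = f"s{i}"
            risk[sid] = (t, rng.uniform(size=t.size))
            events[sid] = [AKIEvent(30.0, 40.0)] if i % 2 else []
        treated = {f"s{i}" for i in range(60) if i % 4 in (0, 1)}
        table = treated_cohort_false_alarm_rates(risk, events, treated, 0.9)
        rates = table["false_alarm_rate"]
        assert abs(rates.iloc[0] - rates.iloc[1]) < 0.25


class TestAttributionProfile:
    def test_additivity_and_absent_feature(self, medium_pipeline):
        from akiwatch.models import GBDTParams, fit_variant

        _, _, fm, _ = medium_pipeline
        ids = sorted(set(fm.frame["stay_id"]))
        model = fit_variant(fm, ids[30:], ids[:30], "snapshot",
                            GBDTParams(n_estimators=40))
        X = fm.frame[fm.frame["valid"]].head(200)
        prof = attribution_profile(model, "lactate", X)
        assert len(prof) == len(X)
        # contributions plus base value reproduce the raw score (log-odds)
        contrib = model.booster.booster_.predict(X[model.feature_cols],
                                                 pred_contrib=True)
        raw = model.booster.booster_.predict(X[model.feature_cols],
                                             raw_score=True)
        assert np.allclose(contrib.sum(axis=1), raw, atol=1e-6)
        with pytest.raises(ValueError):
            attribution_profile(model, "not_a_feature", X)


def test_confounded_dosing_gets_positive_attribution():
    """A model trained with dose features on a confounded cohort associates
    administration with *higher* predicted AKI risk, even though the drug is
    causally protective — the qualitative signature of confounding."""
    from akiwatch import annotate_cohort, apply_treatment_policy, generate_cohort
    from akiwatch import grid_features, models
    from akiwatch.grid_features import FeatureConfig
    from akiwatch.treatment_effect import treatment_study_config

    cfg, policy = treatment_study_config(n_patients=120, seed=33)
    cohort = apply_treatment_policy(generate_cohort(cfg), policy, 0.5)
    ann = annotate_cohort(cohort)
    fm = grid_features.featurize_cohort(cohort, ann,
                                        FeatureConfig(include_treatments=True))
    ids = sorted(set(fm.frame["stay_id"]))
    model = models.fit_variant(fm, ids[24:], ids[:24], "snapshot",
                               models.GBDTParams(n_estimators=60))
    X = fm.frame[fm.frame["valid"]]
    means = []
    for drug in ("furosemide", "fluid_bolus"):
        if drug not in model.feature_cols:
            continue
        prof = attribution_profile(model, drug, X)
        dosed = prof[prof["value"].notna() & (prof["value"] > 0)]
        assert len(dosed) > 100
        means.append(dosed["attribution"].mean())
    assert np.mean(means) > 0


def test_naive_rates_structure():
    pts = _points([0.5] * 4, [0.5] * 4)
    pts.loc[pts.index[:2], "event_observed"] = True
    out = naive_outcome_rates(pts)
    assert out["treated"] == pytest.approx(0.5)
    assert out["control"] == pytest.approx(0.0)
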