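"""Desk-scale experimental designs: split construction, sub-cohort fairness,
gender transfer, data-fraction robustness and clinician-agreement scoring.

Splitting is by whole ICU admissions: a fixed random test set is drawn once,
and the remainder is partitioned into train/validation at 80 %:20 %, several
times at random. Synthetic stays carry no meaningful calendar structure, so
the test draw is random rather than temporal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .event_evaluation import (pr_curve, precision_at_recall,
                               prevalence_corrected_precision)
from .grid_features import FeatureMatrix
from .models import GBDTParams, fit_variant, predict_risk, risk_by_stay

__all__ = [
    "SplitPlan", "make_splits", "event_prevalence", "evaluate_subset",
    "subcohort_eval", "gender_transfer", "data_fraction_experiment",
    "regime_study_config", "homogeneous_study_config",
    "clinician_agreement",
]


def regime_study_config(n_patients: int = 2000, seed: int = 0):
    """Cohort conditions for the time-stacking comparison: the package
    defaults, which carry admission-phase-rotating covariate encoding,
    regime-switching hazard coefficients and frequent benign oliguria dips —
    the features that reward per-hour specialization."""
    from .synthetic_cohort import CohortConfig

    return CohortConfig(n_patients=n_patients, seed=seed)


def homogeneous_study_config(n_patients: int = 2000, seed: int = 0):
    """Control conditions with a time-homogeneous feature-outcome mapping:
    no covariate-encoding rotation, a single hazard regime and rare dips.
    Used as the no-regime control and for the data-fraction robustness
    study, where the question is sample efficiency on a stable task."""
    from .synthetic_cohort import CohortConfig

    return CohortConfig(n_patients=n_patients, seed=seed,
                        signal_rotation_period_h=None,
                        regime_boundaries=(), dip_rate_per_h=0.0)


@dataclass
class SplitPlan:
    test: list[str]
    splits: list[tuple[list[str], list[str]]]  # (train, validation) per split

    def all_development(self) -> list[str]:
        train, val = self.splits[0]
        return list(train) + list(val)


def make_splits(stay_ids, test_fraction: float = 0.1, n_splits: int = 5,
                val_fraction: float = 0.2, seed: int = 0) -> SplitPlan:
    """Fixed test set plus ``n_splits`` seeded train/validation partitions of
    the remainder, all at the level of whole stays."""
    stay_ids = list(stay_ids)
    if len(stay_ids) < 10:
        raise ValueError("need at least 10 stays to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(stay_ids))
    n_test = int(round(test_fraction * len(stay_ids)))
    test = [stay_ids[i] for i in order[:n_test]]
    rest = [stay_ids[i] for i in order[n_test:]]
    splits = []
    for k in range(n_splits):
        sub_rng = np.random.default_rng([seed, k + 1])
        perm = sub_rng.permutation(len(rest))
        n_val = int(round(val_fraction * len(rest)))
        val = [rest[i] for i in perm[:n_val]]
        train = [rest[i] for i in perm[n_val:]]
        splits.append((train, val))
    return SplitPlan(test, splits)


def event_prevalence(events_by_stay: dict, stay_ids=None) -> float:
    """Fraction of stays with at least one AKI event."""
    ids = list(stay_ids) if stay_ids is not None else list(events_by_stay)
    if not ids:
        return float("nan")
    return float(np.mean([len(events_by_stay.get(s, [])) > 0 for s in ids]))


def evaluate_subset(risk: dict, events: dict, stay_ids, recall_level: float = 0.8,
                    prev_ref: float | None = None, **curve_kwargs) -> dict:
    """Event-based metrics on a stay subset: AUPRC, precision at the recall
    level, and (when a reference prevalence is given) prevalence-corrected
    precision at the same operating point."""
    ids = [s for s in stay_ids if s in risk]
    sub_risk = {s: risk[s] for s in ids}
    sub_events = {s: events.get(s, []) for s in ids}
    prev = event_prevalence(sub_events, ids)
    n_events = sum(len(v) for v in sub_events.values())
    out = {"n_stays": len(ids), "n_events": n_events, "prevalence": prev,
           "auprc": float("nan"), "precision_at_recall": float("nan"),
           "corrected_precision": float("nan")}
    if n_events == 0:
        return out
    curve = pr_curve(sub_risk, sub_events, **curve_kwargs)
    out["auprc"] = curve.auprc
    out["precision_at_recall"] = precision_at_recall(curve, recall_level)
    idx = curve.operating_point(recall_level)
    if idx is not None and prev_ref is not None and 0.0 < prev < 1.0:
        out["corrected_precision"] = prevalence_corrected_precision(
            float(curve.tps[idx]), float(curve.fps[idx]), prev, prev_ref)
    return out


def subcohort_eval(risk: dict, events: dict, groups: dict[str, str],
                   recall_level: float = 0.8, **curve_kwargs) -> pd.DataFrame:
    """Per-group event-based metrics, raw and prevalence-corrected against
    the whole evaluated population."""
    ids = [s for s in risk if s in groups]
    prev_ref = event_prevalence({s: events.get(s, []) for s in ids}, ids)
    rows = []
    for g in sorted(set(groups[s] for s in ids)):
        members = [s for s in ids if groups[s] == g]
        res = evaluate_subset(risk, events, members, recall_level, prev_ref,
                              **curve_kwargs)
        rows.append({"group": g, **res})
    return pd.DataFrame(rows)


def age_bins(age: float) -> str:
    """Default age grouping: 16-30, then 15-year bands."""
    if age < 31:
        return "16-30"
    lo = 31 + 15 * int((age - 31) // 15)
    return f"{lo}-{lo + 14}"


def gender_transfer(fm: FeatureMatrix, events_by_stay: dict,
                    gender_by_stay: dict[str, str], params: GBDTParams | None = None,
                    variant: str = "snapshot", test_fraction: float = 0.25,
                    val_fraction: float = 0.2, seed: int = 0,
                    recall_level: float = 0.8) -> pd.DataFrame:
    """Train on each gender separately and evaluate on both: a 2x2 matrix of
    event-based metrics with prevalence-corrected precision."""
    genders = sorted(set(gender_by_stay.values()))
    if len(genders) < 2:
        raise ValueError("gender transfer needs both genders in the cohort")
    p = params or GBDTParams()
    ids = sorted(set(fm.frame["stay_id"]))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_test = int(round(test_fraction * len(ids)))
    test = [ids[i] for i in order[:n_test]]
    dev = [ids[i] for i in order[n_test:]]
    prev_ref = event_prevalence(events_by_stay, test)

    rows = []
    for train_g in genders:
        dev_g = [s for s in dev if gender_by_stay[s] == train_g]
        n_val = max(1, int(round(val_fraction * len(dev_g))))
        val_ids, train_ids = dev_g[:n_val], dev_g[n_val:]
        model = fit_variant(fm, train_ids, val_ids, variant, p)
        risk = risk_by_stay(predict_risk(model, fm.subset(test)))
        for eval_g in genders:
            members = [s for s in test if gender_by_stay[s] == eval_g]
            res = evaluate_subset(risk, events_by_stay, members, recall_level, prev_ref)
            rows.append({"train_gender": train_g, "eval_gender": eval_g, **res})
    return pd.DataFrame(rows)


def data_fraction_experiment(fm: FeatureMatrix, events_by_stay: dict, fractions,
                             seeds, params: GBDTParams | None = None,
                             variant: str = "snapshot", test_fraction: float = 0.25,
                             val_fraction: float = 0.2,
                             split_seed: int = 0) -> pd.DataFrame:
    """Learning curve: test event-based AUPRC as a function of the fraction
    of training stays used, over several subsampling seeds. The test set is
    fixed across fractions and seeds."""
    p = params or GBDTParams()
    ids = sorted(set(fm.frame["stay_id"]))
    rng = np.random.default_rng(split_seed)
    order = rng.permutation(len(ids))
    n_test = int(round(test_fraction * len(ids)))
    test = [ids[i] for i in order[:n_test]]
    dev = [ids[i] for i in order[n_test:]]
    n_val = max(1, int(round(val_fraction * len(dev))))
    val_ids, train_pool = dev[:n_val], dev[n_val:]
    fm_test = fm.subset(test)

    rows = []
    for frac in sorted(fractions):
        n_train = max(2, int(round(frac * len(train_pool))))
        for s in seeds:
            sub_rng = np.random.default_rng([split_seed, s])
            train_ids = [train_pool[i]
                         for i in sub_rng.permutation(len(train_pool))[:n_train]]
            labels = fm.frame[fm.frame["stay_id"].isin(set(train_ids))
                              & fm.frame["valid"]]["label"]
            if labels.nunique() < 2:
                rows.append({"fraction": frac, "seed": s, "n_train_stays": n_train,
                             "auprc": float("nan")})
                continue
            model = fit_variant(fm, train_ids, val_ids, variant,
                                GBDTParams(**{**p.__dict__, "seed": s}))
            risk = risk_by_stay(predict_risk(model, fm_test))
            res = evaluate_subset(risk, events_by_stay, test)
            rows.append({"fraction": frac, "seed": s, "n_train_stays": n_train,
                         "auprc": res["auprc"]})
    return pd.DataFrame(rows)


def clinician_agreement(ranking, ratings: dict[str, float], k: int,
                        unrated: str = "skip", n_random: int = 100,
                        seed: int = 0) -> dict:
    """Mean clinician-assigned relevance of the top-k ranked variables, with
    a random-ranking baseline (mean over ``n_random`` resampled rankings).

    ``unrated`` controls variables missing from the ratings table: ``skip``
    drops them, ``zero`` scores them 0.
    """
    if unrated not in ("skip", "zero"):
        raise ValueError("unrated must be 'skip' or 'zero'")

    def mean_rating(vars_topk):
        vals = []
        for v in vars_topk:
            if v in ratings:
                vals.append(ratings[v])
            elif unrated == "zero":
                vals.append(0.0)
        return float(np.mean(vals)) if vals else float("nan")

    ranking = list(ranking)
    score = mean_rating(ranking[:k])
    rng = np.random.default_rng(seed)
    baselines = []
    for _ in range(n_random):
        perm = list(rng.permutation(ranking))
        baselines.append(mean_rating(perm[:k]))
    return {"k": k, "mean_relevance": score,
            "random_baseline": float(np.nanmean(baselines))}
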