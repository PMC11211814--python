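"""Shared fixtures: small seeded cohorts and their downstream products."""

import numpy as np
import pandas as pd
import pytest

from akiwatch import (CohortConfig, annotate_cohort, generate_cohort)
from akiwatch import grid_features


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_patients=40, seed=7))


@pytest.fixture(scope="session")
def small_annotations(small_cohort):
    return annotate_cohort(small_cohort)


@pytest.fixture(scope="session")
def small_features(small_cohort, small_annotations):
    return grid_features.featurize_cohort(small_cohort, small_annotations)


@pytest.fixture(scope="session")
def medium_cohort():
    return generate_cohort(CohortConfig(n_patients=150, seed=11))


@pytest.fixture(scope="session")
def medium_pipeline(medium_cohort):
    """(cohort, annotations, feature matrix, events-by-stay) at a size where
    models are trainable."""
    ann = annotate_cohort(medium_cohort)
    fm = grid_features.featurize_cohort(medium_cohort, ann)
    events = {sid: a.events for sid, a in ann.items()}
    return medium_cohort, ann, fm, events


def make_stay(n_hours=48, creat=None, urine=None, weight=80.0, rrt=(),
              stay_id="stay_fix", hr_every_min=30):
    """Build a PatientStay from primitive criterion inputs.

    ``creat``: sequence of (time_h, mg/dl); ``urine``: hourly volumes (ml),
    NaN = undocumented, charted at end of hour.
    """
    from akiwatch.synthetic_cohort import PatientStay

    rows = []
    hr_times = np.arange(0.0, n_hours, hr_every_min / 60.0)
    for t in hr_times:
        rows.append(("hr", t, 80.0))
    for t, v in (creat or []):
        rows.append(("creatinine", float(t), float(v)))
    if urine is not None:
        for h, v in enumerate(urine):
            if not np.isnan(v):
                rows.append(("urine", float(h + 1), float(v)))
    obs = (pd.DataFrame(rows, columns=["variable_id", "time_h", "value"])
           .sort_values(["variable_id", "time_h"], kind="stable").reset_index(drop=True))
    return PatientStay(
        stay_id=stay_id, admission_time=pd.Timestamp("2020-01-01"),
        age=60.0, gender="F", weight=weight, diagnostic_group="sepsis",
        discharge_h=float(n_hours), observations=obs,
        treatments=pd.DataFrame(columns=["treatment_id", "time_h", "amount"]),
        rrt_intervals=list(rrt),
    )
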