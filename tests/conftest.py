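import numpy as np
import pandas as pd
import pytest

from cidkit.simulate import (
    DEFAULT_DESIGNS,
    SimulationParams,
    StudyDesign,
    simulate_cohort,
)

TWO_ARMS = {"glycopyrronium": 0.5, "tiotropium": 0.5}


@pytest.fixture(scope="session")
def small_cohort():
    """A 160-patient pooled cohort across the four default study designs."""
    params = SimulationParams(seed=11)
    n = {d.study_id: 40 for d in DEFAULT_DESIGNS}
    return simulate_cohort(DEFAULT_DESIGNS, params, n)


@pytest.fixture(scope="session")
def cid_small(small_cohort):
    from cidkit.endpoints import derive_all

    return derive_all(*small_cohort)


@pytest.fixture(scope="session")
def calibration_cohort():
    """10,000 patients from a single 52-week study at default parameters."""
    design = (StudyDesign("GLOW2", 52, {"glycopyrronium": 0.5, "tiotropium": 0.25, "placebo": 0.25}),)
    return simulate_cohort(design, SimulationParams(seed=5), {"GLOW2": 10_000})


def single_patient_tables(
    weeks,
    fev1,
    sgrq,
    fev1_baseline=1.5,
    sgrq_baseline=50.0,
    duration_weeks=26,
    last_contact_day=None,
    exac_days=(),
    pid="P1",
):
    """Hand-built one-patient cohort tables for endpoint unit tests."""
    end_day = 7 * duration_weeks
    last = end_day if last_contact_day is None else last_contact_day
    baseline = pd.DataFrame(
        [
            {
                "patient_id": pid,
                "study_id": "S",
                "arm": "glycopyrronium",
                "sex": "male",
                "age": 64.0,
                "smoking": "ex",
                "gold_severity": "moderate",
                "fev1_baseline": fev1_baseline,
                "fev1_pct_pred": 55.0,
                "sgrq_baseline": sgrq_baseline,
                "bdi": 6,
                "eosinophils": 150.0,
                "ics_use": True,
                "prior_exacerbation": False,
            }
        ]
    )
    visits = pd.DataFrame(
        {
            "patient_id": pid,
            "visit_week": list(weeks),
            "visit_day": [7 * w for w in weeks],
            "fev1": list(fev1),
            "sgrq": list(sgrq),
        }
    )
    exac = pd.DataFrame(
        {"patient_id": [pid] * len(exac_days), "onset_day": list(exac_days), "severity": ["moderate"] * len(exac_days)},
        columns=["patient_id", "onset_day", "severity"],
    )
    if exac.empty:
        exac = exac.astype({"onset_day": int}, errors="ignore")
    followup = pd.DataFrame(
        [
            {
                "patient_id": pid,
                "last_contact_day": last,
                "discontinued_early": last < end_day,
                "study_end_day": end_day,
            }
        ]
    )
    return baseline, visits, exac, followup


def brute_force_sustained(weeks, flags, interval=4, min_consecutive=2, fraction=0.5):
    """Independent plain-Python evaluation of the written sustained rule.

    ``flags``: sequence of True / False / None (None = measurement missing).
    Returns the earliest qualifying week or None. Rule (a): flagged at v and
    at the visit exactly one interval later (which must be measured and
    flagged), extended to runs of ``min_consecutive``. Rule (b): flagged at
    >= ``fraction`` of all measured visits at or after v.
    """
    weeks = list(weeks)
    flag_of = dict(zip(weeks, flags))
    for v, fl in zip(weeks, flags):
        if fl is not True:
            continue
        run = all(
            flag_of.get(v + j * interval) is True for j in range(1, min_consecutive)
        )
        if run:
            return v
        avail = [w for w in weeks if w >= v and flag_of[w] is not None]
        hits = [w for w in avail if flag_of[w] is True]
        if avail and len(hits) / len(avail) >= fraction:
            return v
    return None
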