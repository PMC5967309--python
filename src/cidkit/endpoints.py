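"""Derivation of first and sustained clinically important deterioration (CID).

A CID is the first occurrence of any of three components relative to
baseline: a >=100 mL fall in pre-dose FEV1, a >=4-point rise in SGRQ total
score, or a moderate-to-severe COPD exacerbation after the first dose. A
component is *sustained* when it recurs at two or more consecutive visits
4 weeks apart, or is present at >=50% of all available subsequent visits;
a qualifying exacerbation is sustained by definition.

Times are integer days from first dose (day 1 = first dose). Patients with
no event are censored at study end, or at last contact after early
discontinuation. Events on the day of discontinuation count as events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEV1 = "FEV1"
SGRQ = "SGRQ"
EXACERBATION = "EXACERBATION"
COMPONENTS = (FEV1, SGRQ, EXACERBATION)

DAYS_PER_WEEK = 7

# guard against float representation noise at the inclusive thresholds;
# a true 1 mL / 0.01 unit perturbation is far larger than this
_EPS = 1e-9


@dataclass(frozen=True)
class CidThresholds:
    """Deterioration thresholds and the sustained-rule parameters.

    fev1_drop: decrease from baseline in pre-dose FEV1, liters (inclusive).
    sgrq_rise: increase from baseline in SGRQ total score (inclusive).
    sustained_min_consecutive: visits in a row (nominal spacing one visit
        interval) that make a component sustained.
    sustained_fraction: alternative route -- fraction of all available
        subsequent visits (including the triggering visit) that must flag.
    """

    fev1_drop: float = 0.100
    sgrq_rise: float = 4.0
    sustained_min_consecutive: int = 2
    sustained_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.fev1_drop <= 0:
            raise ValueError(f"fev1_drop must be > 0, got {self.fev1_drop}")
        if self.sgrq_rise <= 0:
            raise ValueError(f"sgrq_rise must be > 0, got {self.sgrq_rise}")
        if self.sustained_min_consecutive < 2:
            raise ValueError(
                f"sustained_min_consecutive must be >= 2, got {self.sustained_min_consecutive}"
            )
        if not 0.0 < self.sustained_fraction <= 1.0:
            raise ValueError(
                f"sustained_fraction must be in (0, 1], got {self.sustained_fraction}"
            )


def flag_components(
    baseline: pd.DataFrame,
    visits: pd.DataFrame,
    thresholds: CidThresholds | None = None,
) -> pd.DataFrame:
    """Flag the FEV1 and SGRQ deterioration components at every visit.

    Returns one row per visit row with nullable-boolean ``fev1_flag`` and
    ``sgrq_flag`` columns: True when the inclusive threshold is met, False
    when measured and not met, and <NA> when either the visit measurement
    or the baseline value is missing. Patients with a missing baseline are
    excluded from that component with a logged warning, never silently.
    """
    thresholds = thresholds or CidThresholds()
    base = baseline[["patient_id", "fev1_baseline", "sgrq_baseline"]]
    for col, comp in (("fev1_baseline", FEV1), ("sgrq_baseline", SGRQ)):
        missing = base.loc[base[col].isna(), "patient_id"].tolist()
        if missing:
            logger.warning(
                "%d patient(s) excluded from the %s component (missing baseline): %s",
                len(missing),
                comp,
                ", ".join(map(str, missing[:10])),
            )
    m = visits.merge(base, on="patient_id", how="left", validate="many_to_one")

    fev1_drop = m["fev1_baseline"] - m["fev1"]
    sgrq_rise = m["sgrq"] - m["sgrq_baseline"]
    fev1_flag = pd.array(fev1_drop >= thresholds.fev1_drop - _EPS, dtype="boolean")
    sgrq_flag = pd.array(sgrq_rise >= thresholds.sgrq_rise - _EPS, dtype="boolean")
    fev1_flag[fev1_drop.isna().to_numpy()] = pd.NA
    sgrq_flag[sgrq_rise.isna().to_numpy()] = pd.NA

    out = m[["patient_id", "visit_week", "visit_day"]].copy()
    out["fev1_flag"] = fev1_flag
    out["sgrq_flag"] = sgrq_flag
    return out


def censor_day(followup: Mapping) -> int:
    """Censoring day for a patient without an event.

    Completers are censored at study end; early discontinuations at the
    last contact day.
    """
    last = int(followup["last_contact_day"])
    end = int(followup["study_end_day"])
    if last > end:
        raise ValueError(
            f"last_contact_day {last} exceeds study_end_day {end} "
            f"for patient {followup.get('patient_id', '?')}"
        )
    if last < 1:
        raise ValueError(f"last_contact_day must be >= 1, got {last}")
    return last if bool(followup["discontinued_early"]) else end


def _first_flag_week(weeks: np.ndarray, flags: np.ndarray) -> int | None:
    """Week of the first True flag (NaN-coded missing flags never trigger)."""
    hit = np.flatnonzero(flags == 1.0)
    return int(weeks[hit[0]]) if hit.size else None


def _sustained_flag_week(
    weeks: np.ndarray,
    flags: np.ndarray,
    interval_weeks: int,
    min_consecutive: int,
    fraction: float,
) -> int | None:
    """Earliest week at which a flagged component becomes sustained.

    ``flags`` is float-coded: 1.0 flagged, 0.0 measured-not-flagged, NaN
    missing. Rule (a): the component flags at ``min_consecutive`` visits in
    a row at nominal ``interval_weeks`` spacing; a missing intervening
    measurement breaks the run. Rule (b): from the triggering visit onward,
    the component flags at >= ``fraction`` of all visits with an available
    measurement (the triggering visit included). Evaluated retrospectively
    over the full follow-up.
    """
    idx_of_week = {int(w): i for i, w in enumerate(weeks)}
    available = ~np.isnan(flags)
    flagged = available & (flags == 1.0)
    for i in np.flatnonzero(flagged):
        v = int(weeks[i])
        run = True
        for j in range(1, min_consecutive):
            k = idx_of_week.get(v + j * interval_weeks)
            if k is None or not flagged[k]:
                run = False
                break
        if run:
            return v
        later = weeks >= v
        n_avail = int(np.count_nonzero(available & later))
        n_flag = int(np.count_nonzero(flagged & later))
        if n_avail > 0 and n_flag / n_avail >= fraction - _EPS:
            return v
    return None


def _flags_to_float(series: pd.Series) -> np.ndarray:
    return series.astype("Float64").to_numpy(dtype=float, na_value=np.nan)


def _first_exacerbation_day(exacerbations: pd.DataFrame) -> int | None:
    if exacerbations.empty:
        return None
    return int(exacerbations["onset_day"].min())


def _component_result(
    flags: pd.DataFrame,
    exacerbations: pd.DataFrame,
    followup: Mapping,
    thresholds: CidThresholds,
    visit_interval_weeks: int,
    sustained: bool,
) -> tuple[dict[str, int | None], int]:
    """Per-component event days (None = no event) and the censor day."""
    cens = censor_day(followup)
    weeks = flags["visit_week"].to_numpy()
    days: dict[str, int | None] = {}
    for comp, col in ((FEV1, "fev1_flag"), (SGRQ, "sgrq_flag")):
        arr = _flags_to_float(flags[col])
        if sustained:
            w = _sustained_flag_week(
                weeks,
                arr,
                visit_interval_weeks,
                thresholds.sustained_min_consecutive,
                thresholds.sustained_fraction,
            )
        else:
            w = _first_flag_week(weeks, arr)
        days[comp] = None if w is None else w * DAYS_PER_WEEK
    # a single qualifying moderate-to-severe exacerbation is sustained by definition
    days[EXACERBATION] = _first_exacerbation_day(exacerbations)
    return days, cens


def _overall(days: Mapping[str, int | None], cens: int) -> tuple[int, bool, tuple[str, ...]]:
    triggered = {c: d for c, d in days.items() if d is not None}
    if not triggered:
        return cens, False, ()
    t = min(triggered.values())
    comps = tuple(c for c in COMPONENTS if triggered.get(c) == t)  # ties kept
    return t, True, comps


def first_cid(
    flags: pd.DataFrame,
    exacerbations: pd.DataFrame,
    followup: Mapping,
    thresholds: CidThresholds | None = None,
    visit_interval_weeks: int = 4,
) -> dict:
    """First-CID fields for one patient.

    The overall first-CID day is the minimum over triggered component first
    times; every component attaining that minimum is recorded. With no
    trigger the patient is censored (event False) at the censoring day.
    """
    thresholds = thresholds or CidThresholds()
    days, cens = _component_result(
        flags, exacerbations, followup, thresholds, visit_interval_weeks, sustained=False
    )
    t, event, comps = _overall(days, cens)
    out = {"first_cid_day": t, "first_cid_event": event, "first_cid_components": comps}
    for comp, key in ((FEV1, "fev1"), (SGRQ, "sgrq"), (EXACERBATION, "exac")):
        out[f"{key}_first_day"] = days[comp] if days[comp] is not None else cens
        out[f"{key}_first_event"] = days[comp] is not None
    out["censor_day"] = cens
    return out


def sustained_cid(
    flags: pd.DataFrame,
    exacerbations: pd.DataFrame,
    followup: Mapping,
    thresholds: CidThresholds | None = None,
    visit_interval_weeks: int = 4,
) -> dict:
    """Sustained-CID fields for one patient (see module docstring for the rule)."""
    thresholds = thresholds or CidThresholds()
    days, cens = _component_result(
        flags, exacerbations, followup, thresholds, visit_interval_weeks, sustained=True
    )
    t, event, comps = _overall(days, cens)
    out = {
        "sustained_cid_day": t,
        "sustained_cid_event": event,
        "sustained_cid_components": comps,
    }
    for comp, key in ((FEV1, "fev1"), (SGRQ, "sgrq"), (EXACERBATION, "exac")):
        out[f"{key}_sustained_day"] = days[comp] if days[comp] is not None else cens
        out[f"{key}_sustained_event"] = days[comp] is not None
    return out


def _check_referential_integrity(
    baseline: pd.DataFrame,
    visits: pd.DataFrame,
    exacerbations: pd.DataFrame,
    followup: pd.DataFrame,
) -> None:
    known = set(baseline["patient_id"])
    problems: list[str] = []
    for name, table in (("visits", visits), ("exacerbations", exacerbations)):
        orphans = sorted(set(table["patient_id"]) - known)
        if orphans:
            problems.append(f"{name}: unknown patient_id(s) {orphans[:10]}")
    missing_fu = sorted(known - set(followup["patient_id"]))
    if missing_fu:
        problems.append(f"followup: missing patient_id(s) {missing_fu[:10]}")
    orphan_fu = sorted(set(followup["patient_id"]) - known)
    if orphan_fu:
        problems.append(f"followup: unknown patient_id(s) {orphan_fu[:10]}")
    if problems:
        raise ValueError("cohort tables are inconsistent: " + "; ".join(problems))


def derive_all(
    baseline: pd.DataFrame,
    visits: pd.DataFrame,
    exacerbations: pd.DataFrame,
    followup: pd.DataFrame,
    thresholds: CidThresholds | None = None,
    visit_interval_weeks: int = 4,
) -> pd.DataFrame:
    """Derive first- and sustained-CID results for every patient in a cohort.

    Equivalent to applying :func:`flag_components`, :func:`first_cid` and
    :func:`sustained_cid` patient by patient; rejects cohorts with orphan
    visit/exacerbation rows, naming the offending ids.

    Returns a DataFrame with one row per baseline patient: overall and
    per-component event days/indicators for both endpoints, the triggering
    component sets (``"+"``-joined labels), and the censoring day.
    """
    thresholds = thresholds or CidThresholds()
    _check_referential_integrity(baseline, visits, exacerbations, followup)

    flags = flag_components(baseline, visits, thresholds)
    flags = flags.sort_values(["patient_id", "visit_week"], kind="stable")
    flag_groups = dict(iter(flags.groupby("patient_id", sort=False)))
    exa_groups = dict(iter(exacerbations.groupby("patient_id", sort=False)))
    empty_exa = exacerbations.iloc[0:0]
    empty_flags = flags.iloc[0:0]
    fu_indexed = followup.set_index("patient_id", drop=False)

    rows = []
    for pid in baseline["patient_id"]:
        fu = fu_indexed.loc[pid]
        pflags = flag_groups.get(pid, empty_flags)
        pexa = exa_groups.get(pid, empty_exa)
        rec: dict = {"patient_id": pid}
        rec.update(first_cid(pflags, pexa, fu, thresholds, visit_interval_weeks))
        rec.update(sustained_cid(pflags, pexa, fu, thresholds, visit_interval_weeks))
        rec["first_cid_components"] = "+".join(rec["first_cid_components"])
        rec["sustained_cid_components"] = "+".join(rec["sustained_cid_components"])
        rows.append(rec)
    out = pd.DataFrame(rows)
    # internal consistency: sustained implies first, in order
    sus = out["sustained_cid_event"]
    assert bool((~sus | out["first_cid_event"]).all())
    assert bool((out.loc[sus, "first_cid_day"] <= out.loc[sus, "sustained_cid_day"]).all())
    logger.info(
        "derived CID for %d patients: %d first events, %d sustained events",
        len(out),
        int(out["first_cid_event"].sum()),
        int(out["sustained_cid_event"].sum()),
    )
    return out
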