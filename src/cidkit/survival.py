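"""Time-to-event machinery: Kaplan-Meier, log-rank, Cox proportional hazards.

Thin, validated wrappers around lifelines, configured for this analysis:
Efron handling of tied event times (events pile up on the 28-day visit
grid), study as a stratum for pooled fits, log-log (exponential Greenwood)
confidence bands for the median, two-sided Wald tests at alpha = 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times, qth_survival_times

logger = logging.getLogger(__name__)

AGE_CUTOFF_YEARS = 65
EOS_CUTOFF_CELLS_PER_UL = 300

#: Covariates of the adjusted Cox model: treatment, gender, age group,
#: baseline COPD severity, smoking status and baseline eosinophil status.
DEFAULT_COVARIATES = (
    "treatment",
    "sex_male",
    "age_ge65",
    "gold_severe",
    "smoking_current",
    "eos_ge300",
)


@dataclass
class KmCurve:
    """Product-limit estimate with median/quartile summaries.

    ``median`` (and quartiles) are ``inf`` when the curve never reaches the
    corresponding survival level; ``median_defined`` flags that case.
    """

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    survival: np.ndarray
    median: float
    median_ci: tuple[float, float]
    q25: float
    q75: float
    n: int
    n_events: int

    @property
    def median_defined(self) -> bool:
        return np.isfinite(self.median)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "censored": self.censored,
                "survival": self.survival,
            }
        )


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    n_per_group: dict


@dataclass
class CoxFit:
    """Per-covariate hazard ratios with Wald 95% CIs and p-values."""

    summary: pd.DataFrame  # index: covariate; columns: coef, se, hr, ci_lower, ci_upper, p
    log_likelihood: float
    n: int
    n_events: int
    diagnostics: list[str] = field(default_factory=list)

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.summary.loc[covariate]
        return float(row["ci_lower"]), float(row["ci_upper"])

    def p(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])


def km_estimate(
    records: pd.DataFrame, duration_col: str = "time", event_col: str = "event"
) -> KmCurve:
    """Kaplan-Meier product-limit estimate of the time-to-event curve.

    The median is the earliest time at which survival drops to <= 0.5, with
    a log-log Greenwood 95% CI; 25%/75% quartiles analogously. An
    all-censored sample yields survival identically 1 and an undefined
    (infinite) median.
    """
    if records.empty:
        raise ValueError("km_estimate requires at least one record")
    t = records[duration_col].to_numpy(dtype=float)
    if np.any(t <= 0):
        raise ValueError("event/censoring times must be > 0")
    e = records[event_col].to_numpy(dtype=bool)

    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index else kmf.event_table
    sf = kmf.survival_function_["KM_estimate"]
    surv_at = sf.reindex(table.index).to_numpy()

    if e.any():
        median = float(kmf.median_survival_time_)
        ci_df = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci_df.iloc[0, 0]), float(ci_df.iloc[0, 1])
    else:
        median, lo, hi = np.inf, np.inf, np.inf
    q25 = float(qth_survival_times(0.75, sf))
    q75 = float(qth_survival_times(0.25, sf))

    return KmCurve(
        times=table.index.to_numpy(dtype=float),
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
        censored=table["censored"].to_numpy(dtype=int),
        survival=surv_at,
        median=median,
        median_ci=(lo, hi),
        q25=q25,
        q75=q75,
        n=len(t),
        n_events=int(e.sum()),
    )


def logrank_test(
    records: pd.DataFrame,
    group_col: str = "group",
    duration_col: str = "time",
    event_col: str = "event",
) -> LogrankResult:
    """Two-group log-rank test (1-df chi-square)."""
    groups = [g for g, _ in records.groupby(group_col, sort=True)]
    if len(groups) != 2:
        raise ValueError(f"logrank_test requires exactly two groups, got {groups}")
    sub = {g: records[records[group_col] == g] for g in groups}
    for g, df in sub.items():
        if df.empty:
            raise ValueError(f"group {g!r} has zero subjects")
    a, b = groups
    res = _ll_logrank(
        sub[a][duration_col],
        sub[b][duration_col],
        event_observed_A=sub[a][event_col].astype(bool),
        event_observed_B=sub[b][event_col].astype(bool),
    )
    return LogrankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        n_per_group={a: len(sub[a]), b: len(sub[b])},
    )


def cox_fit(
    records: pd.DataFrame,
    covariates: Sequence[str] = ("treatment",),
    duration_col: str = "time",
    event_col: str = "event",
    strata: str | None = None,
) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties, optional baseline strata).

    Degenerate strata (zero events) and convergence problems are reported
    in ``diagnostics`` rather than silently ignored.
    """
    covariates = list(covariates)
    cols = covariates + [duration_col, event_col] + ([strata] if strata else [])
    df = records[cols].copy()
    n_events = int(df[event_col].sum())
    if n_events == 0:
        raise ValueError("cox_fit requires at least one event")
    if df[covariates].drop_duplicates().shape[0] < 2:
        raise ValueError("cox_fit requires >= 2 distinct covariate patterns")

    diagnostics: list[str] = []
    if strata:
        for s, g in df.groupby(strata):
            if int(g[event_col].sum()) == 0:
                diagnostics.append(
                    f"stratum {s!r} has zero events and contributes no information"
                )
    for cov in covariates:
        tab = df.groupby(cov)[event_col].sum()
        if (tab == 0).any() and df[cov].nunique() == 2:
            diagnostics.append(
                f"covariate {cov!r} has a level with zero events (possible separation)"
            )

    cph = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(
                df,
                duration_col=duration_col,
                event_col=event_col,
                strata=strata,
                show_progress=False,
            )
        except Exception as exc:  # convergence failure, singular matrix, ...
            raise ValueError(f"Cox model failed to converge: {exc}") from exc
    for w in caught:
        if "converg" in str(w.message).lower() or "variance" in str(w.message).lower():
            diagnostics.append(str(w.message))

    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    if diagnostics:
        logger.warning("cox_fit diagnostics: %s", "; ".join(diagnostics))
    return CoxFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=n_events,
        diagnostics=diagnostics,
    )


def make_survival_records(
    cid_results: pd.DataFrame,
    baselines: pd.DataFrame,
    endpoint: str = "first",
    component: str | None = None,
) -> pd.DataFrame:
    """Join derived CID results to baselines into an analysis-ready table.

    ``endpoint`` is ``"first"`` or ``"sustained"``; ``component`` one of
    ``"fev1"``, ``"sgrq"``, ``"exac"`` or None for the overall composite.
    Output columns: patient_id, time, event, arm, study_id and the grouped
    covariates used by the Cox model (age_group, eos_group, ...).
    """
    if endpoint not in ("first", "sustained"):
        raise ValueError(f"endpoint must be 'first' or 'sustained', got {endpoint!r}")
    if component is None:
        time_col, event_col = f"{endpoint}_cid_day", f"{endpoint}_cid_event"
    else:
        if component not in ("fev1", "sgrq", "exac"):
            raise ValueError(f"unknown component {component!r}")
        time_col, event_col = f"{component}_{endpoint}_day", f"{component}_{endpoint}_event"

    cols = [
        "patient_id",
        "study_id",
        "arm",
        "sex",
        "age",
        "gold_severity",
        "smoking",
        "eosinophils",
    ]
    m = cid_results[["patient_id", time_col, event_col]].merge(
        baselines[cols], on="patient_id", validate="one_to_one"
    )
    out = pd.DataFrame(
        {
            "patient_id": m["patient_id"],
            "time": m[time_col].astype(float),
            "event": m[event_col].astype(bool),
            "arm": m["arm"],
            "study_id": m["study_id"],
            "sex": m["sex"],
            "age_group": np.where(m["age"] >= AGE_CUTOFF_YEARS, ">=65", "<65"),
            "gold_severity": m["gold_severity"],
            "smoking": m["smoking"],
            "eos_group": np.where(
                m["eosinophils"] >= EOS_CUTOFF_CELLS_PER_UL, ">=300", "<300"
            ),
        }
    )
    return out


def encode_covariates(records: pd.DataFrame, contrast: tuple[str, str]) -> pd.DataFrame:
    """Binary design columns: treatment (contrast[0]=1 vs contrast[1]=0) and
    the standard adjustment covariates."""
    active, reference = contrast
    df = records[records["arm"].isin(contrast)].copy()
    df["treatment"] = (df["arm"] == active).astype(int)
    df["sex_male"] = (df["sex"] == "male").astype(int)
    df["age_ge65"] = (df["age_group"] == ">=65").astype(int)
    df["gold_severe"] = (df["gold_severity"] == "severe").astype(int)
    df["smoking_current"] = (df["smoking"] == "current").astype(int)
    df["eos_ge300"] = (df["eos_group"] == ">=300").astype(int)
    return df


@dataclass
class TreatmentContrast:
    """Headline two-arm comparison: Cox HR, per-arm KM curves, log-rank test."""

    contrast: tuple[str, str]
    endpoint: str
    cox: CoxFit
    km: dict[str, KmCurve]
    logrank: LogrankResult

    @property
    def hazard_ratio(self) -> float:
        return self.cox.hr("treatment")


def fit_treatment_contrasts(
    cid_results: pd.DataFrame,
    baselines: pd.DataFrame,
    contrast: tuple[str, str] = ("glycopyrronium", "tiotropium"),
    endpoint: str = "first",
    adjust: bool = True,
    stratify_by_study: bool = True,
) -> TreatmentContrast:
    """Fit the headline two-arm comparison on derived CID results.

    Cox model with treatment (plus the standard covariates when
    ``adjust``), baseline hazard stratified by study by default; per-arm
    Kaplan-Meier curves; two-group log-rank test.
    """
    records = make_survival_records(cid_results, baselines, endpoint=endpoint)
    present = set(records["arm"])
    unknown = [a for a in contrast if a not in present]
    if unknown:
        raise ValueError(f"unknown arm label(s) {unknown}; cohort arms are {sorted(present)}")
    df = encode_covariates(records, contrast)
    covs = list(DEFAULT_COVARIATES) if adjust else ["treatment"]
    cox = cox_fit(df, covs, strata="study_id" if stratify_by_study else None)
    km = {arm: km_estimate(df[df["arm"] == arm]) for arm in contrast}
    lr = logrank_test(df.assign(group=df["arm"]), group_col="group")
    return TreatmentContrast(
        contrast=tuple(contrast), endpoint=endpoint, cox=cox, km=km, logrank=lr
    )
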