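"""Reporting surfaces: event-count summaries, at-event comparisons, forests.

Three tabular products mirror the standard presentation of a pooled CID
analysis: a per-arm event-count table (first/sustained x overall/FEV1/
SGRQ/exacerbation, n and %), a comparison of FEV1 and SGRQ at baseline
versus at the triggering visit, and subgroup forest tables of two-arm
hazard ratios. Because a printed p-value in this literature may come from
either the log-rank test or the Cox model, both are emitted side by side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import survival

logger = logging.getLogger(__name__)

ENDPOINTS = ("first", "sustained")
COMPONENT_KEYS = {"overall": None, "FEV1": "fev1", "SGRQ": "sgrq", "exacerbation": "exac"}


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed trial tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(count: int, n: int, ndigits: int = 1) -> float:
    """Percentage as printed in event tables: 100*count/n, half-away, 1 dp."""
    if n <= 0:
        raise ValueError(f"arm N must be positive, got {n}")
    if not 0 <= count <= n:
        raise ValueError(f"count {count} outside [0, {n}]")
    return round_half_away(100.0 * count / n, ndigits)


def summarize_events(
    cid_results: pd.DataFrame,
    baselines: pd.DataFrame,
    contrast: tuple[str, str] = ("glycopyrronium", "tiotropium"),
    stratify_by_study: bool = True,
) -> pd.DataFrame:
    """Per-arm counts and percentages of first/sustained CID by component.

    One row per endpoint x component with ``n_<arm>``, ``count_<arm>``,
    ``pct_<arm>`` columns for each arm of ``contrast`` plus between-arm
    ``p_logrank`` and ``p_cox`` from the corresponding time-to-event
    comparison.
    """
    arm_n = baselines["arm"].value_counts()
    for arm in contrast:
        if arm_n.get(arm, 0) == 0:
            raise ValueError(f"arm {arm!r} is empty")
    rows = []
    for endpoint in ENDPOINTS:
        for label, component in COMPONENT_KEYS.items():
            rec = survival.make_survival_records(
                cid_results, baselines, endpoint=endpoint, component=component
            )
            rec = rec[rec["arm"].isin(contrast)]
            row: dict = {"endpoint": endpoint, "component": label}
            for arm in contrast:
                sub = rec[rec["arm"] == arm]
                count = int(sub["event"].sum())
                row[f"n_{arm}"] = int(arm_n[arm])
                row[f"count_{arm}"] = count
                row[f"pct_{arm}"] = format_percent(count, int(arm_n[arm]))
            if rec["event"].any():
                lr = survival.logrank_test(rec.assign(group=rec["arm"]), group_col="group")
                row["p_logrank"] = lr.p_value
                try:
                    cox = survival.cox_fit(
                        survival.encode_covariates(rec, contrast),
                        ["treatment"],
                        strata="study_id" if stratify_by_study else None,
                    )
                    row["p_cox"] = cox.p("treatment")
                except ValueError as exc:
                    logger.warning("Cox comparison unavailable for %s/%s: %s", endpoint, label, exc)
                    row["p_cox"] = np.nan
            else:
                row["p_logrank"] = np.nan
                row["p_cox"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def values_at_event(
    cid_results: pd.DataFrame,
    visits: pd.DataFrame,
    baselines: pd.DataFrame,
    contrast: tuple[str, str] = ("glycopyrronium", "tiotropium"),
) -> pd.DataFrame:
    """Mean +/- SD of FEV1/SGRQ at baseline and at the triggering visit.

    For each endpoint and measure, restricted to patients whose
    corresponding component triggered; the at-event value is the
    measurement at the visit whose day equals the component event day.
    Event days with no matching measured visit are counted per arm in
    ``n_unmatched`` (and excluded from the at-event moments). Single-patient
    cells report SD 0 with ``n`` = 1 so degenerate groups stay visible.
    A cohort with no events yields an empty frame, not an error.
    """
    measures = {
        "FEV1": ("fev1", "fev1_baseline", "fev1"),
        "SGRQ": ("sgrq", "sgrq_baseline", "sgrq"),
    }
    base = baselines.set_index("patient_id")
    rows = []
    for endpoint in ENDPOINTS:
        for measure, (key, base_col, visit_col) in measures.items():
            ev = cid_results[cid_results[f"{key}_{endpoint}_event"]]
            for arm in contrast:
                pids = [p for p in ev["patient_id"] if base.loc[p, "arm"] == arm]
                sub = ev[ev["patient_id"].isin(pids)]
                merged = sub.merge(
                    visits,
                    left_on=["patient_id", f"{key}_{endpoint}_day"],
                    right_on=["patient_id", "visit_day"],
                    how="left",
                )
                vals = merged[visit_col]
                unmatched = merged.loc[vals.isna(), "patient_id"].tolist()
                if unmatched:
                    logger.warning(
                        "%s/%s (%s): %d event day(s) without a measured visit: %s",
                        endpoint,
                        measure,
                        arm,
                        len(unmatched),
                        ", ".join(map(str, unmatched[:10])),
                    )
                vals = vals.dropna()
                base_vals = base.loc[sub["patient_id"], base_col]
                n = len(vals)
                rows.append(
                    {
                        "endpoint": endpoint,
                        "measure": measure,
                        "arm": arm,
                        "n": n,
                        "n_unmatched": len(unmatched),
                        "baseline_mean": float(base_vals.mean()) if len(base_vals) else np.nan,
                        "baseline_sd": _sd(base_vals),
                        "event_mean": float(vals.mean()) if n else np.nan,
                        "event_sd": _sd(vals),
                    }
                )
            a = [r for r in rows if r["endpoint"] == endpoint and r["measure"] == measure]
            p_base, p_event = _between_arm_p(
                cid_results, visits, base, endpoint, key, base_col, visit_col, contrast
            )
            for r in a[-len(contrast):]:
                r["p_baseline"] = p_base
                r["p_event"] = p_event
    out = pd.DataFrame(rows)
    return out[out["n"] + out["n_unmatched"] > 0].reset_index(drop=True)


def _sd(values: pd.Series) -> float:
    values = pd.Series(values).dropna()
    if len(values) == 0:
        return np.nan
    if len(values) == 1:
        return 0.0  # n=1 cell; visible through the n column
    return float(values.std(ddof=1))


def _between_arm_p(cid_results, visits, base, endpoint, key, base_col, visit_col, contrast):
    """Welch t-test comparing arms at baseline and at the event visit."""
    samples_base, samples_event = [], []
    ev = cid_results[cid_results[f"{key}_{endpoint}_event"]]
    for arm in contrast:
        pids = [p for p in ev["patient_id"] if base.loc[p, "arm"] == arm]
        sub = ev[ev["patient_id"].isin(pids)]
        merged = sub.merge(
            visits,
            left_on=["patient_id", f"{key}_{endpoint}_day"],
            right_on=["patient_id", "visit_day"],
            how="left",
        )
        samples_event.append(merged[visit_col].dropna().to_numpy())
        samples_base.append(base.loc[sub["patient_id"], base_col].dropna().to_numpy())
    out = []
    for pair in (samples_base, samples_event):
        if min(len(pair[0]), len(pair[1])) < 2:
            out.append(np.nan)
        else:
            out.append(float(stats.ttest_ind(pair[0], pair[1], equal_var=False).pvalue))
    return out[0], out[1]


@dataclass(frozen=True)
class SubgroupSpec:
    """A named total split of the baseline table into labelled levels."""

    name: str
    levels: tuple[str, ...]
    splitter: Callable[[pd.DataFrame], pd.Series]

    def split(self, baselines: pd.DataFrame) -> pd.Series:
        lv = pd.Series(self.splitter(baselines), index=baselines.index)
        bad = sorted(set(lv.dropna().unique()) - set(self.levels))
        if bad or lv.isna().any():
            raise ValueError(
                f"subgroup {self.name!r}: splitter produced unexpected levels {bad} "
                f"or missing assignments"
            )
        return lv


def _spec(name, levels, fn):
    return SubgroupSpec(name=name, levels=levels, splitter=fn)


#: The nine shipped subgroup splits (cutoffs inclusive on the high side for
#: age >=65 and eosinophils >=300; SGRQ >25 and BDI >7 are the "high" levels).
DEFAULT_SUBGROUPS: tuple[SubgroupSpec, ...] = (
    _spec("sex", ("male", "female"), lambda b: b["sex"]),
    _spec("age", ("<65", ">=65"), lambda b: np.where(b["age"] >= 65, ">=65", "<65")),
    _spec("smoking", ("ex", "current"), lambda b: b["smoking"]),
    _spec(
        "prior_exacerbation",
        ("yes", "no"),
        lambda b: np.where(b["prior_exacerbation"].astype(bool), "yes", "no"),
    ),
    _spec("ics_use", ("yes", "no"), lambda b: np.where(b["ics_use"].astype(bool), "yes", "no")),
    _spec("sgrq", ("<=25", ">25"), lambda b: np.where(b["sgrq_baseline"] > 25, ">25", "<=25")),
    _spec("bdi", ("<=7", ">7"), lambda b: np.where(b["bdi"] > 7, ">7", "<=7")),
    _spec("severity", ("moderate", "severe"), lambda b: b["gold_severity"]),
    _spec(
        "eosinophils",
        ("<300", ">=300"),
        lambda b: np.where(b["eosinophils"] >= 300, ">=300", "<300"),
    ),
)


def gold_group_spec() -> SubgroupSpec:
    """GOLD A+B vs C+D split via surrogates (high risk = prior-year
    exacerbation). Shipped but not in the defaults: with low exacerbation
    burden the grouping is not representative, so it is opt-in."""
    return _spec(
        "gold_group",
        ("A+B", "C+D"),
        lambda b: np.where(b["prior_exacerbation"].astype(bool), "C+D", "A+B"),
    )


def subgroup_forest(
    cid_results: pd.DataFrame,
    baselines: pd.DataFrame,
    specs: Sequence[SubgroupSpec] = DEFAULT_SUBGROUPS,
    contrast: tuple[str, str] = ("glycopyrronium", "tiotropium"),
    endpoint: str = "first",
    adjust: bool = False,
    stratify_by_study: bool = True,
) -> pd.DataFrame:
    """Forest table: one row per subgroup level with per-arm n, HR, CI, p.

    HRs come from a treatment-only (or, with ``adjust``, fully adjusted)
    Cox model restricted to the level, baseline hazard stratified by study.
    Levels where the model cannot be fit (e.g. an arm with zero events)
    are emitted with a diagnostic note and NaN estimates so they can be
    excluded from plotting without disappearing from the table.
    """
    records = survival.make_survival_records(cid_results, baselines, endpoint=endpoint)
    records = records.set_index("patient_id")
    rows = []
    for spec in specs:
        level_by_pid = pd.Series(
            spec.split(baselines).to_numpy(), index=baselines["patient_id"]
        )
        for level in spec.levels:
            pids = level_by_pid.index[level_by_pid == level]
            sub = records.loc[records.index.intersection(pids)].reset_index()
            sub = sub[sub["arm"].isin(contrast)]
            row: dict = {"subgroup": spec.name, "level": level, "endpoint": endpoint}
            for arm in contrast:
                row[f"n_{arm}"] = int((sub["arm"] == arm).sum())
            row["n_events"] = int(sub["event"].sum())
            try:
                df = survival.encode_covariates(sub, contrast)
                covs = list(survival.DEFAULT_COVARIATES) if adjust else ["treatment"]
                fit = survival.cox_fit(
                    df, covs, strata="study_id" if stratify_by_study else None
                )
                row["hr"] = fit.hr("treatment")
                row["ci_lower"], row["ci_upper"] = fit.ci("treatment")
                row["p"] = fit.p("treatment")
                row["note"] = "; ".join(fit.diagnostics)
            except (ValueError, KeyError) as exc:
                row["hr"] = row["ci_lower"] = row["ci_upper"] = row["p"] = np.nan
                row["note"] = f"not estimable: {exc}"
                logger.warning("subgroup %s=%s: %s", spec.name, level, exc)
            rows.append(row)
    return pd.DataFrame(rows)


def forest_plot(forest: pd.DataFrame, path) -> None:
    """Write a simple forest plot (rows with NaN HR are excluded)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = forest.dropna(subset=["hr", "ci_lower", "ci_upper"]).reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(6, 0.4 * max(len(ok), 4) + 1))
    y = np.arange(len(ok))[::-1]
    ax.errorbar(
        ok["hr"],
        y,
        xerr=[ok["hr"] - ok["ci_lower"], ok["ci_upper"] - ok["hr"]],
        fmt="s",
        color="black",
        ecolor="gray",
        capsize=2,
    )
    ax.axvline(1.0, color="steelblue", lw=1, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(ok["subgroup"] + ": " + ok["level"])
    ax.set_xlabel("Hazard ratio (95% CI)")
    ax.set_xscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def km_plot(contrast_result, path) -> None:
    """Write step plots of the per-arm Kaplan-Meier curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for arm, curve in contrast_result.km.items():
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=arm)
    ax.set_xlabel("Days since first dose")
    ax.set_ylabel("Proportion without CID")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
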