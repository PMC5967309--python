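"""CSV readers/writers and cohort schema validation.

The interchange format is plain RFC-4180 CSV with a header row, UTF-8.
Four tables make a cohort: baseline (one row per randomized patient),
visits (one row per scheduled post-baseline visit), exacerbations (one row
per episode) and followup (censoring information). Column dictionaries are
in docs/methods.md.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TABLE_NAMES = ("baseline", "visits", "exacerbations", "followup")

SCHEMAS: dict[str, dict[str, str]] = {
    "baseline": {
        "patient_id": "str",
        "study_id": "str",
        "arm": "str",
        "sex": "str",
        "age": "float",
        "smoking": "str",
        "gold_severity": "str",
        "fev1_baseline": "float",
        "fev1_pct_pred": "float",
        "sgrq_baseline": "float",
        "bdi": "int",
        "eosinophils": "float",
        "ics_use": "bool",
        "prior_exacerbation": "bool",
    },
    "visits": {
        "patient_id": "str",
        "visit_week": "int",
        "visit_day": "int",
        "fev1": "float",
        "sgrq": "float",
    },
    "exacerbations": {"patient_id": "str", "onset_day": "int", "severity": "str"},
    "followup": {
        "patient_id": "str",
        "last_contact_day": "int",
        "discontinued_early": "bool",
        "study_end_day": "int",
    },
}


class Cohort(NamedTuple):
    baseline: pd.DataFrame
    visits: pd.DataFrame
    exacerbations: pd.DataFrame
    followup: pd.DataFrame


class CohortValidationError(ValueError):
    """Schema or cross-table consistency failure; ``problems`` lists each one."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("cohort validation failed:\n  - " + "\n  - ".join(problems))


def _coerce(df: pd.DataFrame, schema: Mapping[str, str], name: str, problems: list[str]):
    missing = [c for c in schema if c not in df.columns]
    if missing:
        problems.append(f"{name}: missing column(s) {missing}")
        return df
    df = df[list(schema)].copy()
    for col, kind in schema.items():
        try:
            if kind == "int":
                df[col] = df[col].astype(int)
            elif kind == "float":
                df[col] = df[col].astype(float)
            elif kind == "bool":
                if df[col].dtype == object:
                    df[col] = df[col].map(
                        {"True": True, "False": False, True: True, False: False}
                    )
                df[col] = df[col].astype(bool)
            else:
                df[col] = df[col].astype(str)
        except (ValueError, TypeError) as exc:
            problems.append(f"{name}.{col}: cannot coerce to {kind} ({exc})")
    return df


def validate_cohort(
    baseline: pd.DataFrame,
    visits: pd.DataFrame,
    exacerbations: pd.DataFrame,
    followup: pd.DataFrame,
) -> Cohort:
    """Coerce dtypes and check uniqueness, referential integrity, invariants."""
    problems: list[str] = []
    baseline = _coerce(baseline, SCHEMAS["baseline"], "baseline", problems)
    visits = _coerce(visits, SCHEMAS["visits"], "visits", problems)
    exacerbations = _coerce(exacerbations, SCHEMAS["exacerbations"], "exacerbations", problems)
    followup = _coerce(followup, SCHEMAS["followup"], "followup", problems)
    if problems:
        raise CohortValidationError(problems)

    dup = baseline.loc[baseline["patient_id"].duplicated(), "patient_id"].tolist()
    if dup:
        problems.append(f"baseline: duplicate patient_id(s) {sorted(set(dup))[:10]}")
    dup_fu = followup.loc[followup["patient_id"].duplicated(), "patient_id"].tolist()
    if dup_fu:
        problems.append(f"followup: duplicate patient_id(s) {sorted(set(dup_fu))[:10]}")
    known = set(baseline["patient_id"])
    for name, tbl in (("visits", visits), ("exacerbations", exacerbations), ("followup", followup)):
        orphans = sorted(set(tbl["patient_id"]) - known)
        if orphans:
            problems.append(f"{name}: unknown patient_id(s) {orphans[:10]}")
    missing_fu = sorted(known - set(followup["patient_id"]))
    if missing_fu:
        problems.append(f"followup: no record for patient_id(s) {missing_fu[:10]}")

    if not followup.empty:
        bad = followup[followup["last_contact_day"] > followup["study_end_day"]]
        if len(bad):
            problems.append(
                f"followup: last_contact_day > study_end_day for {bad['patient_id'].tolist()[:10]}"
            )
        bad2 = followup[
            (followup["last_contact_day"] < followup["study_end_day"])
            != followup["discontinued_early"]
        ]
        if len(bad2):
            problems.append(
                "followup: discontinued_early inconsistent with days for "
                f"{bad2['patient_id'].tolist()[:10]}"
            )
    if not visits.empty:
        bad = visits[visits["visit_day"] != 7 * visits["visit_week"]]
        if len(bad):
            problems.append(
                f"visits: visit_day != 7*visit_week for {bad['patient_id'].tolist()[:10]}"
            )
    if not exacerbations.empty and exacerbations["onset_day"].min() < 1:
        problems.append("exacerbations: onset_day < 1")
    if not baseline.empty:
        if (baseline["fev1_baseline"] <= 0).any():
            problems.append("baseline: non-positive fev1_baseline")
        if ((baseline["sgrq_baseline"] < 0) | (baseline["sgrq_baseline"] > 100)).any():
            problems.append("baseline: sgrq_baseline outside [0, 100]")
    if problems:
        raise CohortValidationError(problems)
    return Cohort(baseline, visits, exacerbations, followup)


def read_cohort(source: Mapping[str, str | Path] | str | Path) -> Cohort:
    """Read and validate the four cohort CSVs.

    ``source`` is either a directory containing ``baseline.csv`` etc., or a
    mapping from table name to path.
    """
    if isinstance(source, (str, Path)):
        d = Path(source)
        paths = {name: d / f"{name}.csv" for name in TABLE_NAMES}
    else:
        paths = {name: Path(p) for name, p in source.items()}
    missing = [str(p) for p in paths.values() if not Path(p).exists()]
    if missing:
        raise CohortValidationError([f"missing input file(s): {missing}"])
    frames = {name: pd.read_csv(paths[name]) for name in TABLE_NAMES}
    cohort = validate_cohort(**frames)
    logger.info(
        "read cohort: %d patients, %d visits, %d exacerbations",
        len(cohort.baseline),
        len(cohort.visits),
        len(cohort.exacerbations),
    )
    return cohort


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write the four tables to ``outdir`` as ``<table>.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in zip(TABLE_NAMES, cohort):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
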