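"""End-to-end pipeline driver: simulate/read -> derive -> analyze -> report.

A :class:`PipelineConfig` fully specifies one run (inputs or simulator
settings, thresholds, analysis options, seed); :func:`run_pipeline` writes
the derived CID table, KM curves, model report, the three report CSVs and
a JSON manifest from which the run can be replayed byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from . import reporting, simulate, survival
from .endpoints import CidThresholds, derive_all

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """One of ``input_dir``/``input_paths`` (read a cohort) or ``simulate``
    (generate one) must be set, never both."""

    input_dir: str | None = None
    input_paths: Mapping[str, str] | None = None
    simulate: Mapping[str, Any] | None = None  # {"n_per_study": {...}, "params": {...}}
    thresholds: Mapping[str, Any] = field(default_factory=dict)
    contrast: tuple[str, str] = ("glycopyrronium", "tiotropium")
    endpoints: tuple[str, ...] = ("first", "sustained")
    adjust: bool = True
    stratify_by_study: bool = True
    subgroups: bool = True
    plots: bool = False
    outdir: str = "cid_output"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_input = self.input_dir is not None or self.input_paths is not None
        has_sim = self.simulate is not None
        if has_input == has_sim:
            raise ValueError(
                "config must specify exactly one of input paths or simulator settings"
            )
        CidThresholds(**dict(self.thresholds))  # validates eagerly

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        raw = dict(raw)
        if "contrast" in raw:
            raw["contrast"] = tuple(raw["contrast"])
        if "endpoints" in raw:
            raw["endpoints"] = tuple(raw["endpoints"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contrast"] = list(self.contrast)
        d["endpoints"] = list(self.endpoints)
        return d


def _build_simulation(config: PipelineConfig) -> cio.Cohort:
    sim = dict(config.simulate or {})
    n_per_study = sim.get("n_per_study")
    designs = simulate.DEFAULT_DESIGNS
    if "designs" in sim:
        designs = tuple(
            simulate.StudyDesign(
                study_id=d["study_id"],
                duration_weeks=int(d["duration_weeks"]),
                arms=dict(d["arms"]),
                visit_interval_weeks=int(d.get("visit_interval_weeks", 4)),
            )
            for d in sim["designs"]
        )
    param_kwargs = dict(sim.get("params", {}))
    if "baseline" in param_kwargs:
        param_kwargs["baseline"] = simulate.BaselineTargets(**param_kwargs["baseline"])
    params = simulate.SimulationParams(seed=config.seed, **param_kwargs)
    tables = simulate.simulate_cohort(designs, params, n_per_study)
    return cio.validate_cohort(*tables)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the output bundle.

    Returns the manifest (also written as ``manifest.json``): config echo,
    seed, thresholds, package version and per-stage patient/event counts.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    if not outdir.exists():
        logger.info("creating output directory %s", outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "input"
    try:
        if config.simulate is not None:
            cohort = _build_simulation(config)
            cio.write_cohort(cohort, outdir / "cohort")
        elif config.input_dir is not None:
            cohort = cio.read_cohort(config.input_dir)
        else:
            cohort = cio.read_cohort(config.input_paths)

        stage = "derive"
        thresholds = CidThresholds(**dict(config.thresholds))
        cid = derive_all(
            cohort.baseline, cohort.visits, cohort.exacerbations, cohort.followup, thresholds
        )
        cid.to_csv(outdir / "cid_results.csv", index=False)

        stage = "analyze"
        model_report: dict[str, Any] = {}
        arms_present = set(cohort.baseline["arm"])
        for endpoint in config.endpoints:
            if not set(config.contrast) <= arms_present:
                raise ValueError(
                    f"contrast arms {config.contrast} not all present in cohort "
                    f"({sorted(arms_present)})"
                )
            contrast_fit = survival.fit_treatment_contrasts(
                cid,
                cohort.baseline,
                contrast=config.contrast,
                endpoint=endpoint,
                adjust=config.adjust,
                stratify_by_study=config.stratify_by_study,
            )
            km_frames = []
            for arm, curve in contrast_fit.km.items():
                f = curve.to_frame()
                f.insert(0, "arm", arm)
                km_frames.append(f)
            pd.concat(km_frames).to_csv(outdir / f"km_{endpoint}.csv", index=False)
            model_report[endpoint] = {
                "contrast": list(config.contrast),
                "hazard_ratio": contrast_fit.hazard_ratio,
                "hr_ci": list(contrast_fit.cox.ci("treatment")),
                "p_cox": contrast_fit.cox.p("treatment"),
                "logrank_statistic": contrast_fit.logrank.statistic,
                "p_logrank": contrast_fit.logrank.p_value,
                "n_events": contrast_fit.cox.n_events,
                "diagnostics": contrast_fit.cox.diagnostics,
                "median_days": {
                    arm: c.median if np.isfinite(c.median) else None
                    for arm, c in contrast_fit.km.items()
                },
            }
            if config.plots:
                reporting.km_plot(contrast_fit, outdir / f"km_{endpoint}.png")
        with open(outdir / "model_report.json", "w") as fh:
            json.dump(model_report, fh, indent=2, sort_keys=True, default=_json_default)

        stage = "report"
        events = reporting.summarize_events(
            cid, cohort.baseline, config.contrast, config.stratify_by_study
        )
        events.to_csv(outdir / "events_summary.csv", index=False)
        at_event = reporting.values_at_event(
            cid, cohort.visits, cohort.baseline, config.contrast
        )
        at_event.to_csv(outdir / "at_event.csv", index=False)
        if config.subgroups:
            for endpoint in config.endpoints:
                forest = reporting.subgroup_forest(
                    cid,
                    cohort.baseline,
                    contrast=config.contrast,
                    endpoint=endpoint,
                    stratify_by_study=config.stratify_by_study,
                )
                forest.to_csv(outdir / f"forest_{endpoint}.csv", index=False)
                if config.plots:
                    reporting.forest_plot(forest, outdir / f"forest_{endpoint}.png")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": dataclasses.asdict(thresholds),
        "config": config.to_dict(),
        "counts": {
            "patients": int(len(cohort.baseline)),
            "visits": int(len(cohort.visits)),
            "exacerbations": int(len(cohort.exacerbations)),
            "first_cid_events": int(cid["first_cid_event"].sum()),
            "sustained_cid_events": int(cid["sustained_cid_event"].sum()),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
    logger.info(
        "pipeline complete: %d patients in, %d first-CID events, %d sustained",
        manifest["counts"]["patients"],
        manifest["counts"]["first_cid_events"],
        manifest["counts"]["sustained_cid_events"],
    )
    return manifest


def config_from_manifest(path: str | Path, outdir: str | None = None) -> PipelineConfig:
    """Rebuild a :class:`PipelineConfig` from a run manifest for replay."""
    with open(path) as fh:
        manifest = json.load(fh)
    raw = dict(manifest["config"])
    if outdir is not None:
        raw["outdir"] = outdir
    return PipelineConfig.from_dict(raw)
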