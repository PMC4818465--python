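"""End-to-end cutpoint-derivation pipeline.

Stage order: read cohort -> complete-case filter + descriptive
comparison -> metabolic-syndrome classification -> unweighted cutpoint
derivation (all / male / female) -> survey-weighted derivation when the
design columns are present -> adjusted logistic validation -> external
validation when a second cohort is supplied.

Every run writes its fully resolved configuration next to the outputs,
so a rerun with the same inputs reproduces the artifacts byte for byte.
Logs (stage names and timings) go to stderr and never mix with the
machine-readable outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import cohort as cio
from .cutpoint import derive_cutoff
from .mets import classify_cohort
from .survey import GridSpec, SurveyDesign, weighted_grid_search
from .validation import external_validate, fit_validation_model

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("whtrcut")

DEFAULT_REQUIRED = ["sex", "race", "age", "smoking_days", "height_cm",
                    "waist_cm", "sbp", "dbp", "hba1c_pct",
                    "tg_decile", "hdl_decile"]


@dataclass
class PipelineConfig:
    """Resolved pipeline settings; serialized alongside every run."""

    schema: str | None = None
    required: list = field(default_factory=lambda: list(DEFAULT_REQUIRED))
    bp_threshold: str = "paper"          # "paper" (>=135) or "standard" (>=130)
    decile_mode: str = "precomputed"
    grid: GridSpec = field(default_factory=GridSpec)
    weighted: str = "auto"               # auto | on | off
    sex_strata: tuple = ("all", "male", "female")
    seed: int = 0
    outdir: str = "whtrcut_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        grid = GridSpec(**raw.pop("grid", {}))
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(grid=grid, **known)

    def effective(self) -> dict:
        d = asdict(self)
        d["sex_strata"] = list(self.sex_strata)
        return d


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default,
                  allow_nan=True)
        fh.write("\n")


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            log.info("stage %s: done in %.2fs", self.name, dt)
        else:
            log.error("stage %s: FAILED after %.2fs: %s", self.name, dt, exc)
        return False


def _subset(classified, sex):
    if sex == "all":
        return classified
    return classified[classified["sex"] == sex]


def run_pipeline(config: PipelineConfig, cohort_path: str | Path,
                 external_path: str | Path | None = None) -> dict:
    """Run the full analysis; returns the consolidated report dict and
    writes per-stage artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_json(config.effective(), outdir / "effective_config.json")
    with open(outdir / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(config.effective(), fh, sort_keys=True)

    report: dict = {"config": config.effective()}

    with _Stage("read"):
        cohort = cio.read_cohort(cohort_path, schema=config.schema)
        report["n_read"] = len(cohort)

    with _Stage("complete_case"):
        complete, incomplete = cio.complete_case_filter(cohort, config.required)
        report["n_complete"] = len(complete)
        report["n_incomplete"] = len(incomplete)
        if len(complete) and len(incomplete):
            comparison = cio.compare_samples(complete, incomplete)
            comparison.to_csv(outdir / "table1_comparison.csv", index=False)
        else:
            log.info("one partition empty; comparison table skipped")

    with _Stage("classify"):
        classified = classify_cohort(complete, bp_threshold=config.bp_threshold,
                                     decile_mode=config.decile_mode)
        classified.to_csv(outdir / "classified.csv", index=False)
        mets = classified["mets"].astype(bool)
        report["prevalence"] = float(mets.mean())

    with _Stage("derive_unweighted"):
        report["unweighted"] = {}
        for sex in config.sex_strata:
            sub = _subset(classified, sex)
            res = derive_cutoff(sub["whtr"].to_numpy(float),
                                sub["mets"].astype(bool).to_numpy(),
                                sex_stratum=sex)
            res.sweep.to_csv(outdir / f"sweep_unweighted_{sex}.csv", index=False)
            report["unweighted"][sex] = res.as_dict()

    use_weighted = (config.weighted == "on"
                    or (config.weighted == "auto" and complete.design_present))
    if config.weighted == "on" and not complete.design_present:
        raise ValueError("weighted analysis requested but design columns "
                         "are not complete")
    if use_weighted:
        with _Stage("derive_weighted"):
            report["weighted"] = {}
            design_all = SurveyDesign.from_frame(classified)
            w = design_all.weights
            report["weighted_prevalence"] = float(
                (w * mets.to_numpy()).sum() / w.sum())
            for sex in config.sex_strata:
                mask = (np.ones(len(classified), bool) if sex == "all"
                        else (classified["sex"] == sex).to_numpy(bool))
                res = weighted_grid_search(
                    classified["whtr"].to_numpy(float)[mask],
                    mets.to_numpy()[mask],
                    design_all.subset(mask), config.grid, sex_stratum=sex)
                res.coarse_table.to_csv(
                    outdir / f"grid_coarse_weighted_{sex}.csv", index=False)
                res.fine_table.to_csv(
                    outdir / f"grid_fine_weighted_{sex}.csv", index=False)
                report["weighted"][sex] = res.as_dict()
    else:
        log.info("design columns incomplete; weighted stages skipped")
        report["weighted"] = None

    with _Stage("logistic_validation"):
        report["logistic"] = {}
        for sex in config.sex_strata:
            cut = report["unweighted"][sex]["cutoff"]
            fit = fit_validation_model(classified, cut, sex_stratum=sex)
            report["logistic"][f"unweighted_{sex}"] = {
                "terms": fit.as_records(), "n": fit.n,
                "converged": fit.converged, "separation": fit.separation}
            if use_weighted:
                fitw = fit_validation_model(
                    classified, report["weighted"][sex]["cutoff"],
                    design=SurveyDesign.from_frame(classified),
                    sex_stratum=sex)
                report["logistic"][f"weighted_{sex}"] = {
                    "terms": fitw.as_records(), "n": fitw.n,
                    "converged": fitw.converged, "separation": fitw.separation}

    if external_path is not None:
        with _Stage("external_validation"):
            ext = cio.read_cohort(external_path, schema=config.schema)
            ext_complete, _ = cio.complete_case_filter(ext, config.required)
            ext_classified = classify_cohort(
                ext_complete, bp_threshold=config.bp_threshold,
                decile_mode=config.decile_mode)
            cuts = {s: report["unweighted"][s]["cutoff"]
                    for s in ("all", "male", "female") if s in report["unweighted"]}
            cuts = {"full": cuts.get("all"), "male": cuts.get("male"),
                    "female": cuts.get("female")}
            ext_design = (SurveyDesign.from_frame(ext_classified)
                          if ext_complete.design_present else None)
            report["external"] = external_validate(ext_classified, cuts,
                                                   design=ext_design)

    _write_json(report, outdir / "report.json")
    return report
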