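"""End-to-end pipeline: generate/ingest -> derive -> factors -> discriminate -> stage.

``run_pipeline`` orchestrates the whole analysis on synthetic, step-level
or subject-level input and writes a reproducible report bundle (subject
table with factor and model scores, Table-3-style discrimination report,
effect-size grid, radar z-score export, ANOVA summary, JSON run log).
Identical configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import reference as ref
from . import discrimination as disc
from . import factor_model as fm
from . import staging
from . import synthetic_cohort as sc
from .exceptions import PDGaitError, PipelineStageError
from .gait_metrics import derive_table
from .io import config_hash, read_step_table, read_subject_table, save_json, write_table

log = logging.getLogger("pdgait")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    mode: str = "synthetic"  # synthetic | step | subject
    input_path: str | None = None
    outdir: str = "pdgait_out"
    seed: int = 0
    staged: bool = True  # synthetic mode: split PD over the six stages
    steps_per_trial: int = 7
    simulate_steps: bool = False  # synthetic mode: go through step records
    pool_trials: bool = False
    efa_mode: str = "fit"  # fit | template
    n_factors: int = 3
    rotation: str = "varimax"
    loading_threshold: float = ref.LOADING_THRESHOLD
    wss_weighting: str = "unit"
    reference: str = "pooled"  # z-score reference: pooled | hs
    hs_label: str = "HS"
    write_outputs: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    def analysis_dict(self) -> dict:
        """Config fields that determine the results (not where they go)."""
        d = asdict(self)
        d.pop("outdir")
        d.pop("write_outputs")
        return d


@dataclass
class ReportBundle:
    """In-memory results of one pipeline run."""

    subjects: pd.DataFrame
    loadings: pd.DataFrame
    allocation: dict[str, list[str]]
    scores: pd.DataFrame
    model: disc.LogisticGaitModel | None
    report: pd.DataFrame | None
    grid: pd.DataFrame | None
    radar: pd.DataFrame | None
    anova: dict | None
    log: dict = field(default_factory=dict)


def _acquire(config: PipelineConfig) -> pd.DataFrame:
    if config.mode == "synthetic":
        cohort = (
            sc.staged_config_from_table2(seed=config.seed)
            if config.staged
            else sc.default_config_from_table2(seed=config.seed)
        )
        if config.simulate_steps:
            _, steps = sc.sample_cohort_steps(
                cohort, steps_per_trial=config.steps_per_trial
            )
            return derive_table(steps, pool_trials=config.pool_trials)
        return sc.sample_subjects(cohort)
    if config.input_path is None:
        raise PipelineStageError("ingest", f"mode {config.mode!r} requires input_path")
    if config.mode == "step":
        steps = read_step_table(config.input_path)
        return derive_table(steps, pool_trials=config.pool_trials)
    if config.mode == "subject":
        return read_subject_table(config.input_path)
    raise PipelineStageError("ingest", f"unknown mode {config.mode!r}")


def _condition(subjects: pd.DataFrame, hs_label: str) -> pd.Series:
    return pd.Series(
        np.where(subjects["group"] == hs_label, "HS", "PD"), index=subjects.index
    )


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis; see the module docstring.

    Stage failures are re-raised as ``PipelineStageError`` tagged with the
    failing stage.
    """
    t0 = time.time()
    run_log: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config_hash(config.analysis_dict()),
        "stages": {},
    }
    provenance = {
        "seed": config.seed,
        "config_hash": run_log["config_hash"],
        "data": "synthetic cohort" if config.mode == "synthetic" else config.input_path,
    }

    def _stage(name, fn):
        t = time.time()
        try:
            out = fn()
        except PDGaitError as err:
            raise PipelineStageError(name, str(err)) from err
        run_log["stages"][name] = {"seconds": round(time.time() - t, 3)}
        return out

    subjects = _stage("ingest", lambda: _acquire(config))
    run_log["stages"]["ingest"]["rows"] = len(subjects)
    log.info("ingest: %d subjects", len(subjects))

    def _factors():
        if config.efa_mode == "template":
            flm = fm.FactorLoadingMatrix(
                loadings=ref.reference_loadings(),
                threshold=config.loading_threshold,
                method="template",
                rotation="none",
            )
        else:
            flm = fm.align_to_reference(
                fm.fit_efa(
                    subjects,
                    n_factors=config.n_factors,
                    rotation=config.rotation,
                    threshold=config.loading_threshold,
                )
            )
        allocation = fm.allocate_variables(flm)
        if config.reference == "hs":
            base = subjects[subjects["group"] == config.hs_label]
        else:
            base = subjects
        reference = fm.ZScoreReference.from_table(base, source=config.reference)
        scores = fm.weighted_sum_scores(
            subjects, allocation, reference, flm, weighting=config.wss_weighting
        )
        return flm, allocation, scores

    flm, allocation, scores = _stage("factors", _factors)
    enriched = pd.concat([subjects, scores], axis=1)
    condition = _condition(enriched, config.hs_label)
    enriched["condition"] = condition

    def _discriminate():
        model = disc.fit_logistic(scores, condition)
        enriched["gait_model"] = model.predict_proba(scores)
        report = disc.discrimination_report(enriched, condition)
        return model, report

    try:
        model, report = _stage("discriminate", _discriminate)
    except PipelineStageError:
        # leave the factor-score stage's outputs behind before aborting
        if config.write_outputs:
            partial = ReportBundle(
                subjects=enriched,
                loadings=flm.loadings,
                allocation=allocation,
                scores=scores,
                model=None,
                report=None,
                grid=None,
                radar=None,
                anova=None,
                log=run_log,
            )
            write_reports(partial, config.outdir, provenance)
        raise

    grid = radar = anova = None
    stages_present = enriched.get("stage")
    if stages_present is not None and stages_present.notna().any():

        def _stage_layer():
            grid = staging.build_grid(enriched)
            radar = staging.radar_zscores(enriched)
            anova = staging.anova_factor_scores(enriched)
            return grid, radar, anova

        grid, radar, anova = _stage("stage", _stage_layer)

    run_log["seconds_total"] = round(time.time() - t0, 3)
    bundle = ReportBundle(
        subjects=enriched,
        loadings=flm.loadings,
        allocation=allocation,
        scores=scores,
        model=model,
        report=report,
        grid=grid,
        radar=radar,
        anova=anova,
        log=run_log,
    )
    if config.write_outputs:
        write_reports(bundle, config.outdir, provenance)
    return bundle


def write_reports(bundle: ReportBundle, outdir: str | Path, provenance: dict) -> Path:
    """Write the report bundle as provenance-stamped CSV/JSON files."""
    out = Path(outdir)
    write_table(bundle.subjects, out / "factor_scores.csv", provenance)
    write_table(
        bundle.loadings.reset_index(names="variable"),
        out / "factor_loadings.csv",
        provenance,
    )
    if bundle.report is not None:
        write_table(bundle.report, out / "discrimination_report.csv", provenance)
    if bundle.grid is not None:
        write_table(bundle.grid, out / "effect_size_grid.csv", provenance)
    if bundle.radar is not None:
        write_table(bundle.radar, out / "radar_zscores.csv", provenance)
    if bundle.anova is not None:
        save_json(
            {
                f: {
                    "F": r["F"],
                    "p": r["p"],
                    "posthoc": r["posthoc"],
                }
                for f, r in bundle.anova.items()
            },
            out / "anova_factor_scores.json",
        )
    if bundle.model is not None:
        save_json(
            {
                "intercept": bundle.model.intercept,
                "coefficients": dict(bundle.model.coefficients),
                "log_likelihood": bundle.model.log_likelihood,
                "converged": bundle.model.converged,
                "separation": bundle.model.separation,
            },
            out / "logistic_model.json",
        )
    save_json({**bundle.log, "allocation": bundle.allocation}, out / "run_log.json")
    return out
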