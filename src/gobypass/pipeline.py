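"""End-to-end orchestration: data -> decision matrix -> statistics -> report.

A single :class:`PipelineConfig` (JSON or YAML) drives a full run: obtain
a cohort and a barrier profile (from CSV files or from the synthetic
generators), derive the a-priori thresholds, execute the decision matrix,
fit the statistical layer, and write all tabular outputs plus a
human-readable summary.  Timestamps are isolated to a metadata file so
that scientific outputs are byte-diffable across runs with the same seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ascent_model as am
from . import synthetic_data as sd
from .barrier_profile import (FlowProfile, max_pool_spacing, max_velocity,
                              read_flow_csv, worked_example_profile,
                              write_flow_csv)
from .decision_matrix import (FishRecord, ThresholdSet, compute_thresholds,
                              run_decision_matrix, summarize_traces,
                              traces_to_frame)
from .swim_performance import SwimModel

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "run_pipeline",
    "read_cohort_csv",
    "write_cohort_csv",
    "load_config",
]

PREDICTORS = ["length", "boldness", "asociability", "activity"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one run needs.  Exactly one cohort source and one flow
    source must be active: a CSV path, or the synthetic generator."""

    seed: int = 0
    output_dir: str = "gobypass_out"
    # cohort source
    cohort_csv: str | None = None
    n_front: int = 161
    n_center: int = 98
    center_effect_size: float = 1.0
    # flow source: "worked_example", "synthetic", or a CSV path
    flow_source: str = "worked_example"
    flow_metadata: str | None = None
    # threshold overrides (None -> derived from front cohort / profile)
    boldness_mean: float | None = None
    activity_mean: float | None = None
    asociability_mean: float | None = None
    flow_limit_m_s: float | None = None
    distance_limit_m: float | None = None
    min_traits_above: int = 2
    # swim model
    swim: dict = field(default_factory=dict)
    # statistical options
    hl_groups: int = 10
    log_base: str = "ten"


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from JSON or YAML."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return PipelineConfig(**data)


def write_cohort_csv(cohort: list[FishRecord], path: str | Path) -> None:
    pd.DataFrame([asdict(f) for f in cohort]).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[FishRecord]:
    df = pd.read_csv(path)
    return [FishRecord(fish_id=str(r.fish_id), tl_cm=float(r.tl_cm),
                       boldness=float(r.boldness), activity=float(r.activity),
                       asociability=float(r.asociability),
                       population=str(getattr(r, "population", "front")))
            for r in df.itertuples()]


def _resolve_cohort(cfg: PipelineConfig) -> list[FishRecord]:
    if cfg.cohort_csv is not None:
        cohort = read_cohort_csv(cfg.cohort_csv)
        logger.info("loaded cohort: %d individuals from %s",
                    len(cohort), cfg.cohort_csv)
        return cohort
    seeds = sd.child_seeds(cfg.seed, 3)
    front = sd.generate_cohort(sd.front_cohort_config(cfg.n_front, seeds[0]))
    center = sd.generate_cohort(
        sd.center_cohort_config(cfg.n_center, seeds[1],
                                effect_size=cfg.center_effect_size))
    logger.info("generated cohort: %d front + %d center individuals",
                len(front), len(center))
    return front + center


def _resolve_profile(cfg: PipelineConfig) -> FlowProfile:
    if cfg.flow_source == "worked_example":
        return worked_example_profile()
    if cfg.flow_source == "synthetic":
        seeds = sd.child_seeds(cfg.seed, 3)
        return sd.generate_flow_profile(11, 6.0, (0.3, 0.5), (0.6, 1.4),
                                        seed=seeds[2])
    return read_flow_csv(cfg.flow_source, cfg.flow_metadata)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; write outputs under ``cfg.output_dir``.

    Returns the report dict.  Any stage failure raises
    :class:`PipelineStageError` naming the stage.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        cohort = _resolve_cohort(cfg)
        profile = _resolve_profile(cfg)
    except PipelineStageError:
        raise
    except Exception as err:
        raise PipelineStageError("inputs", err) from err

    try:
        front = [f for f in cohort if f.population == "front"]
        if all(v is not None for v in (cfg.boldness_mean, cfg.activity_mean,
                                       cfg.asociability_mean)):
            thr = ThresholdSet(cfg.boldness_mean, cfg.activity_mean,
                               cfg.asociability_mean, cfg.flow_limit_m_s,
                               cfg.distance_limit_m, cfg.min_traits_above)
        else:
            thr = compute_thresholds(front or cohort, cfg.flow_limit_m_s,
                                     cfg.distance_limit_m,
                                     cfg.min_traits_above)
        logger.info("thresholds: boldness %.3f activity %.3f asociability %.3f",
                    thr.boldness_mean, thr.activity_mean, thr.asociability_mean)
    except Exception as err:
        raise PipelineStageError("thresholds", err) from err

    try:
        swim = SwimModel(**cfg.swim)
        traces = run_decision_matrix(cohort, profile, swim, thr)
        summary = summarize_traces(traces)
        logger.info("decision matrix: %d in -> %d traces (%d excluded), "
                    "%d ascents", len(cohort), len(traces),
                    summary["n_excluded"], summary["n_success"])
    except Exception as err:
        raise PipelineStageError("decision_matrix", err) from err

    try:
        trace_df = traces_to_frame(traces)
        scored = trace_df[~trace_df.excluded].reset_index(drop=True)
        by_id = {f.fish_id: f for f in cohort}
        X = np.array([[by_id[i].tl_cm, by_id[i].boldness,
                       by_id[i].asociability, by_id[i].activity]
                      for i in scored.fish_id]).reshape(-1, 4)
        y = scored.overall.to_numpy(dtype=float)
        fit = subset_table = corr = gof = moments = None
        if len(y) < 10:
            logger.warning("only %d scored individuals: statistical layer "
                           "skipped (needs >= 10)", len(y))
        else:
            fit = am.fit_logit(X, y, PREDICTORS)
            subset_table = am.subset_model_table(X, y, PREDICTORS)
            corr = am.spearman_matrix({
                "length": X[:, 0], "asociability": X[:, 2],
                "boldness": X[:, 1], "activity": X[:, 3], "success": y})
            if fit.degenerate:
                logger.warning("one-class outcome: Hosmer-Lemeshow skipped")
            else:
                gof = am.hosmer_lemeshow(am.predict_proba(fit, X), y,
                                         n_groups=min(cfg.hl_groups, len(y)))
            moments = {name: asdict(am.moment_check(X[:, j]))
                       for j, name in enumerate(PREDICTORS)}
            logger.info("logit: deviance %.3f aic %.3f lr_chi2 %.3f "
                        "pct_correct %.1f separation=%s", fit.deviance,
                        fit.aic, fit.lr_chi2, fit.pct_correct,
                        fit.separation_warning)
    except Exception as err:
        raise PipelineStageError("statistics", err) from err

    try:
        trace_df.to_csv(out / "decision_traces.csv", index=False)
        write_cohort_csv(cohort, out / "cohort.csv")
        write_flow_csv(profile, out / "flow_profile.csv",
                       out / "flow_metadata.json")
        if subset_table is not None:
            subset_table.to_csv(out / "subset_table.csv", index=False)
        if corr is not None:
            corr.matrix.to_csv(out / "correlations.csv")
        report = {
            "thresholds": asdict(thr),
            "flow_limit_m_s": thr.flow_limit_m_s
                or max_velocity(profile, "near_bottom"),
            "distance_limit_m": thr.distance_limit_m
                or max_pool_spacing(profile),
            "summary": summary,
            "logit": None if fit is None else {
                "predictors": fit.predictor_names,
                "coefficients": fit.coefficients.tolist(),
                "intercept": fit.intercept,
                "deviance": fit.deviance,
                "aic": fit.aic,
                "lr_chi2": fit.lr_chi2,
                "lr_df": fit.lr_df,
                "lr_p": fit.lr_p,
                "pct_correct": fit.pct_correct,
                "converged": fit.converged,
                "separation_warning": fit.separation_warning,
                "degenerate": fit.degenerate,
            },
            "hosmer_lemeshow": None if gof is None else {
                "statistic": gof.statistic, "df": gof.df,
                "p_value": gof.p_value,
                "n_groups_merged": gof.n_groups_merged,
            },
            "moments": moments,
            "seed": cfg.seed,
        }
        (out / "model_report.json").write_text(json.dumps(report, indent=1))
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        (out / "summary.txt").write_text(_render_summary(report))
        import datetime
        (out / "run_metadata.json").write_text(json.dumps(
            {"timestamp": datetime.datetime.now().isoformat()}, indent=1))
    except Exception as err:
        raise PipelineStageError("outputs", err) from err

    return report


def _render_summary(report: dict) -> str:
    s = report["summary"]
    lg = report["logit"]
    lines = [
        "gobypass run summary",
        "====================",
        f"individuals:        {s['n']} ({s['n_excluded']} excluded)",
        f"successful ascents: {s['n_success']} "
        f"({100 * s['fraction_success']:.1f}% of scored)",
        f"flow limit:         {report['flow_limit_m_s']:.3f} m/s",
        f"distance limit:     {report['distance_limit_m']:.2f} m",
        "thresholds (front means): "
        f"boldness {report['thresholds']['boldness_mean']:.3f}, "
        f"activity {report['thresholds']['activity_mean']:.3f}, "
        f"asociability {report['thresholds']['asociability_mean']:.3f}",
    ]
    if lg is None:
        lines.append("statistical layer skipped (cohort too small)")
    else:
        lines += [
            f"logit: deviance {lg['deviance']:.3f}, AIC {lg['aic']:.3f}, "
            f"LR chi2 {lg['lr_chi2']:.3f} (df {lg['lr_df']}, "
            f"p {lg['lr_p']:.3g}), "
            f"{lg['pct_correct']:.0f}% classified correctly",
            f"separation warning: {lg['separation_warning']}",
        ]
    if report["hosmer_lemeshow"] is not None:
        hl = report["hosmer_lemeshow"]
        lines.append(f"Hosmer-Lemeshow: chi2 {hl['statistic']:.3f} "
                     f"(df {hl['df']}, p {hl['p_value']:.3f})")
    return "\n".join(lines) + "\n"
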