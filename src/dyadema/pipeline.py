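"""Pipeline orchestration: simulate -> process -> fit -> report.

The full pipeline renders epoch-level count streams, applies the wear-time
and valid-day rules, extracts prompt-matched 45-min windows, applies the
inclusion funnel, person-centers affect, Box-Cox transforms MVPA, fits the
two-intercept dyadic model, and writes tabular artifacts.  Everything is
deterministic given the run seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accelerometry as acc
from . import descriptives, scoring, simulate, windows
from .apim import ApimFit, build_design, fit_apim

__all__ = [
    "RunConfig",
    "PipelineResult",
    "classify_study",
    "analysis_from_study",
    "prepare_model_frame",
    "fit_analysis",
    "run_pipeline",
    "write_report",
    "write_study_csvs",
    "load_study_csvs",
]

AFFECT_COLS = ("m_pa", "m_na", "c_pa", "c_na")
TABLE1_VARS = ("m_na", "m_pa", "m_mvpa_min", "m_sed_min",
               "c_na", "c_pa", "c_mvpa_min", "c_sed_min")


@dataclass
class RunConfig:
    """One reproducible run: input source, model choices, output directory."""

    input_dir: str | None = None          # None -> simulate
    outcome: str = "mvpa"                 # 'mvpa' | 'sedentary'
    estimator: str = "ML"                 # 'ML' | 'REML'
    lambda_mode: str = "fixed"            # 'fixed' | 'ml' | 'log'
    boxcox_lambda: float = 0.06
    min_wear_min: float = 30.0
    outdir: str = "dyadema_out"
    seed: int = 0
    generator: simulate.GeneratorConfig = field(
        default_factory=simulate.GeneratorConfig)
    thresholds: acc.Thresholds = field(default_factory=acc.Thresholds)

    def __post_init__(self):
        if self.outcome not in {"mvpa", "sedentary"}:
            raise ValueError("outcome must be 'mvpa' or 'sedentary'")
        if self.lambda_mode not in {"fixed", "ml", "log"}:
            raise ValueError("lambda_mode must be 'fixed', 'ml' or 'log'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", {})
        thr = raw.pop("thresholds", {})
        cfg = cls(**raw)
        if gen:
            cfg.generator = dataclasses.replace(cfg.generator, **gen)
        if thr:
            cfg.thresholds = dataclasses.replace(cfg.thresholds, **thr)
        return cfg


# --------------------------------------------------------------------------
# Processing stages


def classify_study(series_map, child_ages, thresholds=acc.Thresholds()):
    """Wear detection + intensity classification for every subject series.

    ``series_map`` maps (dyad_id, member, wave) -> EpochSeries.  Returns
    (classified, valid_days): per (dyad_id, member), the concatenated
    (labels, epoch index) across waves and the set of valid dates.
    """
    classified = {}
    valid_days = {}
    for (dyad, member, wave) in sorted(series_map):
        es = series_map[(dyad, member, wave)]
        ann = acc.detect_non_wear(es, thresholds)
        age = child_ages.get(dyad) if member == "child" else None
        labels = acc.classify_epochs(es, ann, member, age, thresholds)
        key = (dyad, member)
        if key in classified:
            old_lab, old_idx = classified[key]
            classified[key] = (np.concatenate([old_lab, labels]),
                               old_idx.append(es.epoch_start))
        else:
            classified[key] = (labels, es.epoch_start)
        valid_days.setdefault(key, set()).update(ann.valid_days)
    return classified, valid_days


def analysis_from_study(prompts, pairs, classified, valid_days,
                        covariates, min_wear_min=30.0):
    """Window extraction plus the inclusion funnel -> analysis table."""
    metrics = windows.window_metrics_for_prompts(prompts, pairs, classified,
                                                 valid_days)
    analysis, funnel = windows.build_analysis_set(prompts, pairs, metrics,
                                                  min_wear_min=min_wear_min)
    analysis = simulate.attach_covariates(analysis, covariates)
    return analysis, funnel, metrics


def prepare_model_frame(analysis: pd.DataFrame, outcome: str,
                        lambda_mode: str = "fixed",
                        boxcox_lambda: float = 0.06):
    """Person-center affect and place the outcome pair in (m_out, c_out).

    MVPA minutes go through the Box-Cox transform (lambda fixed, ML, or the
    log special case); sedentary minutes stay in raw minutes.  Returns the
    model frame plus a provenance record of the transform actually used.
    """
    df = scoring.add_person_centered(analysis, AFFECT_COLS)
    record = {"outcome": outcome, "transform": "identity"}
    if outcome == "mvpa":
        pooled = np.concatenate([df["m_mvpa_min"].to_numpy(),
                                 df["c_mvpa_min"].to_numpy()])
        if lambda_mode == "fixed":
            lam = boxcox_lambda
        elif lambda_mode == "log":
            lam = 0.0
        else:
            lam = scoring.boxcox_transform(pooled).lmbda
        offset = 1.0 if (pooled == 0).any() else 0.0
        df["m_out"] = scoring.apply_boxcox(df["m_mvpa_min"], lam, offset)
        df["c_out"] = scoring.apply_boxcox(df["c_mvpa_min"], lam, offset)
        record.update(transform="boxcox", lmbda=float(lam), offset=float(offset),
                      skewness_before=scoring.sample_skewness(pooled),
                      skewness_after=scoring.sample_skewness(
                          np.concatenate([df["m_out"], df["c_out"]])))
    else:
        df["m_out"] = df["m_sed_min"]
        df["c_out"] = df["c_sed_min"]
    return df, record


def fit_analysis(model_frame: pd.DataFrame, estimator: str = "ML") -> ApimFit:
    design = build_design(model_frame)
    return fit_apim(design, method=estimator)


def recovery_experiment(outcome: str, seeds, config=None,
                        estimator: str = "ML"):
    """Simulate-and-refit replicates of the parameter-recovery experiment.

    For each seed: draw a study-scale analysis set with the outcome model's
    generating truth (model scale), person-center the affect composites the
    way the estimation pipeline does, fit by (RE)ML.  Returns the list of
    :class:`~dyadema.apim.ApimFit` objects.
    """
    config = config or simulate.GeneratorConfig()
    fits = []
    for seed in seeds:
        df = simulate.simulate_recovery_dataset(config, seed=int(seed),
                                                outcome=outcome)
        frame = scoring.add_person_centered(df, AFFECT_COLS)
        fits.append(fit_analysis(frame, estimator))
    return fits


# --------------------------------------------------------------------------
# End-to-end run


@dataclass
class PipelineResult:
    config: RunConfig
    analysis: pd.DataFrame
    funnel: windows.FunnelReport
    fit: ApimFit
    summary: pd.DataFrame
    correlations: pd.DataFrame
    transform_record: dict
    outdir: Path


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the complete pipeline and write artifacts to ``config.outdir``."""
    if config.input_dir is None:
        gen = dataclasses.replace(config.generator, seed=config.seed)
        study = simulate.simulate_study(gen, config.seed)
        prompts, pairs, covs = study.prompts, study.pairs, study.covariates
        series_map, child_ages = study.series, study.child_ages
    else:
        prompts, pairs, covs, series_map, child_ages = load_study_csvs(
            config.input_dir)
    classified, valid_days = classify_study(series_map, child_ages,
                                            config.thresholds)
    analysis, funnel, _ = analysis_from_study(
        prompts, pairs, classified, valid_days, covs,
        min_wear_min=config.min_wear_min)
    model_frame, record = prepare_model_frame(
        analysis, config.outcome, config.lambda_mode, config.boxcox_lambda)
    fit = fit_analysis(model_frame, config.estimator)
    summary = descriptives.summary_table(analysis, list(TABLE1_VARS))
    corr = descriptives.between_within_correlations(
        analysis, list(TABLE1_VARS)).to_frame()
    outdir = Path(config.outdir)
    result = PipelineResult(config=config, analysis=analysis, funnel=funnel,
                            fit=fit, summary=summary, correlations=corr,
                            transform_record=record, outdir=outdir)
    write_report(result)
    return result


def _fmt3(x) -> str:
    return f"{x:.3f}"


def write_report(result: PipelineResult) -> None:
    """CSV + JSON + human-readable artifacts, numbers at 3 decimals."""
    out = result.outdir
    out.mkdir(parents=True, exist_ok=True)
    result.funnel.to_frame().to_csv(out / "funnel.csv", index=False)
    result.summary.to_csv(out / "table1_summary.csv", index=False,
                          float_format="%.3f")
    result.correlations.to_csv(out / "table1_correlations.csv",
                               float_format="%.3f")
    fe = result.fit.fixed_effects()
    fe.to_csv(out / "fixed_effects.csv", index=False)
    result.fit.random_effects().to_csv(out / "random_effects.csv", index=False)
    with open(out / "fit.json", "w") as fh:
        json.dump(result.fit.to_dict(), fh, indent=2)
    cfg = result.config
    log_lines = [
        f"outcome: {cfg.outcome}",
        f"estimator: {cfg.estimator}",
        f"seed: {cfg.seed}",
        f"min_wear_min: {cfg.min_wear_min}",
        f"sedentary_cpm: {cfg.thresholds.sedentary_cpm}",
        f"adult_mvpa_cpm: {cfg.thresholds.adult_mvpa_cpm}",
        f"child_met_target: {cfg.thresholds.child_met_target}",
        f"nonwear_rule_min: {cfg.thresholds.nonwear_min} (strictly greater)",
        f"valid_day_wear_min: {cfg.thresholds.valid_day_wear_min}",
        f"transform: {result.transform_record}",
        f"converged: {result.fit.converged} (boundary: {result.fit.boundary})",
    ]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    lines = [f"Dyadic multilevel model ({cfg.outcome}); "
             f"{result.fit.n_windows} windows, {result.fit.n_dyads} dyads",
             "", "Fixed effects (estimate / SE / stars):"]
    for row in fe.itertuples(index=False):
        lines.append(f"  {row.term:24s} {_fmt3(row.estimate):>8s} "
                     f"{_fmt3(row.se):>8s} {row.stars}")
    lines.append("")
    lines.append("Random effects:")
    for row in result.fit.random_effects().itertuples(index=False):
        lines.append(f"  {row.component:26s} {_fmt3(row.value):>8s}")
    lines.append("")
    lines.append("Funnel:")
    for stage, count in result.funnel.stages:
        lines.append(f"  {stage:24s} {count}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# On-disk study bundle (delimited text only)


def write_study_csvs(study: simulate.SimulatedStudy, outdir) -> Path:
    """EMA CSV, per-subject-wave epoch CSVs, covariates CSV and truth JSON."""
    out = Path(outdir)
    (out / "epochs").mkdir(parents=True, exist_ok=True)
    ema = study.prompts.copy()
    ema["scheduled_ts"] = pd.DatetimeIndex(ema["scheduled_ts"]).strftime(
        "%Y-%m-%dT%H:%M:%S")
    resp = pd.DatetimeIndex(ema["response_ts"])
    ema["response_ts"] = np.where(resp.isna(), "",
                                  resp.strftime("%Y-%m-%dT%H:%M:%S"))
    drop = [c for c in ema.columns if c.endswith("_true") or c in ("pa", "na")]
    ema.drop(columns=drop).to_csv(out / "ema.csv", index=False)
    study.covariates.to_csv(out / "covariates.csv", index=False)
    for (dyad, member, wave), es in study.series.items():
        acc.write_epoch_csv(es, out / "epochs" / f"d{dyad:04d}_{member}_w{wave}.csv")
    truth = {
        "generator": _config_dict(study.config),
        "windows": study.window_truth.assign(
            anchor_ts=pd.DatetimeIndex(study.window_truth["anchor_ts"]).strftime(
                "%Y-%m-%dT%H:%M:%S")).to_dict(orient="list"),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, default=_jsonable)
    return out


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _config_dict(cfg: simulate.GeneratorConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["affect_params"] = {f"{mem}:{scale}": dataclasses.asdict(ap)
                          for (mem, scale), ap in cfg.affect_params.items()}
    for key in ("apim_mvpa", "apim_sedentary"):
        d[key]["G"] = np.asarray(getattr(cfg, key).G).tolist()
    return d


def load_study_csvs(indir):
    """Read a study bundle back; composites are scored from the item columns."""
    ind = Path(indir)
    prompts = pd.read_csv(ind / "ema.csv", parse_dates=["scheduled_ts"])
    prompts["response_ts"] = pd.to_datetime(prompts["response_ts"], errors="coerce")
    prompts["answered"] = prompts["answered"].astype(bool)
    for scale in ("pa", "na"):
        item_cols = sorted(c for c in prompts.columns
                           if c.startswith(f"{scale}_item"))
        comp = pd.Series(np.nan, index=prompts.index)
        for member in ("mother", "child"):
            rows = prompts["member"] == member
            items = prompts.loc[rows, item_cols].dropna(axis=1, how="all")
            comp[rows] = scoring.score_composite(items)
        prompts[scale] = comp
    covs = pd.read_csv(ind / "covariates.csv")
    pairs = simulate.attach_covariates(windows.pair_prompts(prompts), covs)
    series_map = {}
    for path in sorted((ind / "epochs").glob("*.csv")):
        stem = path.stem            # d0000_member_w0
        dyad = int(stem[1:5])
        member = stem.split("_")[1]
        wave = int(stem.split("_w")[-1])
        series_map[(dyad, member, wave)] = acc.read_epoch_csv(path, stem)
    child_ages = dict(zip(covs["dyad_id"], covs["c_age_base"]))
    return prompts, pairs, covs, series_map, child_ages
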