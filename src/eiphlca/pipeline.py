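"""End-to-end pipeline: cohort -> descriptives -> latent-class fit -> MAP ->
ROC -> F1 threshold -> cross-tabulation -> prior sensitivity.

``run_pipeline`` sequences the analyses in the order a reader of the study
would meet them and writes a structured JSON report plus delimited-text
artifacts.  Reruns with the same configuration are byte-identical: every
random draw flows from the master seed and serialization applies a fixed
rounding rule.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    CohortDesign,
    ExamRecord,
    LatentClassParams,
    PARAM_NAMES,
    default_study_params,
    generate_cohort,
    read_cohort,
    records_to_frame,
    write_cohort,
)
from .descriptive import (
    cross_tabulate,
    overlap_interval,
    pooled_summary,
    repeated_measures_anova,
    score_summary_table,
    spearman_tied,
)
from .model import McmcConfig, PosteriorSummary, PriorSpec, fit_mcmc, map_estimate, prior_sensitivity
from .roc import optimal_threshold, roc_from_normals

__all__ = ["PipelineConfig", "run_pipeline", "read_cohort"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs; exactly one of ``cohort_path`` or
    (``synthesis_params``, ``design``) must be given.

    The master ``seed`` drives both synthesis and sampling unless those
    components carry explicit seeds of their own, and is echoed into every
    output.  All paper-visible constants (iteration counts, the 0.01
    false-positive prior bound, the 0.5 prevalence assumed for precision)
    live here with the study values as defaults.
    """

    cohort_path: Optional[str] = None
    synthesis_params: Optional[LatentClassParams] = None
    design: Optional[CohortDesign] = None
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    f1_mean: str = "harmonic"
    prevalence_assumed: float = 0.5
    threshold_inclusive: bool = True
    run_prior_sensitivity: bool = True
    sensitivity_scales: tuple[float, ...] = (0.9, 1.0, 1.1)
    roc_grid_points: int = 512
    seed: int = 20191227
    report_float_decimals: int = 6

    def validate(self) -> "PipelineConfig":
        has_path = self.cohort_path is not None
        has_synth = self.synthesis_params is not None or self.design is not None
        if has_path == has_synth:
            raise ValueError(
                "exactly one of cohort_path or (synthesis_params, design) must be set"
            )
        if self.f1_mean not in ("harmonic", "geometric"):
            raise ValueError("f1_mean must be 'harmonic' or 'geometric'")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "synthesis_params" in kwargs and kwargs["synthesis_params"] is not None:
            sp = kwargs["synthesis_params"]
            kwargs["synthesis_params"] = (
                default_study_params() if sp == "default" else LatentClassParams(**sp)
            )
        if "design" in kwargs and kwargs["design"] is not None:
            kwargs["design"] = CohortDesign(**kwargs["design"])
        if "priors" in kwargs and kwargs["priors"] is not None:
            p = {k: tuple(v) if isinstance(v, list) else v for k, v in kwargs["priors"].items()}
            kwargs["priors"] = PriorSpec(**p)
        if "mcmc" in kwargs and kwargs["mcmc"] is not None:
            kwargs["mcmc"] = McmcConfig(**kwargs["mcmc"])
        if "sensitivity_scales" in kwargs:
            kwargs["sensitivity_scales"] = tuple(kwargs["sensitivity_scales"])
        return cls(**kwargs).validate()


def _config_digest(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _round_floats(obj, nd: int):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), nd)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _pct(numerator: int, denominator: int) -> dict:
    return {
        "numerator": int(numerator),
        "denominator": int(denominator),
        "percent": 100.0 * numerator / denominator if denominator else float("nan"),
    }


def _descriptives(records: Sequence[ExamRecord]) -> dict:
    out: dict = {}
    exercised = [r for r in records if r.group == "exercised" and r.tbe_score is not None]
    sedentary = [r for r in records if r.group == "sedentary"]

    if exercised:
        rows = score_summary_table(exercised)
        out["score_summary"] = [vars(r) for r in rows]
        if len(rows) >= 2:
            ov = overlap_interval(rows)
            out["overlap_interval"] = {"low": ov.low, "high": ov.high, "empty": ov.empty}
        scores = [r.tbe_score for r in exercised]
        counts = [r.balf_rbc for r in exercised]
        if len(set(scores)) > 1 and len(set(counts)) > 1:
            rs = spearman_tied(scores, counts)
            out["spearman"] = {"rs": rs.correlation, "p_value": rs.p_value, "n": len(scores)}

    if sedentary:
        by_occ: dict[int, list[float]] = {}
        for r in sedentary:
            by_occ.setdefault(r.occasion, []).append(r.balf_rbc)
        occ_summ = {
            occ: {"n": len(v), "mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0}
            for occ, v in sorted(by_occ.items())
        }
        out["sedentary_by_occasion"] = occ_summ
        groups = [(s["n"], s["mean"], s["sd"]) for s in occ_summ.values() if s["n"] >= 2]
        if len(groups) >= 1:
            pooled = pooled_summary(groups)
            out["sedentary_pooled"] = {"n": pooled.n, "mean": pooled.mean, "sd": pooled.sd}
        occasions = sorted(by_occ)
        sizes = {len(by_occ[o]) for o in occasions}
        if len(occasions) >= 2 and len(sizes) == 1 and sizes.pop() >= 2:
            cmpres = repeated_measures_anova([by_occ[o] for o in occasions])
            out["repeat_lavage_anova"] = {
                "f_stat": cmpres.f_stat,
                "p_value": cmpres.p_value,
                "df_num": cmpres.df_num,
                "df_den": cmpres.df_den,
                "occasion_means": list(cmpres.group_means),
                "occasion_sds": list(cmpres.group_sds),
            }
    return out


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full analysis; returns the report dict (also written to
    ``outdir/report.json`` alongside the cohort, posterior, draw, ROC and
    summary-table artifacts)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    report: dict = {
        "seed": config.seed,
        "config_digest": _config_digest(config),
        "config": _round_floats(asdict(config), 12),
    }

    # --- stage: cohort -----------------------------------------------------
    try:
        if config.cohort_path is not None:
            records = read_cohort(config.cohort_path)
            report["cohort"] = {"source": str(config.cohort_path), "n_records": len(records)}
        else:
            params = config.synthesis_params or default_study_params()
            design = config.design if config.design is not None else CohortDesign(seed=config.seed)
            records = generate_cohort(params, design)
            write_cohort(records, outdir / "cohort.csv")
            report["cohort"] = {
                "source": "synthesized",
                "n_records": len(records),
                "design": asdict(design),
                "generating_params": asdict(params),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'cohort' failed: {exc}") from exc
    logger.info("cohort ready: %d records (%.2fs)", len(records), time.perf_counter() - t0)

    # --- stage: descriptives ----------------------------------------------
    t1 = time.perf_counter()
    try:
        report["descriptive"] = _descriptives(records)
        if "score_summary" in report["descriptive"]:
            pd.DataFrame(report["descriptive"]["score_summary"]).to_csv(
                outdir / "score_summary.csv", index=False
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'descriptive' failed: {exc}") from exc
    logger.info("descriptives done (%.2fs)", time.perf_counter() - t1)

    # --- stage: latent-class fit -------------------------------------------
    t2 = time.perf_counter()
    try:
        mcmc = config.mcmc
        if mcmc.seed == 0:  # unset: derive from the master seed
            mcmc = replace(mcmc, seed=(config.seed + 1) % 2**31)
        summary = fit_mcmc(records, config.priors, mcmc)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'fit' failed: {exc}") from exc
    summary.table.rename_axis("parameter").to_csv(outdir / "posterior_summary.csv")
    _dump_draws(summary, outdir / "draws.csv")
    report["posterior"] = {
        "table": {
            name: {c: float(summary.table.loc[name, c]) for c in summary.table.columns}
            for name in PARAM_NAMES
        },
        "converged": summary.converged,
        "warnings": list(summary.warnings),
        "tbe_specificity_mean": 1.0 - summary.posterior_mean("fpr_tbe"),
    }
    logger.info("latent-class fit done (%.2fs)", time.perf_counter() - t2)

    # --- stage: ROC + threshold -------------------------------------------
    t3 = time.perf_counter()
    try:
        map_params = map_estimate(summary)
        grid = np.linspace(
            map_params.mu_neg - 5 * map_params.sigma_neg,
            map_params.mu_pos + 5 * map_params.sigma_pos,
            config.roc_grid_points,
        )
        roc = roc_from_normals(map_params, grid, config.prevalence_assumed, config.f1_mean)
        pd.DataFrame(
            {
                "threshold_natural": roc.thresholds_natural,
                "threshold_log": roc.thresholds_log,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
                "precision": roc.precision,
                "f1": roc.f1,
            }
        ).to_csv(outdir / "roc.csv", index=False)
        thr = optimal_threshold(map_params, config.prevalence_assumed, config.f1_mean)
        report["map_params"] = asdict(map_params)
        report["threshold"] = {
            "threshold_natural": thr.threshold_natural,
            "threshold_rounded": round(thr.threshold_natural),
            "threshold_log": thr.threshold_log,
            "sensitivity": thr.sensitivity,
            "specificity": thr.specificity,
            "precision": thr.precision,
            "f1": thr.f1,
            "prevalence_assumed": thr.prevalence_assumed,
            "boundary": thr.boundary,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'threshold' failed: {exc}") from exc
    logger.info("ROC/threshold done (%.2fs)", time.perf_counter() - t3)

    # --- stage: cross-tabulation at the derived threshold -------------------
    try:
        both = [r for r in records if r.group == "exercised" and r.tbe_score is not None]
        ct = cross_tabulate(both, thr.threshold_natural, config.threshold_inclusive)
        report["cross_tab"] = {
            "tp": ct.tp,
            "fn_balf": ct.fn_balf,
            "fp_tbe_absent": ct.fp_tbe_absent,
            "tn": ct.tn,
            "total": ct.total,
            "tbe_prevalence": _pct(ct.tp + ct.fn_balf, ct.total),
            "balf_prevalence": _pct(ct.tp + ct.fp_tbe_absent, ct.total),
            "balf_false_negative": _pct(ct.fn_balf, ct.total),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'cross_tab' failed: {exc}") from exc

    # --- stage: prior sensitivity ------------------------------------------
    if config.run_prior_sensitivity:
        t4 = time.perf_counter()
        try:
            mcmc = config.mcmc
            if mcmc.seed == 0:
                mcmc = replace(mcmc, seed=config.seed)
            sens = prior_sensitivity(records, config.priors, mcmc, config.sensitivity_scales)
            report["prior_sensitivity"] = {
                "posterior_means": {
                    f"{s:g}": {n: float(sens.means.loc[s, n]) for n in PARAM_NAMES}
                    for s in sens.means.index
                },
                "max_abs_deviation": {n: float(sens.max_abs_deviation[n]) for n in PARAM_NAMES},
            }
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'prior_sensitivity' failed: {exc}") from exc
        logger.info("prior sensitivity done (%.2fs)", time.perf_counter() - t4)

    report = _round_floats(report, config.report_float_decimals)
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")
    logger.info("pipeline complete (%.2fs total)", time.perf_counter() - t0)
    return report


def _dump_draws(summary: PosteriorSummary, path) -> None:
    """Columnar dump: one row per retained draw (chain, iteration, params,
    log_joint)."""
    n_chains, n_kept, _ = summary.draws.shape
    frames = []
    for c in range(n_chains):
        df = pd.DataFrame(summary.draws[c], columns=list(PARAM_NAMES))
        df.insert(0, "iteration", np.arange(n_kept))
        df.insert(0, "chain", c)
        df["log_joint"] = summary.log_joint_draws[c]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
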