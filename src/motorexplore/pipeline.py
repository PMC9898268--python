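"""End-to-end orchestration: angles -> patterns -> exploration -> report.

The pipeline reproduces the full analysis chain on either a recorded angle
CSV or a generated synthetic cohort: low-pass filter, cycle segmentation,
continuous relative phase, pooled coordination-profile clustering with BIC
plateau selection, per-learner drifting Markov models at two drift degrees,
the per-pattern exploration quantity, exponential learning-curve fits, and
the group statistics.  Every stage's output is written to the output
directory together with a manifest naming the package version, config hash
and seed; runs are deterministic given config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .dmm import DriftingMarkov, PatternLabelSequence
from .exploration import exploration_quantity, exploration_summary
from .kinematics import extract_crp_cycles
from .learning_curve import ExponentialLearningCurve, SessionPerformance
from .profiling import assign_labels, fit_profiles, select_k
from .stats import (WithinSubjectTable, correlation, levene_mean_centered,
                    paired_t, rm_anova2, sample_variance)
from .synthetic import generate_cohort

logger = logging.getLogger("motorexplore")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    input_csv: str | None = None          # recorded angle CSV, or None
    scenario: dict = field(default_factory=dict)   # synthetic cohort kwargs
    L: int = 100
    cutoff_hz: float = 8.0
    min_period_s: float = 0.5
    k_min: int = 2
    k_max: int = 16
    degrees: tuple = (1, 3)
    exploration_mode: str = "appearance"
    cluster_method: str = "fisher_em"
    n_init: int = 10
    seed: int = 0
    outdir: str = "motorexplore_out"

    def __post_init__(self) -> None:
        if self.k_max < self.k_min:
            raise ValueError("empty K range")
        if len(set(self.degrees)) != len(self.degrees):
            raise ValueError("drift degrees must be distinct")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _collect_cycles(traces, cfg: PipelineConfig) -> pd.DataFrame:
    """Kinematic chain per trial; returns one row per retained cycle."""
    rows = []
    for tr in traces:
        try:
            segments, crp = extract_crp_cycles(
                tr, cutoff=cfg.cutoff_hz, min_period=cfg.min_period_s,
                L=cfg.L)
        except Exception as exc:
            raise RuntimeError(
                f"stage kinematics failed on trial {tr.meta}: {exc}") from exc
        fs = tr.fs
        for seg, curve in zip(segments, crp):
            rows.append({
                "learner": tr.meta.get("learner", 0),
                "speed": tr.meta.get("speed", "low"),
                "session": tr.meta.get("session", 0),
                "trial": tr.meta.get("trial", 0),
                "freq_hz": fs / (seg.end_idx - seg.start_idx),
                "crp": curve,
            })
    df = pd.DataFrame(rows)
    df = df.sort_values(["learner", "speed", "session", "trial"],
                        kind="stable").reset_index(drop=True)
    df["cycle_index"] = df.groupby(["learner", "speed"]).cumcount()
    return df


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full chain and write the report bundle.

    Returns a dict with the selected K, per-learner exploration profiles,
    learning-curve fits and the statistics report.
    """
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict = {}

    # -- stage 1: input ------------------------------------------------------
    if cfg.input_csv:
        traces = mio.read_angle_csv(cfg.input_csv)
        stages["input"] = {"source": cfg.input_csv, "n_trials": len(traces)}
    else:
        sc = dict(cfg.scenario)
        sc.setdefault("seed", cfg.seed)
        cohort = generate_cohort(**sc)
        traces = [rec.trace for ds in cohort for rec in ds.trials]
        stages["input"] = {"source": "synthetic",
                           "n_learners": len({d.scenario.meta.get("learner")
                                              for d in cohort}),
                           "n_trials": len(traces)}
    logger.info("input: %d trials", len(traces))

    # -- stage 2: kinematics -------------------------------------------------
    cycles = _collect_cycles(traces, cfg)
    crp_matrix = np.vstack(cycles["crp"].to_numpy())
    meta_cols = cycles[["learner", "speed", "cycle_index", "session",
                        "trial", "freq_hz"]]
    mio.write_crp_csv(crp_matrix, outdir / "crp_cycles.csv",
                      meta=meta_cols)
    stages["kinematics"] = {"n_cycles": int(len(cycles))}
    logger.info("kinematics: %d cycles", len(cycles))

    # -- stage 3: profiling --------------------------------------------------
    ss = np.random.SeedSequence(cfg.seed)
    k_values = list(range(cfg.k_min, cfg.k_max + 1))
    cluster_seeds = {k: int(s.generate_state(1)[0] % (2**31))
                     for k, s in zip(k_values, ss.spawn(len(k_values)))}
    fits = {}
    for k in k_values:
        fits[k] = fit_profiles(crp_matrix, k, seed=cluster_seeds[k],
                               n_init=cfg.n_init, method=cfg.cluster_method)
    bic_by_k = {k: fits[k].bic for k in k_values}
    k_star, no_plateau = select_k(bic_by_k)
    labels, profiles = assign_labels(fits[k_star])
    cycles = cycles.assign(pattern=labels)
    mio.write_labels_tsv(cycles, outdir / "labels.tsv")
    pd.DataFrame({p.pattern_id: p.mean_crp for p in profiles}) \
        .to_csv(outdir / "profile_means.csv", index=False)
    stages["profiling"] = {"bic_by_k": bic_by_k, "k_star": int(k_star),
                           "no_plateau": bool(no_plateau)}
    logger.info("profiling: K* = %d", k_star)

    # -- stage 4: drift models + exploration ---------------------------------
    expl_rows, summaries = [], []
    for (learner, speed), grp in cycles.groupby(["learner", "speed"]):
        seq = PatternLabelSequence(grp.sort_values("cycle_index")["pattern"]
                                   .to_numpy(), m=int(k_star))
        results = {}
        for d in cfg.degrees:
            results[d] = DriftingMarkov(seq, degree=d, m=int(k_star)).fit()
        d_lo, d_hi = min(cfg.degrees), max(cfg.degrees)
        Q = exploration_quantity(results[d_lo], results[d_hi],
                                 mode=cfg.exploration_mode)
        prof = exploration_summary(Q, seq,
                                   meta={"learner": learner, "speed": speed})
        for k in range(int(k_star)):
            expl_rows.append({"learner": learner, "speed": speed,
                              "pattern": k + 1, "Q_percent": Q[k],
                              "visited": bool(prof.visited_mask[k])})
        summaries.append({"learner": learner, "speed": speed,
                          "visited": prof.visited,
                          "mean_Q": float(np.mean(Q)),
                          "max_Q": float(np.max(Q)),
                          "sd_Q": prof.sd_across_patterns,
                          **{f"loglik_d{d}": results[d].loglik
                             for d in cfg.degrees},
                          **{f"bic_d{d}": results[d].bic
                             for d in cfg.degrees}})
        (outdir / f"dmm_{learner}_{speed}.json").write_text(
            json.dumps({f"degree_{d}": json.loads(results[d].to_json())
                        for d in cfg.degrees}))
    expl_df = pd.DataFrame(expl_rows)
    summary_df = pd.DataFrame(summaries)
    expl_df.to_csv(outdir / "exploration.csv", index=False)
    summary_df.to_csv(outdir / "exploration_summary.csv", index=False)
    stages["exploration"] = {"n_models": len(summaries)}

    # -- stage 5: learning curves --------------------------------------------
    fit_rows = []
    for (learner, speed), grp in cycles.groupby(["learner", "speed"]):
        means = grp.groupby("session")["freq_hz"].mean()
        perf = SessionPerformance(means.index.to_numpy(float),
                                  means.to_numpy(float),
                                  meta={"learner": learner, "speed": speed})
        fit = ExponentialLearningCurve(perf).fit()
        fit_rows.append({"participant": learner, "condition": speed,
                         "b": fit.b, "r2": fit.r2, "rmse": fit.rmse,
                         "a": fit.a, "c": fit.c,
                         "converged": fit.converged})
    fits_df = pd.DataFrame(fit_rows)
    fits_df.to_csv(outdir / "learning_fits.csv", index=False)
    stages["learning_curve"] = {"n_fits": len(fits_df)}

    # -- stage 6: statistics -------------------------------------------------
    report = _stats_report(fits_df, expl_df, summary_df)
    (outdir / "stats_report.json").write_text(
        json.dumps(report, indent=1, default=float))
    stages["stats"] = {"tests": sorted(report)}

    mio.write_manifest(outdir, cfg.to_dict(), cfg.seed, stages)
    return {
        "k_star": int(k_star),
        "bic_by_k": bic_by_k,
        "cycles": cycles,
        "profiles": profiles,
        "exploration": expl_df,
        "exploration_summary": summary_df,
        "learning_fits": fits_df,
        "stats": report,
        "outdir": str(outdir),
    }


def _stats_report(fits_df: pd.DataFrame, expl_df: pd.DataFrame,
                  summary_df: pd.DataFrame) -> dict:
    """Group statistics over learners, mirroring the analysis plan."""
    report: dict = {}
    conds = sorted(fits_df["condition"].unique())
    if len(conds) == 2:
        piv = fits_df.pivot(index="participant", columns="condition",
                            values="b").dropna()
        if len(piv) >= 2:
            x, y = piv[conds[0]].to_numpy(), piv[conds[1]].to_numpy()
            try:
                report["learning_rate_paired_t"] = paired_t(x, y).to_dict()
            except ValueError as exc:
                report["learning_rate_paired_t"] = {"error": str(exc)}
            report["learning_rate_levene"] = \
                levene_mean_centered([x, y]).to_dict()
            report["learning_rate_variance"] = {
                conds[0]: sample_variance(x), conds[1]: sample_variance(y)}
    if len(conds) == 2 and expl_df["learner"].nunique() >= 2:
        try:
            table = WithinSubjectTable.from_frame(
                expl_df.rename(columns={"learner": "subject"}),
                subject="subject", a="pattern", b="speed",
                value="Q_percent")
            report["exploration_anova"] = {
                name: r.to_dict() for name, r in rm_anova2(table).items()}
        except ValueError as exc:
            report["exploration_anova"] = {"error": str(exc)}
    if len(summary_df) >= 3:
        try:
            r = correlation(summary_df["visited"], summary_df["mean_Q"],
                            method="pearson")
            report["visited_vs_exploration"] = r.to_dict()
        except ValueError as exc:
            report["visited_vs_exploration"] = {"error": str(exc)}
    return report
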