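"""End-to-end orchestration: simulate -> preprocess -> rhythms -> sleep -> stats.

A run consumes either a cohort directory (subjects.csv, mctq.csv,
actimetry/*.csv) or simulates one on the fly, then writes an output
directory containing the QC report, per-subject rhythm metrics, sleep
variables, BMI-group comparisons, the two prevalence-ratio models
(questionnaire-based and actimetry-based), group-profile and metric plots,
a frozen copy of the resolved configuration, and a stage-by-stage subject
accounting log.  Re-running with the same config and seed reproduces every
CSV byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import actio, inferstats, mctq as mctq_mod, rhythms, synthgen
from .series import EpochSeries

log = logging.getLogger(__name__)

BMI_GROUPS = ("normal", "overweight", "obese")
NPCRA_VARS = ("IS", "IV", "M10", "L5", "RA", "mesor", "amplitude")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    input_dir: str | None = None          # None => simulate on the fly
    cohort: synthgen.CohortParams = field(default_factory=synthgen.CohortParams)
    epoch_min: int = 10
    nonwear_min_run: int = 10
    window_days: int = 7
    max_missing_h: float = 4.0
    normalization: str = "mean_sd"        # {"mean_sd", "quantile", "none"}
    reference_device: str = "Actiwatch2"
    npcra_hourly: bool = False
    bootstrap_B: int = 2000
    stats_seed: int = 17
    urbanization_reference: str = "no_electricity"
    adjust_brand: bool = False            # add device covariate to model 2
    adjust_season: bool = False           # add season-of-recording covariate
    make_plots: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _fit_dropping_separated(y, X, terms):
    """Fit the modified Poisson model, dropping indicator columns whose
    stratum carries all or no events (quasi-separation) and retrying.
    Dropped terms are logged; the intercept and continuous terms stay."""
    import numpy as np
    keep = list(range(X.shape[1]))
    for j, t in enumerate(terms):
        if t == "intercept":
            continue
        col = X[:, j]
        vals = set(np.unique(col))
        if vals <= {0.0, 1.0} and len(vals) > 1:
            m1 = y[col == 1].mean()
            m0 = y[col == 0].mean()
            if m1 in (0.0, 1.0) or m0 in (0.0, 1.0):
                keep.remove(j)
                log.warning("dropping separated term %s (stratum event rates "
                            "%g / %g)", t, m0, m1)
        elif len(vals) == 1:
            keep.remove(j)
            log.warning("dropping constant term %s", t)
    kept_terms = [terms[j] for j in keep]
    try:
        return inferstats.fit_modified_poisson(y, X[:, keep], kept_terms)
    except inferstats.StatError as e:
        # sparse categorical strata can still separate jointly; fall back to
        # the model without categorical dummies (degenerate-cohort guard)
        reduced = [j for j, t in zip(keep, kept_terms) if "[" not in t]
        if len(reduced) == len(keep):
            raise
        log.warning("full model failed (%s); refitting without categorical "
                    "dummies", e)
        return inferstats.fit_modified_poisson(
            y, X[:, reduced], [terms[j] for j in reduced])


def _load_cohort(config: PipelineConfig):
    if config.input_dir is None:
        cohort = synthgen.simulate_cohort(config.cohort)
        subjects = {s.subject_id: s for s in cohort.subjects}
        return subjects, cohort.mctq, cohort.series
    d = Path(config.input_dir)
    sdf = pd.read_csv(d / "subjects.csv")
    subjects = {}
    for row in sdf.itertuples():
        subjects[str(row.subject_id)] = mctq_mod.make_subject_record(
            row.subject_id, row.age, row.sex, row.urbanization,
            row.height_m, row.weight_kg, bool(row.self_report_flag))
    records = mctq_mod.read_mctq_csv(d / "mctq.csv")
    series = []
    for f in sorted((d / "actimetry").glob("*.csv")):
        from .series import read_csv
        series.append(read_csv(f))
    return subjects, records, series


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = []

    with open(outdir / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    subjects, records, series_list = _load_cohort(config)
    counts.append(("subjects_in", len(subjects)))

    # --- MCTQ-side: sleep variables, eligibility, BMI
    sleep_df = mctq_mod.sleep_table(records, subjects)
    sleep_df.to_csv(outdir / "sleep.csv", index=False)
    eligible_ids = set(sleep_df.loc[sleep_df["eligible"] == 1, "subject_id"])
    reason_counts = {}
    for r in sleep_df.loc[sleep_df["eligible"] == 0, "reasons"]:
        for code in str(r).split(";"):
            if code:
                reason_counts[code] = reason_counts.get(code, 0) + 1
    counts.append(("mctq_eligible", len(eligible_ids)))
    for code, c in sorted(reason_counts.items()):
        counts.append((f"mctq_excluded_{code}", c))
    counts.append(("mctq_excluded_total", len(subjects) - len(eligible_ids)))

    # --- Actimetry QC
    accepted, qc_rows = [], []
    for s in series_list:
        win, rep = actio.preprocess(s, epoch_min=config.epoch_min,
                                    nonwear_min_run=config.nonwear_min_run,
                                    n_days=config.window_days,
                                    max_missing_h=config.max_missing_h)
        qc_rows.append({
            "subject_id": rep.subject_id, "accepted": int(rep.accepted),
            "rejection_reason": rep.rejection_reason or "",
            "window_start": str(rep.window_start) if rep.window_start is not None else "",
            "days_retained": rep.days_retained,
            "nonwear_runs": rep.nonwear_runs, "nonwear_epochs": rep.nonwear_epochs,
        })
        if win is not None:
            accepted.append(win)
    pd.DataFrame(qc_rows).to_csv(outdir / "qc_report.csv", index=False)
    counts.append(("actimetry_in", len(series_list)))
    counts.append(("actimetry_accepted", len(accepted)))
    counts.append(("actimetry_rejected", len(series_list) - len(accepted)))

    # --- Brand normalization
    if config.normalization in ("mean_sd", "quantile") and any(
            s.device != config.reference_device for s in accepted):
        try:
            ref = actio.reference_stats(accepted, config.reference_device,
                                        keep_pool=config.normalization == "quantile")
            accepted = [actio.normalize_brand(s, ref, config.reference_device,
                                              mode=config.normalization)
                        for s in accepted]
        except actio.NormalizationError as e:
            log.warning("brand normalization skipped: %s", e)

    # --- Rhythm metrics
    rhythm_frames = []
    for s in accepted:
        try:
            rhythm_frames.append(rhythms.subject_rhythms(
                s, hourly=config.npcra_hourly))
        except rhythms.MetricError as e:
            raise PipelineError(f"rhythms stage failed for {s.subject_id}: {e}") from e
    rhythms_df = (pd.concat(rhythm_frames, ignore_index=True)
                  if rhythm_frames else pd.DataFrame())
    rhythms_df.to_csv(outdir / "rhythms.csv", index=False, float_format="%.6g")

    # --- Analysis table
    subj_df = pd.DataFrame([{
        "subject_id": s.subject_id, "age": s.age, "sex": s.sex,
        "urbanization": s.urbanization, "bmi": s.bmi,
        "bmi_category": s.bmi_category,
    } for s in subjects.values()])
    analysis = subj_df.merge(sleep_df[["subject_id", "SJL_gt_1h", "eligible"]],
                             on="subject_id")
    analysis = analysis[(analysis["eligible"] == 1)
                        & analysis["bmi_category"].isin(BMI_GROUPS)]
    analysis["female"] = (analysis["sex"] == "F").astype(int)
    analysis["overweight_or_obese"] = analysis["bmi_category"].isin(
        ("overweight", "obese")).astype(int)
    counts.append(("analysis_mctq_n", len(analysis)))

    # --- Group comparisons (actimetry metrics across BMI categories)
    comp_rows = []
    if not rhythms_df.empty:
        merged = rhythms_df.merge(analysis[["subject_id", "bmi_category"]],
                                  on="subject_id")
        for channel in rhythms.CHANNELS:
            sub = merged[merged["channel"] == channel]
            for var in NPCRA_VARS:
                groups, labels = [], []
                for g in BMI_GROUPS:
                    v = sub.loc[sub["bmi_category"] == g, var].dropna().to_numpy()
                    if v.size:
                        groups.append(v)
                        labels.append(g)
                if len(groups) < 2:
                    comp_rows.append({"channel": channel, "variable": var,
                                      "available": 0})
                    continue
                try:
                    gc = inferstats.compare_groups(
                        f"{channel}_{var}", groups, labels,
                        B=config.bootstrap_B, seed=config.stats_seed)
                except inferstats.StatError:
                    comp_rows.append({"channel": channel, "variable": var,
                                      "available": 0})
                    continue
                row = {"channel": channel, "variable": var, "available": 1,
                       "k": gc.k, "n": gc.n, "H": gc.H, "df": gc.df, "p": gc.p,
                       "epsilon_sq": gc.epsilon_sq,
                       "epsilon_sq_lo": gc.epsilon_sq_ci[0],
                       "epsilon_sq_hi": gc.epsilon_sq_ci[1],
                       "eta_sq": gc.eta_sq,
                       "eta_sq_lo": gc.eta_sq_ci[0], "eta_sq_hi": gc.eta_sq_ci[1]}
                for pr in gc.pairwise:
                    tag = f"{pr.pair[0]}_vs_{pr.pair[1]}"
                    row[f"p_sidak_{tag}"] = pr.p_sidak
                comp_rows.append(row)
    pd.DataFrame(comp_rows).to_csv(outdir / "comparisons.csv", index=False)

    # --- Regression models
    reg_frames = []
    try:
        X1, t1 = inferstats.build_design(
            analysis, continuous=["age"], binary=["female", "SJL_gt_1h"],
            categorical={"urbanization": config.urbanization_reference})
        fit1 = _fit_dropping_separated(
            analysis["overweight_or_obese"].to_numpy(), X1, t1)
        f1 = fit1.to_frame()
        f1.insert(0, "model", "mctq")
        reg_frames.append(f1)
    except inferstats.StatError as e:
        log.warning("MCTQ model not fitted: %s", e)

    if not rhythms_df.empty:
        iv_wide = rhythms_df.pivot_table(index="subject_id", columns="channel",
                                         values="IV").rename(
            columns={"activity": "IV_activity", "light": "IV_light"}).reset_index()
        act_analysis = analysis.merge(iv_wide, on="subject_id")
        extra_binary = []
        if config.adjust_brand:
            device = {s.subject_id: int(s.device == "ActTrust") for s in accepted}
            act_analysis["acttrust"] = act_analysis["subject_id"].map(device)
            extra_binary.append("acttrust")
        if config.adjust_season:
            # southern-hemisphere cool season: Mar 20 - Sep 22 window starts
            season = {s.subject_id: int(
                (s.start_time.month, s.start_time.day) >= (3, 20)
                and (s.start_time.month, s.start_time.day) < (9, 23))
                for s in accepted}
            act_analysis["cool_season"] = act_analysis["subject_id"].map(season)
            extra_binary.append("cool_season")
        counts.append(("analysis_actimetry_n", len(act_analysis)))
        if len(act_analysis) >= 10:
            try:
                X2, t2 = inferstats.build_design(
                    act_analysis,
                    continuous=["age", "IV_light", "IV_activity"],
                    binary=["female"] + extra_binary)
                fit2 = _fit_dropping_separated(
                    act_analysis["overweight_or_obese"].to_numpy(), X2, t2)
                f2 = fit2.to_frame()
                f2.insert(0, "model", "actimetry")
                reg_frames.append(f2)
            except inferstats.StatError as e:
                log.warning("actimetry model not fitted: %s", e)
    reg_cols = ["model", "term", "PR", "ci_low", "ci_high", "p",
                "coef", "se_robust", "VIF"]
    reg_df = (pd.concat(reg_frames, ignore_index=True)
              if reg_frames else pd.DataFrame(columns=reg_cols))
    reg_df.to_csv(outdir / "regression.csv", index=False)

    # --- Plots
    if config.make_plots and not rhythms_df.empty:
        try:
            _plots(outdir, accepted, analysis, rhythms_df)
        except Exception as e:  # plotting must never sink a run
            log.warning("plotting failed: %s", e)

    pd.DataFrame(counts, columns=["stage", "n"]).to_csv(
        outdir / "counts.csv", index=False)
    with open(outdir / "run.log", "w") as fh:
        fh.write(json.dumps({"counts": dict(counts)}, indent=2) + "\n")
    return outdir


def _plots(outdir: Path, accepted, analysis: pd.DataFrame,
           rhythms_df: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    cat = dict(zip(analysis["subject_id"], analysis["bmi_category"]))
    colors = {"normal": "tab:orange", "overweight": "lightblue", "obese": "tab:blue"}

    for channel in rhythms.CHANNELS:
        fig, ax = plt.subplots(figsize=(7, 4))
        for g in BMI_GROUPS:
            profs = [rhythms.daily_profile(s, channel, "mean")
                     for s in accepted if cat.get(s.subject_id) == g]
            if not profs:
                continue
            gp = rhythms.group_profile(profs, "mean")
            h = gp.bin_hours()
            ax.plot(h, gp.values, label=f"{g} (n={len(profs)})", color=colors[g])
            if gp.sem is not None:
                ax.fill_between(h, gp.values - gp.sem, gp.values + gp.sem,
                                alpha=0.3, color=colors[g])
        ax.set_xlabel("clock hour")
        ax.set_ylabel(channel)
        ax.legend()
        fig.tight_layout()
        fig.savefig(figdir / f"profile_{channel}.png", dpi=100)
        plt.close(fig)

    merged = rhythms_df.merge(analysis[["subject_id", "bmi_category"]],
                              on="subject_id")
    for channel in rhythms.CHANNELS:
        sub = merged[merged["channel"] == channel]
        fig, axes = plt.subplots(1, len(NPCRA_VARS), figsize=(3 * len(NPCRA_VARS), 3))
        for ax, var in zip(np.atleast_1d(axes), NPCRA_VARS):
            data = [sub.loc[sub["bmi_category"] == g, var].dropna()
                    for g in BMI_GROUPS]
            ax.boxplot([d.to_numpy() for d in data], tick_labels=BMI_GROUPS)
            ax.set_title(var)
            ax.tick_params(axis="x", rotation=45)
        fig.suptitle(channel)
        fig.tight_layout()
        fig.savefig(figdir / f"metrics_{channel}.png", dpi=100)
        plt.close(fig)


def make_report(run_dir) -> Path:
    """Render a single human-readable markdown summary of a finished run."""
    run_dir = Path(run_dir)
    required = ["counts.csv", "comparisons.csv", "regression.csv", "sleep.csv"]
    missing = [f for f in required if not (run_dir / f).exists()]
    if missing:
        raise PipelineError(f"run incomplete, missing: {', '.join(missing)}")
    counts = pd.read_csv(run_dir / "counts.csv")
    comps = pd.read_csv(run_dir / "comparisons.csv")
    regs = pd.read_csv(run_dir / "regression.csv")

    lines = ["# Run summary", "", "## Subject accounting", ""]
    for row in counts.itertuples():
        lines.append(f"- {row.stage}: {row.n}")

    lines += ["", "## BMI-group comparisons (Kruskal-Wallis + Dunn/Sidak)", ""]
    if comps.empty:
        lines.append("(no comparisons available)")
    else:
        for row in comps.itertuples():
            if getattr(row, "available", 1) != 1:
                lines.append(f"- {row.channel} {row.variable}: unavailable "
                             "(empty or degenerate group)")
            else:
                lines.append(
                    f"- {row.channel} {row.variable}: H = {row.H:.2f}, "
                    f"p = {row.p:.4f}, eps^2 = {row.epsilon_sq:.3f} "
                    f"[{row.epsilon_sq_lo:.3f}, {row.epsilon_sq_hi:.3f}]")

    for model, title in (("mctq", "Model 1: questionnaire variables"),
                         ("actimetry", "Model 2: actimetry variables")):
        sub = regs[regs["model"] == model] if not regs.empty else regs
        lines += ["", f"## {title} (modified Poisson, HC0)", ""]
        if sub is None or sub.empty:
            lines.append("(model not fitted)")
            continue
        lines.append("| term | PR | 95% CI | p | VIF |")
        lines.append("|---|---|---|---|---|")
        for row in sub.itertuples():
            lines.append(f"| {row.term} | {row.PR:.3f} | "
                         f"{row.ci_low:.3f}-{row.ci_high:.3f} | {row.p:.4f} | "
                         f"{'' if pd.isna(row.VIF) else f'{row.VIF:.2f}'} |")

    out = run_dir / "report.md"
    out.write_text("\n".join(lines) + "\n")
    return out
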