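"""End-to-end pipeline: simulate -> preprocess -> RQA -> fit -> report.

Every stage logs its input/output row counts into a run manifest so that
retention at each step (fixation filters, trial exclusions) is auditable,
and a fixed seed reproduces the run byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .experiment import AccuracyModel, ExperimentDesign, generate_experiment
from .geometry import degrees_to_pixels
from .inference import (
    ModelSpec,
    correlation_panel,
    fit_model,
    individual_differences,
    spread_recurrence_summary,
)
from .preprocess import exclude_trials, filter_fixations, spread_table
from .rqa import rqa_table
from .scanpaths import MechanismParams

logger = logging.getLogger("gazedyn")

RQA_RESPONSES = ("recurrence", "determinism", "corm")


@dataclass
class RunManifest:
    config: dict
    version: str
    row_counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timing_s: dict = field(default_factory=dict)

    def write(self, path: Path) -> Path:
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "version": self.version,
                    "row_counts": self.row_counts,
                    "outputs": {k: str(v) for k, v in self.outputs.items()},
                    "timing_s": self.timing_s,
                },
                fh,
                indent=2,
            )
        return path


def threshold_px(config: PipelineConfig) -> float:
    if config.threshold_px is not None:
        return float(config.threshold_px)
    return degrees_to_pixels(config.threshold_deg)


def mechanism_params(config: PipelineConfig) -> MechanismParams:
    return MechanismParams(
        mechanism=config.mechanism,
        anchor_sd_px=config.anchor_sd_px,
        restriction_release=config.restriction_release,
        revisit_prob=config.revisit_prob,
        fixation_rate_hz=config.fixation_rate_hz,
        duration_s=config.maintenance_duration_s,
    )


def build_trial_measures(
    trials: pd.DataFrame,
    fixations: pd.DataFrame,
    d: float,
    min_line: int = 2,
    screen=(1920, 1080),
    min_ms: float = 100.0,
    max_ms: float = 5000.0,
):
    """Filter fixations, compute spread and RQA, and join onto the trials."""
    kept_fix, filter_report = filter_fixations(
        fixations, screen=screen, min_ms=min_ms, max_ms=max_ms
    )
    spreads = spread_table(kept_fix)
    measures = rqa_table(kept_fix, d=d, min_line=min_line)
    per_trial = trials.merge(spreads, on=["participant", "trial"], how="inner").merge(
        measures, on=["participant", "trial"], how="inner"
    )
    return per_trial, kept_fix, filter_report


def participant_measure_table(
    analyzed: pd.DataFrame,
    trials_all: pd.DataFrame,
    participants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per participant: mean gaze dynamics, imagery rating, VPT score."""
    table = (
        analyzed.groupby("participant")[["recurrence", "determinism", "corm"]]
        .mean()
        .reset_index()
    )
    rating = trials_all.groupby("participant")["rating"].mean().rename("imagery_rating")
    table = table.merge(rating.reset_index(), on="participant")
    if participants is not None and "vpt_score" in participants.columns:
        table = table.merge(
            participants[["participant", "vpt_score"]], on="participant"
        )
    return table


def fit_stage(
    analyzed: pd.DataFrame, config: PipelineConfig, trials_all: pd.DataFrame
) -> dict:
    """Fit the standard model set and return fits keyed by response."""
    fixed = ["segments"] + (["dvn"] if config.dvn_factor else [])
    rqa_fixed = fixed + (["spread_px"] if config.include_spread_covariate else [])
    profile = config.profile
    fits = {}
    for resp in RQA_RESPONSES:
        spec = ModelSpec.profile(
            profile,
            response=resp,
            family="zoib",
            fixed_effects=list(rqa_fixed),
            sampler=config.sampler,
            seed=config.seed,
        )
        fits[resp] = fit_model(analyzed, spec)
    fits["spread_px"] = fit_model(
        analyzed,
        ModelSpec.profile(
            profile,
            response="spread_px",
            family="exgaussian",
            fixed_effects=list(fixed),
            sampler=config.sampler,
            seed=config.seed,
        ),
    )
    acc = trials_all.assign(correct_num=trials_all["correct"].astype(float))
    fits["accuracy"] = fit_model(
        acc,
        ModelSpec.profile(
            profile,
            response="correct_num",
            family="bernoulli",
            fixed_effects=list(fixed),
            sampler=config.sampler,
            seed=config.seed,
        ),
    )
    return fits


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline described by ``config``."""
    config.validate()
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), version=__version__)
    rng = np.random.default_rng(config.seed)

    # --- simulate ------------------------------------------------------
    t = time.time()
    design = ExperimentDesign(
        n_participants=config.n_participants,
        trials_per_participant=config.trials_per_participant,
        dvn_factor=config.dvn_factor,
        seed=config.seed,
    )
    data = generate_experiment(
        design,
        mechanism_params(config),
        AccuracyModel(intercept=config.accuracy_intercept, slope=config.accuracy_slope),
        rng=rng,
        heterogeneity=config.heterogeneity,
    )
    paths = data.write(out)
    manifest.outputs.update(paths)
    manifest.row_counts["trials_simulated"] = len(data.trials)
    manifest.row_counts["fixations_simulated"] = len(data.fixations)
    manifest.row_counts["trials_per_segment_level"] = int(
        len(data.trials) // config.n_participants // 4
    )
    manifest.timing_s["simulate"] = round(time.time() - t, 2)
    logger.info("simulated %d trials, %d fixations", len(data.trials), len(data.fixations))

    # --- preprocess + RQA ---------------------------------------------
    t = time.time()
    d_px = threshold_px(config)
    per_trial, kept_fix, filter_report = build_trial_measures(
        data.trials,
        data.fixations,
        d=d_px,
        min_line=config.min_line,
        min_ms=config.min_fixation_ms,
        max_ms=config.max_fixation_ms,
    )
    manifest.row_counts["fixations_kept"] = filter_report.n_kept
    manifest.row_counts["fixation_filter"] = filter_report.to_dict()
    with open(out / "filter_report.json", "w") as fh:
        json.dump(filter_report.to_dict(), fh, indent=2)

    analyzed, exclusion = exclude_trials(per_trial, min_rating=config.min_rating)
    manifest.row_counts["trials_with_measures"] = len(per_trial)
    manifest.row_counts["trials_analyzed"] = len(analyzed)
    manifest.row_counts["trials_excluded"] = len(per_trial) - len(analyzed)
    with open(out / "exclusion_report.json", "w") as fh:
        json.dump(exclusion.to_dict(), fh, indent=2)
    per_trial.to_csv(out / "per_trial_measures.csv", index=False)
    manifest.outputs["per_trial_measures"] = out / "per_trial_measures.csv"
    manifest.timing_s["preprocess_rqa"] = round(time.time() - t, 2)
    logger.info(
        "kept %.1f%% of fixations; analyzing %d of %d trials",
        100 * filter_report.proportion_kept,
        len(analyzed),
        len(per_trial),
    )

    # --- inference -----------------------------------------------------
    t = time.time()
    fits = fit_stage(analyzed, config, data.trials)
    model_summaries = {name: fit.to_dict() for name, fit in fits.items()}
    with open(out / "model_summaries.json", "w") as fh:
        json.dump(model_summaries, fh, indent=2, default=str)
    manifest.outputs["model_summaries"] = out / "model_summaries.json"
    manifest.timing_s["fit"] = round(time.time() - t, 2)

    quadrants = spread_recurrence_summary(analyzed, rec_cut=50.0, spread_cut=d_px)
    with open(out / "quadrant_summary.json", "w") as fh:
        json.dump(quadrants.to_dict(), fh, indent=2)

    panel = None
    subject_table = participant_measure_table(analyzed, data.trials, data.participants)
    subject_table.to_csv(out / "participant_measures.csv", index=False)
    manifest.outputs["participant_measures"] = out / "participant_measures.csv"
    if len(subject_table) >= 4:
        panel = correlation_panel(
            subject_table.drop(columns=["participant"]), alpha=0.01
        )

    # --- report + figures ---------------------------------------------
    t = time.time()
    report_text = report(data.trials, analyzed, fits, quadrants, d_px, panel)
    (out / "report.md").write_text(report_text)
    manifest.outputs["report"] = out / "report.md"
    if config.make_figures:
        manifest.outputs.update(make_figures(data.trials, analyzed, fits, d_px, out))
    manifest.timing_s["report"] = round(time.time() - t, 2)
    manifest.timing_s["total"] = round(time.time() - t0, 2)

    manifest.write(out / "manifest.json")
    return manifest


def effect_direction_table(fits: dict) -> pd.DataFrame:
    """Sign and CI-exclusion of the complexity slope, per response."""
    rows = []
    for name, fit in fits.items():
        if "segments" not in fit.coefficients.index:
            continue
        row = fit.coefficients.loc["segments"]
        rows.append(
            {
                "response": name,
                "slope_median": row["median"],
                "ci_low": row["ci_low"],
                "ci_high": row["ci_high"],
                "effect_present": bool(row["effect_present"]),
                "direction": "+" if row["median"] > 0 else "-",
            }
        )
    return pd.DataFrame(rows)


def report(trials_all, analyzed, fits, quadrants, d_px: float, panel=None) -> str:
    """Human-readable run summary (accuracy, effects, quadrants, spread of participants)."""
    lines = ["# Maintenance-scanpath analysis report", ""]
    acc = trials_all.groupby("segments")["correct"].mean()
    lines.append("## Accuracy by number of segments\n")
    lines.append(acc.rename("accuracy").reset_index().to_string(index=False))
    lines.append(f"\noverall accuracy: {100 * trials_all['correct'].mean():.2f}%")

    lines.append("\n## Effect of complexity (posterior slope on segments)\n")
    table = effect_direction_table(fits)
    lines.append(table.to_string(index=False))

    lines.append(f"\n## Spread x recurrence quadrants (threshold d = {d_px:.1f} px)\n")
    for key, val in quadrants.to_dict().items():
        lines.append(f"- {key}: {val}")

    if "recurrence" in fits:
        idiff = individual_differences(fits["recurrence"], analyzed)
        lines.append("\n## Individual differences (recurrence model)\n")
        lines.append(f"- random-intercept SD: {idiff.sd_intercept}")
        if idiff.sd_slope:
            lines.append(f"- random-slope SD: {idiff.sd_slope}")
        if idiff.cor_intercept_slope:
            lines.append(f"- intercept-slope correlation: {idiff.cor_intercept_slope}")
        if idiff.response_range:
            lo, hi = idiff.response_range
            lines.append(f"- participant mean recurrence range: {lo:.2f}% - {hi:.2f}%")

    if panel is not None:
        lines.append("\n## Participant-level correlations (Holm-adjusted)\n")
        lines.append(panel.r.round(2).to_string())
        sig = panel.significant_pairs()
        lines.append(
            f"\nsignificant at adjusted p < {panel.alpha}: "
            + (", ".join(f"{a}-{b}" for a, b in sig) if sig else "none")
        )
    return "\n".join(lines) + "\n"


def make_figures(trials_all, analyzed, fits, d_px: float, out: Path) -> dict:
    """Accuracy-by-complexity, slope posteriors, and spread-recurrence plots."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outputs = {}

    fig, ax = plt.subplots(figsize=(5, 4))
    for dvn, grp in trials_all.groupby("dvn"):
        acc = grp.groupby("segments")["correct"].mean()
        ax.plot(acc.index, 100 * acc.values, marker="o", label=f"DVN={dvn}")
    ax.set_xlabel("number of segments")
    ax.set_ylabel("accuracy (%)")
    ax.set_xticks(sorted(trials_all["segments"].unique()))
    if trials_all["dvn"].nunique() > 1:
        ax.legend()
    fig.tight_layout()
    p = out / "fig_accuracy.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    outputs["fig_accuracy"] = p

    table = effect_direction_table(fits)
    if len(table):
        fig, ax = plt.subplots(figsize=(5, 4))
        ypos = np.arange(len(table))
        ax.errorbar(
            table["slope_median"],
            ypos,
            xerr=[
                table["slope_median"] - table["ci_low"],
                table["ci_high"] - table["slope_median"],
            ],
            fmt="o",
            capsize=4,
        )
        ax.axvline(0.0, color="k", lw=0.8, ls="--")
        ax.set_yticks(ypos)
        ax.set_yticklabels(table["response"])
        ax.set_xlabel("posterior slope of segments (95% CI)")
        fig.tight_layout()
        p = out / "fig_effects.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        outputs["fig_effects"] = p

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(analyzed["spread_px"], analyzed["recurrence"], s=8, alpha=0.4)
    ax.axvline(d_px, color="k", ls="--", lw=0.8)
    ax.axhline(50.0, color="gray", ls=":", lw=0.8)
    ax.set_xlim(0, 400)
    ax.set_xlabel("spread of fixations (px)")
    ax.set_ylabel("recurrence (%)")
    fig.tight_layout()
    p = out / "fig_spread_recurrence.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    outputs["fig_spread_recurrence"] = p
    return outputs
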