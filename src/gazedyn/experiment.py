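"""Full-experiment simulation: balanced designs, responses, trial tables.

Emulates the study design the analysis assumes: each participant completes
120 maintenance trials crossing four complexity levels (30 each), optionally
crossed with a two-level dynamic-visual-noise factor (15 per cell). Each
trial carries a freshly generated pattern, a mechanism-driven scanpath, a
probe response whose accuracy declines with complexity, and a 1-7
maintainability rating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scanpaths import MechanismParams, Scanpath, simulate_scanpath
from .stimuli import StimulusPattern, generate_pattern

FIXATION_COLUMNS = [
    "participant",
    "trial",
    "fixation_index",
    "x_px",
    "y_px",
    "onset_ms",
    "duration_ms",
]


@dataclass
class AccuracyModel:
    """Log-odds model of probe accuracy and a latent model of ratings.

    ``P(correct) = logistic(intercept + slope * k)``; the rating is a latent
    normal ``rating_intercept + rating_slope * k + noise`` rounded and
    clipped to the 1-7 scale, so ratings fall stochastically with complexity.
    """

    intercept: float = 3.2
    slope: float = -0.45
    rating_intercept: float = 5.4
    rating_slope: float = -0.6
    rating_sd: float = 1.5

    def p_correct(self, k: int) -> float:
        return 1.0 / (1.0 + np.exp(-(self.intercept + self.slope * k)))


def simulate_response(
    pattern: StimulusPattern,
    k: int,
    accuracy_model: AccuracyModel,
    rng: np.random.Generator,
) -> tuple[str, bool, int]:
    """Simulate (answer, correct, rating) for one probe trial."""
    truth = "black" if pattern.probe[1] else "white"
    correct = bool(rng.random() < accuracy_model.p_correct(k))
    answer = truth if correct else ("white" if truth == "black" else "black")
    latent = (
        accuracy_model.rating_intercept
        + accuracy_model.rating_slope * k
        + rng.normal(0.0, accuracy_model.rating_sd)
    )
    rating = int(np.clip(round(latent), 1, 7))
    return answer, correct, rating


@dataclass
class ExperimentDesign:
    """Balanced within-participant design.

    With ``dvn_factor`` (the Experiment-B layout) trials split evenly over
    segments x DVN cells; without it (Experiment A) over segment levels only.
    """

    n_participants: int = 20
    trials_per_participant: int = 120
    segment_levels: tuple[int, ...] = (1, 2, 3, 4)
    dvn_factor: bool = False
    balanced: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("need at least one participant")
        n_cells = len(self.segment_levels) * (2 if self.dvn_factor else 1)
        if self.balanced and self.trials_per_participant % n_cells != 0:
            raise ValueError(
                f"{self.trials_per_participant} trials do not divide evenly over "
                f"{n_cells} design cells"
            )

    def trial_conditions(self, rng: np.random.Generator) -> pd.DataFrame:
        """Shuffled (segments, dvn) condition list for one participant."""
        dvn_levels = (False, True) if self.dvn_factor else (False,)
        n_cells = len(self.segment_levels) * len(dvn_levels)
        per_cell = self.trials_per_participant // n_cells
        if per_cell == 0:
            raise ValueError("design cells of size 0")
        rows = [
            {"segments": k, "dvn": d}
            for k in self.segment_levels
            for d in dvn_levels
            for _ in range(per_cell)
        ]
        df = pd.DataFrame(rows)
        return df.sample(frac=1.0, random_state=rng).reset_index(drop=True)


@dataclass
class ParticipantEffects:
    """Per-participant heterogeneity in maintenance style.

    ``anchor_sd_multiplier`` is log-normal (median 1); ``weight_shift`` moves
    the logit of the restriction weight. Together they emulate the large
    between-participant variance in refixation behaviour.
    """

    anchor_sd_multiplier: float = 1.0
    weight_shift: float = 0.0


@dataclass
class ExperimentData:
    """Simulated experiment: trial metadata, fixations, participant summary.

    ``participants`` carries one row per participant: the drawn mechanism
    heterogeneity and a visuo-spatial short-term-memory span score (VPT),
    drawn independently of the gaze mechanism — span and gaze dynamics are
    unrelated in this population.
    """

    trials: pd.DataFrame
    fixations: pd.DataFrame
    participants: pd.DataFrame
    seed: int

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "trials": directory / "trials.csv",
            "fixations": directory / "fixations.csv",
            "participants": directory / "participants.csv",
        }
        self.trials.to_csv(paths["trials"], index=False)
        self.fixations.to_csv(paths["fixations"], index=False)
        self.participants.to_csv(paths["participants"], index=False)
        return paths


def draw_participant_effects(
    rng: np.random.Generator,
    anchor_sd_log_sd: float = 0.5,
    weight_shift_sd: float = 0.8,
) -> ParticipantEffects:
    return ParticipantEffects(
        anchor_sd_multiplier=float(rng.lognormal(0.0, anchor_sd_log_sd)),
        weight_shift=float(rng.normal(0.0, weight_shift_sd)),
    )


def generate_experiment(
    design: ExperimentDesign,
    params: MechanismParams | None = None,
    accuracy_model: AccuracyModel | None = None,
    rng: np.random.Generator | None = None,
    heterogeneity: bool = True,
) -> ExperimentData:
    """Simulate the full experiment for every participant in ``design``."""
    params = params or MechanismParams()
    accuracy_model = accuracy_model or AccuracyModel()
    rng = rng if rng is not None else np.random.default_rng(design.seed)

    trial_rows = []
    fix_frames = []
    participant_rows = []
    for p in range(design.n_participants):
        effects = (
            draw_participant_effects(rng) if heterogeneity else ParticipantEffects()
        )
        # VPT span: correctly reproduced patterns, clipped to the test's range
        vpt = int(np.clip(round(rng.normal(8.0, 2.5)), 2, 15))
        participant_rows.append(
            {
                "participant": p,
                "anchor_sd_multiplier": effects.anchor_sd_multiplier,
                "weight_shift": effects.weight_shift,
                "vpt_score": vpt,
            }
        )
        conditions = design.trial_conditions(rng)
        for t, cond in conditions.iterrows():
            k = int(cond["segments"])
            pattern = generate_pattern(k, rng)
            path = simulate_scanpath(
                pattern,
                params,
                rng,
                anchor_sd_multiplier=effects.anchor_sd_multiplier,
                restriction_weight_shift=effects.weight_shift,
            )
            answer, correct, rating = simulate_response(pattern, k, accuracy_model, rng)
            trial_rows.append(
                {
                    "participant": p,
                    "trial": t,
                    "segments": k,
                    "dvn": bool(cond["dvn"]),
                    "answer": answer,
                    "correct": correct,
                    "rating": rating,
                    "n_fixations_raw": len(path),
                    "stimulus_dispersion_px": pattern.pixel_dispersion(),
                }
            )
            f = path.to_frame()
            f.insert(0, "trial", t)
            f.insert(0, "participant", p)
            fix_frames.append(f)

    trials = pd.DataFrame(trial_rows)
    fixations = pd.concat(fix_frames, ignore_index=True)[FIXATION_COLUMNS]
    return ExperimentData(
        trials=trials,
        fixations=fixations,
        participants=pd.DataFrame(participant_rows),
        seed=design.seed,
    )
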