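"""Fixation filtering, fixation spread, and trial-level exclusions.

Filters mirror standard eye-tracking practice for this task: drop fixations
outside the screen, shorter than 100 ms, or longer than 5 s (bounds
inclusive on the kept side). The spread of fixations is the median Euclidean
distance of a trial's fixations from their unweighted centroid. Trials are
analysed only when the probe answer was correct and the maintainability
rating was at least 3 of 7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import SCREEN_PX

#: rule precedence for the filter report: a fixation failing several rules is
#: counted once, under the first rule in this order.
FILTER_RULES = ("off_screen", "too_short", "too_long")


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    reasons: dict[str, int]

    @property
    def proportion_kept(self) -> float:
        return self.n_kept / self.n_input if self.n_input else 1.0

    def __post_init__(self) -> None:
        if self.n_kept + sum(self.reasons.values()) != self.n_input:
            raise ValueError("filter report counts do not add up")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "proportion_kept": self.proportion_kept,
            "reasons": dict(self.reasons),
        }


def filter_fixations(
    fixations: pd.DataFrame,
    screen: tuple[int, int] = SCREEN_PX,
    min_ms: float = 100.0,
    max_ms: float = 5000.0,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the three fixation filters; order of rows is preserved.

    Expects columns ``x_px``, ``y_px``, ``duration_ms``. Kept fixations
    satisfy ``0 <= x < width``, ``0 <= y < height`` and
    ``min_ms <= duration <= max_ms``.
    """
    if screen[0] <= 0 or screen[1] <= 0:
        raise ValueError("screen dimensions must be positive")
    x = fixations["x_px"].to_numpy(dtype=float)
    y = fixations["y_px"].to_numpy(dtype=float)
    dur = fixations["duration_ms"].to_numpy(dtype=float)

    off = (x < 0) | (x >= screen[0]) | (y < 0) | (y >= screen[1])
    short = dur < min_ms
    long_ = dur > max_ms

    reasons = {
        "off_screen": int(off.sum()),
        "too_short": int((short & ~off).sum()),
        "too_long": int((long_ & ~off & ~short).sum()),
    }
    keep = ~(off | short | long_)
    kept = fixations.loc[keep].copy()
    report = FilterReport(n_input=len(fixations), n_kept=len(kept), reasons=reasons)
    return kept, report


@dataclass
class SpreadResult:
    centroid: tuple[float, float]
    spread: float
    n_fixations: int


def spread(fixations: pd.DataFrame | np.ndarray) -> SpreadResult:
    """Median distance of fixations from their centroid.

    Accepts a fixation DataFrame (``x_px``/``y_px`` columns) or an (n, 2)
    position array. Raises on empty input.
    """
    if isinstance(fixations, pd.DataFrame):
        pos = fixations[["x_px", "y_px"]].to_numpy(dtype=float)
    else:
        pos = np.asarray(fixations, dtype=float)
    if pos.size == 0:
        raise ValueError("spread undefined for an empty scanpath")
    centroid = pos.mean(axis=0)
    dists = np.sqrt(((pos - centroid) ** 2).sum(axis=1))
    return SpreadResult(
        centroid=(float(centroid[0]), float(centroid[1])),
        spread=float(np.median(dists)),
        n_fixations=len(pos),
    )


def spread_table(fixations: pd.DataFrame) -> pd.DataFrame:
    """Per-trial spread for a long-format fixation table."""
    rows = []
    for (p, t), grp in fixations.groupby(["participant", "trial"], sort=True):
        s = spread(grp)
        rows.append(
            {
                "participant": p,
                "trial": t,
                "spread_px": s.spread,
                "centroid_x": s.centroid[0],
                "centroid_y": s.centroid[1],
                "n_fixations": s.n_fixations,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ExclusionReport:
    n_input: int
    n_kept: int
    n_wrong_answer: int
    n_low_rating: int
    by_segment: pd.DataFrame = field(repr=False)

    @property
    def proportion_excluded(self) -> float:
        return 1.0 - self.n_kept / self.n_input if self.n_input else 0.0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_wrong_answer": self.n_wrong_answer,
            "n_low_rating": self.n_low_rating,
            "proportion_excluded": self.proportion_excluded,
            "by_segment": self.by_segment.to_dict(orient="records"),
        }


def exclude_trials(
    trials: pd.DataFrame, min_rating: int = 3
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Keep trials that were answered correctly and rated >= ``min_rating``.

    Wrong answers are counted first; low ratings only among correct trials.
    The per-segment table reports exclusion proportions per complexity level.
    """
    for col in ("correct", "rating"):
        if col not in trials.columns:
            raise KeyError(f"trial table lacks required column {col!r}")
    bad = trials["correct"].isna() | trials["rating"].isna()
    if bad.any():
        idx = trials.index[bad][0]
        raise ValueError(f"trial at index {idx} has missing correctness or rating")

    correct = trials["correct"].astype(bool)
    low = trials["rating"] < min_rating
    keep = correct & ~low
    by_segment = (
        trials.assign(excluded=~keep)
        .groupby("segments")["excluded"]
        .mean()
        .rename("proportion_excluded")
        .reset_index()
        if "segments" in trials.columns
        else pd.DataFrame(columns=["segments", "proportion_excluded"])
    )
    report = ExclusionReport(
        n_input=len(trials),
        n_kept=int(keep.sum()),
        n_wrong_answer=int((~correct).sum()),
        n_low_rating=int((correct & low).sum()),
        by_segment=by_segment,
    )
    return trials.loc[keep].copy(), report
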