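"""Generative scanpath models for the 20-s maintenance phase.

Two candidate maintenance mechanisms produce refixations in imagery:

* **gaze restriction** — fixations cluster around a single anchor; the
  cluster dispersion grows with stimulus complexity (the restriction is
  progressively released as images get harder to hold);
* **reactivation of place-bound content** — fixations visit the imagined
  segment locations in turn, occasionally revisiting a segment already
  inspected to refresh its fading content.

A per-fixation mixture of the two lets complexity shift the balance between
them. These simulators generate the statistical structure the recurrence
analysis is designed to detect; they make no claim about saccade kinematics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
import pandas as pd

from .geometry import SCREEN_PX

Mechanism = Literal["restriction", "reactivation", "mixture"]


@dataclass
class Scanpath:
    """Ordered fixations of one trial: positions in px, times in ms."""

    x: np.ndarray
    y: np.ndarray
    onset_ms: np.ndarray
    duration_ms: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.onset_ms = np.asarray(self.onset_ms, dtype=float)
        self.duration_ms = np.asarray(self.duration_ms, dtype=float)
        n = len(self.x)
        if not (len(self.y) == len(self.onset_ms) == len(self.duration_ms) == n):
            raise ValueError("scanpath arrays must share one length")

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fixation_index": np.arange(len(self)),
                "x_px": self.x,
                "y_px": self.y,
                "onset_ms": self.onset_ms,
                "duration_ms": self.duration_ms,
            }
        )

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def default_mixture_weight(k: int) -> float:
    """Weight on the restriction process as a function of complexity ``k``.

    Logistic decline: simple images are held almost entirely by gaze
    restriction; complex ones increasingly require place-bound refixations.
    """
    return 1.0 / (1.0 + math.exp(-(2.0 - 0.8 * (k - 1))))


@dataclass
class MechanismParams:
    """Parameters of the generative maintenance-scanpath model.

    anchor_sd_px
        dispersion (per axis, px) of the restricted gaze cluster at k=1.
    restriction_release
        multiplicative growth of that dispersion per added segment (>1 means
        the restriction loosens as complexity rises).
    revisit_prob
        probability that a reactivation visit returns to an already-visited
        segment rather than moving on to a new one.
    fixation_rate_hz, duration_s
        mean fixations per second and maintenance duration.
    mixture_weight_fn
        complexity -> weight on the restriction process (per fixation).
    """

    mechanism: Mechanism = "mixture"
    anchor_sd_px: float = 45.0
    restriction_release: float = 1.35
    revisit_prob: float = 0.3
    fixation_rate_hz: float = 3.0
    duration_s: float = 20.0
    mixture_weight_fn: Callable[[int], float] = default_mixture_weight
    reactivation_jitter_px: float = 25.0
    anchor_jitter_px: float = 30.0
    #: mean fixations per reactivation visit; 1.0 makes visits single
    #: fixations, so reactivation recurrences arise only from revisits whose
    #: lag is spread over the whole past — temporally neutral like the
    #: restriction cluster, leaving CORM flat across complexity
    fixations_per_visit_mean: float = 1.0
    #: fraction of revisits drawn in proportion to a segment's accumulated
    #: fixation count (memory-trace strength) instead of uniformly over
    #: visited segments; the default blend keeps the revisit-lag
    #: distribution flat so CORM carries no complexity trend by construction
    revisit_trace_weight: float = 0.2
    saccade_gap_ms: float = 30.0
    duration_median_ms: float = 300.0
    duration_log_sd: float = 0.35

    def __post_init__(self) -> None:
        if not 0.0 <= self.revisit_prob <= 1.0:
            raise ValueError("revisit_prob must be in [0, 1]")
        if self.anchor_sd_px <= 0 or self.reactivation_jitter_px <= 0:
            raise ValueError("dispersions must be positive")
        if self.duration_s <= 0 or self.fixation_rate_hz <= 0:
            raise ValueError("duration and fixation rate must be positive")

    def dispersion_px(self, k: int) -> float:
        """Cluster dispersion at complexity ``k``."""
        return self.anchor_sd_px * self.restriction_release ** (k - 1)


class _ReactivationState:
    """Visit process over segment centroids with occasional revisits."""

    def __init__(self, centroids: np.ndarray, params: MechanismParams, rng: np.random.Generator):
        self.centroids = centroids
        self.params = params
        self.rng = rng
        self.counts = np.zeros(len(centroids))
        self.current = int(rng.integers(len(centroids)))
        self.counts[self.current] += 1
        self.left_in_visit = self._visit_length()

    def _visit_length(self) -> int:
        return 1 + int(self.rng.poisson(max(self.params.fixations_per_visit_mean - 1.0, 0.0)))

    def _next_segment(self) -> int:
        # revisits target visited segments (current included); a small share
        # is drawn in proportion to trace strength so the lag distribution of
        # recurrent pairs stays flat across complexity levels
        visited = np.nonzero(self.counts)[0]
        unvisited = np.nonzero(self.counts == 0)[0]
        if len(unvisited) == 0 or self.rng.random() < self.params.revisit_prob:
            if self.rng.random() < self.params.revisit_trace_weight:
                w = self.counts[visited] / self.counts[visited].sum()
                return int(self.rng.choice(visited, p=w))
            return int(self.rng.choice(visited))
        return int(self.rng.choice(unvisited))

    def draw(self) -> np.ndarray:
        if self.left_in_visit == 0:
            self.current = self._next_segment()
            self.counts[self.current] += 1
            self.left_in_visit = self._visit_length()
        self.left_in_visit -= 1
        jitter = self.rng.normal(0.0, self.params.reactivation_jitter_px, size=2)
        return self.centroids[self.current] + jitter


def _fixation_timing(
    n: int, params: MechanismParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Durations (truncated log-normal) and cumulative onsets."""
    mu = math.log(params.duration_median_ms)
    durations = np.clip(
        rng.lognormal(mu, params.duration_log_sd, size=n), 100.0, 5000.0
    )
    onsets = np.concatenate([[0.0], np.cumsum(durations[:-1] + params.saccade_gap_ms)])
    return durations, onsets


def simulate_scanpath(
    pattern,
    params: MechanismParams,
    rng: np.random.Generator,
    anchor_sd_multiplier: float = 1.0,
    restriction_weight_shift: float = 0.0,
    screen_px: tuple[int, int] = SCREEN_PX,
) -> Scanpath:
    """Simulate one maintenance scanpath for ``pattern``.

    ``anchor_sd_multiplier`` and ``restriction_weight_shift`` (a shift on the
    logit of the restriction weight) carry per-participant heterogeneity.
    """
    expected = params.fixation_rate_hz * params.duration_s
    if expected < 3:
        raise ValueError(
            "expected fixation count below 3; recurrence analysis is undefined "
            "for such short scanpaths"
        )
    n = max(3, int(rng.poisson(expected)))

    k = pattern.k
    sd = params.dispersion_px(k) * anchor_sd_multiplier
    anchor = np.asarray(pattern.centroid_px()) + rng.normal(
        0.0, params.anchor_jitter_px, size=2
    )

    w = params.mixture_weight_fn(k)
    if params.mechanism == "restriction":
        w = 1.0
    elif params.mechanism == "reactivation":
        w = 0.0
    else:
        logit = math.log(w / (1 - w)) if 0 < w < 1 else (30.0 if w >= 1 else -30.0)
        w = 1.0 / (1.0 + math.exp(-(logit + restriction_weight_shift)))

    react = _ReactivationState(pattern.segment_centroids_px(), params, rng)
    pos = np.empty((n, 2))
    use_restriction = rng.random(n) < w
    for i in range(n):
        if use_restriction[i]:
            pos[i] = anchor + rng.normal(0.0, sd, size=2)
        else:
            pos[i] = react.draw()
    pos[:, 0] = np.clip(pos[:, 0], 0.0, screen_px[0] - 1.0)
    pos[:, 1] = np.clip(pos[:, 1], 0.0, screen_px[1] - 1.0)

    durations, onsets = _fixation_timing(n, params, rng)
    return Scanpath(x=pos[:, 0], y=pos[:, 1], onset_ms=onsets, duration_ms=durations)
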