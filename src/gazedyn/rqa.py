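"""Recurrence quantification analysis (RQA) of a single scanpath.

Two fixations are *recurrent* when they fall within a distance threshold
``d`` of each other (inclusive), conventionally the foveal extent — here
2 degrees of visual angle (~104 px at the study geometry) by default. Only
the strictly upper triangle of the recurrence matrix is used (``i < j``,
1-based); the main diagonal is never counted.

Measures
--------
recurrence
    ``100 * 2R / (N(N-1))`` — percentage of recurrent fixation pairs.
determinism
    percentage of recurrent points lying on diagonal lines of length >= L
    in the upper triangle; indexes repeated fixation sub-sequences.
corm
    ``100 * sum((j - i) * r_ij) / ((N - 1) R)`` — centre of recurrence
    mass; low values mean refixations follow soon after the original
    fixation, high values mean they are separated by many intervening
    fixations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import degrees_to_pixels
from .scanpaths import Scanpath

DEFAULT_THRESHOLD_DEG = 2.0


def default_threshold_px() -> float:
    """Default recurrence threshold: 2 degrees of visual angle in pixels."""
    return degrees_to_pixels(DEFAULT_THRESHOLD_DEG)


def _positions(scanpath) -> np.ndarray:
    if isinstance(scanpath, Scanpath):
        return scanpath.positions()
    if isinstance(scanpath, pd.DataFrame):
        return scanpath[["x_px", "y_px"]].to_numpy(dtype=float)
    return np.asarray(scanpath, dtype=float)


@dataclass
class RecurrenceMatrix:
    """Strictly upper-triangular recurrence structure of one scanpath."""

    r: np.ndarray  # (N, N) bool, nonzero only for i < j
    N: int
    d: float

    @property
    def R(self) -> int:
        return int(self.r.sum())

    @property
    def n_pairs(self) -> int:
        return self.N * (self.N - 1) // 2


def recurrence_matrix(scanpath, d: float) -> RecurrenceMatrix:
    """Build the recurrence matrix with Euclidean distance, threshold <= d."""
    if d <= 0:
        raise ValueError("threshold d must be positive")
    pos = _positions(scanpath)
    n = len(pos)
    if n < 2:
        raise ValueError("recurrence requires at least 2 fixations")
    diff = pos[:, None, :] - pos[None, :, :]
    close = (diff**2).sum(axis=2) <= d * d
    r = np.triu(close, k=1)
    return RecurrenceMatrix(r=r, N=n, d=float(d))


def recurrence_rate(m: RecurrenceMatrix) -> float:
    return 100.0 * m.R / m.n_pairs


def _diagonal_line_points(r: np.ndarray, min_line: int) -> int:
    """Recurrent points on diagonal runs of length >= min_line (upper triangle)."""
    n = r.shape[0]
    total = 0
    for offset in range(1, n):
        diag = np.diag(r, k=offset)
        if diag.size == 0 or not diag.any():
            continue
        # run lengths of consecutive True values
        padded = np.concatenate([[0], diag.astype(int), [0]])
        changes = np.diff(padded)
        starts = np.nonzero(changes == 1)[0]
        ends = np.nonzero(changes == -1)[0]
        lengths = ends - starts
        total += int(lengths[lengths >= min_line].sum())
    return total


def determinism(m: RecurrenceMatrix, min_line: int = 2) -> float:
    """Percent of recurrent points on diagonal lines; 0 when R = 0."""
    if min_line < 2:
        raise ValueError("minimum line length must be >= 2")
    if m.R == 0:
        return 0.0
    return 100.0 * _diagonal_line_points(m.r, min_line) / m.R


def corm(m: RecurrenceMatrix) -> float:
    """Centre of recurrence mass; 0 when R = 0."""
    if m.R == 0:
        return 0.0
    i, j = np.nonzero(m.r)
    return 100.0 * float((j - i).sum()) / ((m.N - 1) * m.R)


@dataclass
class RQAMeasures:
    recurrence: float
    determinism: float
    corm: float
    N: int
    R: int
    d: float
    min_line: int
    degenerate: bool  # True when R = 0 and determinism/corm default to 0

    def to_dict(self) -> dict:
        return {
            "recurrence": self.recurrence,
            "determinism": self.determinism,
            "corm": self.corm,
            "N": self.N,
            "R": self.R,
            "d": self.d,
            "min_line": self.min_line,
            "degenerate": self.degenerate,
        }


def rqa(scanpath, d: float | None = None, min_line: int = 2) -> RQAMeasures:
    """Compute recurrence, determinism and CORM for one scanpath."""
    d = default_threshold_px() if d is None else d
    m = recurrence_matrix(scanpath, d)
    return RQAMeasures(
        recurrence=recurrence_rate(m),
        determinism=determinism(m, min_line),
        corm=corm(m),
        N=m.N,
        R=m.R,
        d=m.d,
        min_line=min_line,
        degenerate=m.R == 0,
    )


def rqa_table(
    fixations: pd.DataFrame, d: float | None = None, min_line: int = 2
) -> pd.DataFrame:
    """Per-trial RQA measures for a long-format fixation table.

    Trials with fewer than 2 fixations are dropped (RQA undefined).
    """
    d = default_threshold_px() if d is None else d
    rows = []
    for (p, t), grp in fixations.groupby(["participant", "trial"], sort=True):
        if len(grp) < 2:
            continue
        meas = rqa(grp, d=d, min_line=min_line)
        row = {"participant": p, "trial": t}
        row.update(meas.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def threshold_sweep(
    fixations: pd.DataFrame,
    thresholds_px: list[float],
    min_line: int = 2,
) -> pd.DataFrame:
    """Recompute per-trial RQA across candidate thresholds.

    Sensitivity utility: the threshold is a convention (foveal extent), so
    reports should show how the measures move as it varies.
    """
    frames = []
    for d in thresholds_px:
        tab = rqa_table(fixations, d=d, min_line=min_line)
        tab["threshold_px"] = d
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
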