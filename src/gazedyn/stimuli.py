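"""Pattern stimuli: black straight segments on a 4 x 5 grid.

A stimulus of complexity ``k`` is a set of ``k`` straight segments (horizontal
or vertical contiguous runs of 1-4 filled cells) placed on the grid. Segments
may touch side-on but must not overlap and must not line up into a single
longer run, so the complexity remains recoverable from the occupancy grid
alone: ``k`` equals the minimum number of straight runs needed to cover the
black cells (four black cells in a row count as one segment, not four).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    BRACKET_GAP,
    BRACKET_W,
    CELL_H,
    CELL_W,
    GRID_COLS,
    GRID_ROWS,
    Rect,
    bracket_rects,
    cell_rect,
    stimulus_bounding_box,
)

Cell = tuple[int, int]  # (row, col)

MAX_SEGMENT_CELLS = 4


@dataclass
class StimulusPattern:
    """A grid pattern of ``k`` straight segments plus a probe location."""

    grid: np.ndarray  # (GRID_ROWS, GRID_COLS) bool
    k: int
    segments: list[list[Cell]]
    probe: tuple[Cell, bool]  # (cell, on_black)
    cell_size: tuple[int, int] = (CELL_W, CELL_H)
    bracket_width: int = BRACKET_W

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.shape != (GRID_ROWS, GRID_COLS):
            raise ValueError("grid must be 5 rows x 4 columns")

    @property
    def n_black(self) -> int:
        return int(self.grid.sum())

    def black_cell_centers_px(self) -> np.ndarray:
        """(n_black, 2) array of (x, y) pixel centres of filled cells."""
        rows, cols = np.nonzero(self.grid)
        return np.array([cell_rect(r, c).center for r, c in zip(rows, cols)])

    def centroid_px(self) -> tuple[float, float]:
        centers = self.black_cell_centers_px()
        return (float(centers[:, 0].mean()), float(centers[:, 1].mean()))

    def segment_centroids_px(self) -> np.ndarray:
        """(k, 2) array of pixel centroids, one per placed segment."""
        out = []
        for seg in self.segments:
            pts = np.array([cell_rect(r, c).center for r, c in seg])
            out.append(pts.mean(axis=0))
        return np.array(out)

    def pixel_dispersion(self) -> float:
        """RMS distance of black-cell centres from their centroid (px).

        Summary of how spread out the stimulus itself is; used as an optional
        covariate to probe the looking-at-nothing confound.
        """
        centers = self.black_cell_centers_px()
        d = centers - centers.mean(axis=0)
        return float(np.sqrt((d**2).sum(axis=1).mean()))


def _candidate_runs(cells: frozenset[Cell]) -> list[frozenset[Cell]]:
    """All straight contiguous runs (length >= 1) contained in ``cells``."""
    runs: set[frozenset[Cell]] = set()
    for r, c in cells:
        for dr, dc in ((0, 1), (1, 0)):
            run = []
            rr, cc = r, c
            while (rr, cc) in cells:
                run.append((rr, cc))
                runs.add(frozenset(run))
                rr += dr
                cc += dc
    return sorted(runs, key=len, reverse=True)


def segment_count(grid: np.ndarray) -> int:
    """Minimum number of straight runs covering all black cells.

    Exact branch-and-bound: repeatedly pick the first uncovered cell and try
    every candidate run through it, longest first. The grid has at most 20
    cells so the search is trivial.
    """
    grid = np.asarray(grid, dtype=bool)
    cells = frozenset((int(r), int(c)) for r, c in zip(*np.nonzero(grid)))
    if not cells:
        return 0
    runs = _candidate_runs(cells)
    best = len(cells)  # singletons always work

    order = sorted(cells)

    def search(covered: frozenset[Cell], used: int) -> None:
        nonlocal best
        if used >= best:
            return
        remaining = [c for c in order if c not in covered]
        if not remaining:
            best = used
            return
        target = remaining[0]
        for run in runs:
            if target in run:
                search(covered | run, used + 1)

    search(frozenset(), 0)
    return best


def _place_segment(
    occupied: set[Cell], rng: np.random.Generator
) -> list[Cell] | None:
    """Sample one straight segment avoiding overlap with ``occupied``."""
    horizontal = bool(rng.integers(2))
    length = int(rng.integers(1, MAX_SEGMENT_CELLS + 1))
    if horizontal:
        max_c = GRID_COLS - length
        if max_c < 0:
            return None
        r = int(rng.integers(GRID_ROWS))
        c = int(rng.integers(max_c + 1))
        seg = [(r, c + i) for i in range(length)]
    else:
        max_r = GRID_ROWS - length
        if max_r < 0:
            return None
        r = int(rng.integers(max_r + 1))
        c = int(rng.integers(GRID_COLS))
        seg = [(r + i, c) for i in range(length)]
    if any(cell in occupied for cell in seg):
        return None
    return seg


def generate_pattern(
    k: int, rng: np.random.Generator, max_attempts: int = 10_000
) -> StimulusPattern:
    """Rejection-sample a pattern whose recoverable segment count equals ``k``."""
    if not 1 <= k <= 4:
        raise ValueError("segment count k must be in 1..4")
    for _ in range(max_attempts):
        occupied: set[Cell] = set()
        segments: list[list[Cell]] = []
        ok = True
        for _ in range(k):
            seg = None
            for _ in range(50):
                seg = _place_segment(occupied, rng)
                if seg is not None:
                    break
            if seg is None:
                ok = False
                break
            segments.append(seg)
            occupied.update(seg)
        if not ok:
            continue
        grid = np.zeros((GRID_ROWS, GRID_COLS), dtype=bool)
        for r, c in occupied:
            grid[r, c] = True
        if segment_count(grid) != k:
            continue  # collinear-adjacent segments merged into a longer run
        probe = _sample_probe(grid, rng)
        return StimulusPattern(grid=grid, k=k, segments=segments, probe=probe)
    raise RuntimeError(f"no valid {k}-segment placement found in {max_attempts} attempts")


def _sample_probe(grid: np.ndarray, rng: np.random.Generator) -> tuple[Cell, bool]:
    """Probe cell uniform within colour; colour a fair coin when possible."""
    want_black = bool(rng.integers(2))
    rows, cols = np.nonzero(grid if want_black else ~grid)
    if len(rows) == 0:
        want_black = not want_black
        rows, cols = np.nonzero(grid if want_black else ~grid)
    i = int(rng.integers(len(rows)))
    cell = (int(rows[i]), int(cols[i]))
    return cell, bool(grid[cell])


@dataclass(frozen=True)
class PatternGeometry:
    """Pixel layout of one pattern: per-cell rectangles plus corner brackets."""

    cell_rects: dict[Cell, Rect]
    bracket_rects: list[Rect]
    bounding_box: Rect
    interior: Rect


def pattern_pixel_geometry(
    p: StimulusPattern, bracket_gap: int = BRACKET_GAP
) -> PatternGeometry:
    """Pixel rectangles of every grid cell and the four corner brackets.

    The 436 x 540 px interior is centred on the screen; the bracket gap is
    configurable because the exact bracket offset is a free layout parameter.
    """
    rects = {
        (r, c): cell_rect(r, c)
        for r in range(GRID_ROWS)
        for c in range(GRID_COLS)
    }
    interior = Rect(
        rects[(0, 0)].x, rects[(0, 0)].y, GRID_COLS * CELL_W, GRID_ROWS * CELL_H
    )
    return PatternGeometry(
        cell_rects=rects,
        bracket_rects=bracket_rects(bracket_gap),
        bounding_box=stimulus_bounding_box(bracket_gap),
        interior=interior,
    )
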