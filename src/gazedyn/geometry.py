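"""Screen and stimulus geometry.

The experiment displays a 4-column x 5-row grid of cells (109 x 108 px each)
centred on a 1920 x 1080 screen, framed by four corner brackets 12 px wide.
Viewing distance is ~76 cm from a 51 x 28 cm display, which fixes the
pixels-per-degree conversion used for the recurrence threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

SCREEN_PX: tuple[int, int] = (1920, 1080)
SCREEN_CM: tuple[float, float] = (51.0, 28.0)
VIEWING_DISTANCE_CM: float = 76.0

GRID_COLS: int = 4
GRID_ROWS: int = 5
CELL_W: int = 109
CELL_H: int = 108
BRACKET_W: int = 12
#: gap between grid interior and bracket, per side; 1 px reproduces the
#: printed 462 x 566 px stimulus bounding box.
BRACKET_GAP: int = 1


def degrees_to_pixels(
    deg: float,
    viewing_distance_cm: float = VIEWING_DISTANCE_CM,
    screen_cm: tuple[float, float] = SCREEN_CM,
    screen_px: tuple[int, int] = SCREEN_PX,
) -> float:
    """Convert a visual angle to horizontal pixels.

    Uses the full trigonometric screen angle (no small-angle shortcut):
    the screen subtends ``2*atan(w/2 / dist)`` degrees over ``screen_px[0]``
    pixels, and the conversion is linear in that ratio.
    """
    if viewing_distance_cm <= 0:
        raise ValueError("viewing distance must be positive")
    if screen_cm[0] <= 0 or screen_px[0] <= 0:
        raise ValueError("screen dimensions must be positive")
    full_angle_deg = 2.0 * math.degrees(
        math.atan((screen_cm[0] / 2.0) / viewing_distance_cm)
    )
    return deg * screen_px[0] / full_angle_deg


@dataclass(frozen=True)
class Rect:
    """Axis-aligned pixel rectangle, origin top-left."""

    x: float
    y: float
    w: float
    h: float

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)


def grid_origin(screen_px: tuple[int, int] = SCREEN_PX) -> tuple[float, float]:
    """Top-left pixel of the grid interior, centred on the screen."""
    interior_w = GRID_COLS * CELL_W
    interior_h = GRID_ROWS * CELL_H
    return ((screen_px[0] - interior_w) / 2.0, (screen_px[1] - interior_h) / 2.0)


def cell_rect(row: int, col: int, screen_px: tuple[int, int] = SCREEN_PX) -> Rect:
    """Pixel rectangle of grid cell (row, col); row 0 is the top row."""
    if not (0 <= row < GRID_ROWS and 0 <= col < GRID_COLS):
        raise ValueError(f"cell ({row}, {col}) outside the {GRID_ROWS}x{GRID_COLS} grid")
    ox, oy = grid_origin(screen_px)
    return Rect(ox + col * CELL_W, oy + row * CELL_H, CELL_W, CELL_H)


def stimulus_bounding_box(
    bracket_gap: int = BRACKET_GAP, screen_px: tuple[int, int] = SCREEN_PX
) -> Rect:
    """Bounding box of grid plus corner brackets (462 x 566 px at gap 1)."""
    ox, oy = grid_origin(screen_px)
    margin = BRACKET_W + bracket_gap
    return Rect(
        ox - margin,
        oy - margin,
        GRID_COLS * CELL_W + 2 * margin,
        GRID_ROWS * CELL_H + 2 * margin,
    )


def bracket_rects(
    bracket_gap: int = BRACKET_GAP,
    arm_len: int = 40,
    screen_px: tuple[int, int] = SCREEN_PX,
) -> list[Rect]:
    """Rectangles forming the four corner brackets (two arms per corner)."""
    bb = stimulus_bounding_box(bracket_gap, screen_px)
    w = BRACKET_W
    rects = []
    for cx, sx in ((bb.x, 1), (bb.x + bb.w - w, -1)):
        for cy, sy in ((bb.y, 1), (bb.y + bb.h - w, -1)):
            # vertical arm
            rects.append(Rect(cx, cy if sy > 0 else bb.y + bb.h - arm_len, w, arm_len))
            # horizontal arm
            rects.append(Rect(cx if sx > 0 else bb.x + bb.w - arm_len, cy, arm_len, w))
    return rects
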