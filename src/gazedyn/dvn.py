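"""Dynamic visual noise (DVN): flickering random black/white cell field.

The noise field matches the stimulus footprint: 116 x 142 cells of 4 x 4 px
(464 x 568 px). On a 144 Hz display the picture changes every 4th frame
(36 updates/s), and at a 50% change rate per second exactly
floor(0.5 * 16472 / 36) = 228 cells toggle per update.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

DVN_COLS: int = 116
DVN_ROWS: int = 142
DVN_CELL_PX: int = 4


@dataclass
class DVNSequence:
    frames: np.ndarray  # (n_frames, DVN_ROWS, DVN_COLS) bool
    updates_per_second: int
    toggles_per_update: int
    duration_s: float
    cell_px: int = DVN_CELL_PX

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_cells(self) -> int:
        return DVN_ROWS * DVN_COLS

    @property
    def frame_px(self) -> tuple[int, int]:
        """(width, height) of one rendered frame in pixels."""
        return (DVN_COLS * self.cell_px, DVN_ROWS * self.cell_px)

    def render_frame(self, i: int) -> np.ndarray:
        """Expand frame ``i`` to a (height, width) uint8 pixel image."""
        f = self.frames[i].astype(np.uint8) * 255
        return np.kron(f, np.ones((self.cell_px, self.cell_px), dtype=np.uint8))

    def export_png(self, directory: str | Path, limit: int | None = None) -> list[Path]:
        """Write frames as PNG images for inspection; returns written paths."""
        import matplotlib.image

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        n = self.n_frames if limit is None else min(limit, self.n_frames)
        for i in range(n):
            path = directory / f"dvn_{i:04d}.png"
            matplotlib.image.imsave(path, self.render_frame(i), cmap="gray", vmin=0, vmax=255)
            paths.append(path)
        return paths


def dvn_toggles_per_update(
    change_rate_per_s: float = 0.5,
    frame_rate_hz: int = 144,
    update_every: int = 4,
) -> int:
    """Cells toggled per noise update: floor(rate * n_cells / updates per s)."""
    updates_per_second = frame_rate_hz // update_every
    return int(np.floor(change_rate_per_s * DVN_ROWS * DVN_COLS / updates_per_second))


def generate_dvn(
    duration_s: float,
    rng: np.random.Generator,
    frame_rate_hz: int = 144,
    update_every: int = 4,
    change_rate_per_s: float = 0.5,
) -> DVNSequence:
    """Generate a DVN sequence, one boolean matrix per noise update.

    The first frame is an independent 50/50 fill; each subsequent frame
    toggles exactly ``toggles_per_update`` distinct cells chosen uniformly.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if frame_rate_hz % update_every != 0:
        raise ValueError("frame rate must be divisible by update_every")
    updates_per_second = frame_rate_hz // update_every
    toggles = dvn_toggles_per_update(change_rate_per_s, frame_rate_hz, update_every)
    n_frames = max(1, int(round(duration_s * updates_per_second)))
    n_cells = DVN_ROWS * DVN_COLS

    frames = np.empty((n_frames, DVN_ROWS, DVN_COLS), dtype=bool)
    frames[0] = rng.integers(0, 2, size=(DVN_ROWS, DVN_COLS), dtype=np.uint8).astype(bool)
    flat = frames[0].ravel().copy()
    for i in range(1, n_frames):
        idx = rng.choice(n_cells, size=toggles, replace=False)
        flat[idx] = ~flat[idx]
        frames[i] = flat.reshape(DVN_ROWS, DVN_COLS)
    return DVNSequence(
        frames=frames,
        updates_per_second=updates_per_second,
        toggles_per_update=toggles,
        duration_s=float(duration_s),
    )
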