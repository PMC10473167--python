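"""Reading and writing fixation reports and trial tables.

The interchange format is a delimited text file with a header, one row per
fixation, in screen pixel coordinates (origin top-left, 0-based, y growing
downward). Vendor exports with different column names are handled through a
``column_map`` from our canonical names to the file's names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .experiment import FIXATION_COLUMNS

REQUIRED_COLUMNS = ["participant", "trial", "x_px", "y_px", "onset_ms", "duration_ms"]
_NUMERIC = ["x_px", "y_px", "onset_ms", "duration_ms"]


@dataclass
class ParseReport:
    n_rows: int
    n_parsed: int
    rejected: pd.DataFrame = field(repr=False)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def read_fixation_report(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
) -> tuple[pd.DataFrame, ParseReport]:
    """Read a fixation report; returns (fixations, parse report).

    ``column_map`` maps canonical column names to the file's names, e.g.
    ``{"x_px": "CURRENT_FIX_X"}``. Rows whose numeric fields fail to parse
    are dropped and reported with their (0-based, header-exclusive) line
    numbers. Missing required columns and empty files raise.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if df.empty:
        raise ValueError(f"{path} contains no fixation rows")
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path} lacks required column {col!r}")

    parsed = df.copy()
    bad = pd.Series(False, index=df.index)
    for col in _NUMERIC:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad |= vals.isna()
        parsed[col] = vals
    rejected = df.loc[bad].copy()
    rejected.insert(0, "line", rejected.index.to_numpy())
    kept = parsed.loc[~bad].reset_index(drop=True)
    report = ParseReport(n_rows=len(df), n_parsed=len(kept), rejected=rejected)
    return kept, report


def write_fixations(fixations: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in FIXATION_COLUMNS if c in fixations.columns]
    fixations[cols].to_csv(path, index=False)
    return path


def attach_scanpaths(fixations: pd.DataFrame) -> dict[tuple, pd.DataFrame]:
    """Split a long fixation table into per-trial frames keyed by (participant, trial)."""
    return {
        key: grp.sort_values("onset_ms").reset_index(drop=True)
        for key, grp in fixations.groupby(["participant", "trial"], sort=True)
    }
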