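"""Post-fit summaries: individual differences, correlation panel, quadrants."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import PosteriorSummary


@dataclass
class IndividualDifferences:
    """Between-participant heterogeneity of a fitted hierarchical model."""

    sd_intercept: tuple[float, float, float]  # median, ci_low, ci_high
    sd_slope: tuple[float, float, float] | None
    cor_intercept_slope: tuple[float, float, float] | None
    participant_effects: pd.DataFrame
    response_range: tuple[float, float] | None  # min/max participant mean

    def to_dict(self) -> dict:
        return {
            "sd_intercept": self.sd_intercept,
            "sd_slope": self.sd_slope,
            "cor_intercept_slope": self.cor_intercept_slope,
            "response_range": self.response_range,
        }


def individual_differences(
    fit: PosteriorSummary, data: pd.DataFrame | None = None
) -> IndividualDifferences:
    """Random-effect SDs, intercept-slope correlation, per-participant effects.

    When the original per-trial ``data`` are supplied, also reports the range
    of participant-level mean responses (the min/max participant average).
    """
    re = fit.random_effects

    def row(name):
        if name not in re.index:
            return None
        r = re.loc[name]
        return (float(r["median"]), float(r["ci_low"]), float(r["ci_high"]))

    response_range = None
    if data is not None:
        means = data.groupby(fit.spec.group)[fit.spec.response].mean()
        response_range = (float(means.min()), float(means.max()))

    return IndividualDifferences(
        sd_intercept=row("sd_intercept"),
        sd_slope=row("sd_slope"),
        cor_intercept_slope=row("cor_intercept_slope"),
        participant_effects=fit.participant_effects,
        response_range=response_range,
    )


@dataclass
class CorrelationPanel:
    r: pd.DataFrame
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame
    flags: pd.DataFrame  # adjusted p < alpha
    alpha: float

    def significant_pairs(self) -> list[tuple[str, str]]:
        pairs = []
        cols = list(self.flags.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                if self.flags.loc[a, b]:
                    pairs.append((a, b))
        return pairs


def correlation_panel(
    subject_measures: pd.DataFrame,
    columns: list[str] | None = None,
    alpha: float = 0.01,
    method: str = "holm",
) -> CorrelationPanel:
    """Pairwise Pearson correlations across participants, Holm-adjusted.

    One row per participant, one column per measure (e.g. mean recurrence,
    determinism, CORM, imagery rating, VPT score). Flags mark pairs whose
    multiplicity-adjusted p-value is below ``alpha``.
    """
    df = subject_measures[columns] if columns is not None else subject_measures
    df = df.select_dtypes(include=[np.number])
    if len(df) < 4:
        raise ValueError("correlation panel needs at least 4 participants")
    cols = list(df.columns)
    m = len(cols)
    r = pd.DataFrame(np.eye(m), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((m, m)), index=cols, columns=cols)
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    pvals = []
    for i, j in pairs:
        rr, pp = stats.pearsonr(df[cols[i]], df[cols[j]])
        r.iloc[i, j] = r.iloc[j, i] = rr
        p.iloc[i, j] = p.iloc[j, i] = pp
        pvals.append(pp)
    adj = multipletests(pvals, method=method)[1] if pairs else np.array([])
    p_adj = pd.DataFrame(np.zeros((m, m)), index=cols, columns=cols)
    flags = pd.DataFrame(np.zeros((m, m), dtype=bool), index=cols, columns=cols)
    for (i, j), a in zip(pairs, adj):
        p_adj.iloc[i, j] = p_adj.iloc[j, i] = a
        flags.iloc[i, j] = flags.iloc[j, i] = a < alpha
    return CorrelationPanel(r=r, p_raw=p, p_adjusted=p_adj, flags=flags, alpha=alpha)


@dataclass
class QuadrantSummary:
    """Trial counts in the spread x recurrence quadrants.

    The diagnostic quadrant is high recurrence (above ``rec_cut`` %) together
    with high spread (above the recurrence threshold): gaze restriction
    leaves it empty, repeated reactivation of distant content populates it.
    """

    low_rec_low_spread: int
    low_rec_high_spread: int
    high_rec_low_spread: int
    high_rec_high_spread: int
    rec_cut: float
    spread_cut: float

    @property
    def upper_right_empty(self) -> bool:
        return self.high_rec_high_spread == 0

    def to_dict(self) -> dict:
        return {
            "low_rec_low_spread": self.low_rec_low_spread,
            "low_rec_high_spread": self.low_rec_high_spread,
            "high_rec_low_spread": self.high_rec_low_spread,
            "high_rec_high_spread": self.high_rec_high_spread,
            "rec_cut": self.rec_cut,
            "spread_cut": self.spread_cut,
            "upper_right_empty": self.upper_right_empty,
        }


def spread_recurrence_summary(
    trials: pd.DataFrame,
    rec_cut: float = 50.0,
    spread_cut: float | None = None,
) -> QuadrantSummary:
    """Count trials in the four quadrants of the spread-recurrence plane.

    ``spread_cut`` defaults to the recurrence threshold recorded in the
    per-trial table (column ``d``), mirroring the dashed threshold line of
    the spread-recurrence plot.
    """
    if spread_cut is None:
        if "d" not in trials.columns:
            raise ValueError("spread_cut not given and no 'd' column present")
        spread_cut = float(trials["d"].iloc[0])
    rec = trials["recurrence"].to_numpy(dtype=float)
    spr = trials["spread_px"].to_numpy(dtype=float)
    high_rec = rec > rec_cut
    high_spr = spr > spread_cut
    return QuadrantSummary(
        low_rec_low_spread=int((~high_rec & ~high_spr).sum()),
        low_rec_high_spread=int((~high_rec & high_spr).sum()),
        high_rec_low_spread=int((high_rec & ~high_spr).sum()),
        high_rec_high_spread=int((high_rec & high_spr).sum()),
        rec_cut=float(rec_cut),
        spread_cut=float(spread_cut),
    )
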