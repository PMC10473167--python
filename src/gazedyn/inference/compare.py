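"""Model comparison via PSIS-LOO expected log predictive density."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import PosteriorSummary


@dataclass
class ElpdComparison:
    """elpd difference (model A minus model B) and its standard error."""

    elpd_diff: float
    se_diff: float
    elpd_a: float
    elpd_b: float

    def favors_a(self, n_se: float = 2.0) -> bool:
        return self.elpd_diff > n_se * self.se_diff


def _pointwise_loo(fit: PosteriorSummary) -> np.ndarray:
    import arviz as az

    if fit.idata is None or not hasattr(fit.idata, "log_likelihood"):
        raise ValueError("fit lacks pointwise log-likelihood (compute_loglik=False?)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loo = az.loo(fit.idata, pointwise=True)
    return np.asarray(loo.loo_i.values)


def compare_models(fit_a: PosteriorSummary, fit_b: PosteriorSummary) -> ElpdComparison:
    """LOO elpd difference, augmented (A) minus reduced (B).

    Positive values favour model A. Both fits must be on the identical data
    rows; this is checked against a hash of the response vector.
    """
    if fit_a.n_obs != fit_b.n_obs or fit_a.data_hash != fit_b.data_hash:
        raise ValueError("models were fit on different data; comparison is invalid")
    li_a = _pointwise_loo(fit_a)
    li_b = _pointwise_loo(fit_b)
    d = li_a - li_b
    n = len(d)
    se = float(np.sqrt(n * np.var(d, ddof=1))) if n > 1 else 0.0
    return ElpdComparison(
        elpd_diff=float(d.sum()),
        se_diff=se,
        elpd_a=float(li_a.sum()),
        elpd_b=float(li_b.sum()),
    )
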