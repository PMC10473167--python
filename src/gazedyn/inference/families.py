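"""Observation families: zero-one-inflated beta, ex-Gaussian, Bernoulli.

Each family exposes the pointwise log-likelihood, its analytic gradient with
respect to the linear predictor and the family's auxiliary parameters (on
unconstrained scales), and forward simulation. Auxiliary parameters are
intercept-only: for the ZOIB, the zero/one inflation probability ``alpha``
and the conditional probability of a one ``gamma`` (both logit-scale) and
the beta precision ``phi`` (log-scale); for the ex-Gaussian, the Gaussian
``sigma`` and exponential mean ``tau`` (both log-scale).
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, expit, gammaln, log_ndtr

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class Family:
    """Interface: names of auxiliary parameters + likelihood callables."""

    name: str = ""
    extra_names: tuple[str, ...] = ()

    def init_extra(self, y: np.ndarray) -> np.ndarray:
        return np.zeros(len(self.extra_names))

    def loglik(self, y: np.ndarray, eta: np.ndarray, extra: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def loglik_grad(
        self, y: np.ndarray, eta: np.ndarray, extra: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (pointwise ll, d ll / d eta, summed d ll / d extra)."""
        raise NotImplementedError

    def eta_curvature(
        self, y: np.ndarray, eta: np.ndarray, extra: np.ndarray
    ) -> np.ndarray:
        """Pointwise negative second derivative ``-d^2 ll / d eta^2``."""
        raise NotImplementedError

    def simulate(
        self, eta: np.ndarray, extra: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        raise NotImplementedError

    def check_response(self, y: np.ndarray) -> None:
        pass


class Bernoulli(Family):
    """Logistic regression for binary accuracy."""

    name = "bernoulli"
    extra_names = ()

    def check_response(self, y: np.ndarray) -> None:
        if not np.isin(y, (0, 1)).all():
            raise ValueError("bernoulli response must be 0/1")

    def loglik(self, y, eta, extra):
        return y * eta - np.logaddexp(0.0, eta)

    def loglik_grad(self, y, eta, extra):
        ll = self.loglik(y, eta, extra)
        return ll, y - expit(eta), np.zeros(0)

    def eta_curvature(self, y, eta, extra):
        p = expit(eta)
        return p * (1.0 - p)

    def simulate(self, eta, extra, rng):
        return (rng.random(len(eta)) < expit(eta)).astype(float)


class ZeroOneInflatedBeta(Family):
    """Beta regression with point masses at exactly 0 and 1.

    With probability ``alpha`` the response is degenerate (then 1 with
    probability ``gamma``, else 0); otherwise it is Beta with logit-linked
    mean ``mu = expit(eta)`` and precision ``phi``.
    """

    name = "zoib"
    extra_names = ("logit_alpha", "logit_gamma", "log_phi")

    def check_response(self, y: np.ndarray) -> None:
        if (y < 0).any() or (y > 1).any():
            raise ValueError("zoib response must lie in [0, 1]")

    def init_extra(self, y):
        p01 = np.clip(((y <= 0) | (y >= 1)).mean(), 0.02, 0.98)
        return np.array([np.log(p01 / (1 - p01)), 0.0, np.log(5.0)])

    def _unpack(self, extra):
        alpha = expit(extra[0])
        gamma = expit(extra[1])
        phi = np.exp(extra[2])
        return alpha, gamma, phi

    def loglik(self, y, eta, extra):
        alpha, gamma, phi = self._unpack(extra)
        mask01 = (y <= 0.0) | (y >= 1.0)
        ll = np.empty_like(y, dtype=float)
        y1 = y >= 1.0
        ll[mask01] = np.log(alpha) + np.where(
            y1[mask01], np.log(gamma), np.log1p(-gamma)
        )
        yb = y[~mask01]
        mu = np.clip(expit(eta[~mask01]), 1e-10, 1.0 - 1e-10)
        a = mu * phi
        b = (1.0 - mu) * phi
        ll[~mask01] = (
            np.log1p(-alpha)
            + (a - 1.0) * np.log(yb)
            + (b - 1.0) * np.log1p(-yb)
            + gammaln(phi)
            - gammaln(a)
            - gammaln(b)
        )
        return ll

    def loglik_grad(self, y, eta, extra):
        alpha, gamma, phi = self._unpack(extra)
        mask01 = (y <= 0.0) | (y >= 1.0)
        n = len(y)
        n01 = int(mask01.sum())
        n1 = int((y >= 1.0).sum())

        ll = self.loglik(y, eta, extra)
        deta = np.zeros(n)
        yb = y[~mask01]
        # clip the mean away from 0/1: keeps digamma(mu*phi) finite while the
        # analytic limit of the gradient term is itself finite
        mu = np.clip(expit(eta[~mask01]), 1e-10, 1.0 - 1e-10)
        a = mu * phi
        b = (1.0 - mu) * phi
        logit_y = np.log(yb) - np.log1p(-yb)
        deta[~mask01] = phi * mu * (1.0 - mu) * (logit_y - digamma(a) + digamma(b))

        d_logit_alpha = n01 - n * alpha
        d_logit_gamma = n1 - n01 * gamma
        dphi = (
            mu * (np.log(yb) - digamma(a))
            + (1.0 - mu) * (np.log1p(-yb) - digamma(b))
            + digamma(phi)
        )
        d_log_phi = phi * float(dphi.sum())
        return ll, deta, np.array([d_logit_alpha, d_logit_gamma, d_log_phi])

    def eta_curvature(self, y, eta, extra):
        from scipy.special import polygamma

        _, _, phi = self._unpack(extra)
        mask01 = (y <= 0.0) | (y >= 1.0)
        w = np.zeros(len(y))
        yb = y[~mask01]
        mu = np.clip(expit(eta[~mask01]), 1e-10, 1.0 - 1e-10)
        a = mu * phi
        b = (1.0 - mu) * phi
        mp = mu * (1.0 - mu)
        logit_y = np.log(yb) - np.log1p(-yb)
        w[~mask01] = phi**2 * mp**2 * (polygamma(1, a) + polygamma(1, b)) - phi * mp * (
            1.0 - 2.0 * mu
        ) * (logit_y - digamma(a) + digamma(b))
        return w

    def simulate(self, eta, extra, rng):
        alpha, gamma, phi = self._unpack(extra)
        n = len(eta)
        mu = expit(eta)
        y = rng.beta(np.maximum(mu * phi, 1e-6), np.maximum((1 - mu) * phi, 1e-6))
        degenerate = rng.random(n) < alpha
        ones = rng.random(n) < gamma
        y[degenerate] = ones[degenerate].astype(float)
        return y


class ExGaussian(Family):
    """Ex-Gaussian regression: response = Normal(eta, sigma) + Exp(mean tau).

    Right-skewed family for strictly positive, skewed measures such as the
    fixation spread; predictors act on the Gaussian location.
    """

    name = "exgaussian"
    extra_names = ("log_sigma", "log_tau")

    def init_extra(self, y):
        s = max(float(np.std(y)), 1e-3)
        return np.array([np.log(s / np.sqrt(2.0)), np.log(s / np.sqrt(2.0))])

    def _unpack(self, extra):
        return np.exp(extra[0]), np.exp(extra[1])

    def loglik(self, y, eta, extra):
        sigma, tau = self._unpack(extra)
        z = y - eta
        w = z / sigma - sigma / tau
        return -np.log(tau) + 0.5 * (sigma / tau) ** 2 - z / tau + log_ndtr(w)

    def loglik_grad(self, y, eta, extra):
        sigma, tau = self._unpack(extra)
        z = y - eta
        w = z / sigma - sigma / tau
        log_phi_w = -0.5 * w * w - _LOG_SQRT_2PI
        r = np.exp(log_phi_w - log_ndtr(w))  # hazard ratio phi(w)/Phi(w)

        ll = -np.log(tau) + 0.5 * (sigma / tau) ** 2 - z / tau + log_ndtr(w)
        deta = 1.0 / tau - r / sigma
        d_log_sigma = float(
            (sigma * (sigma / tau**2) + r * (-z / sigma - sigma / tau)).sum()
        )
        d_log_tau = float((-1.0 - (sigma / tau) ** 2 + z / tau + r * sigma / tau).sum())
        return ll, deta, np.array([d_log_sigma, d_log_tau])

    def eta_curvature(self, y, eta, extra):
        sigma, tau = self._unpack(extra)
        z = y - eta
        w = z / sigma - sigma / tau
        log_phi_w = -0.5 * w * w - _LOG_SQRT_2PI
        r = np.exp(log_phi_w - log_ndtr(w))
        # d^2 ll / d eta^2 = r'(w)/sigma^2 with r' = -r (w + r) <= 0
        return r * (w + r) / sigma**2

    def simulate(self, eta, extra, rng):
        sigma, tau = self._unpack(extra)
        n = len(eta)
        return eta + rng.normal(0.0, sigma, n) + rng.exponential(tau, n)


FAMILIES: dict[str, Family] = {
    "bernoulli": Bernoulli(),
    "binomial": Bernoulli(),  # accepted alias for trial-level 0/1 accuracy
    "zoib": ZeroOneInflatedBeta(),
    "zero_one_inflated_beta": ZeroOneInflatedBeta(),
    "exgaussian": ExGaussian(),
    "ex_gaussian": ExGaussian(),
}


def get_family(name: str) -> Family:
    try:
        return FAMILIES[name.lower()]
    except KeyError:
        raise ValueError(f"unknown family {name!r}; options: {sorted(FAMILIES)}")
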