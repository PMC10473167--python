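"""MAP + Laplace (optionally emcee) fitting of hierarchical regressions.

The model is a generalized hierarchical regression: a linear predictor
``eta = X beta + u0[participant] + u1[participant] * s`` with correlated
participant-level intercepts ``u0`` and slopes ``u1`` on the complexity
covariate ``s`` (non-centred parameterization), an optional second
random-intercept grouping (stimuli), and one of three observation families
(zero-one-inflated beta, ex-Gaussian, Bernoulli).

Priors are weakly informative and data-scaled: normal priors on
coefficients (scaled by the response SD for identity-link families),
half-normal priors on random-effect SDs, an LKJ(2)-type prior on the
intercept-slope correlation, and wide normal priors on auxiliary
parameters on their unconstrained scales.

The default posterior approximation is a Laplace fit around the
penalized-likelihood mode (analytic gradients, finite-difference Hessian),
whose draws are arranged as ``chains x draws`` for arviz. The ``emcee``
sampler provides an exact affine-invariant MCMC alternative on the same
log posterior.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize

from .families import Family, get_family

Sampler = Literal["laplace", "emcee"]


@dataclass
class ModelSpec:
    """Specification of one hierarchical regression."""

    response: str
    family: str
    fixed_effects: list[str] = field(default_factory=lambda: ["segments"])
    group: str = "participant"
    random_slope_on: str | None = "segments"
    stimulus_group: str | None = None
    center: bool = True
    chains: int = 4
    draws: int = 1000
    sampler: Sampler = "laplace"
    seed: int = 0
    prior_scale_beta: float = 2.5
    prior_scale_sd: float = 1.0
    compute_loglik: bool = True

    @classmethod
    def profile(cls, name: str, **kwargs) -> "ModelSpec":
        """Named sampling profiles: ``test`` (4x1000) and ``full`` (4x5000)."""
        if name == "test":
            return cls(chains=4, draws=1000, **kwargs)
        if name == "full":
            return cls(chains=4, draws=5000, **kwargs)
        raise ValueError(f"unknown profile {name!r}")


@dataclass
class _Design:
    X: np.ndarray
    coef_names: list[str]
    y: np.ndarray
    pid: np.ndarray
    n_participants: int
    s: np.ndarray | None  # centred random-slope covariate
    sid: np.ndarray | None
    n_stimuli: int
    family: Family
    identity_link: bool
    response_scaled: bool
    prior_beta_loc: np.ndarray
    prior_beta_scale: np.ndarray
    prior_sd_scale: float
    prior_extra_loc: np.ndarray
    prior_extra_scale: float = 3.0


def _column(data: pd.DataFrame, name: str, center: bool) -> tuple[np.ndarray, float]:
    if ":" in name:
        a, b = name.split(":", 1)
        xa, _ = _column(data, a, center)
        xb, _ = _column(data, b, center)
        return xa * xb, 0.0
    if name not in data.columns:
        raise KeyError(f"data lacks column {name!r}")
    x = data[name].to_numpy()
    if x.dtype == bool:
        return x.astype(float), 0.0
    x = x.astype(float)
    uniq = np.unique(x)
    if center and len(uniq) > 2:
        m = float(x.mean())
        return x - m, m
    return x, 0.0


def _build_design(data: pd.DataFrame, spec: ModelSpec) -> _Design:
    family = get_family(spec.family)
    if spec.response not in data.columns:
        raise KeyError(f"data lacks response column {spec.response!r}")
    y = data[spec.response].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("response contains missing values")

    response_scaled = False
    if family.name == "zoib" and np.nanmax(y) > 1.0:
        y = y / 100.0  # percentage scale -> unit interval
        response_scaled = True
    family.check_response(y)

    cols = [np.ones(len(data))]
    names = ["intercept"]
    centers: dict[str, float] = {}
    for name in spec.fixed_effects:
        x, m = _column(data, name, spec.center)
        cols.append(x)
        names.append(name)
        centers[name] = m
    X = np.column_stack(cols)

    if spec.group not in data.columns:
        raise KeyError(f"data lacks grouping column {spec.group!r}")
    codes, uniques = pd.factorize(data[spec.group], sort=True)
    pid = codes.astype(np.int64)
    n_participants = len(uniques)
    if n_participants < 2:
        raise ValueError("hierarchical model needs at least 2 participants")

    s = None
    if spec.random_slope_on is not None:
        s, _ = _column(data, spec.random_slope_on, spec.center)

    sid = None
    n_stimuli = 0
    if spec.stimulus_group is not None:
        scodes, suniq = pd.factorize(data[spec.stimulus_group], sort=True)
        sid = scodes.astype(np.int64)
        n_stimuli = len(suniq)

    identity_link = family.name == "exgaussian"
    sy = max(float(np.std(y)), 1e-8)
    if identity_link:
        loc = np.zeros(X.shape[1])
        loc[0] = float(np.mean(y))
        scale = np.full(X.shape[1], spec.prior_scale_beta * sy)
        scale[0] = 5.0 * sy
        sd_scale = spec.prior_scale_sd * sy
    else:
        loc = np.zeros(X.shape[1])
        scale = np.full(X.shape[1], spec.prior_scale_beta)
        scale[0] = 5.0
        sd_scale = spec.prior_scale_sd

    return _Design(
        X=X,
        coef_names=names,
        y=y,
        pid=pid,
        n_participants=n_participants,
        s=s,
        sid=sid,
        n_stimuli=n_stimuli,
        family=family,
        identity_link=identity_link,
        response_scaled=response_scaled,
        prior_beta_loc=loc,
        prior_beta_scale=scale,
        prior_sd_scale=sd_scale,
        prior_extra_loc=family.init_extra(y),
    )


class _Posterior:
    """Unnormalized log posterior with analytic gradient."""

    def __init__(self, design: _Design):
        self.d = design
        p = design.X.shape[1]
        P = design.n_participants
        self.p = p
        self.P = P
        self.has_slope = design.s is not None
        self.zdim = 2 * P if self.has_slope else P
        self.n_scale = 3 if self.has_slope else 1  # log_sa (+ log_sb, zrho)
        self.Q = design.n_stimuli
        self.stim_dim = (self.Q + 1) if design.sid is not None else 0
        self.n_extra = len(design.family.extra_names)
        self.dim = p + self.zdim + self.n_scale + self.stim_dim + self.n_extra

    # --- packing -------------------------------------------------------
    def split(self, theta: np.ndarray):
        p, P = self.p, self.P
        i = p
        beta = theta[:p]
        z = theta[i : i + self.zdim]
        i += self.zdim
        scales = theta[i : i + self.n_scale]
        i += self.n_scale
        if self.stim_dim:
            z_stim = theta[i : i + self.Q]
            log_ss = theta[i + self.Q]
            i += self.stim_dim
        else:
            z_stim, log_ss = None, None
        extra = theta[i:]
        return beta, z, scales, z_stim, log_ss, extra

    def init(self, rng: np.random.Generator) -> np.ndarray:
        d = self.d
        theta = np.zeros(self.dim)
        beta0 = np.linalg.lstsq(d.X, self._init_working_response(), rcond=None)[0]
        theta[: self.p] = beta0
        i = self.p + self.zdim
        theta[i] = np.log(0.3 * self.d.prior_sd_scale + 1e-8)
        if self.has_slope:
            theta[i + 1] = np.log(0.15 * self.d.prior_sd_scale + 1e-8)
        if self.stim_dim:
            theta[self.p + self.zdim + self.n_scale + self.Q] = np.log(
                0.1 * self.d.prior_sd_scale + 1e-8
            )
        theta[self.dim - self.n_extra :] = self.d.prior_extra_loc
        theta += 0.01 * rng.standard_normal(self.dim)
        return theta

    def _init_working_response(self) -> np.ndarray:
        y = self.d.y
        if self.d.identity_link:
            return y
        if self.d.family.name == "zoib":
            yc = np.clip(y, 0.02, 0.98)
            return np.log(yc / (1 - yc))
        p = np.clip(y, 0.05, 0.95)
        return np.log(p / (1 - p))

    # --- log posterior -------------------------------------------------
    def _random_effects(self, z, scales):
        P = self.P
        sa = np.exp(scales[0])
        if self.has_slope:
            sb = np.exp(scales[1])
            rho = np.tanh(scales[2])
            z1, z2 = z[:P], z[P:]
            u0 = sa * z1
            u1 = sb * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)
            return u0, u1, sa, sb, rho
        return sa * z, None, sa, None, None

    def eta(self, theta: np.ndarray) -> np.ndarray:
        d = self.d
        beta, z, scales, z_stim, log_ss, extra = self.split(theta)
        u0, u1, *_ = self._random_effects(z, scales)
        eta = d.X @ beta + u0[d.pid]
        if u1 is not None:
            eta = eta + u1[d.pid] * d.s
        if z_stim is not None:
            eta = eta + np.exp(log_ss) * z_stim[d.sid]
        return eta

    def log_post_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        d = self.d
        P = self.P
        beta, z, scales, z_stim, log_ss, extra = self.split(theta)
        u0, u1, sa, sb, rho = self._random_effects(z, scales)

        eta = d.X @ beta + u0[d.pid]
        if u1 is not None:
            eta = eta + u1[d.pid] * d.s
        if z_stim is not None:
            ss = np.exp(log_ss)
            eta = eta + ss * z_stim[d.sid]

        ll, deta, dextra = d.family.loglik_grad(d.y, eta, extra)
        lp = float(ll.sum())
        grad = np.empty(self.dim)

        # fixed effects + normal prior
        resid = (beta - d.prior_beta_loc) / d.prior_beta_scale**2
        grad[: self.p] = d.X.T @ deta - resid
        lp += float(-0.5 * (((beta - d.prior_beta_loc) / d.prior_beta_scale) ** 2).sum())

        # participant effects
        g0 = np.bincount(d.pid, weights=deta, minlength=P)
        i = self.p
        if self.has_slope:
            gs = np.bincount(d.pid, weights=deta * d.s, minlength=P)
            c = np.sqrt(1.0 - rho**2)
            z1, z2 = z[:P], z[P:]
            grad[i : i + P] = sa * g0 + sb * rho * gs - z1
            grad[i + P : i + 2 * P] = sb * c * gs - z2
            i += 2 * P
            # scales: half-normal prior on sd (+ log jacobian), LKJ(2) on rho
            lam = d.prior_sd_scale
            grad[i] = float((g0 * u0).sum()) - sa**2 / lam**2 + 1.0
            grad[i + 1] = float((gs * u1).sum()) - sb**2 / lam**2 + 1.0
            db_drho = sb * (z1 - rho / c * z2)
            grad[i + 2] = float((gs * db_drho).sum()) * (1.0 - rho**2) - 4.0 * rho
            lp += (
                -0.5 * float((z**2).sum())
                - sa**2 / (2 * lam**2)
                + np.log(sa)
                - sb**2 / (2 * lam**2)
                + np.log(sb)
                + 2.0 * np.log1p(-rho**2)
            )
            i += 3
        else:
            grad[i : i + P] = sa * g0 - z
            i += P
            lam = d.prior_sd_scale
            grad[i] = float((g0 * u0).sum()) - sa**2 / lam**2 + 1.0
            lp += -0.5 * float((z**2).sum()) - sa**2 / (2 * lam**2) + np.log(sa)
            i += 1

        if z_stim is not None:
            gstim = np.bincount(d.sid, weights=deta, minlength=self.Q)
            grad[i : i + self.Q] = ss * gstim - z_stim
            grad[i + self.Q] = float((gstim * ss * z_stim).sum()) - ss**2 / lam**2 + 1.0
            lp += -0.5 * float((z_stim**2).sum()) - ss**2 / (2 * lam**2) + np.log(ss)
            i += self.Q + 1

        if self.n_extra:
            loc = d.prior_extra_loc
            sc = d.prior_extra_scale
            grad[i:] = dextra - (extra - loc) / sc**2
            lp += float(-0.5 * (((extra - loc) / sc) ** 2).sum())
        return lp, grad

    def log_post(self, theta: np.ndarray) -> float:
        return self.log_post_grad(theta)[0]


def _fd_hessian(grad_fn, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of a scalar function from its gradient."""
    n = len(x)
    H = np.empty((n, n))
    for j in range(n):
        h = rel_step * (1.0 + abs(x[j]))
        xp = x.copy()
        xm = x.copy()
        xp[j] += h
        xm[j] -= h
        H[:, j] = (grad_fn(xp) - grad_fn(xm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def _fd_hessian_scalar(fn, x: np.ndarray, rel_step: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian from function values only."""
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    f0 = fn(x)
    H = np.empty((n, n))
    for i in range(n):
        xp = x.copy()
        xm = x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        H[i, i] = (fn(xp) - 2.0 * f0 + fn(xm)) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            xpp = x.copy()
            xpm = x.copy()
            xmp = x.copy()
            xmm = x.copy()
            xpp[[i, j]] += h[[i, j]]
            xpm[i] += h[i]
            xpm[j] -= h[j]
            xmp[i] -= h[i]
            xmp[j] += h[j]
            xmm[[i, j]] -= h[[i, j]]
            H[i, j] = H[j, i] = (fn(xpp) - fn(xpm) - fn(xmp) + fn(xmm)) / (
                4.0 * h[i] * h[j]
            )
    return H


class _Marginal:
    """Nested-Laplace marginal over the hyperparameters.

    The linear predictor is linear in ``u = (beta, z, z_stim)`` once the
    hyperparameters ``phi = (log-scales, correlation, auxiliaries)`` are
    fixed, so the inner problem is a penalized GLM solved by Newton steps
    with an analytic Hessian; the latent block is integrated out by a
    Laplace approximation and only the handful of hyperparameters are
    optimized on the approximate marginal (the approach of lme4/glmmTMB).
    This avoids the known failure of the joint mode in the non-centred
    parameterization, which rides the random-effect SD up to its prior
    scale regardless of the data.
    """

    def __init__(self, design: _Design, post: _Posterior):
        self.d = design
        self.post = post
        p, P = post.p, post.P
        self.has_stim = design.sid is not None
        self.du = p + post.zdim + (post.Q if self.has_stim else 0)
        self.dphi = post.n_scale + (1 if self.has_stim else 0) + post.n_extra
        # prior precision and mean of u
        prec = np.ones(self.du)
        prec[:p] = 1.0 / design.prior_beta_scale**2
        self.u_prior_prec = prec
        mean = np.zeros(self.du)
        mean[:p] = design.prior_beta_loc
        self.u_prior_mean = mean
        self._warm: np.ndarray | None = None

    def split_phi(self, phi: np.ndarray):
        scales = phi[: self.post.n_scale]
        log_ss = phi[self.post.n_scale] if self.has_stim else None
        extra = phi[self.dphi - self.post.n_extra :] if self.post.n_extra else np.zeros(0)
        return scales, log_ss, extra

    def phi_bounds(self) -> list[tuple[float, float]]:
        """Generous box bounds on the unconstrained hyperparameters.

        Scales are kept within a wide window around the prior scale and the
        correlation within |rho| < 0.995 to stop the outer optimizer from
        chasing flat boundary directions.
        """
        lam = self.d.prior_sd_scale
        b: list[tuple[float, float]] = [(np.log(1e-4 * lam), np.log(50 * lam))]
        if self.post.has_slope:
            b.append((np.log(1e-4 * lam), np.log(50 * lam)))
            b.append((-3.0, 3.0))
        if self.has_stim:
            b.append((np.log(1e-4 * lam), np.log(50 * lam)))
        for loc in (self.d.prior_extra_loc if self.post.n_extra else []):
            b.append((loc - 12.0, loc + 12.0))
        return b

    def phi0(self) -> np.ndarray:
        lam = self.d.prior_sd_scale
        parts = [np.log(0.3 * lam)]
        if self.post.has_slope:
            parts += [np.log(0.15 * lam), 0.0]
        if self.has_stim:
            parts.append(np.log(0.1 * lam))
        phi = np.array(parts, dtype=float)
        if self.post.n_extra:
            phi = np.concatenate([phi, self.d.prior_extra_loc])
        return phi

    def build_A(self, phi: np.ndarray) -> np.ndarray:
        d, post = self.d, self.post
        p, P = post.p, post.P
        scales, log_ss, _ = self.split_phi(phi)
        n = len(d.y)
        A = np.zeros((n, self.du))
        A[:, :p] = d.X
        rows = np.arange(n)
        sa = np.exp(scales[0])
        if post.has_slope:
            sb = np.exp(scales[1])
            rho = np.tanh(scales[2])
            c = np.sqrt(1.0 - rho**2)
            A[rows, p + d.pid] = sa + sb * rho * d.s
            A[rows, p + P + d.pid] = sb * c * d.s
        else:
            A[rows, p + d.pid] = sa
        if self.has_stim:
            A[rows, p + post.zdim + d.sid] = np.exp(log_ss)
        return A

    def _u_init(self) -> np.ndarray:
        u = np.zeros(self.du)
        post = self.post
        yw = post._init_working_response()
        u[: post.p] = np.linalg.lstsq(self.d.X, yw, rcond=None)[0]
        return u

    def inner(self, phi: np.ndarray, tol: float = 1e-8, max_iter: int = 200):
        """Newton solve for the latent block at fixed hyperparameters.

        Warm-started from the previous solve; if that solve fails to
        converge (the outer optimizer may probe extreme hyperparameters
        whose mode poisons the warm start), it is retried from a fresh
        initialization and the better of the two solutions is kept.
        """
        first = self._newton(phi, self._warm, tol, max_iter)
        if not first[-1] and self._warm is not None:
            fresh = self._newton(phi, None, tol, max_iter)
            if fresh[-1] or fresh[1] > first[1]:
                first = fresh
        u, lp, logdet, cho, A, converged = first
        self._warm = u.copy() if converged else None
        return first

    def _newton(self, phi: np.ndarray, u0, tol: float, max_iter: int):
        from scipy.linalg import cho_factor, cho_solve

        d = self.d
        _, _, extra = self.split_phi(phi)
        A = self.build_A(phi)
        u = u0.copy() if u0 is not None else self._u_init()
        prec, mean = self.u_prior_prec, self.u_prior_mean

        def penalized(u_vec, ll_vec):
            dev = u_vec - mean
            return float(ll_vec.sum()) - 0.5 * float((prec * dev * dev).sum())

        eta = A @ u
        ll = d.family.loglik(d.y, eta, extra)
        lp = penalized(u, ll)
        if not np.isfinite(lp):
            u = self._u_init()
            eta = A @ u
            lp = penalized(u, d.family.loglik(d.y, eta, extra))
        converged = False
        cho = None
        for _ in range(max_iter):
            _, deta, _ = d.family.loglik_grad(d.y, eta, extra)
            g = A.T @ deta - prec * (u - mean)
            w = d.family.eta_curvature(d.y, eta, extra)
            w = np.clip(np.nan_to_num(w, nan=1e-10), 1e-10, None)
            H = (A * w[:, None]).T @ A
            H[np.diag_indices_from(H)] += prec
            ridge = 0.0
            for _ in range(6):
                try:
                    cho = cho_factor(H + ridge * np.eye(self.du), lower=True)
                    break
                except np.linalg.LinAlgError:
                    ridge = max(10.0 * ridge, 1e-8 * float(np.trace(H)) / self.du)
            if np.max(np.abs(g)) < tol * (1.0 + abs(lp)):
                converged = True
                break
            step = cho_solve(cho, g)
            ok = False
            t = 1.0
            while t > 1e-6:
                u_new = u + t * step
                eta_new = A @ u_new
                ll_new = d.family.loglik(d.y, eta_new, extra)
                lp_new = penalized(u_new, ll_new)
                if np.isfinite(lp_new) and lp_new >= lp - 1e-10:
                    ok = True
                    break
                t /= 2.0
            if not ok:
                break  # no ascent direction left; keep current u
            if abs(lp_new - lp) < tol * (1.0 + abs(lp)) and np.max(np.abs(g)) < 1e-3:
                u, eta, lp = u_new, eta_new, lp_new
                converged = True
                break
            u, eta, lp = u_new, eta_new, lp_new
        logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        return u, lp, logdet, cho, A, converged

    def phi_log_prior(self, phi: np.ndarray) -> float:
        post, d = self.post, self.d
        scales, log_ss, extra = self.split_phi(phi)
        lam = d.prior_sd_scale
        sa = np.exp(scales[0])
        lp = np.log(sa) - sa**2 / (2 * lam**2)
        if post.has_slope:
            sb = np.exp(scales[1])
            rho = np.tanh(scales[2])
            lp += np.log(sb) - sb**2 / (2 * lam**2) + 2.0 * np.log1p(-rho**2)
        if log_ss is not None:
            ss = np.exp(log_ss)
            lp += np.log(ss) - ss**2 / (2 * lam**2)
        if post.n_extra:
            loc, sc = d.prior_extra_loc, d.prior_extra_scale
            lp += -0.5 * float((((extra - loc) / sc) ** 2).sum())
        return float(lp)

    def marginal(self, phi: np.ndarray) -> float:
        """Laplace-approximate log marginal posterior of phi."""
        _, lp_joint, logdet, _, _, _ = self.inner(phi)
        return lp_joint - 0.5 * logdet + self.phi_log_prior(phi)


@dataclass
class PosteriorSummary:
    """Posterior medians, 95% credibility intervals, and diagnostics."""

    coefficients: pd.DataFrame
    random_effects: pd.DataFrame
    auxiliary: pd.DataFrame
    participant_effects: pd.DataFrame
    diagnostics: dict
    ppc: dict
    idata: object  # arviz.InferenceData
    spec: ModelSpec
    n_obs: int
    data_hash: str
    response_scaled: bool

    def effect_present(self, name: str) -> bool:
        row = self.coefficients.loc[name]
        return bool(row["ci_low"] > 0.0 or row["ci_high"] < 0.0)

    def coefficient_ci(self, name: str) -> tuple[float, float]:
        row = self.coefficients.loc[name]
        return float(row["ci_low"]), float(row["ci_high"])

    def to_dict(self) -> dict:
        return {
            "response": self.spec.response,
            "family": self.spec.family,
            "n_obs": self.n_obs,
            "coefficients": self.coefficients.reset_index().to_dict(orient="records"),
            "random_effects": self.random_effects.reset_index().to_dict(orient="records"),
            "auxiliary": self.auxiliary.reset_index().to_dict(orient="records"),
            "diagnostics": {
                k: (v if not isinstance(v, np.generic) else v.item())
                for k, v in self.diagnostics.items()
            },
            "ppc": self.ppc,
        }


def _summarize(draws: np.ndarray) -> tuple[float, float, float]:
    """(median, 2.5%, 97.5%) of a flat draw vector."""
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
    return float(med), float(lo), float(hi)


def _fit_marginal_laplace(
    design: _Design, post: _Posterior, n_draws: int, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    """Optimize the Laplace marginal over phi; draw from the joint Gaussian.

    Hyperparameter draws come from a normal on the unconstrained scale with
    covariance from the finite-difference Hessian of the marginal; latent
    draws condition on the hyperparameter mode.
    """
    from scipy.linalg import solve_triangular

    marg = _Marginal(design, post)
    phi0 = marg.phi0()
    bounds = marg.phi_bounds()
    res = optimize.minimize(
        lambda phi: -marg.marginal(phi),
        phi0,
        method="L-BFGS-B",
        jac="2-point",
        bounds=bounds,
        options={"maxiter": 200, "eps": 1e-5},
    )
    outer_ok = bool(res.success)
    if not outer_ok:
        # quadratic interpolation in L-BFGS-B can stall on FD noise; polish
        # with a simplex pass from the current best point
        polish = optimize.minimize(
            lambda phi: -marg.marginal(phi),
            res.x,
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxfev": 1500},
        )
        if polish.fun <= res.fun:
            res = polish
        outer_ok = bool(polish.success) or bool(res.success)
    phi_hat = res.x
    u_hat, _, _, cho, _, inner_conv = marg.inner(phi_hat)

    H_phi = _fd_hessian_scalar(marg.marginal, phi_hat)
    vals, vecs = np.linalg.eigh(-0.5 * (H_phi + H_phi.T))
    pd = bool((vals > 0).all())
    # floor the precision: weakly identified hyperparameters (e.g. a slope SD
    # with few groups) otherwise yield flat directions and absurd draws; the
    # floor caps the unconstrained-scale draw SD at 3, the prior's own order
    vals = np.clip(vals, 1.0 / 9.0, None)
    cov_phi = vecs @ np.diag(1.0 / vals) @ vecs.T
    L_phi = np.linalg.cholesky(cov_phi + 1e-12 * np.eye(len(phi_hat)))
    phi_draws = phi_hat + rng.standard_normal((n_draws, marg.dphi)) @ L_phi.T

    L_u = np.tril(cho[0])
    zs = rng.standard_normal((n_draws, marg.du))
    u_draws = u_hat + solve_triangular(L_u.T, zs.T, lower=False).T

    p, P = post.p, post.P
    theta = np.zeros((n_draws, post.dim))
    theta[:, :p] = u_draws[:, :p]
    i = p + post.zdim
    theta[:, i : i + post.n_scale] = phi_draws[:, : post.n_scale]

    # rescale the non-centred z draws per hyperparameter draw so the
    # NATURAL-scale random effects are preserved: z' = L(phi_s)^-1 L(phi_hat) z.
    # Drawing z and the scales independently would otherwise produce draws
    # deep in the funnel with wildly unrealistic effects.
    z_draws = u_draws[:, p : p + post.zdim]
    sa_hat = np.exp(phi_hat[0])
    sa_s = np.exp(phi_draws[:, 0])
    if post.has_slope:
        sb_hat, rho_hat = np.exp(phi_hat[1]), np.tanh(phi_hat[2])
        c_hat = np.sqrt(1.0 - rho_hat**2)
        sb_s, rho_s = np.exp(phi_draws[:, 1]), np.tanh(phi_draws[:, 2])
        c_s = np.sqrt(1.0 - rho_s**2)
        m00 = sa_hat / sa_s
        m10 = (-rho_s / (c_s * sa_s)) * sa_hat + (sb_hat * rho_hat) / (sb_s * c_s)
        m11 = (sb_hat * c_hat) / (sb_s * c_s)
        z1, z2 = z_draws[:, :P], z_draws[:, P:]
        theta[:, p : p + P] = m00[:, None] * z1
        theta[:, p + P : p + 2 * P] = m10[:, None] * z1 + m11[:, None] * z2
    else:
        theta[:, p : p + P] = (sa_hat / sa_s)[:, None] * z_draws

    if marg.has_stim:
        ss_hat = np.exp(phi_hat[post.n_scale])
        ss_s = np.exp(phi_draws[:, post.n_scale])
        theta[:, i + post.n_scale : i + post.n_scale + post.Q] = (ss_hat / ss_s)[
            :, None
        ] * u_draws[:, p + post.zdim :]
        theta[:, i + post.n_scale + post.Q] = phi_draws[:, post.n_scale]
    if post.n_extra:
        theta[:, post.dim - post.n_extra :] = phi_draws[:, marg.dphi - post.n_extra :]

    diag = {
        "sampler": "laplace",
        "optimizer_converged": outer_ok,
        "optimizer_message": str(res.message),
        "inner_converged": bool(inner_conv),
        "marginal_evals": int(res.nfev),
        "hessian_pd": pd,
        "converged": outer_ok and inner_conv,
    }
    return theta, diag


def _sample_emcee(
    post: _Posterior,
    theta_hat: np.ndarray,
    n_draws: int,
    rng: np.random.Generator,
    burn: int = 500,
) -> tuple[np.ndarray, dict]:
    import emcee

    nwalkers = max(2 * post.dim + 2, 40)
    p0 = theta_hat + 0.01 * rng.standard_normal((nwalkers, post.dim))
    sampler = emcee.EnsembleSampler(nwalkers, post.dim, post.log_post)
    steps = burn + int(np.ceil(n_draws / nwalkers)) + 1
    sampler.run_mcmc(p0, steps, progress=False)
    chain = sampler.get_chain(discard=burn, flat=True)
    idx = rng.choice(len(chain), size=n_draws, replace=False)
    diag = {
        "sampler_acceptance": float(np.mean(sampler.acceptance_fraction)),
        "hessian_pd": True,
    }
    return chain[idx], diag


def fit_model(data: pd.DataFrame, spec: ModelSpec) -> PosteriorSummary:
    """Fit the hierarchical model in ``spec`` to per-trial ``data``."""
    design = _build_design(data, spec)
    post = _Posterior(design)
    rng = np.random.default_rng(spec.seed)
    n_draws = spec.chains * spec.draws

    if spec.sampler == "laplace":
        draws, diagnostics = _fit_marginal_laplace(design, post, n_draws, rng)
    else:
        theta0 = post.init(rng)
        res = optimize.minimize(
            lambda x: tuple(-v for v in post.log_post_grad(x)),
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "maxfun": 20000},
        )
        draws, samp_diag = _sample_emcee(post, res.x, n_draws, rng)
        diagnostics = {
            "sampler": "emcee",
            "optimizer_converged": bool(res.success),
            "converged": bool(res.success)
            and 0.1 < samp_diag.get("sampler_acceptance", 0.0) < 0.9,
            **samp_diag,
        }

    return _summarize_fit(design, post, spec, draws, diagnostics, rng)


def _summarize_fit(
    design: _Design,
    post: _Posterior,
    spec: ModelSpec,
    draws: np.ndarray,
    diagnostics: dict,
    rng: np.random.Generator,
) -> PosteriorSummary:
    import arviz as az

    p, P = post.p, post.P
    chains, ndraw = spec.chains, spec.draws
    beta_d = draws[:, :p]

    coef_rows = {}
    for j, name in enumerate(design.coef_names):
        med, lo, hi = _summarize(beta_d[:, j])
        coef_rows[name] = {
            "median": med,
            "ci_low": lo,
            "ci_high": hi,
            "effect_present": bool(lo > 0 or hi < 0),
        }
    coefficients = pd.DataFrame(coef_rows).T

    # random effects on natural scale
    i = p + post.zdim
    re_rows = {}
    sa_d = np.exp(draws[:, i])
    med, lo, hi = _summarize(sa_d)
    re_rows["sd_intercept"] = {"median": med, "ci_low": lo, "ci_high": hi}
    u0_all = np.empty((len(draws), P))
    u1_all = None
    if post.has_slope:
        sb_d = np.exp(draws[:, i + 1])
        rho_d = np.tanh(draws[:, i + 2])
        med, lo, hi = _summarize(sb_d)
        re_rows["sd_slope"] = {"median": med, "ci_low": lo, "ci_high": hi}
        med, lo, hi = _summarize(rho_d)
        re_rows["cor_intercept_slope"] = {"median": med, "ci_low": lo, "ci_high": hi}
        z1 = draws[:, p : p + P]
        z2 = draws[:, p + P : p + 2 * P]
        u0_all = sa_d[:, None] * z1
        u1_all = sb_d[:, None] * (
            rho_d[:, None] * z1 + np.sqrt(1 - rho_d**2)[:, None] * z2
        )
    else:
        u0_all = sa_d[:, None] * draws[:, p : p + P]
    if design.sid is not None:
        j = p + post.zdim + post.n_scale + post.Q
        med, lo, hi = _summarize(np.exp(draws[:, j]))
        re_rows["sd_stimulus"] = {"median": med, "ci_low": lo, "ci_high": hi}
    random_effects = pd.DataFrame(re_rows).T

    aux_rows = {}
    extra_d = draws[:, post.dim - post.n_extra :] if post.n_extra else np.zeros((len(draws), 0))
    for j, raw_name in enumerate(design.family.extra_names):
        nat_name = raw_name.split("_", 1)[1]
        vals = extra_d[:, j]
        if raw_name.startswith("log_"):
            vals = np.exp(vals)
        elif raw_name.startswith("logit_"):
            vals = 1.0 / (1.0 + np.exp(-vals))
        med, lo, hi = _summarize(vals)
        aux_rows[nat_name] = {"median": med, "ci_low": lo, "ci_high": hi}
    auxiliary = pd.DataFrame(aux_rows).T if aux_rows else pd.DataFrame(
        columns=["median", "ci_low", "ci_high"]
    )

    pe = {"participant": np.arange(P), "intercept": np.median(u0_all, axis=0)}
    if u1_all is not None:
        pe["slope"] = np.median(u1_all, axis=0)
    participant_effects = pd.DataFrame(pe)

    posterior = {
        name: beta_d[:, j].reshape(chains, ndraw) for j, name in enumerate(design.coef_names)
    }
    posterior["sd_intercept"] = sa_d.reshape(chains, ndraw)
    if post.has_slope:
        posterior["sd_slope"] = sb_d.reshape(chains, ndraw)
        posterior["cor_intercept_slope"] = rho_d.reshape(chains, ndraw)
        posterior["u_slope"] = u1_all.reshape(chains, ndraw, P)
    posterior["u_intercept"] = u0_all.reshape(chains, ndraw, P)

    log_likelihood = None
    if spec.compute_loglik:
        ll = np.empty((len(draws), len(design.y)))
        chunk = 250
        for a in range(0, len(draws), chunk):
            b = min(a + chunk, len(draws))
            etas = design.X @ beta_d[a:b].T  # (n, m)
            etas += u0_all[a:b].T[design.pid]
            if u1_all is not None:
                etas += u1_all[a:b].T[design.pid] * design.s[:, None]
            if design.sid is not None:
                j0 = p + post.zdim + post.n_scale
                ss = np.exp(draws[a:b, j0 + post.Q])
                zs = draws[a:b, j0 : j0 + post.Q]
                etas += (ss[:, None] * zs).T[design.sid]
            for m in range(b - a):
                ll[a + m] = design.family.loglik(design.y, etas[:, m], extra_d[a + m])
        log_likelihood = {"y": ll.reshape(chains, ndraw, -1)}

    idata = az.from_dict(posterior=posterior, log_likelihood=log_likelihood)

    ppc = _posterior_predictive_check(design, post, draws, extra_d, u0_all, u1_all, rng)

    data_hash = hashlib.sha1(
        np.ascontiguousarray(design.y).tobytes()
    ).hexdigest()

    return PosteriorSummary(
        coefficients=coefficients,
        random_effects=random_effects,
        auxiliary=auxiliary,
        participant_effects=participant_effects,
        diagnostics=diagnostics,
        ppc=ppc,
        idata=idata,
        spec=spec,
        n_obs=len(design.y),
        data_hash=data_hash,
        response_scaled=design.response_scaled,
    )


def _posterior_predictive_check(
    design: _Design, post: _Posterior, draws, extra_d, u0_all, u1_all, rng, n_rep: int = 100
) -> dict:
    """Simulate replicate datasets; report tail probabilities of mean and SD."""
    idx = rng.choice(len(draws), size=min(n_rep, len(draws)), replace=False)
    means, sds = [], []
    for m in idx:
        eta = design.X @ draws[m, : post.p] + u0_all[m][design.pid]
        if u1_all is not None:
            eta = eta + u1_all[m][design.pid] * design.s
        y_rep = design.family.simulate(eta, extra_d[m], rng)
        means.append(float(np.mean(y_rep)))
        sds.append(float(np.std(y_rep)))
    means = np.array(means)
    sds = np.array(sds)
    return {
        "observed_mean": float(np.mean(design.y)),
        "observed_sd": float(np.std(design.y)),
        "ppc_mean_q05": float(np.percentile(means, 5)),
        "ppc_mean_q95": float(np.percentile(means, 95)),
        "p_mean": float(np.mean(means >= np.mean(design.y))),
        "p_sd": float(np.mean(sds >= np.std(design.y))),
    }
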