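"""EM fitting of the semiparametric gamma-frailty mixed Poisson rate model.

Model: conditional on an unobserved frailty ``u_i`` (gamma, mean 1,
variance ``theta``) and the baseline marker ``m_i``, subject ``i``'s event
process is Poisson with rate ``u_i * rho0(t) * exp(beta * m_i)``.  The
unknowns are ``Theta = (beta, theta, mu0(.))`` with ``mu0`` the cumulative
baseline mean, estimated nonparametrically as a right-continuous step
function with jumps at the pooled observed event times.

The E-step uses the conjugate gamma posterior of ``u_i`` given the observed
history (shape ``1/theta + n_i``, scale ``theta / (1 + theta*mu_i(C_i))``),
which gives closed forms for ``E[u_i]`` and ``E[log u_i]``.  The M-step
profiles the baseline through a Breslow-type estimator with frailty-weighted
risk sets, solves the marker-coefficient score by safeguarded Newton, and
maximizes the gamma-frailty term by bounded 1-D search on ``log theta``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special

from .data_model import RecurrentData

__all__ = [
    "EMConfig",
    "FrailtyFit",
    "estep_frailty_mean",
    "estep_frailty_logmean",
    "update_baseline",
    "update_beta",
    "update_theta",
    "fit_em",
    "marginal_loglik",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EMConfig:
    """EM control parameters.

    ``tol`` is the maximum relative change in ``(beta, theta, mu0(tau))``
    below which iteration stops.  ``theta_floor`` maps boundary solutions of
    the frailty-variance update to the Poisson submodel (``theta = 0``);
    setting it to ``inf`` forces the Poisson fit.
    """

    tol: float = 1e-6
    max_iter: int = 500
    theta_floor: float = 1e-4
    init_beta: float | None = None
    init_theta: float | None = None
    inner_max_cycles: int = 20

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.theta_floor < 0:
            raise ValueError("theta_floor must be >= 0")


@dataclass
class FrailtyFit:
    """Fitted ``Theta = (beta, theta, mu0)`` with convergence diagnostics."""

    beta: float
    theta: float
    baseline_times: np.ndarray
    baseline_increments: np.ndarray
    posterior_frailty_means: np.ndarray
    n_iter: int
    converged: bool
    marginal_loglik: float
    tau: float
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    def mu0_at(self, t) -> np.ndarray:
        """Cumulative baseline mean ``mu0(t)``: right-continuous step lookup.

        Beyond the last jump the function is constant (the step estimator
        places no mass after the largest observed event time).
        """
        cum = np.concatenate([[0.0], np.cumsum(self.baseline_increments)])
        idx = np.searchsorted(self.baseline_times, np.asarray(t, dtype=float), side="right")
        out = cum[idx]
        return out if out.ndim else float(out)

    def rate_params(self):
        from .event_prob import RateParams

        return RateParams(beta=self.beta, theta=self.theta, mu0_at=self.mu0_at)

    def to_json(self) -> str:
        payload = {
            "beta": self.beta,
            "theta": self.theta,
            "baseline": [[float(t), float(d)] for t, d in zip(self.baseline_times, self.baseline_increments)],
            "n_iter": self.n_iter,
            "converged": self.converged,
            "loglik": self.marginal_loglik,
            "tau": self.tau,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "FrailtyFit":
        d = json.loads(text)
        base = np.asarray(d["baseline"], dtype=float).reshape(-1, 2)
        return cls(
            beta=d["beta"],
            theta=d["theta"],
            baseline_times=base[:, 0],
            baseline_increments=base[:, 1],
            posterior_frailty_means=np.empty(0),
            n_iter=d["n_iter"],
            converged=d["converged"],
            marginal_loglik=d["loglik"],
            tau=d["tau"],
        )


def estep_frailty_mean(n_i, theta: float, mu_i) -> np.ndarray:
    """Posterior mean ``E[u | H(tau)] = (1 + n*theta) / (1 + mu*theta)``."""
    n_i = np.asarray(n_i, dtype=float)
    mu_i = np.asarray(mu_i, dtype=float)
    if theta < 0 or np.any(n_i < 0) or np.any(mu_i < 0):
        raise ValueError("inputs must be non-negative")
    out = (1.0 + n_i * theta) / (1.0 + mu_i * theta)
    return out if out.ndim else float(out)


def estep_frailty_logmean(n_i, theta: float, mu_i) -> np.ndarray:
    """Posterior ``E[log u]`` from the gamma posterior.

    Shape ``1/theta + n``, scale ``theta / (1 + theta*mu)``, hence
    ``E[log u] = digamma(1/theta + n) + log(theta / (1 + theta*mu))``.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0 (use the Poisson branch at the boundary)")
    n_i = np.asarray(n_i, dtype=float)
    mu_i = np.asarray(mu_i, dtype=float)
    out = special.digamma(1.0 / theta + n_i) + np.log(theta) - np.log1p(theta * mu_i)
    return out if out.ndim else float(out)


# -- internal array representation -------------------------------------------


class _Arrays:
    """Dataset flattened into numpy arrays, precomputed for EM iterations."""

    def __init__(self, data: Sequence[RecurrentData]):
        self.n = len(data)
        self.m = np.array([d.marker for d in data])
        self.C = np.array([d.censor_time for d in data])
        self.counts = np.array([d.n_events for d in data])
        self.tau = data[0].tau if data else np.nan
        all_times = np.concatenate([d.event_times for d in data]) if data else np.empty(0)
        self.s, self.d = np.unique(all_times, return_counts=True)  # pooled jump times, multiplicities
        self.event_jump_idx = np.searchsorted(self.s, all_times)  # map each event to its jump
        # risk-set bookkeeping: subjects sorted by censoring time
        self.order_C = np.argsort(self.C)
        self.C_sorted = self.C[self.order_C]
        # number of subjects with C < s_l, per jump time
        self.n_left = np.searchsorted(self.C_sorted, self.s, side="left")
        # index of last jump time <= C_i, exclusive end for cumsum lookup
        self.jumps_before_C = np.searchsorted(self.s, self.C, side="right")

    def mu0_at_C(self, dmu0: np.ndarray) -> np.ndarray:
        cum = np.concatenate([[0.0], np.cumsum(dmu0)])
        return cum[self.jumps_before_C]


def _risk_denominators(arr: _Arrays, weights: np.ndarray) -> np.ndarray:
    """``sum_{i: C_i >= s_l} w_i`` for every pooled jump time ``s_l``."""
    w_sorted = weights[arr.order_C]
    pref = np.concatenate([[0.0], np.cumsum(w_sorted)])
    return pref[-1] - pref[arr.n_left]


def update_baseline(data, beta: float, frailty_means) -> tuple[np.ndarray, np.ndarray]:
    """Breslow-type baseline increments ``dmu0(s) = d(s) / sum_{C_i>=s} u~_i e^{beta m_i}``.

    ``d(s)`` counts events at ``s`` across subjects (across-subject ties
    allowed); risk-set membership is closed at ``s`` (``C_i >= s``).
    """
    arr = data if isinstance(data, _Arrays) else _Arrays(list(data))
    u = np.asarray(frailty_means, dtype=float)
    if np.any(u <= 0):
        raise ValueError("frailty means must be positive")
    denom = _risk_denominators(arr, u * np.exp(beta * arr.m))
    if np.any(denom <= 0):
        raise ValueError("empty risk set at an observed event time")
    return arr.s, arr.d / denom


def _beta_score(beta: float, arr: _Arrays, u: np.ndarray, dmu0: np.ndarray) -> float:
    mu_C = arr.mu0_at_C(dmu0) * np.exp(beta * arr.m)
    return float(np.sum(arr.m * (arr.counts - u * mu_C)))


def update_beta(data, frailty_means, baseline, init: float = 0.0, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve the marker-coefficient score ``sum m_i (n_i - u~_i mu_i(C_i)) = 0``.

    The score is strictly decreasing in ``beta`` (for a non-degenerate
    marker), so a bracket-expanding safeguarded Newton always converges.
    With all markers equal the score is identically its fixed part and the
    initial value is returned.
    """
    arr = data if isinstance(data, _Arrays) else _Arrays(list(data))
    u = np.asarray(frailty_means, dtype=float)
    _, dmu0 = baseline if isinstance(baseline, tuple) else (None, np.asarray(baseline, dtype=float))
    if np.ptp(arr.m) == 0:
        return float(init)

    mu0C = arr.mu0_at_C(dmu0)

    def score_and_grad(b):
        e = np.exp(b * arr.m)
        s = np.sum(arr.m * (arr.counts - u * mu0C * e))
        g = -np.sum(arr.m**2 * u * mu0C * e)
        return s, g

    b = float(init)
    lo, hi = None, None  # bracket: score(lo) > 0 > score(hi)
    for _ in range(max_iter):
        s, g = score_and_grad(b)
        if abs(s) < 1e-10 * (1.0 + abs(np.sum(arr.m * arr.counts))):
            return b
        if s > 0:
            lo = b
        else:
            hi = b
        step = -s / g if g < 0 else np.sign(s)
        b_new = b + step
        if lo is not None and hi is not None and not (lo < b_new < hi):
            b_new = 0.5 * (lo + hi)
        elif abs(step) > 5.0:
            b_new = b + 5.0 * np.sign(step)
        if abs(b_new - b) < tol * (1.0 + abs(b)):
            return b_new
        b = b_new
    raise RuntimeError(
        f"beta update did not converge: last beta={b:.6g}, score={score_and_grad(b)[0]:.3g}"
    )


def _theta_objective(theta: float, Eu: np.ndarray, Elog: np.ndarray) -> float:
    inv = 1.0 / theta
    return float(
        np.sum((inv - 1.0) * Elog - Eu * inv)
        - Eu.size * (special.gammaln(inv) + inv * np.log(theta))
    )


_THETA_LO, _THETA_HI = 1e-6, 50.0


def update_theta(event_counts, frailty_means, frailty_logmeans, theta_floor: float = 1e-4) -> float:
    """Maximize the expected gamma-frailty log-likelihood term over ``theta``.

    Bounded Brent search on ``log theta`` in ``[log 1e-6, log 50]``; a
    maximizer below ``theta_floor`` is mapped to 0 (Poisson submodel).
    """
    Eu = np.asarray(frailty_means, dtype=float)
    Elog = np.asarray(frailty_logmeans, dtype=float)
    if not np.isfinite(theta_floor):
        return 0.0
    res = optimize.minimize_scalar(
        lambda lt: -_theta_objective(np.exp(lt), Eu, Elog),
        bounds=(np.log(_THETA_LO), np.log(_THETA_HI)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    theta = float(np.exp(res.x))
    return 0.0 if theta < theta_floor else theta


def _loglik_arrays(arr: _Arrays, beta: float, theta: float, dmu0: np.ndarray) -> float:
    """Marginal log-likelihood of the observed paths at ``(beta, theta, dmu0)``."""
    with np.errstate(divide="ignore"):
        ev_term = float(np.sum(np.log(dmu0[arr.event_jump_idx]))) + beta * float(np.sum(arr.counts * arr.m))
    mu_C = arr.mu0_at_C(dmu0) * np.exp(beta * arr.m)
    n_i = arr.counts
    if theta < 1e-10:
        return ev_term - float(np.sum(mu_C))
    inv = 1.0 / theta
    mix = (
        special.gammaln(inv + n_i)
        - special.gammaln(inv)
        - inv * np.log1p(theta * mu_C)
        - n_i * (np.log1p(theta * mu_C) - np.log(theta))
    )
    return ev_term + float(np.sum(mix))


def marginal_loglik(fit: FrailtyFit, data: Sequence[RecurrentData]) -> float:
    """Recompute the marginal log-likelihood of ``data`` under a fitted model."""
    arr = _Arrays(list(data))
    dmu0 = np.zeros_like(arr.s)
    pos = np.searchsorted(fit.baseline_times, arr.s)
    ok = (pos < fit.baseline_times.size) & np.isclose(fit.baseline_times[np.minimum(pos, fit.baseline_times.size - 1)], arr.s)
    dmu0[ok] = fit.baseline_increments[pos[ok]]
    return _loglik_arrays(arr, fit.beta, fit.theta, dmu0)


def _inner_baseline_beta(arr: _Arrays, u: np.ndarray, beta: float, max_cycles: int, tol: float) -> tuple[float, np.ndarray]:
    """Alternate Breslow baseline and beta score until the profile stabilizes."""
    for _ in range(max_cycles):
        _, dmu0 = update_baseline(arr, beta, u)
        beta_new = update_beta(arr, u, (arr.s, dmu0), init=beta)
        if abs(beta_new - beta) < tol * (1.0 + abs(beta)):
            beta = beta_new
            break
        beta = beta_new
    _, dmu0 = update_baseline(arr, beta, u)
    return beta, dmu0


def _moment_theta(counts: np.ndarray) -> float:
    mean = counts.mean()
    if mean <= 0:
        return 0.01
    return max(0.01, (counts.var() - mean) / mean**2)


def fit_em(data: Sequence[RecurrentData], config: EMConfig | None = None) -> FrailtyFit:
    """Fit ``Theta = (beta, theta, mu0)`` by EM.

    Alternates the closed-form gamma E-step with M-step updates of the
    baseline/beta profile and the frailty variance until the maximum
    relative parameter change drops below ``config.tol``.  The marginal
    log-likelihood is tracked per iteration and is non-decreasing up to
    numerical tolerance.
    """
    config = config or EMConfig()
    data = list(data)
    arr = _Arrays(data)
    if arr.s.size == 0:
        raise ValueError("cannot fit: no events in dataset")

    # Poisson initialization for beta (theta = 0, unit frailties)
    ones = np.ones(arr.n)
    beta = config.init_beta if config.init_beta is not None else 0.0
    beta, dmu0 = _inner_baseline_beta(arr, ones, beta, max_cycles=200, tol=1e-10)
    if not np.isfinite(config.theta_floor):
        theta = 0.0
    elif config.init_theta is not None:
        theta = config.init_theta
    else:
        theta = _moment_theta(arr.counts)

    u = ones
    loglik_path = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        mu_C = arr.mu0_at_C(dmu0) * np.exp(beta * arr.m)
        if theta > 0:
            u = estep_frailty_mean(arr.counts, theta, mu_C)
            elog = estep_frailty_logmean(arr.counts, theta, mu_C)
        else:
            u = ones
            elog = np.zeros(arr.n)

        beta_new, dmu0_new = _inner_baseline_beta(arr, u, beta, config.inner_max_cycles, tol=0.1 * config.tol)
        theta_new = update_theta(arr.counts, u, elog, config.theta_floor) if theta > 0 else 0.0

        mu0_tau_old = float(np.sum(dmu0))
        mu0_tau_new = float(np.sum(dmu0_new))
        delta = max(
            abs(beta_new - beta) / (1.0 + abs(beta)),
            abs(theta_new - theta) / (1.0 + abs(theta)),
            abs(mu0_tau_new - mu0_tau_old) / (1.0 + mu0_tau_old),
        )
        beta, dmu0, theta = beta_new, dmu0_new, theta_new
        loglik_path.append(_loglik_arrays(arr, beta, theta, dmu0))
        if delta < config.tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"EM did not converge in {config.max_iter} iterations", RuntimeWarning)
        logger.warning("EM not converged: beta=%.6g theta=%.6g iters=%d", beta, theta, it)

    mu_C = arr.mu0_at_C(dmu0) * np.exp(beta * arr.m)
    u = estep_frailty_mean(arr.counts, theta, mu_C) if theta > 0 else ones
    return FrailtyFit(
        beta=float(beta),
        theta=float(theta),
        baseline_times=arr.s,
        baseline_increments=dmu0,
        posterior_frailty_means=np.asarray(u, dtype=float),
        n_iter=it,
        converged=converged,
        marginal_loglik=loglik_path[-1],
        tau=float(arr.tau),
        loglik_path=np.asarray(loglik_path),
    )
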