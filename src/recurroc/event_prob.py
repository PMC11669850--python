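"""Marginal event-count probabilities under the gamma-frailty mixed Poisson model.

Conditional on the frailty ``u`` and marker ``m``, the count process is
Poisson with mean ``u * mu(t)`` where ``mu(t) = mu0(t) * exp(beta * m)``.
With a gamma frailty of mean 1 and variance ``theta``, the marginal count at
time ``t`` is negative binomial:

    Pr(N(t) = j | m) = Gamma(j + 1/theta) / (j! Gamma(1/theta))
                       * (theta*mu)^j / (1 + theta*mu)^(j + 1/theta).

All evaluation is done on the log scale; ``theta`` below ``1e-10`` falls back
to the Poisson mass.  Tail probabilities use the exact complement
``1 - sum_{j<r} f_j`` so no truncation constant enters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import special

__all__ = ["RateParams", "count_pmf", "tail_prob", "nb_pmf", "nb_tail"]

_THETA_POISSON = 1e-10
_LOG_UNDERFLOW = -745.0


@dataclass(frozen=True)
class RateParams:
    """Rate-model parameters: log rate ratio, frailty variance, baseline mean."""

    beta: float
    theta: float
    mu0_at: Callable[[float], float]

    def mean_at(self, t: float, m) -> np.ndarray:
        """Cumulative mean ``mu(t | m) = mu0(t) * exp(beta * m)``."""
        return np.asarray(self.mu0_at(t)) * np.exp(self.beta * np.asarray(m, dtype=float))


def nb_pmf(j, mu, theta: float) -> np.ndarray:
    """Negative-binomial mass at count ``j`` for mean ``mu``, dispersion ``theta``.

    Broadcasts over ``j`` and ``mu``; reduces to the Poisson mass as
    ``theta -> 0``.
    """
    j = np.asarray(j)
    if np.any(j < 0):
        raise ValueError("count j must be non-negative")
    mu = np.asarray(mu, dtype=float)
    j = j.astype(float)
    if theta < _THETA_POISSON:
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.where(mu > 0, j * np.log(mu), np.where(j == 0, 0.0, -np.inf)) - mu - special.gammaln(j + 1)
    else:
        inv = 1.0 / theta
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = (
                special.gammaln(j + inv)
                - special.gammaln(j + 1)
                - special.gammaln(inv)
                + np.where(mu > 0, j * np.log(theta * mu), np.where(j == 0, 0.0, -np.inf))
                - (j + inv) * np.log1p(theta * mu)
            )
    return np.exp(np.maximum(logp, _LOG_UNDERFLOW))


def nb_tail(r: int, mu, theta: float) -> np.ndarray:
    """``Pr(N >= r)`` via the complement of the partial pmf sum."""
    if r < 1:
        raise ValueError("r must be >= 1")
    js = np.arange(r)
    mu = np.asarray(mu, dtype=float)
    pm = nb_pmf(js, mu[..., None], theta)
    return np.clip(1.0 - pm.sum(axis=-1), 0.0, 1.0)


def count_pmf(j: int, t: float, m, params: RateParams) -> np.ndarray:
    """``Pr(N(t) = j | M = m)`` under the fitted/specified rate model."""
    return nb_pmf(j, params.mean_at(t, m), params.theta)


def tail_prob(r: int, t: float, m, params: RateParams) -> np.ndarray:
    """``Pr(N(t) >= r | M = m)``: the case probability at horizon ``t``."""
    return nb_tail(r, params.mean_at(t, m), params.theta)
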