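"""Recurrent-event data generator with latent truth retained.

Subjects are i.i.d.: marker ``M ~ N(0,1)``; frailty ``u`` gamma or lognormal
with mean 1 and variance ``theta``; given ``(u, M)`` the event process on
``[0, tau]`` is Poisson with cumulative intensity
``u * Lambda0(t) * exp(beta1 * M)`` and ``Lambda0(t) = v * t``.  Censoring
follows one of three scenarios:

- ``complete``: ``C = tau`` for everyone;
- ``independent_uniform``: ``C = min(U, tau)`` with ``U ~ Uniform[0, b]``;
  the default upper bound ``b = tau`` gives uniform censoring over the whole
  window, while ``b = tau / p`` calibrates the fraction of subjects censored
  before ``tau`` to ``p`` (e.g. ``b = 10 tau`` for ~10% censoring);
- ``covariate_dependent``: ``C ~ Uniform[1, tau+1]`` if ``M > 0`` else
  ``Exponential(1) + 1``, truncated at ``tau`` (``M = 0`` uses the first
  branch; the event has probability zero).

The full (uncensored) event list and the frailty draw are kept per subject,
so "true" case status ``1{N(t) >= r}`` can be evaluated on the latent
process — the observed record is its prefix up to ``C``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .data_model import RecurrentData

__all__ = [
    "DGPSpec",
    "SimulatedDataset",
    "draw_frailty",
    "simulate_subject",
    "draw_censoring",
    "simulate_dataset",
]

CENSORING_SCENARIOS = ("complete", "independent_uniform", "covariate_dependent")
FRAILTY_FAMILIES = ("gamma", "lognormal")


@dataclass(frozen=True)
class DGPSpec:
    """Generative specification mirroring the simulation-study conditions."""

    n: int = 500
    beta1: float = 0.5
    theta: float = 0.5
    frailty_family: str = "gamma"
    baseline_slope: float = 0.5  # v in Lambda0(t) = v * t
    tau: float = 5.0
    censoring: str = "complete"
    censor_upper: float | None = None  # b for Uniform[0, b] independent censoring
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.baseline_slope <= 0 or self.tau <= 0:
            raise ValueError("baseline slope and tau must be positive")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.frailty_family not in FRAILTY_FAMILIES:
            raise ValueError(f"unknown frailty family {self.frailty_family!r}")
        if self.censoring not in CENSORING_SCENARIOS:
            raise ValueError(f"unknown censoring scenario {self.censoring!r}")

    def with_seed(self, seed: int) -> "DGPSpec":
        return replace(self, seed=int(seed))


@dataclass
class SimulatedDataset:
    """Observed records plus the latent truth they were generated from."""

    observed: list[RecurrentData]
    latent_frailties: np.ndarray
    full_event_times: list[np.ndarray]
    markers: np.ndarray
    spec: DGPSpec

    def true_class(self, r: int, t: float) -> np.ndarray:
        """``1{N(t) >= r}`` evaluated on the latent (uncensored) process."""
        counts = np.array([np.searchsorted(ft, t, side="right") for ft in self.full_event_times])
        return counts >= r

    def true_counts(self, t: float) -> np.ndarray:
        return np.array([np.searchsorted(ft, t, side="right") for ft in self.full_event_times])


def draw_frailty(family: str, theta: float, rng: np.random.Generator, size=None):
    """Frailty draw(s) with mean 1 and variance ``theta``.

    gamma: shape ``1/theta``, scale ``theta``; lognormal: log-scale variance
    ``sigma^2 = log(1 + theta)`` and log-scale mean ``-sigma^2/2``.
    ``theta = 0`` returns the degenerate value 1.
    """
    if family not in FRAILTY_FAMILIES:
        raise ValueError(f"unknown frailty family {family!r}")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if theta == 0:
        out = np.ones(size) if size is not None else 1.0
        return out
    if family == "gamma":
        return rng.gamma(1.0 / theta, theta, size=size)
    s2 = np.log1p(theta)
    return rng.lognormal(-s2 / 2.0, np.sqrt(s2), size=size)


def simulate_subject(spec: DGPSpec, m: float, u: float, rng: np.random.Generator) -> np.ndarray:
    """Event times on ``[0, tau]`` given the subject's frailty and marker.

    With the linear baseline the process is homogeneous given ``(u, m)``:
    inter-event gaps are exponential with rate
    ``u * v * exp(beta1 * m)`` and are accumulated until ``tau`` is passed.
    """
    rate = u * spec.baseline_slope * np.exp(spec.beta1 * m)
    if rate <= 0:
        return np.empty(0)
    times = []
    t = 0.0
    # draw gaps in blocks to limit generator calls
    block = max(8, int(rate * spec.tau) + 4)
    while True:
        gaps = rng.exponential(1.0 / rate, size=block)
        for g in gaps:
            t += g
            if t > spec.tau:
                return np.asarray(times)
            times.append(t)


def draw_censoring(
    scenario: str, m: float, tau: float, rng: np.random.Generator, censor_upper: float | None = None
) -> float:
    """Censoring time for one subject under the given scenario."""
    if scenario == "complete":
        return float(tau)
    if scenario == "independent_uniform":
        b = tau if censor_upper is None else float(censor_upper)
        return float(min(rng.uniform(0.0, b), tau))
    if scenario == "covariate_dependent":
        if m >= 0:
            c = rng.uniform(1.0, tau + 1.0)
        else:
            c = rng.exponential(1.0) + 1.0
        return float(min(c, tau))
    raise ValueError(f"unknown censoring scenario {scenario!r}")


def simulate_dataset(spec: DGPSpec) -> SimulatedDataset:
    """Generate one dataset; deterministic given ``spec.seed``.

    Each subject draws from its own counter-derived substream, so the first
    ``k`` subjects are identical across runs that differ only in ``n``.
    """
    markers = np.empty(spec.n)
    frailties = np.empty(spec.n)
    full = []
    observed = []
    for i in range(spec.n):
        rng = np.random.default_rng([spec.seed, i])
        m = float(rng.standard_normal())
        u = float(draw_frailty(spec.frailty_family, spec.theta, rng))
        events = simulate_subject(spec, m, u, rng)
        c = draw_censoring(spec.censoring, m, spec.tau, rng, spec.censor_upper)
        markers[i] = m
        frailties[i] = u
        full.append(events)
        observed.append(
            RecurrentData(
                subject_id=i,
                marker=m,
                censor_time=c,
                event_times=events[events <= c],
                tau=spec.tau,
            )
        )
    return SimulatedDataset(
        observed=observed,
        latent_frailties=frailties,
        full_event_times=full,
        markers=markers,
        spec=spec,
    )
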