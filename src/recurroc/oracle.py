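"""Population ("true") accuracy values under a fully specified generative model.

Under the study design the marker is standard normal and the case
probability at horizon ``t`` is

    q(m) = Pr(N(t) >= r | M = m),

a negative-binomial tail for gamma frailty (closed form) or a 1-D mixture
integral over the lognormal frailty density.  All population accuracy
quantities are then marker integrals against the standard normal law,
evaluated by Gauss-Legendre quadrature on ``[-8, 8]`` (normal mass outside
is below 1.3e-15):

    marginal risk  p   = E[q(M)]
    TPF(c)/FPF(c)      = tail integrals of q(M), 1-q(M)
    AUC                = Pr(M_case > M_control)
                       = E[q(M) H_control(M)] / (p (1-p))
    PPV(v), NPV(v)     with the normal quantile as threshold.

A brute-force Monte-Carlo oracle (latent counts at huge ``n``) provides an
independent cross-check of the quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import integrate, stats

from .data_model import RiskDefinition
from .event_prob import nb_tail
from .simulate import DGPSpec

__all__ = ["OracleValues", "true_case_prob", "true_accuracy", "mc_oracle"]

_M_LIM = 8.0
_N_NODES = 801


@dataclass
class OracleValues:
    """Population accuracy quantities for one (DGP, risk) pair."""

    risk: RiskDefinition
    marginal_risk: float
    auc: float
    roc: Callable[[float], float]
    ppv: Callable[[float], float]
    npv: Callable[[float], float]
    se: dict | None = None  # Monte-Carlo oracle only


def _lognormal_tail(r: int, mu, theta: float) -> np.ndarray:
    """``Pr(N >= r)`` mixing the Poisson tail over a lognormal frailty.

    Gauss-Hermite in ``log u`` (the smooth, rapidly decaying direction);
    180 nodes give absolute accuracy well below 1e-10 for the moderate
    variances used here.
    """
    s2 = np.log1p(theta)
    nodes, weights = np.polynomial.hermite_e.hermegauss(180)
    u = np.exp(-s2 / 2.0 + np.sqrt(s2) * nodes)  # u = exp(mu_log + sigma*z)
    w = weights / np.sqrt(2.0 * np.pi)
    mu = np.asarray(mu, dtype=float)
    lam = mu[..., None] * u
    tail = stats.poisson.sf(r - 1, lam)
    out = (tail * w).sum(axis=-1)
    return out if out.ndim else float(out)


def true_case_prob(m, spec: DGPSpec, risk: RiskDefinition) -> np.ndarray:
    """Population case probability ``q(m) = Pr(N(t) >= r | M = m)``."""
    mu = spec.baseline_slope * risk.t * np.exp(spec.beta1 * np.asarray(m, dtype=float))
    if spec.theta == 0 or spec.frailty_family == "gamma":
        return nb_tail(risk.r, mu, spec.theta)
    return _lognormal_tail(risk.r, mu, spec.theta)


def _gauss_legendre(a: float, b: float, n: int = _N_NODES):
    x, w = np.polynomial.legendre.leggauss(n)
    mid, half = (a + b) / 2.0, (b - a) / 2.0
    return mid + half * x, half * w


def true_accuracy(spec: DGPSpec, risk: RiskDefinition, n_nodes: int = _N_NODES) -> OracleValues:
    """Population accuracy quantities by quadrature over the marker law."""
    nodes, w = _gauss_legendre(-_M_LIM, _M_LIM, n_nodes)
    phi = stats.norm.pdf(nodes)
    q = true_case_prob(nodes, spec, risk)
    p = float(np.sum(q * phi * w))
    if not 0 < p < 1:
        raise ValueError("degenerate marginal risk; check the generative spec")

    def upper_int(c: float, control: bool) -> float:
        # integral over (c, M_LIM] of q*phi (cases) or (1-q)*phi (controls)
        if c >= _M_LIM:
            return 0.0
        x, wx = _gauss_legendre(c, _M_LIM, 301)
        qx = true_case_prob(x, spec, risk)
        return float(np.sum(((1.0 - qx) if control else qx) * stats.norm.pdf(x) * wx))

    def tpf(c: float) -> float:
        return upper_int(c, control=False) / p

    def fpf(c: float) -> float:
        return upper_int(c, control=True) / (1.0 - p)

    def roc(p0):
        def _one(p0_scalar: float) -> float:
            if p0_scalar <= 0:
                return 0.0
            if p0_scalar >= 1:
                return 1.0
            lo, hi = -_M_LIM, _M_LIM  # fpf(lo)=1, fpf(hi)=0; fpf decreasing in c
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if fpf(mid) > p0_scalar:
                    lo = mid
                else:
                    hi = mid
                if hi - lo < 1e-10:
                    break
            return tpf(0.5 * (lo + hi))

        arr = np.asarray(p0, dtype=float)
        if arr.ndim == 0:
            return _one(float(arr))
        return np.array([_one(x) for x in arr])

    # AUC = E[q(M) H_ctrl(M)] / (p (1-p)) with H_ctrl the control sub-CDF,
    # built on a fine grid by cumulative Simpson integration
    grid = np.linspace(-_M_LIM, _M_LIM, 8193)
    qg = true_case_prob(grid, spec, risk)
    dens_ctrl = (1.0 - qg) * stats.norm.pdf(grid)
    H_ctrl = integrate.cumulative_simpson(dens_ctrl, x=grid, initial=0.0)
    dens_case = qg * stats.norm.pdf(grid)
    auc = float(integrate.simpson(dens_case * H_ctrl, x=grid) / (p * (1.0 - p)))

    def ppv(v):
        def _one(vv: float) -> float:
            thr = stats.norm.ppf(vv)
            return upper_int(thr, control=False) / (1.0 - vv)

        arr = np.asarray(v, dtype=float)
        return _one(float(arr)) if arr.ndim == 0 else np.array([_one(x) for x in arr])

    def npv(v):
        def _one(vv: float) -> float:
            thr = stats.norm.ppf(vv)
            x, wx = _gauss_legendre(-_M_LIM, thr, 301)
            qx = true_case_prob(x, spec, risk)
            return float(np.sum((1.0 - qx) * stats.norm.pdf(x) * wx)) / vv

        arr = np.asarray(v, dtype=float)
        return _one(float(arr)) if arr.ndim == 0 else np.array([_one(x) for x in arr])

    return OracleValues(risk=risk, marginal_risk=p, auc=auc, roc=roc, ppv=ppv, npv=npv)


def mc_oracle(spec: DGPSpec, risk: RiskDefinition, n_large: int = 10**6, seed: int = 0) -> OracleValues:
    """Brute-force Monte-Carlo oracle from latent counts at large ``n``.

    Classes come from the uncensored count at the horizon, accuracy from
    empirical ranks and quantiles.  Reported standard errors: binomial for
    the marginal risk, Hanley-McNeil for the AUC.
    """
    rng = np.random.default_rng(seed)
    m = rng.standard_normal(n_large)
    from .simulate import draw_frailty

    u = draw_frailty(spec.frailty_family, spec.theta, rng, size=n_large)
    lam = u * spec.baseline_slope * risk.t * np.exp(spec.beta1 * m)
    counts = rng.poisson(lam)
    case = counts >= risk.r
    p = float(case.mean())
    n1, n0 = int(case.sum()), int((~case).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("Monte-Carlo oracle produced a degenerate class split")
    ranks = stats.rankdata(m)
    auc = float((ranks[case].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))
    se_auc = float(np.sqrt(auc * (1 - auc) * (1 + (n1 - 1) * (auc / (2 - auc) - auc**2) / (auc * (1 - auc)) + (n0 - 1) * (2 * auc**2 / (1 + auc) - auc**2) / (auc * (1 - auc))) / (n1 * n0)))

    m_case_sorted = np.sort(m[case])
    m_ctrl_sorted = np.sort(m[~case])

    def tpf(c: float) -> float:
        return 1.0 - np.searchsorted(m_case_sorted, c, side="right") / n1

    def fpf(c: float) -> float:
        return 1.0 - np.searchsorted(m_ctrl_sorted, c, side="right") / n0

    def roc(p0):
        def _one(pp: float) -> float:
            if pp <= 0:
                return 0.0
            if pp >= 1:
                return 1.0
            c = np.quantile(m_ctrl_sorted, 1.0 - pp)
            return tpf(c)

        arr = np.asarray(p0, dtype=float)
        return _one(float(arr)) if arr.ndim == 0 else np.array([_one(x) for x in arr])

    m_sorted = np.sort(m)

    def ppv(v):
        def _one(vv: float) -> float:
            thr = np.quantile(m_sorted, vv)
            sel = m > thr
            return float(case[sel].mean())

        arr = np.asarray(v, dtype=float)
        return _one(float(arr)) if arr.ndim == 0 else np.array([_one(x) for x in arr])

    def npv(v):
        def _one(vv: float) -> float:
            thr = np.quantile(m_sorted, vv)
            sel = m <= thr
            return float((~case[sel]).mean())

        arr = np.asarray(v, dtype=float)
        return _one(float(arr)) if arr.ndim == 0 else np.array([_one(x) for x in arr])

    se = {"marginal_risk": float(np.sqrt(p * (1 - p) / n_large)), "auc": se_auc}
    return OracleValues(risk=risk, marginal_risk=p, auc=auc, roc=roc, ppv=ppv, npv=npv, se=se)
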