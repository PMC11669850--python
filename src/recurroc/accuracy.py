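"""Plug-in accuracy estimators: TPF/FPF, ROC/AUC, PPV/NPV curves.

Each subject contributes a model-based case probability
``q_i = Pr(N(t) >= r | m_i)`` from the fitted frailty model; classification
fractions are weighted indicator sums over the observed marker sample:

    TPF(c) = sum_i q_i 1(m_i > c) / sum_i q_i
    FPF(c) = sum_i (1-q_i) 1(m_i > c) / sum_i (1-q_i)
    PPV(v) = (1/n) sum_i q_i 1(m_i > G^{-1}(v)) / (1 - v)
    NPV(v) = (1/n) sum_i (1-q_i) 1(m_i <= G^{-1}(v)) / v

with ``G^{-1}`` the left-continuous empirical marker quantile.  The PPV
indicator uses ``>`` and the NPV indicator ``<=`` so positives and negatives
partition the sample, making the conservation identity
``(1-v) PPV(v) + v (1-NPV(v)) = Pr-hat(N(t) >= r)`` exact whenever the
empirical mass at or below the quantile equals ``v``.

The ROC curve is traced at all distinct marker thresholds (plus the two
trivial endpoints), read at a false-positive grid by linear interpolation
in FPF, and summarized by the trapezoidal AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import EmpiricalCDF, RiskDefinition, empirical_cdf
from .event_prob import tail_prob

__all__ = [
    "AccuracyCurves",
    "case_probabilities",
    "tpf_fpf",
    "weighted_tpf_fpf",
    "roc_points",
    "roc_curve",
    "ppv_npv",
    "ppv_inverse",
    "evaluate_accuracy",
]

DEFAULT_V_GRID = np.round(np.arange(0.01, 1.0, 0.01), 10)


@dataclass
class AccuracyCurves:
    """Accuracy summaries of a marker for a given risk definition."""

    risk: RiskDefinition
    thresholds: np.ndarray = field(default_factory=lambda: np.empty(0))
    tpf: np.ndarray = field(default_factory=lambda: np.empty(0))
    fpf: np.ndarray = field(default_factory=lambda: np.empty(0))
    roc_grid: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    auc: float = np.nan
    v_grid: np.ndarray = field(default_factory=lambda: np.empty(0))
    ppv: np.ndarray = field(default_factory=lambda: np.empty(0))
    npv: np.ndarray = field(default_factory=lambda: np.empty(0))
    marginal_risk: float = np.nan

    def roc(self, p0) -> np.ndarray:
        """ROC value at false-positive fraction ``p0`` (interpolated)."""
        return np.interp(p0, self.roc_grid[:, 0], self.roc_grid[:, 1])

    def to_frames(self):
        import pandas as pd

        roc_df = pd.DataFrame({"fpf": self.fpf, "tpf": self.tpf, "threshold": self.thresholds})
        pv_df = pd.DataFrame({"v": self.v_grid, "ppv": self.ppv, "npv": self.npv})
        return roc_df, pv_df

    def plot(self, path=None):
        """Two-panel figure: ROC curve and PPV/NPV curves with the
        marginal-risk benchmark line."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        ax1.plot(self.fpf, self.tpf, "-")
        ax1.plot([0, 1], [0, 1], ":", color="gray")
        ax1.set_xlabel("FPF")
        ax1.set_ylabel("TPF")
        ax1.set_title(f"ROC, AUC={self.auc:.3f}")
        ax2.plot(self.v_grid, self.ppv, label="PPV")
        ax2.plot(self.v_grid, self.npv, label="NPV")
        ax2.axhline(self.marginal_risk, ls=":", color="gray", label="marginal risk")
        ax2.set_xlabel("v (marker quantile)")
        ax2.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path)
            plt.close(fig)
        return fig


def case_probabilities(risk: RiskDefinition, fit, markers) -> np.ndarray:
    """Model-based case probabilities ``q_i = Pr(N(t) >= r | m_i)``."""
    return np.asarray(tail_prob(risk.r, risk.t, np.asarray(markers, dtype=float), fit.rate_params()))


def weighted_tpf_fpf(markers, q, c: float) -> tuple[float, float]:
    """TPF/FPF at threshold ``c`` from case weights ``q`` (strict ``m > c``)."""
    markers = np.asarray(markers, dtype=float)
    q = np.asarray(q, dtype=float)
    sq, sq1 = q.sum(), (1.0 - q).sum()
    if sq <= 0:
        raise ValueError("no case probability mass: TPF undefined")
    if sq1 <= 0:
        raise ValueError("no control probability mass: FPF undefined")
    ind = markers > c
    return float(q[ind].sum() / sq), float((1.0 - q)[ind].sum() / sq1)


def tpf_fpf(c: float, risk: RiskDefinition, fit, markers) -> tuple[float, float]:
    """TPF/FPF of the marker at threshold ``c`` under the fitted model."""
    return weighted_tpf_fpf(markers, case_probabilities(risk, fit, markers), c)


def roc_points(markers, q) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(thresholds, fpf, tpf) at all distinct marker values plus +-inf.

    Returned in increasing-FPF order (thresholds decreasing), starting at
    (0, 0) and ending at (1, 1).
    """
    markers = np.asarray(markers, dtype=float)
    q = np.asarray(q, dtype=float)
    sq, sq1 = q.sum(), (1.0 - q).sum()
    if sq <= 0 or sq1 <= 0:
        raise ValueError("degenerate case-probability mass")
    order = np.argsort(markers)[::-1]  # highest marker first
    mq = q[order]
    m_sorted = markers[order]
    cum_q = np.cumsum(mq)
    cum_1q = np.cumsum(1.0 - mq)
    # threshold just below each distinct marker value includes that value;
    # keep the last index of each run of ties
    distinct_last = np.nonzero(np.diff(m_sorted, append=-np.inf))[0]
    tpf = np.clip(np.concatenate([[0.0], cum_q[distinct_last] / sq]), 0.0, 1.0)
    fpf = np.clip(np.concatenate([[0.0], cum_1q[distinct_last] / sq1]), 0.0, 1.0)
    tpf[-1] = 1.0  # cumulative sums end at the totals exactly
    fpf[-1] = 1.0
    thresholds = np.concatenate([[np.inf], m_sorted[distinct_last]])
    return thresholds, fpf, tpf


def _auc_trapezoid(fpf: np.ndarray, tpf: np.ndarray) -> float:
    return float(np.trapezoid(tpf, fpf))


def roc_curve(risk: RiskDefinition, fit, markers, p0_grid=None) -> AccuracyCurves:
    """ROC curve and trapezoidal AUC from the fitted model and marker sample."""
    q = case_probabilities(risk, fit, markers)
    return roc_curve_from_weights(risk, markers, q, p0_grid)


def roc_curve_from_weights(risk: RiskDefinition, markers, q, p0_grid=None) -> AccuracyCurves:
    if p0_grid is None:
        p0_grid = DEFAULT_V_GRID
    p0_grid = np.asarray(p0_grid, dtype=float)
    thresholds, fpf, tpf = roc_points(markers, q)
    # collapse duplicate FPF values to the best TPF so interpolation is
    # single valued along vertical ROC segments
    uniq_fpf, inv = np.unique(fpf, return_inverse=True)
    best_tpf = np.zeros_like(uniq_fpf)
    np.maximum.at(best_tpf, inv, tpf)
    roc_vals = np.interp(p0_grid, uniq_fpf, best_tpf)
    curves = AccuracyCurves(
        risk=risk,
        thresholds=thresholds,
        tpf=tpf,
        fpf=fpf,
        roc_grid=np.column_stack([p0_grid, roc_vals]),
        auc=_auc_trapezoid(fpf, tpf),
        marginal_risk=float(np.mean(q)),
    )
    return curves


def ppv_npv(v_grid, risk: RiskDefinition, fit, markers) -> AccuracyCurves:
    """Predictive-value curves on the marker-quantile grid ``v_grid``."""
    q = case_probabilities(risk, fit, markers)
    return ppv_npv_from_weights(v_grid, risk, markers, q)


def ppv_npv_from_weights(v_grid, risk: RiskDefinition, markers, q) -> AccuracyCurves:
    markers = np.asarray(markers, dtype=float)
    q = np.asarray(q, dtype=float)
    v_grid = np.asarray(v_grid, dtype=float)
    if np.any((v_grid <= 0) | (v_grid >= 1)):
        raise ValueError("v grid must lie strictly inside (0, 1)")
    g = empirical_cdf(markers)
    n = markers.size
    cuts = g.quantile(v_grid)
    pos = markers[None, :] > np.asarray(cuts)[:, None]
    ppv = (pos * q[None, :]).sum(axis=1) / n / (1.0 - v_grid)
    npv = ((~pos) * (1.0 - q)[None, :]).sum(axis=1) / n / v_grid
    return AccuracyCurves(
        risk=risk,
        v_grid=v_grid,
        ppv=ppv,
        npv=npv,
        marginal_risk=float(np.mean(q)),
    )


def ppv_inverse(p: float, risk: RiskDefinition, fit, markers, v_grid=None) -> tuple[float, bool]:
    """Smallest grid ``v`` whose PPV reaches ``p``.

    Returns ``(v, attainable)``; when ``p`` exceeds the maximum PPV on the
    grid the flag is False and ``v`` is NaN.
    """
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    if v_grid is None:
        v_grid = DEFAULT_V_GRID
    curves = ppv_npv(v_grid, risk, fit, markers)
    ok = np.nonzero(curves.ppv >= p)[0]
    if ok.size == 0:
        return float("nan"), False
    return float(curves.v_grid[ok[0]]), True


def evaluate_accuracy(fit, markers, risk: RiskDefinition, v_grid=None, p0_grid=None) -> AccuracyCurves:
    """Full accuracy summary (ROC/AUC and PPV/NPV) in one pass."""
    if v_grid is None:
        v_grid = DEFAULT_V_GRID
    q = case_probabilities(risk, fit, markers)
    roc = roc_curve_from_weights(risk, markers, q, p0_grid)
    pv = ppv_npv_from_weights(v_grid, risk, markers, q)
    roc.v_grid, roc.ppv, roc.npv = pv.v_grid, pv.ppv, pv.npv
    return roc
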