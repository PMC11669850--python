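"""Bootstrap inference and the simulation-study harness.

``bootstrap_accuracy`` resamples subjects with replacement, refits the EM and
recomputes the requested accuracy estimands; the SE is the standard deviation
over resamples and the confidence interval is the percentile interval.

``run_simulation_study`` repeats simulate -> fit -> estimate (optionally with
a bootstrap CI per replicate) and aggregates bias, SD of the estimates, mean
bootstrap SE and coverage against the population (quadrature-oracle) truth.

``first_event_auc`` is the comparator the recurrent-event analysis is judged
against: the marker's cumulative/dynamic AUC at the horizon computed from
time-to-first-event data with inverse-probability-of-censoring weighting
(Kaplan-Meier censoring weights, via scikit-survival).  It deliberately
discards recurrences beyond the first event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .accuracy import evaluate_accuracy
from .data_model import RecurrentData, RiskDefinition
from .frailty_em import EMConfig, fit_em
from .oracle import true_accuracy
from .simulate import DGPSpec, simulate_dataset

__all__ = [
    "StudyConfig",
    "StudyResult",
    "compute_estimands",
    "bootstrap_accuracy",
    "run_simulation_study",
    "first_event_auc",
]

logger = logging.getLogger(__name__)

DEFAULT_ESTIMANDS = (
    ("AUC", None),
    ("ROC", 0.9),
    ("ROC", 0.5),
    ("ROC", 0.1),
    ("PPV", 0.1),
    ("PPV", 0.5),
    ("PPV", 0.9),
    ("NPV", 0.1),
    ("NPV", 0.5),
    ("NPV", 0.9),
)


@dataclass(frozen=True)
class StudyConfig:
    """One simulation-study cell: generative spec, risk, replication plan."""

    spec: DGPSpec
    risk: RiskDefinition
    n_replicates: int = 200
    bootstrap_B: int = 100
    ci_level: float = 0.90
    estimands: tuple = DEFAULT_ESTIMANDS
    seed: int = 0
    em: EMConfig = field(default_factory=EMConfig)

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class StudyResult:
    """Aggregated per-estimand performance, Table-style."""

    estimands: list
    truth: np.ndarray
    mean_estimate: np.ndarray
    bias: np.ndarray
    sd: np.ndarray
    mean_boot_se: np.ndarray
    coverage: np.ndarray
    n_used: int
    n_dropped: int

    def to_frame(self):
        import pandas as pd

        names = [f"{n}({a})" if a is not None else n for n, a in self.estimands]
        return pd.DataFrame(
            {
                "estimand": names,
                "True": self.truth,
                "B": self.bias,
                "SE": self.mean_boot_se,
                "SD": self.sd,
                "CP": self.coverage,
            }
        )


def _estimand_names(estimands) -> list[str]:
    return [f"{n}({a})" if a is not None else str(n) for n, a in estimands]


def compute_estimands(fit, markers, risk: RiskDefinition, estimands=DEFAULT_ESTIMANDS) -> np.ndarray:
    """Evaluate (name, argument) accuracy estimands on one fitted dataset."""
    curves = evaluate_accuracy(fit, markers, risk)
    out = []
    for name, arg in estimands:
        if name == "AUC":
            out.append(curves.auc)
        elif name == "ROC":
            out.append(float(curves.roc(arg)))
        elif name == "PPV":
            idx = int(np.argmin(np.abs(curves.v_grid - arg)))
            out.append(float(curves.ppv[idx]))
        elif name == "NPV":
            idx = int(np.argmin(np.abs(curves.v_grid - arg)))
            out.append(float(curves.npv[idx]))
        elif name == "marginal_risk":
            out.append(curves.marginal_risk)
        else:
            raise ValueError(f"unknown estimand {name!r}")
    return np.asarray(out)


def oracle_truth(spec: DGPSpec, risk: RiskDefinition, estimands=DEFAULT_ESTIMANDS) -> np.ndarray:
    """Population values of the estimands from the quadrature oracle."""
    vals = true_accuracy(spec, risk)
    out = []
    for name, arg in estimands:
        if name == "AUC":
            out.append(vals.auc)
        elif name == "ROC":
            out.append(float(vals.roc(arg)))
        elif name == "PPV":
            out.append(float(vals.ppv(arg)))
        elif name == "NPV":
            out.append(float(vals.npv(arg)))
        elif name == "marginal_risk":
            out.append(vals.marginal_risk)
        else:
            raise ValueError(f"unknown estimand {name!r}")
    return np.asarray(out)


def _fit_and_estimate(data: Sequence[RecurrentData], risk, estimands, em_config) -> np.ndarray:
    fit = fit_em(data, em_config)
    markers = np.array([d.marker for d in data])
    return compute_estimands(fit, markers, risk, estimands)


def bootstrap_accuracy(
    data: Sequence[RecurrentData],
    risk: RiskDefinition,
    B: int = 100,
    ci_level: float = 0.90,
    seed: int = 0,
    estimands=DEFAULT_ESTIMANDS,
    em_config: EMConfig | None = None,
    max_drop_frac: float = 0.10,
):
    """Subject-resampling bootstrap SEs and percentile CIs for the estimands.

    Resamples that fail to fit are dropped with a warning; more than
    ``max_drop_frac`` failures aborts.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    data = list(data)
    em_config = em_config or EMConfig()
    n = len(data)
    rng = np.random.default_rng(seed)
    rows = []
    dropped = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        sample = [data[i] for i in idx]
        try:
            rows.append(_fit_and_estimate(sample, risk, estimands, em_config))
        except Exception as exc:  # EM failure on a pathological resample
            dropped += 1
            logger.warning("bootstrap resample %d dropped: %s", b, exc)
    if dropped > max_drop_frac * B:
        raise RuntimeError(f"{dropped}/{B} bootstrap resamples failed")
    est = np.vstack(rows)
    alpha = (1.0 - ci_level) / 2.0
    se = est.std(axis=0, ddof=1)
    lo = np.quantile(est, alpha, axis=0)
    hi = np.quantile(est, 1.0 - alpha, axis=0)
    return {
        "names": _estimand_names(estimands),
        "se": se,
        "ci_low": lo,
        "ci_high": hi,
        "n_dropped": dropped,
        "resamples": est,
    }


def run_simulation_study(config: StudyConfig) -> StudyResult:
    """Replicate simulate -> fit -> estimate and aggregate performance.

    Coverage is the fraction of percentile bootstrap intervals containing the
    population truth; with ``bootstrap_B = 0`` the SE/coverage columns are
    reported as NaN.  Deterministic given ``config.seed``.
    """
    truth = oracle_truth(config.spec, config.risk, config.estimands)
    k = len(config.estimands)
    estimates, ses, covers = [], [], []
    dropped = 0
    ss = np.random.SeedSequence(config.seed)
    rep_seeds = ss.generate_state(2 * config.n_replicates).reshape(-1, 2) % (2**31)
    for rep in range(config.n_replicates):
        spec = config.spec.with_seed(int(rep_seeds[rep, 0]))
        ds = simulate_dataset(spec)
        try:
            est = _fit_and_estimate(ds.observed, config.risk, config.estimands, config.em)
        except Exception as exc:
            dropped += 1
            logger.warning("replicate %d dropped: %s", rep, exc)
            continue
        estimates.append(est)
        if config.bootstrap_B > 0:
            boot = bootstrap_accuracy(
                ds.observed,
                config.risk,
                B=config.bootstrap_B,
                ci_level=config.ci_level,
                seed=int(rep_seeds[rep, 1]),
                estimands=config.estimands,
                em_config=config.em,
            )
            ses.append(boot["se"])
            covers.append((boot["ci_low"] <= truth) & (truth <= boot["ci_high"]))
    if not estimates:
        raise RuntimeError("all replicates failed")
    est = np.vstack(estimates)
    mean_est = est.mean(axis=0)
    sd = est.std(axis=0, ddof=1) if est.shape[0] > 1 else np.full(k, np.nan)
    mean_se = np.vstack(ses).mean(axis=0) if ses else np.full(k, np.nan)
    coverage = np.vstack(covers).mean(axis=0) if covers else np.full(k, np.nan)
    return StudyResult(
        estimands=list(config.estimands),
        truth=truth,
        mean_estimate=mean_est,
        bias=mean_est - truth,
        sd=sd,
        mean_boot_se=mean_se,
        coverage=coverage,
        n_used=est.shape[0],
        n_dropped=dropped,
    )


def first_event_auc(data: Sequence[RecurrentData], t: float) -> float:
    """Crude cumulative/dynamic AUC at ``t`` from time-to-first-event data.

    Follow-up is truncated at the first event (or at censoring); the AUC is
    the IPCW cumulative/dynamic estimator with Kaplan-Meier censoring
    weights.  This is the standard single-event comparator that ignores
    recurrence information.
    """
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    data = list(data)
    times = np.array([d.event_times[0] if d.n_events else d.censor_time for d in data])
    status = np.array([d.n_events > 0 for d in data])
    markers = np.array([d.marker for d in data])
    if not np.any(status & (times <= t)):
        raise ValueError(f"no first events observed by t={t}")
    y = Surv.from_arrays(event=status, time=times)
    # evaluation time must lie strictly inside the observed follow-up range
    t_eval = min(t, times.max() * (1.0 - 1e-9))
    t_eval = max(t_eval, times.min() * (1.0 + 1e-9))
    aucs, _ = cumulative_dynamic_auc(y, y, markers, [t_eval])
    return float(aucs[0])
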