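import numpy as np
import pytest

from recurroc import RiskDefinition
from recurroc.accuracy import (
    case_probabilities,
    evaluate_accuracy,
    ppv_inverse,
    ppv_npv_from_weights,
    roc_curve_from_weights,
    roc_points,
    tpf_fpf,
    weighted_tpf_fpf,
)

RISK = RiskDefinition(r=2, t=5.0)


def brute_force_tpf_fpf(markers, q, c):
    num_t = sum(qi for mi, qi in zip(markers, q) if mi > c)
    num_f = sum(1 - qi for mi, qi in zip(markers, q) if mi > c)
    return num_t / sum(q), num_f / sum(1 - qi for qi in q)


def brute_force_auc(markers, q):
    num = den = 0.0
    for mi, qi in zip(markers, q):
        for mk, qk in zip(markers, q):
            w = qi * (1 - qk)
            num += w * (1.0 if mi > mk else 0.5 if mi == mk else 0.0)
            den += w
    return num / den


class TestTpfFpf:
    def test_hand_computed_weighted_sums(self):
        markers = [1.0, 2.0, 3.0]
        q = [0.1, 0.5, 0.9]
        tpf, fpf = weighted_tpf_fpf(markers, q, 1.5)
        assert tpf == pytest.approx((0.5 + 0.9) / 1.5)
        assert fpf == pytest.approx((0.5 + 0.1) / 1.5)
        assert (tpf, fpf) == pytest.approx(brute_force_tpf_fpf(markers, q, 1.5))

    def test_boundary_thresholds(self):
        markers = np.array([0.0, 1.0, 2.0])
        q = np.array([0.2, 0.5, 0.8])
        assert weighted_tpf_fpf(markers, q, -np.inf) == (1.0, 1.0)
        assert weighted_tpf_fpf(markers, q, np.inf) == (0.0, 0.0)

    def test_uninformative_weights_reduce_to_marker_fractions(self):
        markers = np.array([-1.0, 0.0, 0.5, 2.0])
        q = np.full(4, 0.37)
        tpf, fpf = weighted_tpf_fpf(markers, q, 0.2)
        assert tpf == pytest.approx(0.5)
        assert fpf == pytest.approx(0.5)

    def test_fit_based_wrapper(self, gamma_fit, gamma_dataset):
        m = gamma_dataset.markers
        q = case_probabilities(RISK, gamma_fit, m)
        assert tpf_fpf(0.0, RISK, gamma_fit, m) == pytest.approx(
            weighted_tpf_fpf(m, q, 0.0)
        )

    def test_degenerate_mass_rejected(self):
        with pytest.raises(ValueError):
            weighted_tpf_fpf([1.0, 2.0], [0.0, 0.0], 0.5)


class TestRoc:
    def test_uninformative_model_gives_diagonal(self):
        rng = np.random.default_rng(0)
        markers = rng.normal(size=200)
        q = np.full(200, 0.4)
        curves = roc_curve_from_weights(RISK, markers, q)
        assert curves.auc == pytest.approx(0.5, abs=1e-12)
        np.testing.assert_allclose(curves.roc([0.25, 0.5, 0.75]), [0.25, 0.5, 0.75], atol=1e-9)

    def test_perfect_separation(self):
        markers = np.array([1.0, 2.0, 3.0, 4.0])
        q = np.array([0.0, 0.0, 1.0, 1.0])
        assert roc_curve_from_weights(RISK, markers, q).auc == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_auc_equals_weighted_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        markers = np.round(rng.normal(size=n), 1)  # ties likely
        q = rng.uniform(0.05, 0.95, size=n)
        curves = roc_curve_from_weights(RISK, markers, q)
        assert curves.auc == pytest.approx(brute_force_auc(markers, q), abs=1e-12)

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(7)
        markers = rng.normal(size=50)
        q = rng.uniform(0, 1, size=50)
        a1 = roc_curve_from_weights(RISK, markers, q).auc
        a2 = roc_curve_from_weights(RISK, np.exp(3 * markers), q).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_roc_monotone_and_anchored(self, gamma_fit, gamma_dataset):
        curves = roc_curve_from_weights(
            RISK, gamma_dataset.markers, case_probabilities(RISK, gamma_fit, gamma_dataset.markers)
        )
        assert curves.fpf[0] == 0 and curves.tpf[0] == 0
        assert curves.fpf[-1] == 1 and curves.tpf[-1] == 1
        assert np.all(np.diff(curves.tpf) >= 0)
        assert np.all(np.diff(curves.fpf) >= 0)
        # informative marker: TPF dominates FPF pointwise
        assert np.all(curves.tpf >= curves.fpf - 1e-12)


class TestPpvNpv:
    def test_constant_risk_gives_flat_curves(self):
        rng = np.random.default_rng(1)
        markers = rng.normal(size=200)  # continuous: no ties
        q = np.full(200, 0.3)
        v = np.arange(0.05, 1.0, 0.05).round(10)  # v*n integral
        curves = ppv_npv_from_weights(v, RISK, markers, q)
        np.testing.assert_allclose(curves.ppv, 0.3, atol=1e-12)
        np.testing.assert_allclose(curves.npv, 0.7, atol=1e-12)

    def test_small_v_approaches_marginal_risk(self, gamma_fit, gamma_dataset):
        m = gamma_dataset.markers
        q = case_probabilities(RISK, gamma_fit, m)
        curves = ppv_npv_from_weights(np.array([1.0 / len(m)]), RISK, m, q)
        # only the minimum marker is excluded from the positives
        expected = (q.sum() - q[np.argmin(m)]) / (len(m) - 1)
        assert curves.ppv[0] == pytest.approx(expected, abs=1e-12)

    def test_conservation_identity(self, gamma_fit, gamma_dataset):
        m = gamma_dataset.markers  # n=300, continuous markers
        q = case_probabilities(RISK, gamma_fit, m)
        v = np.arange(1, 300) / 300.0  # v*n integral for all grid points
        curves = ppv_npv_from_weights(v, RISK, m, q)
        lhs = (1 - v) * curves.ppv + v * (1 - curves.npv)
        np.testing.assert_allclose(lhs, curves.marginal_risk, atol=1e-10)

    def test_out_of_range_v_rejected(self, gamma_fit, gamma_dataset):
        with pytest.raises(ValueError):
            ppv_npv_from_weights([0.0], RISK, gamma_dataset.markers, np.full(300, 0.5))


class TestPpvInverse:
    def test_marginal_risk_attained_near_zero(self, gamma_fit, gamma_dataset):
        m = gamma_dataset.markers
        q = case_probabilities(RISK, gamma_fit, m)
        v, ok = ppv_inverse(float(np.mean(q)), RISK, gamma_fit, m)
        assert ok and v <= 0.05

    def test_unattainable_flagged(self, gamma_fit, gamma_dataset):
        v, ok = ppv_inverse(0.9999, RISK, gamma_fit, gamma_dataset.markers)
        assert not ok and np.isnan(v)

    def test_bracketing_on_grid(self, gamma_fit, gamma_dataset):
        m = gamma_dataset.markers
        grid = np.arange(0.01, 1.0, 0.01).round(10)
        from recurroc.accuracy import ppv_npv

        curves = ppv_npv(grid, RISK, gamma_fit, m)
        p = 0.6
        v, ok = ppv_inverse(p, RISK, gamma_fit, m, v_grid=grid)
        assert ok
        i = np.searchsorted(grid, v)
        assert curves.ppv[i] >= p
        assert np.all(curves.ppv[:i] < p)


def test_evaluate_accuracy_bundles_all_parts(gamma_fit, gamma_dataset):
    curves = evaluate_accuracy(gamma_fit, gamma_dataset.markers, RISK)
    assert 0.5 < curves.auc < 1.0
    assert curves.v_grid.size == 99
    assert np.all((curves.ppv >= 0) & (curves.ppv <= 1))
    assert np.all((curves.npv >= 0) & (curves.npv <= 1))
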