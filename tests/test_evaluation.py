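"""Comparison statistics: NRMSE, angular errors, sigma estimation, spectra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from darktensor.evaluation import (
    NormalizationError,
    angular_error,
    compare_spectra,
    evaluate_instance,
    fit_sigma_theta,
    histogram_mode,
    mean_signal_check,
    nrmse,
    normalized_spectrum,
)
from darktensor.tensors import random_rotation


def rayleigh_samples(sigma, n, rng):
    """Inverse-CDF sampling from the small-angle inclination density
    theta * exp(-theta^2 / (2 sigma^2)) -- a Rayleigh distribution."""
    u = rng.uniform(0.0, 1.0, n)
    return sigma * np.sqrt(-2.0 * np.log1p(-u))


class TestNrmse:
    def test_examples(self):
        assert nrmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert nrmse([1, 2, 3], [1, 2, 4]) == pytest.approx((1 / np.sqrt(3)) / 2)
        assert nrmse([1, 3], [2, 2]) == pytest.approx(0.5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            nrmse([], [])
        with pytest.raises(ValueError):
            nrmse([1, 2], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            nrmse([-1.0, 1.0], [0.0, 0.0])


class TestAngularError:
    def test_examples(self):
        v = np.array([0.6, 0.0, 0.8])
        assert angular_error(v, v) == 0.0
        assert angular_error(v, -v) == 0.0
        assert angular_error([1, 0, 0], [0, 1, 0]) == pytest.approx(90.0)

    def test_symmetric_in_arguments(self):
        a = np.array([1.0, 0.0, 0.0])
        b = np.array([np.cos(0.3), np.sin(0.3), 0.0])
        assert angular_error(a, b) == pytest.approx(angular_error(b, a))
        assert angular_error(a, b) == pytest.approx(np.degrees(0.3))

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_invariant_under_joint_rotation(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal((2, 3))
        a /= np.linalg.norm(a)
        b /= np.linalg.norm(b)
        Q = random_rotation(rng)
        assert angular_error(Q @ a, Q @ b) == pytest.approx(
            angular_error(a, b), abs=1e-8
        )

    def test_rounding_clamp_and_rejection(self):
        v = np.array([1.0, 0.0, 0.0])
        assert angular_error(v * (1 + 1e-12), v) == 0.0
        with pytest.raises(ValueError):
            angular_error(2 * v, v)


class TestSigmaEstimator:
    def test_analytic_mode_is_sigma(self):
        # d/dx [x exp(-x^2/2s^2)] = 0 at x = s
        s = 2.7
        x = np.linspace(0.01, 10, 100000)
        pdf = x * np.exp(-0.5 * x**2 / s**2)
        assert x[np.argmax(pdf)] == pytest.approx(s, abs=1e-3)

    @pytest.mark.parametrize("sigma", [0.3, 1.0, 5.0])
    def test_recovers_sigma_from_samples(self, sigma):
        rng = np.random.default_rng(42)
        samples = rayleigh_samples(sigma, 100_000, rng)
        est = fit_sigma_theta(samples)
        assert est == pytest.approx(sigma, rel=0.10)

    def test_cross_fit_agrees(self):
        rng = np.random.default_rng(7)
        samples = rayleigh_samples(1.0, 100_000, rng)
        mode, details = fit_sigma_theta(samples, return_details=True)
        assert details["sigma_fit_up_to_max"] == pytest.approx(1.0, rel=0.15)
        assert details["n"] == 100_000

    def test_point_mass(self):
        assert fit_sigma_theta([5.0, 5.0, 5.0]) == pytest.approx(5.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fit_sigma_theta([])

    def test_exact_sin_weighted_mode_close_for_small_sigma(self):
        # the sin-weighted density sin(t) exp(-t^2/2s^2) has its mode where
        # cot(t) = t / s^2; for s <= 5 deg it deviates from s by < 1%
        for sigma_deg in (0.5, 2.0, 5.0):
            s = np.radians(sigma_deg)
            mode = brentq(lambda t: np.cos(t) * s**2 - np.sin(t) * t, 1e-9, np.pi / 2)
            assert abs(mode - s) / s < 0.01

    def test_histogram_mode_bimodal(self):
        x = np.concatenate([np.full(100, 1.0), np.full(300, 3.0)])
        assert histogram_mode(x) == pytest.approx(3.0, abs=0.5)


class TestCompareSpectra:
    def test_self_comparison_identity(self):
        T = np.diag([0.2, 0.3, 0.5])
        pairs = compare_spectra(T, T, "E")
        np.testing.assert_allclose(pairs[:, 0], pairs[:, 1], atol=1e-14)

    def test_scale_invariance(self):
        T = np.diag([0.2, 0.3, 0.5])
        U = np.diag([2.0, 3.0, 5.0])
        pairs = compare_spectra(T, U, "E")
        np.testing.assert_allclose(pairs[:, 0], [0.2, 0.3, 0.5], atol=1e-14)
        np.testing.assert_allclose(pairs[:, 1], [0.2, 0.3, 0.5], atol=1e-14)

    def test_reverse_pairing_for_optical_axis_model(self):
        # anti-correlated spectra are matched: truth ascending vs
        # surrogate descending
        T = np.diag([0.2, 0.3, 0.5])
        U = np.diag([5.0, 3.0, 2.0])
        pairs = compare_spectra(T, U, "N")
        np.testing.assert_allclose(pairs[:, 0], [0.2, 0.3, 0.5], atol=1e-14)
        np.testing.assert_allclose(pairs[:, 1], [0.5, 0.3, 0.2], atol=1e-14)

    def test_monotone_pair_order(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((3, 3))
        U = 0.5 * (A + A.T) + 2 * np.eye(3)
        pairs_e = compare_spectra(np.diag([0.1, 0.3, 0.6]), U, "E")
        assert np.all(np.diff(pairs_e[:, 1]) >= 0)
        pairs_n = compare_spectra(np.diag([0.1, 0.3, 0.6]), U, "N")
        assert np.all(np.diff(pairs_n[:, 1]) <= 0)

    def test_vanishing_trace_raises(self):
        with pytest.raises(NormalizationError):
            normalized_spectrum([1.0, -1.0, 1e-9])


class TestMeanSignalCheck:
    def test_trivial_cases(self):
        assert mean_signal_check(2.0 * np.eye(3), [2.0, 2.0]) == (2.0, 2.0)
        assert mean_signal_check(np.zeros((3, 3)), [0.0, 0.0]) == (0.0, 0.0)

    def test_uniform_directions_expectation_is_third_trace(self):
        # E[r^T U r] over uniform unit r is trace(U)/3 (Monte-Carlo oracle)
        rng = np.random.default_rng(11)
        A = rng.standard_normal((3, 3))
        U = 0.5 * (A + A.T)
        r = rng.standard_normal((200_000, 3))
        r /= np.linalg.norm(r, axis=1, keepdims=True)
        mu = np.einsum("ni,ij,nj->n", r, U, r)
        mean_eig, mean_sig = mean_signal_check(U, mu)
        assert mean_eig == pytest.approx(np.trace(U) / 3.0)
        assert mean_sig == pytest.approx(mean_eig, abs=0.01)


class TestEvaluateInstance:
    def test_perfect_surrogate_record(self, full_geom):
        from darktensor.reconstruction import (
            matrix_to_components,
            quadratic_form_design,
        )

        T = np.diag([0.2, 0.3, 0.5])
        mu = quadratic_form_design(full_geom.e_hat) @ matrix_to_components(T)
        rec = evaluate_instance(T, T, "E", mu, full_geom.e_hat, instance_id=3)
        assert rec.nrmse == pytest.approx(0.0, abs=1e-12)
        assert rec.delta_theta_deg == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(rec.spectrum_truth, rec.spectrum_surrogate)
        assert not rec.spectrum_flagged
        assert rec.instance_id == 3
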