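"""Regression model: prediction, precision, likelihood, grid search, fitting."""

import math

import numpy as np
import pytest
from scipy import special

from dmreg import (
    AnglePairs,
    DMParams,
    InvalidParameterError,
    SampleTooSmallError,
    fit,
    grid_initialize,
    log_likelihood,
    predict,
    rho_hat,
    wrap_angle,
)
from dmreg.model import DEFAULT_ALPHA_STEP, DEFAULT_OMEGA_STEP

from .conftest import make_noise_free


class TestPredict:
    def test_at_alpha_returns_beta(self):
        for omega in (-1.0, -0.3, 0.0, 0.7, 1.0):
            p = DMParams(alpha=1.2, beta=2.5, omega=omega)
            assert predict(1.2, p) == pytest.approx(2.5, abs=1e-12)

    def test_identity_map(self):
        p = DMParams(0.0, 0.0, 1.0)
        assert predict(1.0, p) == pytest.approx(1.0, abs=1e-12)

    def test_half_slope_example(self):
        p = DMParams(0.0, 0.0, 0.5)
        assert predict(math.pi / 2, p) == pytest.approx(2 * math.atan(0.5), abs=1e-12)

    def test_singular_point_limits(self):
        # u - alpha = pi: the map's limit is beta + pi for omega != 0, beta for omega = 0
        assert predict(math.pi, DMParams(0.0, 1.0, 0.5)) == pytest.approx(
            wrap_angle(1.0 + math.pi), abs=1e-9
        )
        assert predict(math.pi, DMParams(0.0, 1.0, -0.5)) == pytest.approx(
            wrap_angle(1.0 - math.pi), abs=1e-9
        )
        assert predict(math.pi, DMParams(0.0, 1.0, 0.0)) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_omega_rejected(self):
        with pytest.raises(InvalidParameterError):
            DMParams(0.0, 0.0, 1.5)

    @pytest.mark.parametrize("omega", [0.25, -0.6, 1.0])
    def test_bijection_for_nonzero_omega(self, omega):
        # the unwrapped map u -> v is monotone, hence one-to-one on the circle
        p = DMParams(alpha=0.3, beta=-1.0, omega=omega)
        u = np.linspace(0.3 - math.pi + 1e-6, 0.3 + math.pi - 1e-6, 2000)
        shift = 2.0 * np.arctan(omega * np.tan(0.5 * (u - 0.3)))
        assert np.all(np.sign(omega) * np.diff(shift) > 0)


class TestRhoHat:
    def test_perfect_fit(self, exact_params, noise_free_data):
        assert rho_hat(noise_free_data, exact_params) == pytest.approx(1.0, abs=1e-12)

    def test_antipodal_fit(self, exact_params, noise_free_data):
        flipped = AnglePairs(noise_free_data.u, noise_free_data.v + math.pi)
        assert rho_hat(flipped, exact_params) == pytest.approx(-1.0, abs=1e-12)

    def test_two_point_hand_value(self):
        p = DMParams(0.0, 0.0, 1.0)  # identity map
        data = AnglePairs([0.5, 1.0], [0.5, 1.0 + math.pi / 2])
        # angular errors {0, pi/2}: mean cosine = (1 + 0)/2
        assert rho_hat(data, p) == pytest.approx(0.5, abs=1e-12)


class TestLogLikelihood:
    def test_zero_kappa(self, exact_params, noise_free_data):
        assert log_likelihood(noise_free_data, exact_params, 0.0) == pytest.approx(0.0)

    def test_perfect_fit_value(self, exact_params):
        data = make_noise_free(exact_params, n=10, seed=3)
        expected = -10.0 * math.log(special.i0(2.0)) + 20.0  # ~11.76
        assert log_likelihood(data, exact_params, 2.0) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(11.76, abs=0.005)

    def test_profile_maximal_at_kappa_hat(self, exact_params, rng):
        u = rng.uniform(0, 2 * math.pi, 40)
        v = predict(u, exact_params) + rng.vonmises(0.0, 5.0, 40)
        data = AnglePairs(u, v)
        f = fit(data)
        at_hat = log_likelihood(data, f.params, f.kappa_hat)
        assert at_hat >= log_likelihood(data, f.params, f.kappa_hat + 0.5)
        assert at_hat >= log_likelihood(data, f.params, max(f.kappa_hat - 0.5, 0.0))

    def test_negative_kappa_rejected(self, exact_params, noise_free_data):
        with pytest.raises(InvalidParameterError):
            log_likelihood(noise_free_data, exact_params, -1.0)


class TestGridInitialize:
    def test_recovers_lattice_truth_exactly(self, exact_params, noise_free_data):
        got = grid_initialize(noise_free_data)
        assert got.alpha == pytest.approx(exact_params.alpha, abs=1e-9)
        assert got.beta == pytest.approx(exact_params.beta, abs=1e-9)
        assert got.omega == pytest.approx(exact_params.omega, abs=1e-12)

    def test_off_lattice_truth_within_one_step(self):
        truth = DMParams(1.5, 1.5, 0.5)
        data = make_noise_free(truth, n=60, seed=4)
        got = grid_initialize(data)
        assert abs(got.alpha - truth.alpha) <= DEFAULT_ALPHA_STEP + 1e-9
        assert abs(got.beta - truth.beta) <= DEFAULT_ALPHA_STEP + 1e-9
        assert abs(got.omega - truth.omega) <= DEFAULT_OMEGA_STEP + 1e-9

    def test_degenerate_lattice_rejected(self, noise_free_data):
        with pytest.raises(InvalidParameterError):
            grid_initialize(noise_free_data, alpha_step=-1.0)


class TestFit:
    def test_exact_recovery_noise_free(self):
        truth = DMParams(1.5, 1.5, 0.5)
        data = make_noise_free(truth, n=50, seed=5)
        f = fit(data)
        assert f.rho_hat >= 1.0 - 1e-6
        assert f.params.alpha == pytest.approx(truth.alpha, abs=1e-3)
        assert f.params.beta == pytest.approx(truth.beta, abs=1e-3)
        assert f.params.omega == pytest.approx(truth.omega, abs=1e-3)
        assert np.all(f.residuals < 1e-3)

    def test_sample_too_small(self):
        with pytest.raises(SampleTooSmallError):
            fit(AnglePairs([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]))

    def test_fit_contract_fields(self, rng):
        truth = DMParams(1.5, 1.5, 0.5)
        u = wrap_angle(rng.vonmises(math.pi / 2, 3.0, 40))
        v = predict(u, truth) + rng.vonmises(0.0, 10.0, 40)
        data = AnglePairs(u, v)
        f = fit(data)
        assert f.n == 40
        assert len(f.fitted) == len(f.residuals) == 40
        assert np.all((f.residuals >= 0) & (f.residuals <= math.pi))
        assert -1.0 <= f.rho_hat <= 1.0
        # rho_hat is the mean residual cosine at the estimates
        assert f.rho_hat == pytest.approx(
            float(np.mean(np.cos(data.v - f.fitted))), abs=1e-12
        )

    def test_shift_equivariance(self, rng):
        truth = DMParams(1.5, 1.5, 0.5)
        u = wrap_angle(rng.vonmises(math.pi / 2, 3.0, 60))
        v = predict(u, truth) + rng.vonmises(0.0, 20.0, 60)
        base = fit(AnglePairs(u, v))
        c = 0.9
        shifted = fit(AnglePairs(u, wrap_angle(v + c)))
        d_beta = (shifted.params.beta - base.params.beta - c + math.pi) % (2 * math.pi) - math.pi
        assert d_beta == pytest.approx(0.0, abs=1e-3)
        assert shifted.params.omega == pytest.approx(base.params.omega, abs=1e-3)

    def test_never_loses_to_grid_start(self, rng):
        u = wrap_angle(rng.vonmises(math.pi / 2, 3.0, 25))
        v = predict(u, DMParams(1.5, 1.5, 0.5)) + rng.vonmises(0.0, 5.0, 25)
        data = AnglePairs(u, v)
        start = grid_initialize(data)
        f = fit(data, init=start)
        assert f.rho_hat >= rho_hat(data, start) - 1e-12

    def test_parameter_recovery_under_noise(self):
        # moderate-size check; the acceptance suite runs the full replication
        truth = DMParams(1.5, 1.5, 0.5)
        ests = []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            u = wrap_angle(rng.vonmises(math.pi / 2, 3.0, 150))
            v = predict(u, truth) + rng.vonmises(0.0, 20.0, 150)
            f = fit(AnglePairs(u, v))
            ests.append([f.params.alpha, f.params.beta, f.params.omega])
        ests = np.array(ests)
        means = ests.mean(axis=0)
        ses = ests.std(axis=0, ddof=1) / math.sqrt(len(ests))
        for mean, se, true in zip(means, ses, [1.5, 1.5, 0.5]):
            assert abs(mean - true) < 3 * se + 1e-3
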