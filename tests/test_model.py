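import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from oracles import kernel_by_recursion
from pgbar.model import (
    ContractViolation,
    DomainError,
    FluorescenceTrace,
    KernelCoefficients,
    LatentState,
    ModelParameters,
    ar_to_kinetics,
    calcium_from_spikes,
    gaussian_convolution,
    initial_logdensity,
    kernel_response,
    kinetics_to_ar,
    observation_logdensity,
    transition_logdensity,
)


class TestReparameterization:
    def test_fast_kinetics_peak_position(self):
        # 3 kHz grid, rise 3.7 ms, decay 40 ms: discrete peak within one
        # sampling step of the rise time
        dt = 1.0 / 3000.0
        c = kinetics_to_ar(0.0037, 0.040, 1.0, dt)
        resp = kernel_response(c, 300)
        t_peak = (np.argmax(resp) + 1) * dt
        assert abs(t_peak - 0.0037) <= dt

    def test_round_trip_identity(self):
        dt = 1.0 / 3000.0
        c = kinetics_to_ar(0.0037, 0.040, 2.5, dt)
        a_max, tau_r, tau_d = ar_to_kinetics(c, dt)
        assert a_max == pytest.approx(2.5, rel=1e-8)
        assert tau_r == pytest.approx(0.0037, rel=1e-8)
        assert tau_d == pytest.approx(0.040, rel=1e-8)

    @given(
        ratio=st.floats(0.01, 0.9),
        tau_d=st.floats(0.005, 2.0),
        a_max=st.floats(0.1, 10.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_round_trip_property(self, ratio, tau_d, a_max):
        dt = tau_d / 100.0
        c = kinetics_to_ar(ratio * tau_d, tau_d, a_max, dt)
        a2, tr2, td2 = ar_to_kinetics(c, dt)
        assert a2 == pytest.approx(a_max, rel=1e-6)
        assert tr2 == pytest.approx(ratio * tau_d, rel=1e-6)
        assert td2 == pytest.approx(tau_d, rel=1e-6)

    def test_ar_to_kinetics_against_tail_regression(self):
        # gamma1=1.70, gamma2=-0.712 in per-step units: decay constant from
        # the closed form must match an exponential fit of the kernel tail,
        # and the rise time must match the brute-force argmax region
        g1, g2 = 1.70, -0.712
        disc = math.sqrt(g1**2 + 4 * g2)
        rp = (g1 + disc) / 2
        c = KernelCoefficients(
            gamma1=g1, gamma2=g2, a=1.0,
            g_plus=math.log(rp), g_minus=math.log((g1 - disc) / 2), g_a=1.0,
        )
        a_max, tau_r, tau_d = ar_to_kinetics(c, dt=1.0)
        seq = kernel_by_recursion(g1, g2, 1.0, 500)
        # tail slope of log kernel -> -1/tau_d
        t0 = 100
        slope = np.polyfit(np.arange(t0, 500), np.log(seq[t0:500]), 1)[0]
        assert tau_d == pytest.approx(-1.0 / slope, rel=1e-3)
        assert tau_d == pytest.approx(-1.0 / math.log(rp), rel=1e-12)
        assert abs((np.argmax(seq) + 1) - tau_r) <= 1.0

    def test_degenerate_first_order_rejected(self):
        c = KernelCoefficients(
            gamma1=0.9, gamma2=0.0, a=1.0, g_plus=0.0, g_minus=0.0, g_a=1.0
        )
        with pytest.raises(DomainError):
            ar_to_kinetics(c, dt=1.0)

    def test_invalid_orderings_rejected(self):
        with pytest.raises(DomainError):
            kinetics_to_ar(0.05, 0.04, 1.0, 0.001)
        with pytest.raises(DomainError):
            kinetics_to_ar(0.04, 0.04, 1.0, 0.001)
        with pytest.raises(DomainError):
            kinetics_to_ar(0.004, 0.04, 1.0, -0.1)


class TestKernelResponse:
    def test_first_value_is_increment(self, coeffs):
        resp = kernel_response(coeffs, 50)
        assert resp[0] == pytest.approx(coeffs.a, rel=1e-12)

    def test_peak_equals_a_max_within_discretization(self):
        # on a fine grid the discrete peak approaches the nominal amplitude
        dt = 1e-4
        c = kinetics_to_ar(0.02, 0.1, 1.7, dt)
        resp = kernel_response(c, 5000)
        assert resp.max() == pytest.approx(1.7, rel=1e-4)

    def test_closed_form_equals_recursion(self, coeffs):
        resp = kernel_response(coeffs, 100)
        brute = kernel_by_recursion(coeffs.gamma1, coeffs.gamma2, coeffs.a, 100)
        np.testing.assert_allclose(resp, brute, rtol=1e-10)

    def test_tail_slope(self):
        dt = 1.0 / 1000.0
        c = kinetics_to_ar(0.005, 0.05, 1.0, dt)
        resp = kernel_response(c, 400)
        t0 = int(5 * 0.005 / dt)
        slope = np.polyfit(np.arange(t0, 400), np.log(resp[t0:400]), 1)[0]
        assert slope / dt == pytest.approx(-1.0 / 0.05, rel=0.01)


class TestCalciumFromSpikes:
    def test_matches_recursion_definition(self, coeffs, rng):
        from oracles import calcium_by_recursion

        s = rng.poisson(0.5, size=40)
        c = calcium_from_spikes(s, coeffs, c0=0.7)
        brute = calcium_by_recursion(s, coeffs.gamma1, coeffs.gamma2, coeffs.a, 0.7)
        np.testing.assert_allclose(c, brute, rtol=1e-10, atol=1e-12)


class TestGaussianConvolution:
    def test_zero_mean_case(self):
        assert gaussian_convolution(0, 0, 1, 1) == pytest.approx(
            1.0 / math.sqrt(4 * math.pi)
        )

    def test_symmetry(self):
        assert gaussian_convolution(1.3, -0.4, 0.5, 0.25) == pytest.approx(
            gaussian_convolution(-0.4, 1.3, 0.25, 0.5)
        )

    def test_matches_quadrature(self):
        def integrand(x, y1, y2, v1, v2):
            return (
                math.exp(-((x - y1) ** 2) / (2 * v1) - (x - y2) ** 2 / (2 * v2))
                / (2 * math.pi * math.sqrt(v1 * v2))
            )

        val, _ = quad(integrand, -np.inf, np.inf, args=(1.0, 0.0, 0.5, 0.25))
        assert gaussian_convolution(1.0, 0.0, 0.5, 0.25) == pytest.approx(
            val, rel=1e-9
        )

    def test_normalizes_over_y2(self, rng):
        for _ in range(5):
            y1 = rng.normal()
            v1, v2 = rng.uniform(0.1, 2.0, 2)
            val, _ = quad(
                lambda y2: gaussian_convolution(y1, y2, v1, v2),
                -np.inf,
                np.inf,
            )
            assert val == pytest.approx(1.0, rel=1e-8)

    def test_rejects_bad_variance(self):
        with pytest.raises(DomainError):
            gaussian_convolution(0, 0, -1, 1)


def _make_state(q, s, c_vec, b):
    return LatentState(q=q, s=s, c_vec=np.array(c_vec, dtype=float), b=b)


class TestDensities:
    def test_observation_zero_residual(self, theta):
        x = _make_state(0, 0, [0.5, 0.2], 0.3)
        val = observation_logdensity(0.8, x, theta)
        assert val == pytest.approx(-0.5 * math.log(2 * math.pi * theta.sigma2))

    def test_observation_one_sigma(self, theta):
        x = _make_state(0, 0, [0.5, 0.2], 0.3)
        f = 0.8 + math.sqrt(theta.sigma2)
        val = observation_logdensity(f, x, theta)
        assert val == pytest.approx(
            -0.5 * math.log(2 * math.pi * theta.sigma2) - 0.5
        )

    def test_observation_integrates_to_one(self, theta):
        x = _make_state(0, 0, [0.5, 0.2], 0.3)
        val, _ = quad(
            lambda f: math.exp(observation_logdensity(f, x, theta)),
            -20,
            20,
        )
        assert val == pytest.approx(1.0, rel=1e-8)

    def test_transition_zero_spike_zero_increment(self, coeffs, dt):
        theta = ModelParameters(
            r0=0.0, r1=5.0, w01=2.0, w10=3.0, a_max=1.0,
            tau_r=0.02, tau_d=0.1, c0=0.0, sigma2=0.1, sigma2_b=0.3,
        )
        c_prev = np.array([0.4, 0.3])
        c_next = np.array(
            [coeffs.gamma1 * 0.4 + coeffs.gamma2 * 0.3, 0.4]
        )
        x_prev = _make_state(0, 0, c_prev, 0.1)
        x = _make_state(0, 0, c_next, 0.1)
        val = transition_logdensity(x_prev, x, theta, coeffs, dt)
        expected = math.log(1 - 2.0 * dt) - 0.5 * math.log(
            2 * math.pi * dt * 0.3
        )
        assert val == pytest.approx(expected)

    def test_transition_poisson_term(self, theta, coeffs):
        # s=2 with r1*dt = 0.1 contributes 0.1^2 e^-0.1 / 2
        dt = 0.1 / theta.r1
        c_prev = np.array([0.0, 0.0])
        c_next = np.array([coeffs.a * 2, 0.0])
        x_prev = _make_state(1, 0, c_prev, 0.0)
        x = _make_state(1, 2, c_next, 0.0)
        val = transition_logdensity(x_prev, x, theta, coeffs, dt)
        w11 = 1 - theta.w10 * dt
        gauss = -0.5 * math.log(2 * math.pi * dt * theta.sigma2_b)
        pois = math.log(0.1**2 * math.exp(-0.1) / 2)
        assert val == pytest.approx(math.log(w11) + pois + gauss)

    def test_transition_rejects_inconsistent_calcium(self, theta, coeffs, dt):
        x_prev = _make_state(0, 0, [0.4, 0.3], 0.1)
        x = _make_state(0, 0, [99.0, 0.4], 0.1)
        with pytest.raises(ContractViolation):
            transition_logdensity(x_prev, x, theta, coeffs, dt)

    def test_transition_normalizes(self, theta, coeffs, dt):
        # summing over (q, s) and integrating over b recovers probability 1
        # (up to the tiny truncated Poisson tail)
        x_prev = _make_state(0, 1, [0.4, 0.3], 0.15)
        total = 0.0
        for q in (0, 1):
            for s in range(30):
                c_next = np.array(
                    [
                        coeffs.gamma1 * 0.4 + coeffs.gamma2 * 0.3 + coeffs.a * s,
                        0.4,
                    ]
                )
                val, _ = quad(
                    lambda b, q=q, s=s, c_next=c_next: math.exp(
                        transition_logdensity(
                            x_prev,
                            _make_state(q, s, c_next, b),
                            theta,
                            coeffs,
                            dt,
                        )
                    ),
                    -10,
                    10,
                )
                total += val
        assert total == pytest.approx(1.0, rel=1e-6)

    def test_initial_zero_spike_value(self, coeffs, dt):
        theta = ModelParameters(
            r0=1.5, r1=5.0, w01=2.0, w10=3.0, a_max=1.0,
            tau_r=0.02, tau_d=0.1, c0=0.2, sigma2=0.1, sigma2_b=0.3,
        )
        x1 = _make_state(0, 0, [0.2, 0.0], 0.0)
        val = initial_logdensity(x1, theta, coeffs, dt)
        expected = math.log(0.5) - 1.5 * dt - 0.5 * math.log(2 * math.pi)
        assert val == pytest.approx(expected)

    def test_initial_equal_state_mass(self, theta, coeffs, dt):
        # with equal rates both regimes have identical initial mass
        theta_eq = theta.replace(r1=theta.r0)
        x0 = _make_state(0, 1, [theta.c0 + coeffs.a, 0.0], 0.5)
        x1 = _make_state(1, 1, [theta.c0 + coeffs.a, 0.0], 0.5)
        assert initial_logdensity(x0, theta_eq, coeffs, dt) == pytest.approx(
            initial_logdensity(x1, theta_eq, coeffs, dt)
        )

    def test_initial_normalizes(self, theta, coeffs, dt):
        total = 0.0
        for q in (0, 1):
            for s in range(30):
                c_vec = np.array([theta.c0 + coeffs.a * s, 0.0])
                val, _ = quad(
                    lambda b, q=q, s=s, c_vec=c_vec: math.exp(
                        initial_logdensity(
                            _make_state(q, s, c_vec, b), theta, coeffs, dt
                        )
                    ),
                    -12,
                    12,
                )
                total += val
        assert total == pytest.approx(1.0, rel=1e-6)


class TestTypes:
    def test_parameter_invariants(self, dt):
        with pytest.raises(DomainError):
            ModelParameters(
                r0=-1, r1=5, w01=2, w10=3, a_max=1, tau_r=0.02,
                tau_d=0.1, c0=0, sigma2=0.1, sigma2_b=0.3,
            ).validate(dt)
        with pytest.raises(DomainError):
            ModelParameters(
                r0=1, r1=5, w01=60, w10=3, a_max=1, tau_r=0.02,
                tau_d=0.1, c0=0, sigma2=0.1, sigma2_b=0.3,
            ).validate(dt)

    def test_trace_invariants(self):
        with pytest.raises(DomainError):
            FluorescenceTrace(np.array([1.0]), 0.01)
        with pytest.raises(DomainError):
            FluorescenceTrace(np.array([1.0, np.nan]), 0.01)
        with pytest.raises(DomainError):
            FluorescenceTrace(np.array([1.0, 2.0]), 0.0)

    def test_latent_state_invariants(self):
        with pytest.raises(DomainError):
            LatentState(q=2, s=0, c_vec=np.zeros(2), b=0.0)
        with pytest.raises(DomainError):
            LatentState(q=0, s=-1, c_vec=np.zeros(2), b=0.0)
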