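"""Stationary-density BVP: coefficients, solver, closed forms, expansions."""
import numpy as np
import pytest

from ousync.langevin import empirical_density, simulate_phase_pair
from ousync.metrics import order_parameter
from ousync.prc import PeriodicFunction, cross_correlation_h, make_double_sine
from ousync.theory import (DegenerateProblemError, build_problem,
                           closed_form_density, filtered_correlation,
                           noise_frequency_shift, ou_filter, small_c_expansion,
                           solve_density)

TWO_PI = 2.0 * np.pi


class TestOUFilter:
    def test_first_harmonic_multiplier(self):
        h = PeriodicFunction.from_callable(np.cos)
        g = ou_filter(h, 1.0)
        assert np.allclose(g.values, 0.5 * np.cos(g.grid), atol=1e-12)

    def test_white_noise_limit_returns_input(self):
        h = PeriodicFunction.from_callable(
            lambda x: np.cos(x) + 0.3 * np.sin(2 * x) + 0.1)
        g = ou_filter(h, 1e-6)
        assert np.allclose(g.values, h.values, atol=1e-4)

    def test_constant_passes_through(self):
        h = PeriodicFunction(np.full(128, 0.7))
        for tau in (0.1, 1.0, 10.0):
            assert np.allclose(ou_filter(h, tau).values, 0.7, atol=1e-14)

    def test_rejects_nonpositive_tau(self):
        h = PeriodicFunction.from_callable(np.cos)
        with pytest.raises(ValueError):
            ou_filter(h, 0.0)


class TestBuildProblem:
    def test_identical_prcs_have_zero_c2(self):
        prc = make_double_sine(0.3, 0.4)
        for tau in (0.25, 1.0, 4.0):
            problem = build_problem(prc, prc, tau, 0.5, 0.0)
            assert problem.C2 == 0.0
            # g even symmetric for identical PRCs
            assert np.allclose(problem.g.values[1:],
                               problem.g.values[1:][::-1], atol=1e-12)

    @pytest.mark.parametrize("tau", [0.25, 1.0, 4.0])
    def test_first_harmonic_c1_identity(self, tau):
        # (1 + tau^2) C1 = (1 + tau^2)(sin^2 a1 + sin^2 a2) + 1
        a1, a2 = 0.1, 0.6
        problem = build_problem(make_double_sine(a1, 0.0),
                                make_double_sine(a2, 0.0), tau, 0.5, 0.0)
        expected = ((1 + tau ** 2) * (np.sin(a1) ** 2 + np.sin(a2) ** 2)
                    + 1.0) / (1 + tau ** 2)
        assert problem.C1 == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("tau", [0.1, 1.0, 10.0])
    def test_pure_sine_pair_coefficients(self, tau):
        prc = make_double_sine(0.0, 0.0)
        problem = build_problem(prc, prc, tau, 0.8, 0.0)
        assert problem.C1 == pytest.approx(1.0 / (1 + tau ** 2), abs=1e-12)
        assert np.allclose(problem.g.values,
                           np.cos(problem.g.grid) / (1 + tau ** 2),
                           atol=1e-12)

    def test_k_consistency_relation(self, fig3_pair):
        problem = build_problem(*fig3_pair, 1.0, 0.8, 0.5)
        assert problem.K == pytest.approx(
            (2 * 0.5 / 1.0 - problem.C2) / TWO_PI)

    def test_rejects_invalid_inputs(self, fig3_pair):
        with pytest.raises(ValueError):
            build_problem(*fig3_pair, -1.0, 0.5, 0.0)
        with pytest.raises(ValueError):
            build_problem(*fig3_pair, 1.0, 1.5, 0.0)


class TestSolveDensity:
    def test_uncorrelated_is_uniform(self, fig3_pair):
        problem = build_problem(*fig3_pair, 1.0, 0.0, 0.0)
        density = solve_density(problem)
        assert np.allclose(density.values, 1 / TWO_PI, atol=1e-10)

    def test_matches_closed_form_for_identical_prcs(self):
        prc = make_double_sine(0.1, 0.32)
        problem = build_problem(prc, prc, 1.0, 0.8, 0.0)
        bvp = solve_density(problem, n_modes=128, n_bins=256)
        closed = closed_form_density(prc, 1.0, 0.8, n_bins=256)
        assert np.max(np.abs(bvp.values - closed.values)) < 1e-8

    def test_degenerate_limit_rejected(self):
        prc = make_double_sine(0.1, 0.32)
        problem = build_problem(prc, prc, 1.0, 1.0, 0.0)
        assert problem.degenerate
        with pytest.raises(DegenerateProblemError):
            solve_density(problem)

    def test_detuning_offsets_peak(self, fig3_pair):
        # frequency difference pushes the peak in its own direction
        problem = build_problem(*fig3_pair, 1.0, 0.8, 0.5)
        density = solve_density(problem)
        peak0 = order_parameter(
            solve_density(build_problem(*fig3_pair, 1.0, 0.8, 0.0))
        ).peak_angle
        peak = order_parameter(density).peak_angle
        assert peak > peak0

    def test_density_integrates_to_one(self, fig3_pair):
        for omega in (0.0, 0.3):
            density = solve_density(
                build_problem(*fig3_pair, 0.5, 0.9, omega))
            assert density.is_normalized
            assert np.min(density.values) > -1e-6


class TestClosedForm:
    def test_sine_pair_value_at_zero(self):
        # R(phi) = sqrt(1-c^2) / (2 pi (1 - c cos phi)) for -sin PRCs
        prc = make_double_sine(0.0, 0.0)
        for tau in (0.25, 1.0, 4.0):
            density = closed_form_density(prc, tau, 0.8, n_bins=1024)
            i0 = np.argmin(np.abs(density.bin_centers))
            expected = np.sqrt(1 - 0.64) / (TWO_PI * (1 - 0.8 * np.cos(
                density.bin_centers[i0])))
            assert density.values[i0] == pytest.approx(expected, rel=1e-6)
            assert density.values[i0] == pytest.approx(0.4775, abs=2e-4)

    def test_uncorrelated_uniform(self):
        density = closed_form_density(make_double_sine(0.2, 0.1), 1.0, 0.0)
        assert np.allclose(density.values, 1 / TWO_PI, atol=1e-12)

    def test_tau_invariance_for_zero_dc_first_harmonic(self):
        # pure -sin(theta) PRCs: R is independent of tau
        prc = make_double_sine(0.0, 0.0)
        base = closed_form_density(prc, 0.1, 0.6).values
        for tau in (1.0, 10.0):
            assert np.allclose(closed_form_density(prc, tau, 0.6).values,
                               base, atol=1e-12)

    def test_white_noise_limit_matches_unfiltered_form(self):
        # tau -> 0: R = N / (2 h(0) - 2 c h(phi)) (white-noise result)
        prc = make_double_sine(0.2, 0.3)
        h = cross_correlation_h(prc, prc)
        density = closed_form_density(prc, 1e-4, 0.7, n_bins=256)
        raw = 1.0 / (2 * h(0.0) - 2 * 0.7 * h(density.bin_centers))
        raw /= np.sum(raw) * density.bin_width
        assert np.max(np.abs(density.values - raw)) < 1e-3


class TestSmallCExpansion:
    @pytest.mark.parametrize("tau", [0.25, 1.0, 4.0])
    def test_single_harmonic_slope_formula(self, tau):
        # OP/c = (1/2) / (1 + (tau^2+1)(sin^2 aj + sin^2 ak))
        for aj, ak in [(0.1, 0.1), (0.1, 0.6), (0.6, 0.6)]:
            problem = build_problem(make_double_sine(aj, 0.0),
                                    make_double_sine(ak, 0.0), tau, 0.05, 0.0)
            slope = small_c_expansion(problem).op_slope
            expected = 0.5 / (1 + (tau ** 2 + 1)
                              * (np.sin(aj) ** 2 + np.sin(ak) ** 2))
            assert slope == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("tau", [0.25, 1.0, 4.0])
    def test_heterogeneous_ordering(self, tau):
        # OP_11 > OP_12 > OP_22 for 0 <= a1 < a2 <= pi/2
        a1, a2 = 0.1, 0.6
        slopes = {}
        for key, (aj, ak) in {"11": (a1, a1), "12": (a1, a2),
                              "22": (a2, a2)}.items():
            problem = build_problem(make_double_sine(aj, 0.0),
                                    make_double_sine(ak, 0.0), tau, 0.05, 0.0)
            slopes[key] = small_c_expansion(problem).op_slope
        assert slopes["11"] > slopes["12"] > slopes["22"]

    def test_linear_slope_matches_bvp_at_small_c(self, fig3_pair):
        problem = build_problem(*fig3_pair, 1.0, 0.05, 0.0)
        slope = small_c_expansion(problem).op_slope
        op = order_parameter(solve_density(problem)).op
        assert 0.05 * slope == pytest.approx(op, rel=0.05)

    def test_r0_is_uniform(self, fig3_pair):
        expansion = small_c_expansion(build_problem(*fig3_pair, 1.0, 0.1, 0.0))
        assert expansion.R0 == pytest.approx(1 / TWO_PI)
        assert expansion.R1.mean() == pytest.approx(0.0, abs=1e-14)


class TestFrequencyShift:
    def test_harmonic_formula(self):
        # Delta = -sin + b sin(2 theta): nu = -tau [1/4/(1+t^2) + b^2/(1+4t^2)]
        tau, b = 1.0, 0.8
        prc = make_double_sine(0.0, b)
        expected = -tau * (0.25 / (1 + tau ** 2)
                           + b ** 2 / (1 + 4 * tau ** 2))
        assert noise_frequency_shift(prc, tau) == pytest.approx(
            expected, abs=1e-12)

    def test_single_oscillator_monte_carlo_oracle(self):
        # measured noise-induced slowing (theta' - 1)/eps^2 matches the
        # filtered-correlation prediction (amplitude-fixed noise: the
        # prediction carries the kernel mass tau)
        tau, eps = 1.0, 0.1
        for prc in (make_double_sine(0.0, 0.8), make_double_sine(0.0, 0.0)):
            trace = simulate_phase_pair(prc, prc, eps=eps, omega=0.0,
                                        tau=tau, c=1.0, dt=0.02, T=200000.0,
                                        burn_in=1000.0, seed=5)
            i0 = trace.burn_in_index
            rate = ((trace.theta1[-1] - trace.theta1[i0])
                    / ((trace.n - 1 - i0) * trace.dt))
            nu_hat = (rate - 1.0) / eps ** 2
            nu_pred = tau * noise_frequency_shift(prc, tau)
            assert nu_hat == pytest.approx(nu_pred, rel=0.15, abs=0.01)

    def test_c2_drift_direction_confirmed_by_pair_simulation(self):
        # Delta_1 has extra 2nd-harmonic power, so oscillator 1 slows more
        # and the stationary peak sits at positive phase difference; the
        # simulated pair shows the same sign and comparable magnitude
        p1 = make_double_sine(0.0, 0.8)
        p2 = make_double_sine(0.0, 0.0)
        problem = build_problem(p1, p2, 1.0, 0.8, 0.0)
        assert problem.C2 == pytest.approx(-0.256, abs=1e-12)
        peak_bvp = order_parameter(solve_density(problem)).peak_angle
        trace = simulate_phase_pair(p1, p2, eps=0.3, omega=0.0, tau=1.0,
                                    c=0.8, dt=0.02, T=200000.0,
                                    burn_in=1000.0, seed=6)
        peak_mc = order_parameter(empirical_density(trace, 100)).peak_angle
        assert peak_bvp > 0 and peak_mc > 0
        assert peak_mc == pytest.approx(peak_bvp, abs=0.25)


def test_op_symmetric_in_omega_for_identical_prcs():
    prc = make_double_sine(0.5, 0.3)
    for omega in (0.25, 0.5):
        plus = order_parameter(
            solve_density(build_problem(prc, prc, 0.25, 0.5, omega))).op
        minus = order_parameter(
            solve_density(build_problem(prc, prc, 0.25, 0.5, -omega))).op
        assert plus == pytest.approx(minus, abs=1e-6)
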