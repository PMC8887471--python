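"""Circuit dynamics: regulation kernels, steady states, steps, fixed points."""

import numpy as np
import pytest
from scipy.optimize import brentq

from rpacircuit import (CircuitParameters, CircuitState, StepExperiment,
                        bistable_nonlinear_pf, defaults_v1, dstate_dt,
                        find_fixed_points, hill_activation, hill_repression,
                        input_drive, simulate_step, steady_state)
from rpacircuit.circuit_model import _reduced_residual


def closed_form_A(p):
    """Adapted output level of the ideal-linear leak-free circuit."""
    return p.K_AB * (p.alpha2 / (p.gammaB * p.K_BB) - 1.0) ** (1.0 / p.n_AB)


class TestKernels:
    @pytest.mark.parametrize("x,K,n,beta,expected", [
        (1.0, 1.0, 2.0, 0.0, 0.5),    # half-maximal point
        (5.0, 5.0, 3.7, 0.0, 0.5),
        (0.0, 2.0, 1.0, 0.03, 0.03),  # zero-input limit = leak
        (3.0, 1.0, 1.0, 0.0, 0.75),
    ])
    def test_activation_values(self, x, K, n, beta, expected):
        assert hill_activation(x, K, n, beta) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("x,K,n,beta,expected", [
        (0.0, 1.0, 2.0, 0.05, 1.05),   # no repressor
        (1.0, 1.0, 3.0, 0.0, 0.5),     # half-maximal point
        (1e9, 1.0, 2.0, 0.02, 0.02),   # saturation -> leak
    ])
    def test_repression_values(self, x, K, n, beta, expected):
        assert hill_repression(x, K, n, beta) == pytest.approx(expected, rel=1e-6)

    def test_activation_monotone_and_bounded(self):
        x = np.linspace(0, 50, 500)
        y = hill_activation(x, K=2.0, n=2.5, beta=0.01)
        assert np.all(np.diff(y) > 0)
        assert y.min() >= 0.01 and y.max() <= 1.01

    def test_repression_monotone(self):
        x = np.linspace(0, 50, 500)
        y = hill_repression(x, K=2.0, n=1.5, beta=0.0)
        assert np.all(np.diff(y) < 0)

    @pytest.mark.parametrize("bad", [-1.0, np.nan, np.inf])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            hill_activation(bad, 1.0, 1.0)
        with pytest.raises(ValueError):
            hill_repression(bad, 1.0, 1.0)


class TestInputDrive:
    def test_hand_evaluated_points(self, ideal_leakfree):
        # K_TFtot=3, K_IR=1, n_RA=1: at input 2 the repressor term is
        # 3/(1+2) = 1, so the drive is exactly 1/2; at 0 it is 1/(1+3).
        assert input_drive(2.0, ideal_leakfree) == pytest.approx(0.5, rel=1e-12)
        assert input_drive(0.0, ideal_leakfree) == pytest.approx(0.25, rel=1e-12)

    def test_saturation_limit(self):
        p = defaults_v1("ideal_linear").with_updates(beta_RA=0.01)
        assert input_drive(1e9, p) == pytest.approx(1.01, rel=1e-6)

    def test_strictly_increasing(self, hill_defaults):
        inp = np.geomspace(0.01, 1e4, 200)
        d = input_drive(inp, hill_defaults)
        assert np.all(np.diff(d) > 0)

    def test_negative_input_rejected(self, hill_defaults):
        with pytest.raises(ValueError):
            input_drive(-0.1, hill_defaults)


class TestParameterValidation:
    def test_nonpositive_rate_rejected(self, ideal_leakfree):
        with pytest.raises(ValueError, match="gammaB"):
            ideal_leakfree.with_updates(gammaB=-1.0)

    def test_hill_coefficient_below_one_rejected(self, ideal_leakfree):
        with pytest.raises(ValueError, match="n_AB"):
            ideal_leakfree.with_updates(n_AB=0.5)

    def test_ideal_linear_requires_unit_coefficient(self, ideal_leakfree):
        with pytest.raises(ValueError, match="n_BB"):
            ideal_leakfree.with_updates(n_BB=2.0)

    def test_null_pf_requires_constitutive_level(self, ideal_leakfree):
        with pytest.raises(ValueError, match="c_pf"):
            ideal_leakfree.with_updates(variant="null_pf")

    def test_unknown_key_rejected_by_name(self):
        d = defaults_v1("hill").to_dict()
        d["alpha3"] = 1.0
        with pytest.raises(ValueError, match="alpha3"):
            CircuitParameters.from_dict(d)

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            CircuitState(-0.1, 1.0)

    def test_step_grid_must_start_at_zero(self):
        with pytest.raises(ValueError):
            StepExperiment(2.0, 200.0, np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            StepExperiment(2.0, 200.0, np.array([0.0, 2.0, 1.0]))


class TestSteadyState:
    def test_ideal_closed_form(self, ideal_leakfree):
        # self-activation balance forces the repression factor to
        # gammaB*K_BB/alpha2 = 0.5, hence A* = K_AB = 1; the input branch
        # then gives 1 = 10*0.5*B/(1+B), i.e. B* = 0.25.
        ss = steady_state(2.0, ideal_leakfree)
        assert ss.A == pytest.approx(1.0, rel=1e-8)
        assert ss.B == pytest.approx(0.25, rel=1e-8)

    def test_adapted_level_is_input_independent(self, ideal_leakfree):
        a_star = closed_form_A(ideal_leakfree)
        for inp in (2.0, 20.0, 200.0):
            ss = steady_state(inp, ideal_leakfree)
            assert ss.A == pytest.approx(a_star, rel=1e-6)

    def test_derivatives_vanish_at_steady_state(self, ideal_leakfree):
        ss = steady_state(2.0, ideal_leakfree)
        dA, dB = dstate_dt(ss, 2.0, ideal_leakfree)
        assert abs(dA) < 1e-9 and abs(dB) < 1e-9

    def test_closed_form_state_is_stationary(self, ideal_leakfree):
        dA, dB = dstate_dt(CircuitState(1.0, 0.25), 2.0, ideal_leakfree)
        assert abs(dA) < 1e-12 and abs(dB) < 1e-12

    def test_no_repression_decouples(self):
        # saturating self-activation keeps B finite once repression is gone;
        # the B equation decouples and A follows alpha1*drive*act(B*)/gammaA
        p = defaults_v1("hill", leak_free=True).with_updates(
            variant="no_repression")
        b_star = None
        for inp in (2.0, 50.0):
            ss = steady_state(inp, p)
            expected_A = (p.alpha1 * input_drive(inp, p) * p.activation(ss.B)
                          / p.gammaA)
            assert ss.A == pytest.approx(expected_A, rel=1e-8)
            if b_star is None:
                b_star = ss.B
            else:  # B* is input-independent once decoupled
                assert ss.B == pytest.approx(b_star, rel=1e-8)

    def test_origin_invariant_when_leak_free(self, ideal_leakfree):
        dA, dB = dstate_dt(CircuitState(0.0, 0.0), 2.0, ideal_leakfree)
        assert dA == 0.0 and dB == 0.0


class TestAnalyticAdaptationLimit:
    def test_steady_output_matches_closed_form_over_100_fold_inputs(
            self, ideal_leakfree):
        a_star = closed_form_A(ideal_leakfree)
        for inp in np.geomspace(2.0, 200.0, 7):
            ss = steady_state(inp, ideal_leakfree)
            assert ss.A == pytest.approx(a_star, rel=1e-6)

    def test_monotone_in_alpha2_invariant_to_alpha1_KBA_input(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 20:
            p = defaults_v1("ideal_linear", leak_free=True).with_updates(
                alpha1=float(rng.uniform(5, 100)),
                alpha2=float(rng.uniform(1.3, 20)),
                K_BA=float(rng.uniform(0.2, 5)),
                K_AB=float(rng.uniform(0.2, 5)),
                n_AB=float(rng.integers(1, 4)),
                K_BB=1.0)
            a_star = closed_form_A(p)
            # skip draws whose activation branch cannot support A*
            inp = float(rng.uniform(1, 50))
            if p.alpha1 * input_drive(inp, p) * 0.8 < a_star:
                continue
            ss = steady_state(inp, p)
            assert ss.A == pytest.approx(a_star, rel=1e-6)
            # increasing alpha2 raises the adapted level
            p_up = p.with_updates(alpha2=p.alpha2 * 1.7)
            assert closed_form_A(p_up) > a_star
            if p.alpha1 * input_drive(inp, p) * 0.8 > closed_form_A(p_up):
                ss_up = steady_state(inp, p_up)
                assert ss_up.A > ss.A
            # alpha1 and K_BA leave it unchanged
            for q in (p.with_updates(alpha1=p.alpha1 * 2),
                      p.with_updates(K_BA=p.K_BA * 0.5)):
                assert steady_state(inp, q).A == pytest.approx(a_star, rel=1e-6)
            checked += 1

    def test_hill_form_consistent_with_ideal_limit(self):
        # saturating self-activation, n_BB=1, operating B << K_BB: the
        # post-step steady output deviates < 5% from the ideal-linear
        # closed form computed at the same parameters
        p = defaults_v1("hill", leak_free=True)
        a_star = closed_form_A(p)
        ss = steady_state(300.0, p)
        assert ss.B <= 0.05 * p.K_BB
        assert ss.A == pytest.approx(a_star, rel=0.05)


class TestSimulateStep:
    def test_no_perturbation_stays_at_steady_state(self, ideal_leakfree):
        exp = StepExperiment(2.0, 2.0, np.arange(0.0, 10.01, 0.5))
        stepped, control = simulate_step(exp, ideal_leakfree)
        assert np.allclose(stepped.A, stepped.A[0], rtol=1e-6)
        assert np.allclose(stepped.A, control.A, rtol=1e-6)

    def test_ideal_leakfree_returns_to_baseline(self, ideal_step_trajs):
        stepped, _ = ideal_step_trajs
        assert stepped.A[-1] == pytest.approx(1.0, rel=1e-6)

    def test_pulse_has_single_interior_maximum(self, ideal_step_trajs):
        stepped, _ = ideal_step_trajs
        y = stepped.A
        i = int(np.argmax(y))
        assert 0 < i < len(y) - 1
        assert y[i] > y[0] * 1.1
        # single transient maximum: rises before the peak, decays after,
        # up to the small numerical ripple of the spiral return
        assert np.all(np.diff(y[: i + 1]) > -1e-9)

    def test_control_series_is_flat(self, ideal_step_trajs):
        _, control = ideal_step_trajs
        assert np.allclose(control.A, control.A[0], rtol=1e-7)


class TestFixedPoints:
    def test_monostable_full_circuit(self, ideal_leaky):
        fps = find_fixed_points(2.0, ideal_leaky)
        stable = [s for s, ok in fps if ok]
        assert len(stable) == 1

    def test_clamped_buffer_cubic_balance(self):
        # with repression effectively absent, the buffer subsystem is
        # dB/dt = 4*(B^2.3/(1+B^2.3)+0.01) - B: two stable states separated
        # by a threshold (roots frozen from a brentq oracle)
        g = lambda b: 4.0 * (b ** 2.3 / (1 + b ** 2.3) + 0.01) - b
        grid = np.geomspace(1e-4, 1e2, 100000)
        v = g(grid)
        oracle = [brentq(g, grid[i], grid[i + 1], xtol=1e-14)
                  for i in np.nonzero(v[:-1] * v[1:] < 0)[0]]
        assert len(oracle) == 3
        assert oracle[0] == pytest.approx(0.042853, abs=1e-5)
        assert oracle[2] == pytest.approx(3.869578, abs=1e-5)

        p = bistable_nonlinear_pf().with_updates(K_AB=1e6, beta_AB=0.0)
        fps = find_fixed_points(2.0, p)
        assert len(fps) == 3
        for (state, _), b_oracle in zip(fps, oracle):
            assert state.B == pytest.approx(b_oracle, rel=1e-6)
        assert [ok for _, ok in fps] == [True, False, True]

    def test_nonlinear_pf_bistable_operating_point(self):
        fps = find_fixed_points(2.0, bistable_nonlinear_pf())
        stable = [s for s, ok in fps if ok]
        unstable = [s for s, ok in fps if not ok]
        assert len(stable) == 2 and len(unstable) == 1

    def test_matches_dense_grid_oracle_on_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = defaults_v1("hill").with_updates(
                alpha1=float(10 ** rng.uniform(-0.5, 2.5)),
                alpha2=float(10 ** rng.uniform(-0.5, 2.5)),
                K_BA=float(10 ** rng.uniform(-1, 1)),
                K_AB=float(10 ** rng.uniform(-1, 1)),
                K_BB=float(10 ** rng.uniform(-1, 1.5)),
                n_BA=float(rng.integers(1, 4)),
                n_AB=float(rng.integers(1, 4)),
                n_BB=float(rng.integers(1, 4)))
            found = [s.B for s, _ in find_fixed_points(2.0, p)]
            b_hi = 10.0 * p.alpha2 * (1 + p.beta_AB) * (1 + p.beta_BB)
            grid = np.geomspace(1e-9, b_hi, 100000)
            v = _reduced_residual(grid, 2.0, p)
            oracle = [brentq(_reduced_residual, grid[i], grid[i + 1],
                             args=(2.0, p), xtol=1e-14, rtol=1e-15)
                      for i in np.nonzero(np.sign(v[:-1]) * np.sign(v[1:]) < 0)[0]]
            assert len(found) == len(oracle)
            for b, bo in zip(found, sorted(oracle)):
                assert b == pytest.approx(bo, rel=1e-8, abs=1e-12)
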