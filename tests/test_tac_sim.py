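"""Compartment-model simulator: input curves, V_T identities, blocking."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coxpet as cp
from coxpet.tac_sim import analytic_vt, apply_blocking, simulate_input, simulate_tac


class TestSimulateInput:
    def test_zero_amplitudes_give_flat_zero_curve(self, fine_times):
        p = cp.InputModelParams(a_fast=0.0, a_slow=0.0)
        inp = simulate_input(p, fine_times)
        assert np.all(inp.parent_plasma == 0)

    def test_deterministic(self, input_params, fine_times):
        a = simulate_input(input_params, fine_times)
        b = simulate_input(input_params, fine_times)
        np.testing.assert_array_equal(a.parent_plasma, b.parent_plasma)

    def test_default_curve_shape(self, input_function, fine_times):
        c = input_function.parent_plasma
        assert c[0] == 0.0
        assert np.all(c >= 0)
        peak = np.argmax(c)
        assert fine_times[peak] < 3.0
        assert c[-1] < 0.1 * c[peak]

    def test_non_ascending_times_rejected_with_index(self, input_params):
        with pytest.raises(ValueError, match="index 2"):
            simulate_input(input_params, np.array([0.0, 1.0, 0.5, 2.0]))

    def test_negative_times_rejected(self, input_params):
        with pytest.raises(ValueError, match="non-negative"):
            simulate_input(input_params, np.array([-1.0, 0.0, 1.0]))


class TestAnalyticVt:
    @pytest.mark.parametrize(
        "params, expected",
        [
            (dict(K1=0.1, k2=0.1), 1.0),
            (dict(K1=0.1, k2=0.1, k3=0.05, k4=0.05), 2.0),
            (dict(K1=0.3, k2=0.1, k3=0.2, k4=0.1), 9.0),
        ],
    )
    def test_closed_form(self, params, expected):
        assert analytic_vt(cp.KineticParams(**params)) == pytest.approx(expected)

    def test_k3_without_k4_rejected_at_construction(self):
        with pytest.raises(ValueError):
            cp.KineticParams(K1=0.1, k2=0.1, k3=0.05, k4=0.0)

    @given(
        K1=st.floats(0.05, 0.3),
        k2=st.floats(0.05, 0.2),
        k3=st.floats(0.01, 0.1),
        k4=st.floats(0.02, 0.1),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_each_rate(self, K1, k2, k3, k4):
        base = analytic_vt(cp.KineticParams(K1=K1, k2=k2, k3=k3, k4=k4))
        eps = 1e-4
        up = lambda **kw: analytic_vt(cp.KineticParams(**{**dict(K1=K1, k2=k2, k3=k3, k4=k4), **kw}))
        assert up(K1=K1 + eps) > base
        assert up(k3=k3 + eps) > base
        assert up(k2=k2 + eps) < base
        assert up(k4=k4 + eps) < base


class TestSimulateTac:
    def test_no_delivery_gives_zero_tac(self, input_function, schedule_120):
        p = cp.KineticParams(K1=0.0, k2=0.1)
        tac = simulate_tac(p, input_function, schedule_120)
        assert np.all(tac.values == 0)

    def test_noise_free_is_reproducible(self, params_2t, input_function, schedule_120):
        a = simulate_tac(params_2t, input_function, schedule_120)
        b = simulate_tac(params_2t, input_function, schedule_120)
        np.testing.assert_array_equal(a.values, b.values)

    def test_noise_free_tac_non_negative(self, input_function, schedule_120):
        for p in (cp.KineticParams(K1=0.05, k2=0.2),
                  cp.KineticParams(K1=0.3, k2=0.05, k3=0.1, k4=0.02, vB=0.05)):
            tac = simulate_tac(p, input_function, schedule_120)
            assert np.all(tac.values >= 0)

    def test_terminal_ratio_approaches_equilibrium(self, input_function, schedule_120):
        # one-tissue V_T = K1/k2 = 2; terminal-frame tissue/plasma near it
        p = cp.KineticParams(K1=0.1, k2=0.05)
        tac = simulate_tac(p, input_function, schedule_120)
        ratio = tac.values[-1] / input_function.at(schedule_120.mid[-1])
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_ratio_converges_with_scan_length(self, input_params):
        p = cp.KineticParams(K1=0.1, k2=0.05)
        t = np.arange(0.0, 240.0001, 0.1)
        inp = cp.simulate_input(input_params, t)
        errs = []
        for total in (60.0, 120.0, 240.0):
            sched = cp.default_frame_schedule(total)
            tac = simulate_tac(p, inp, sched)
            ratio = tac.values[-1] / inp.at(sched.mid[-1])
            errs.append(abs(ratio - 2.0))
        assert errs[2] < errs[0]

    def test_schedule_beyond_input_rejected(self, params_2t, input_params):
        inp = cp.simulate_input(input_params, np.arange(0.0, 60.0001, 0.1))
        with pytest.raises(ValueError, match="support"):
            simulate_tac(params_2t, inp, cp.default_frame_schedule(120.0))

    def test_proportional_noise_is_seeded(self, params_2t, input_function, schedule_120):
        n = cp.NoiseModel("proportional", 0.05, seed=4)
        a = simulate_tac(params_2t, input_function, schedule_120, n)
        b = simulate_tac(params_2t, input_function, schedule_120, n)
        c = simulate_tac(params_2t, input_function, schedule_120,
                         cp.NoiseModel("proportional", 0.05, seed=5))
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)


class TestApplyBlocking:
    def test_zero_occupancy_is_identity(self, params_2t):
        vnd = cp.KineticParams(K1=0.1, k2=0.1)
        assert apply_blocking(params_2t, 0.0, vnd) == params_2t

    def test_full_occupancy_collapses_to_vnd(self, params_2t):
        vnd = cp.KineticParams(K1=0.1, k2=0.1)  # V_ND = 1.0 = K1/k2 of target
        blocked = apply_blocking(params_2t, 1.0, vnd)
        assert analytic_vt(blocked) == pytest.approx(1.0)

    def test_partial_blockade_arithmetic(self):
        # V_T = 10 with V_ND = 4.3 at occupancy 0.78 -> 4.3 + 0.22*5.7 = 5.554
        target = cp.KineticParams(K1=0.43, k2=0.1, k3=0.1 * (10 / 4.3 - 1), k4=0.1)
        vnd = cp.KineticParams(K1=0.43, k2=0.1)
        blocked = apply_blocking(target, 0.78, vnd)
        assert analytic_vt(blocked) == pytest.approx(5.554, abs=1e-9)

    def test_occupancy_out_of_range_rejected(self, params_2t):
        vnd = cp.KineticParams(K1=0.1, k2=0.1)
        with pytest.raises(ValueError):
            apply_blocking(params_2t, 1.2, vnd)

    def test_blocking_then_logan_recovers_blocked_vt(
        self, input_function, schedule_120
    ):
        # forward-model consistency: simulate blocked kinetics noise-free and
        # re-estimate V_T graphically
        target = cp.KineticParams(K1=0.43, k2=0.1, k3=0.06, k4=0.05)  # V_T = 9.46
        vnd = cp.KineticParams(K1=0.43, k2=0.1)
        occ = 0.78
        blocked = apply_blocking(target, occ, vnd)
        expected = 4.3 + (1 - occ) * (analytic_vt(target) - 4.3)
        tac = simulate_tac(blocked, input_function, schedule_120)
        fit = cp.logan_vt(tac, input_function, 30.0)
        assert fit.v_t == pytest.approx(expected, rel=0.02)
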