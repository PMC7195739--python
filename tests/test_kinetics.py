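"""Logan graphical analysis, t* selection, and SUV measures."""
import numpy as np
import pytest

import coxpet as cp
from coxpet.kinetics import logan_vt, select_t_star, suv, suv_ratio_specific
from coxpet.tac_sim import analytic_vt, simulate_tac


def _proportional_tac(input_function, schedule, v=3.0):
    values = v * input_function.at(schedule.mid)
    return cp.TimeActivityCurve("prop", schedule, values)


class TestLoganVt:
    def test_proportional_identity(self, input_function, schedule_120):
        fit = logan_vt(_proportional_tac(input_function, schedule_120), input_function, 10.0)
        assert fit.v_t == pytest.approx(3.0, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_tissue_recovery(self, params_2t, input_function, schedule_120):
        tac = simulate_tac(params_2t, input_function, schedule_120)
        fit = logan_vt(tac, input_function, 30.0)
        assert fit.v_t == pytest.approx(2.0, rel=0.02)

    def test_one_tissue_recovery(self, input_function, schedule_120):
        p = cp.KineticParams(K1=0.1, k2=0.05)
        tac = simulate_tac(p, input_function, schedule_120)
        fit = logan_vt(tac, input_function, 30.0)
        assert fit.v_t == pytest.approx(2.0, rel=0.01)

    def test_scale_equivariance(self, params_2t, input_function, schedule_120):
        # scaling both the input and the TAC by c leaves V_T unchanged
        tac = simulate_tac(params_2t, input_function, schedule_120)
        fit = logan_vt(tac, input_function, 30.0)
        c = 7.3
        scaled_input = cp.InputFunction(
            input_function.times, c * input_function.parent_plasma
        )
        scaled_tac = cp.TimeActivityCurve("s", schedule_120, c * tac.values)
        fit_scaled = logan_vt(scaled_tac, scaled_input, 30.0)
        assert fit_scaled.v_t == pytest.approx(fit.v_t, rel=1e-9)

    def test_nonpositive_tissue_in_window_rejected(self, input_function, schedule_120):
        values = np.ones(schedule_120.n_frames)
        values[-2] = 0.0
        tac = cp.TimeActivityCurve("bad", schedule_120, values)
        with pytest.raises(ValueError, match="frame"):
            logan_vt(tac, input_function, 30.0)

    def test_too_few_fit_points_rejected(self, input_function, schedule_120):
        tac = _proportional_tac(input_function, schedule_120)
        with pytest.raises(ValueError, match="at least 3"):
            logan_vt(tac, input_function, 115.0)

    def test_t_star_outside_scan_rejected(self, input_function, schedule_120):
        tac = _proportional_tac(input_function, schedule_120)
        with pytest.raises(ValueError, match="outside the scan"):
            logan_vt(tac, input_function, 500.0)

    @pytest.mark.parametrize("K1", [0.05, 0.3])
    @pytest.mark.parametrize("k2", [0.05, 0.2])
    @pytest.mark.parametrize("k3", [0.0, 0.1])
    @pytest.mark.parametrize("k4", [0.02, 0.1])
    def test_underestimates_within_box(self, K1, k2, k3, k4, input_function,
                                       schedule_120):
        """Logan slope on noise-free reversible data never exceeds the
        analytic V_T (beyond numerical tolerance); the error stays <= 2%
        for kinetics whose slowest eigenvalue equilibrates on the scan."""
        p = cp.KineticParams(K1=K1, k2=k2, k3=k3, k4=k4 if k3 > 0 else 0.0)
        vt = analytic_vt(p)
        tac = simulate_tac(p, input_function, schedule_120)
        fit = logan_vt(tac, input_function, 30.0)
        assert fit.v_t <= vt * 1.005
        if k3 == 0:
            slowest = k2
        else:
            beta = k2 + k3 + k4
            slowest = 0.5 * (beta - np.sqrt(beta * beta - 4 * k2 * k4))
        if slowest * 120.0 >= 2.0:  # tissue equilibrates within the scan
            assert abs(fit.v_t - vt) / vt <= 0.02

    def test_noisy_mean_bias_small(self, params_2t, input_function, schedule_120):
        """Proportional noise at 5%: |mean bias| of V_T < 5% over 200 seeds."""
        vals = []
        for seed in range(200):
            tac = simulate_tac(params_2t, input_function, schedule_120,
                               cp.NoiseModel("proportional", 0.05, seed))
            try:
                vals.append(logan_vt(tac, input_function, 30.0).v_t)
            except ValueError:
                continue
        assert len(vals) > 190
        assert abs(np.mean(vals) - 2.0) / 2.0 < 0.05


class TestSelectTStar:
    def test_proportional_tac_gives_earliest_midpoint(self, input_function,
                                                      schedule_120):
        tac = _proportional_tac(input_function, schedule_120)
        assert select_t_star(tac, input_function) == schedule_120.mid[0]

    def test_two_tissue_t_star_is_early(self, params_2t, input_function,
                                        schedule_120):
        tac = simulate_tac(params_2t, input_function, schedule_120)
        assert select_t_star(tac, input_function, 0.10) <= 40.0

    def test_pure_noise_falls_back_with_warning(self, input_function, schedule_120):
        rng = np.random.default_rng(0)
        values = rng.normal(0.0, 1.0, schedule_120.n_frames)
        tac = cp.TimeActivityCurve("noise", schedule_120, values)
        with pytest.warns(UserWarning):
            ts = select_t_star(tac, input_function, 0.01)
        assert 0 < ts <= schedule_120.total_minutes


class TestSuv:
    def test_constant_concentration_unit_suv(self, schedule_120):
        # 18.5 kBq/mL, 185 MBq into 10 kg -> SUV exactly 1
        tac = cp.TimeActivityCurve("r", schedule_120,
                                   np.full(schedule_120.n_frames, 18.5))
        assert suv(tac, 185.0, 10.0, (60.0, 90.0)).suv == pytest.approx(1.0)

    def test_zero_activity_zero_suv(self, schedule_120):
        tac = cp.TimeActivityCurve("r", schedule_120,
                                   np.zeros(schedule_120.n_frames))
        assert suv(tac, 185.0, 10.0, (60.0, 90.0)).suv == 0.0

    def test_duration_weighted_mean(self):
        sched = cp.FrameSchedule([0.0, 10.0], [10.0, 30.0])
        tac = cp.TimeActivityCurve("r", sched, np.array([2.0, 1.4]))
        m = suv(tac, 185.0, 10.0, (0.0, 30.0))
        # (10*2.0 + 20*1.4)/30 = 1.6 kBq/mL over 18.5 kBq/g
        assert m.suv == pytest.approx(1.6 / 18.5)

    def test_window_outside_scan_rejected(self, schedule_120):
        tac = cp.TimeActivityCurve("r", schedule_120,
                                   np.ones(schedule_120.n_frames))
        with pytest.raises(ValueError, match="window"):
            suv(tac, 185.0, 10.0, (100.0, 140.0))


class TestSuvRatioSpecific:
    def test_identical_conditions_zero(self):
        assert suv_ratio_specific(3.0, 1.5, 3.0, 1.5) == 0.0

    def test_day1_magnitude(self):
        assert suv_ratio_specific(6.25, 1.0, 1.04, 1.0) == pytest.approx(5.21)

    def test_plain_arithmetic(self):
        assert suv_ratio_specific(4.0, 2.0, 3.0, 2.0) == pytest.approx(0.5)

    def test_zero_blood_rejected(self):
        with pytest.raises(ValueError):
            suv_ratio_specific(4.0, 0.0, 3.0, 2.0)
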