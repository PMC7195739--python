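"""Synthetic tracer-kinetic data: input functions and tissue curves.

The forward model is the reversible two-tissue-compartment system

    dC1/dt = K1*Cp - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2

driven by the metabolite-corrected parent plasma concentration Cp(t).
Its total distribution volume is V_T = (K1/k2) * (1 + k3/k4), reducing
to K1/k2 when k3 = 0 (one-tissue model).  A blocking condition scales
the specific component of V_T by an occupancy fraction, leaving the
nondisplaceable component V_ND untouched:

    V_T(blocked) = V_ND + (1 - occupancy) * (V_T - V_ND).

All concentrations are assumed decay-corrected to injection time; no
radioactive-decay term appears anywhere.

The arterial input is a peaked tri-exponential (two decaying terms and
one shared rising term), which is non-negative, zero at t = 0, has a
single early peak, and integrates in closed form.  The parent-fraction
parameters attached to it let the generator also emit total-plasma and
whole-blood companion curves for SUV ratios and blood-volume terms.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .curves import FrameSchedule, TimeActivityCurve
from .plasma_input import InputFunction, ParentFractionCurve

__all__ = [
    "KineticParams",
    "InputModelParams",
    "NoiseModel",
    "simulate_input",
    "analytic_vt",
    "simulate_tac",
    "apply_blocking",
]

FINE_DT = 0.1  # minutes; fine-grid resolution for the convolution


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the (up to) two-tissue compartment model.

    K1 in mL cm^-3 min^-1; k2, k3, k4 in min^-1; vB is the fractional
    blood volume of the PET region (unitless, < 0.2).
    """

    K1: float
    k2: float
    k3: float = 0.0
    k4: float = 0.0
    vB: float = 0.0

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.k2 <= 0:
            raise ValueError("K1 must be >= 0 and k2 > 0")
        if self.k3 < 0 or self.k4 < 0:
            raise ValueError("k3 and k4 must be >= 0")
        if self.k3 > 0 and self.k4 == 0:
            raise ValueError("k3 > 0 requires k4 > 0 (V_T undefined otherwise)")
        if not (0.0 <= self.vB < 0.2):
            raise ValueError("vB must lie in [0, 0.2)")


@dataclass(frozen=True)
class InputModelParams:
    """Parameters of the parametric arterial input model.

    parent(t) = a_fast*exp(-lam_fast*t) + a_slow*exp(-lam_slow*t)
                - (a_fast + a_slow)*exp(-lam_rise*t)

    with lam_rise > lam_fast, lam_slow so the curve rises from zero to a
    single early peak and stays non-negative.  ``pf_rate``/``pf_plateau``
    parameterize the companion parent-fraction curve
    pf(t) = (1 - c) exp(-rate t) + c used to derive total plasma;
    ``blood_plasma_ratio`` converts total plasma to whole blood.
    """

    a_fast: float = 30.0      # kBq/mL
    a_slow: float = 1.5       # kBq/mL
    lam_fast: float = 0.4     # 1/min
    lam_slow: float = 0.0015  # 1/min
    lam_rise: float = 3.0     # 1/min
    pf_rate: float = 0.06     # 1/min
    pf_plateau: float = 0.08  # unitless
    blood_plasma_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.a_fast < 0 or self.a_slow < 0:
            raise ValueError("amplitudes must be >= 0")
        if min(self.lam_fast, self.lam_slow, self.lam_rise) < 0:
            raise ValueError("rate constants must be >= 0")
        if (self.a_fast + self.a_slow) > 0 and self.lam_rise <= max(self.lam_fast, self.lam_slow):
            raise ValueError("lam_rise must exceed the decay rates (peaked curve)")
        if not (0.0 <= self.pf_plateau <= 1.0) or self.pf_rate < 0:
            raise ValueError("invalid parent-fraction parameters")
        if self.blood_plasma_ratio <= 0:
            raise ValueError("blood_plasma_ratio must be > 0")

    def parent(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        total = self.a_fast + self.a_slow
        c = (self.a_fast * np.exp(-self.lam_fast * t)
             + self.a_slow * np.exp(-self.lam_slow * t)
             - total * np.exp(-self.lam_rise * t))
        return np.maximum(c, 0.0)

    def parent_fraction(self) -> ParentFractionCurve:
        return ParentFractionCurve(self.pf_rate, self.pf_plateau)


@dataclass(frozen=True)
class NoiseModel:
    """Frame-level measurement noise.

    ``proportional`` adds zero-mean Gaussian noise with
    SD = coefficient * value / sqrt(frame duration), which mimics the
    count-statistics scaling of PET frames without modeling decay.
    ``none`` leaves the curve deterministic.
    """

    kind: str = "none"
    coefficient: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "proportional"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.coefficient < 0:
            raise ValueError("coefficient must be >= 0")


def simulate_input(params: InputModelParams, times: np.ndarray) -> InputFunction:
    """Evaluate the parametric arterial model at ``times`` (minutes).

    Returns an :class:`InputFunction` carrying parent plasma plus the
    derived total-plasma and whole-blood companion curves.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("times must be a 1-D array with >= 2 points")
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        bad = int(np.argmax(diffs <= 0)) + 1
        raise ValueError(f"times must be strictly ascending (offending index {bad})")
    if times[0] < 0:
        raise ValueError("times must be non-negative")
    parent = params.parent(times)
    pf = params.parent_fraction()(times)
    with np.errstate(divide="ignore", invalid="ignore"):
        total = np.where(pf > 0, parent / np.maximum(pf, 1e-12), parent)
    wb = total * params.blood_plasma_ratio
    return InputFunction(times=times, parent_plasma=parent,
                         total_plasma=total, whole_blood=wb)


def analytic_vt(params: KineticParams) -> float:
    """Closed-form total distribution volume of the compartment model.

    V_T = K1/k2 * (1 + k3/k4); K1/k2 for the one-tissue case (k3 = 0).
    """
    if params.k3 == 0:
        return params.K1 / params.k2
    if params.k4 == 0:
        raise ValueError("V_T undefined: k3 > 0 with k4 = 0")
    return params.K1 / params.k2 * (1.0 + params.k3 / params.k4)


def _impulse_response(params: KineticParams, t: np.ndarray) -> np.ndarray:
    """Tissue impulse response of the compartment system (closed form)."""
    if params.k3 == 0:
        return params.K1 * np.exp(-params.k2 * t)
    beta = params.k2 + params.k3 + params.k4
    disc = np.sqrt(beta * beta - 4.0 * params.k2 * params.k4)
    a1 = 0.5 * (beta - disc)
    a2 = 0.5 * (beta + disc)
    if a2 - a1 < 1e-12:
        # Repeated eigenvalue; limit of the two-exponential form.
        return params.K1 * np.exp(-a1 * t) * (1.0 + (params.k3 + params.k4 - a1) * t)
    w1 = (params.k3 + params.k4 - a1) / (a2 - a1)
    w2 = (a2 - params.k3 - params.k4) / (a2 - a1)
    return params.K1 * (w1 * np.exp(-a1 * t) + w2 * np.exp(-a2 * t))


def simulate_tac(
    params: KineticParams,
    input_function: InputFunction,
    schedule: FrameSchedule,
    noise: Optional[NoiseModel] = None,
    region: str = "sim",
) -> TimeActivityCurve:
    """Solve the compartment model and average into PET frames.

    The convolution of the input with the compartmental impulse response
    is evaluated by trapezoidal quadrature on a 0.1-min grid, frames are
    sampled by their within-frame mean, a vB-weighted whole-blood term is
    mixed in, and frame noise is applied last.  With ``noise=None`` (or
    kind ``none``) the output is reproducible to numerical tolerance.
    """
    if input_function.span < schedule.total_minutes - 1e-9:
        raise ValueError(
            f"input function support ends at {input_function.span} min but the "
            f"schedule extends to {schedule.total_minutes} min"
        )
    n = int(np.ceil(schedule.total_minutes / FINE_DT)) + 1
    t = np.arange(n) * FINE_DT
    cp = input_function.at(t)
    irf = _impulse_response(params, t)
    conv = np.convolve(cp, irf)[:n]
    ct = FINE_DT * (conv - 0.5 * (cp[0] * irf + irf[0] * cp))
    ct = np.maximum(ct, 0.0)

    if params.vB > 0:
        if input_function.whole_blood is not None:
            wb = np.interp(t, input_function.times, input_function.whole_blood,
                           left=0.0)
        else:
            wb = cp
        measured = (1.0 - params.vB) * ct + params.vB * wb
    else:
        measured = ct

    cum = cumulative_trapezoid(measured, t, initial=0.0)
    frame_int = np.interp(schedule.end, t, cum) - np.interp(schedule.start, t, cum)
    values = frame_int / schedule.duration

    if noise is not None and noise.kind == "proportional" and noise.coefficient > 0:
        rng = np.random.default_rng(noise.seed)
        sd = noise.coefficient * np.abs(values) / np.sqrt(schedule.duration)
        values = values + rng.normal(0.0, 1.0, size=values.shape) * sd

    return TimeActivityCurve(region=region, schedule=schedule, values=values)


def apply_blocking(
    params: KineticParams, occupancy: float, vnd_params: KineticParams
) -> KineticParams:
    """Forward model of pharmacological blockade at a given occupancy.

    Returns rate constants whose analytic V_T equals
    V_ND + (1 - occupancy) * (V_T - V_ND), where V_ND is the analytic
    V_T of ``vnd_params``.  Occupancy 0 returns ``params`` unchanged;
    occupancy 1 collapses V_T onto V_ND.  The blocked curve keeps K1, k2
    and k4 of ``params`` and rescales k3 (the specific-binding step).
    """
    if not (0.0 <= occupancy <= 1.0):
        raise ValueError(f"occupancy must lie in [0, 1], got {occupancy}")
    if occupancy == 0.0:
        return params
    vt = analytic_vt(params)
    vnd = analytic_vt(vnd_params)
    vt_blocked = vnd + (1.0 - occupancy) * (vt - vnd)
    nd_ratio = vt_blocked / (params.K1 / params.k2)
    if nd_ratio < 1.0 - 1e-9:
        raise ValueError(
            "blocked V_T falls below the nondisplaceable volume K1/k2 of the "
            "target region; blocking cannot be represented by rescaling k3"
        )
    k4 = params.k4 if params.k4 > 0 else vnd_params.k4
    k3 = max(nd_ratio - 1.0, 0.0) * k4
    if k3 > 0 and k4 == 0:
        raise ValueError("cannot represent residual specific binding without k4")
    return replace(params, k3=k3, k4=k4 if k3 > 0 else params.k4)
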