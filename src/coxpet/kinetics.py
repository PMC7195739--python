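"""Logan graphical analysis and SUV measures.

The Logan plot transforms a reversible tracer's kinetics into a straight
line: with x(t) = int_0^t Cp / C_tissue(t) and
y(t) = int_0^t C_tissue / C_tissue(t), the points become linear for
t >= t* and the slope is the total distribution volume V_T.  Integrals
are taken by trapezoid on the frame-midpoint grid (with the input
resampled to the midpoints), and the fit is ordinary least squares on
points at or after t*.

SUV normalizes tissue concentration by injected dose per body weight
under the 1 mL = 1 g mass convention (no density correction).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.stats import linregress

from .curves import FrameSchedule, TimeActivityCurve
from .plasma_input import InputFunction

log = logging.getLogger(__name__)

__all__ = ["LoganFit", "SuvMeasure", "logan_vt", "select_t_star", "suv",
           "suv_ratio_specific"]


@dataclass(frozen=True)
class LoganFit:
    """Result of a Logan graphical fit: slope is V_T (mL cm^-3)."""

    v_t: float
    intercept: float  # minutes
    t_star: float     # minutes
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a Logan fit needs at least 3 points")
        if not (-1e-9 <= self.r_squared <= 1.0 + 1e-9):
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class SuvMeasure:
    """Standardized uptake value over a time window (g/mL convention)."""

    suv: float
    window: Tuple[float, float]  # minutes
    ratio_to_blood: Optional[float] = None

    def __post_init__(self) -> None:
        if self.suv < 0:
            raise ValueError("SUV must be >= 0")


def _logan_points(
    tac: TimeActivityCurve, input_function: InputFunction
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Logan coordinates at frame midpoints plus a validity mask.

    Both numerator integrals are accumulated by trapezoid on the grid
    [0, mid_1, ..., mid_N] so that a TAC exactly proportional to the
    input yields an exactly proportional point cloud.
    """
    mids = tac.schedule.mid
    grid = np.concatenate([[0.0], mids])
    cp = input_function.at(grid)
    ct = np.concatenate([[0.0], tac.values])
    int_cp = cumulative_trapezoid(cp, grid, initial=0.0)[1:]
    int_ct = cumulative_trapezoid(ct, grid, initial=0.0)[1:]
    valid = tac.values > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(valid, int_cp / tac.values, np.nan)
        y = np.where(valid, int_ct / tac.values, np.nan)
    return mids, x, y, valid


def logan_vt(
    tac: TimeActivityCurve, input_function: InputFunction, t_star: float
) -> LoganFit:
    """Estimate V_T as the Logan slope over frames with midpoint >= t*.

    Requires at least three frames at or after ``t_star``, all with
    positive tissue values.
    """
    mids = tac.schedule.mid
    if not (0.0 <= t_star <= mids[-1]):
        raise ValueError(f"t_star {t_star} min lies outside the scan (last midpoint "
                         f"{mids[-1]} min)")
    _, x, y, valid = _logan_points(tac, input_function)
    in_window = mids >= t_star - 1e-9
    bad = in_window & ~valid
    if np.any(bad):
        frame = int(np.argmax(bad))
        raise ValueError(
            f"frame {frame} (midpoint {mids[frame]:.2f} min) has non-positive "
            "tissue activity inside the fit window"
        )
    if int(in_window.sum()) < 3:
        raise ValueError(
            f"only {int(in_window.sum())} frames at/after t* = {t_star} min; "
            "need at least 3"
        )
    res = linregress(x[in_window], y[in_window])
    r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else 0.0
    return LoganFit(
        v_t=float(res.slope),
        intercept=float(res.intercept),
        t_star=float(t_star),
        r_squared=min(r2, 1.0),
        n_points=int(in_window.sum()),
    )


def select_t_star(
    tac: TimeActivityCurve,
    input_function: InputFunction,
    max_rel_err: float = 0.10,
) -> float:
    """Earliest midpoint after which the Logan points are linear.

    A reference line is fit to the final third of the (valid) Logan
    points; the returned t* is the earliest frame midpoint such that
    every later point deviates from that line by at most ``max_rel_err``
    relative, with at least three points remaining.  If no midpoint
    qualifies, falls back to mid-scan with a warning.
    """
    if max_rel_err <= 0:
        raise ValueError("max_rel_err must be > 0")
    mids, x, y, valid = _logan_points(tac, input_function)
    fallback = float(mids[np.argmin(np.abs(mids - 0.5 * tac.schedule.total_minutes))])
    idx = np.flatnonzero(valid)
    if idx.size < 3:
        warnings.warn("too few valid Logan points; falling back to mid-scan t*")
        return fallback
    tail = idx[-max(3, idx.size // 3):]
    res = linregress(x[tail], y[tail])
    with np.errstate(invalid="ignore"):
        dev = np.abs(y - (res.slope * x + res.intercept)) / np.maximum(np.abs(y), 1e-12)
    for i in idx:
        later = idx[idx >= i]
        if later.size >= 3 and np.all(dev[later] <= max_rel_err):
            return float(mids[i])
    warnings.warn("no midpoint satisfied the Logan linearity tolerance; "
                  "falling back to mid-scan t*")
    return fallback


def suv(
    tac: TimeActivityCurve,
    injected_dose_mbq: float,
    body_weight_kg: float,
    window: Tuple[float, float],
) -> SuvMeasure:
    """Duration-weighted mean SUV over a time window.

    SUV = mean concentration (kBq/mL) / (injected dose in kBq per gram
    of body weight); frames partially inside the window contribute by
    their overlap.
    """
    if injected_dose_mbq <= 0 or body_weight_kg <= 0:
        raise ValueError("dose and body weight must be > 0")
    w0, w1 = window
    sched = tac.schedule
    if w0 < sched.start[0] - 1e-9 or w1 > sched.end[-1] + 1e-9 or w1 <= w0:
        raise ValueError(f"window {window} must lie within the scan "
                         f"[{sched.start[0]}, {sched.end[-1]}] min")
    overlap = np.minimum(sched.end, w1) - np.maximum(sched.start, w0)
    overlap = np.maximum(overlap, 0.0)
    if overlap.sum() <= 0:
        raise ValueError("window does not overlap any frame")
    mean_conc = float(np.sum(tac.values * overlap) / overlap.sum())
    dose_kbq_per_g = injected_dose_mbq * 1000.0 / (body_weight_kg * 1000.0)
    return SuvMeasure(suv=max(mean_conc, 0.0) / dose_kbq_per_g, window=(w0, w1))


def suv_ratio_specific(
    brain_suv_base: float,
    blood_suv_base: float,
    brain_suv_block: float,
    blood_suv_block: float,
) -> float:
    """Specific uptake as the drop of the brain/blood SUV ratio under
    self-blockade: (brain/blood)_baseline - (brain/blood)_blocked."""
    if blood_suv_base <= 0 or blood_suv_block <= 0:
        raise ValueError("blood SUV must be > 0")
    return brain_suv_base / blood_suv_base - brain_suv_block / blood_suv_block
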