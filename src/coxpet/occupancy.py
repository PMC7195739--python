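"""Lassen occupancy plots and outcome arithmetic.

The Lassen plot regresses the blockade-induced drop in regional
distribution volume on the baseline value:

    y = V_T(baseline) - V_T(blocked)  vs  x = V_T(baseline).

Under the assumptions of a region-invariant nondisplaceable volume V_ND
and uniform target occupancy, the points are linear: the slope is the
occupancy and the x-intercept is V_ND.  A fit-quality gate (r^2 and
slope sign) marks fits that do not support a reliable straight line.

The same construction applied to SUV instead of V_T is a surrogate
that is only valid insofar as SUV is proportional to V_T; surrogate
results carry an explicit flag.

Also here: binding potential BP_ND = (V_T - V_ND)/V_ND, percent change,
group means, and right/left uptake ratios — the arithmetic behind the
headline outcome numbers — plus the half-up presentation rounding used
when printing them.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import linregress

__all__ = [
    "LassenFit",
    "lassen",
    "lassen_suv_surrogate",
    "bp_nd",
    "percent_change",
    "group_mean",
    "rl_ratio",
    "present",
]

R_SQUARED_GATE = 0.5  # below this the straight-line fit is flagged unreliable


@dataclass(frozen=True)
class LassenFit:
    """Occupancy-plot result.

    ``occupancy`` is the OLS slope (a fraction; unconstrained by the fit
    but ``occupancy_in_range`` flags values outside [0, 1]); ``v_nd`` is
    the x-intercept, NaN when the slope is non-positive.  ``reliable``
    is False when r^2 < 0.5 or the slope is <= 0, mirroring plots whose
    point clouds do not support a straight-line reading.  ``surrogate``
    marks fits run on SUV rather than fully quantified V_T.
    """

    occupancy: float
    v_nd: float
    slope_se: float
    r_squared: float
    p_value: float
    points: Tuple[Tuple[float, float], ...]
    reliable: bool
    surrogate: bool = False

    @property
    def occupancy_in_range(self) -> bool:
        return 0.0 <= self.occupancy <= 1.0


def _lassen_fit(
    baseline: Mapping[str, float],
    blocked: Mapping[str, float],
    surrogate: bool,
) -> LassenFit:
    if set(baseline) != set(blocked):
        missing = set(baseline) ^ set(blocked)
        raise ValueError(f"baseline and blocked region sets differ: {sorted(missing)}")
    if len(baseline) < 3:
        raise ValueError(f"need >= 3 regions for a Lassen fit, got {len(baseline)}")
    regions = sorted(baseline)
    x = np.array([baseline[r] for r in regions], dtype=float)
    y = x - np.array([blocked[r] for r in regions], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("baseline V_T identical across regions; slope undefined")
    res = linregress(x, y)
    slope = float(res.slope)
    intercept = float(res.intercept)
    r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else 0.0
    v_nd = -intercept / slope if slope > 1e-12 else float("nan")
    reliable = (r2 >= R_SQUARED_GATE) and (slope > 0)
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return LassenFit(
        occupancy=slope,
        v_nd=v_nd,
        slope_se=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        r_squared=min(r2, 1.0),
        p_value=p,
        points=tuple(zip(x.tolist(), y.tolist())),
        reliable=reliable,
        surrogate=surrogate,
    )


def lassen(
    baseline: Mapping[str, float], blocked: Mapping[str, float]
) -> LassenFit:
    """Occupancy plot on regional distribution volumes.

    ``baseline`` and ``blocked`` map the same region labels to V_T
    (mL cm^-3) under the two conditions.
    """
    return _lassen_fit(baseline, blocked, surrogate=False)


def lassen_suv_surrogate(
    baseline_suv: Mapping[str, float], blocked_suv: Mapping[str, float]
) -> LassenFit:
    """Occupancy plot on regional SUV, as a surrogate for V_T.

    Numerically identical to :func:`lassen`; the result is flagged
    ``surrogate=True``.  The surrogate is valid only if SUV is
    proportional to V_T across regions, which needs arterial data to
    verify.
    """
    return _lassen_fit(baseline_suv, blocked_suv, surrogate=True)


def bp_nd(v_t: float, v_nd: float) -> float:
    """Binding potential BP_ND = (V_T - V_ND) / V_ND; requires V_ND > 0."""
    if v_nd <= 0:
        raise ValueError("V_ND must be > 0")
    return (v_t - v_nd) / v_nd


def percent_change(before: float, after: float) -> float:
    """100 * (after - before) / before, unrounded (round at presentation)."""
    if before == 0:
        raise ValueError("percent change undefined for a zero baseline")
    return 100.0 * (after - before) / before


def group_mean(values: Sequence[float]) -> float:
    """Arithmetic mean of per-animal values (presentation: 2 decimals)."""
    if len(values) == 0:
        raise ValueError("cannot average an empty list")
    return float(np.mean(np.asarray(values, dtype=float)))


def rl_ratio(right: float, left: float) -> float:
    """Right/left uptake ratio; requires left > 0."""
    if left <= 0:
        raise ValueError("left-side value must be > 0")
    return right / left


def present(value: float, decimals: int = 0) -> float:
    """Half-up presentation rounding (the convention of printed tables,
    where e.g. the mean of 3.71 and 3.48 prints as 3.60)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(round(value, 10))).quantize(q, rounding=ROUND_HALF_UP))
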