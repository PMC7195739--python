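"""Metabolite-corrected arterial input functions.

Radioligand in arterial plasma is progressively metabolized; only the
parent compound drives tissue uptake.  Timed blood samples give total
plasma activity and, on a subset of samples, the measured parent
fraction.  This module fits a smooth monotone parent-fraction curve and
multiplies it into the plasma curve to build the input function used by
the graphical analyses.

The parent-fraction model is a single decaying exponential with a
plateau, pf(t) = (1 - c) * exp(-rate * t) + c with 0 <= c <= 1, which
starts at 1, is monotone non-increasing, and captures the typical
profile of a rapidly metabolized carbon-11 ligand with a stable late
metabolite equilibrium.  The form is a documented default.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import curve_fit

log = logging.getLogger(__name__)

__all__ = [
    "BloodSample",
    "InputFunction",
    "ParentFractionCurve",
    "fit_parent_fraction",
    "build_input",
    "default_sampling_times",
]


@dataclass(frozen=True)
class BloodSample:
    """One timed arterial blood draw.

    ``time`` is minutes from injection (draw midpoint); activities are
    decay-corrected kBq/mL; ``parent_fraction`` is the measured fraction
    of plasma activity that is unmetabolized parent, when available.
    """

    time: float
    whole_blood: float
    plasma: float
    parent_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("sample time must be >= 0")
        if self.whole_blood < 0 or self.plasma < 0:
            raise ValueError("activities must be >= 0")
        if self.parent_fraction is not None and not (0.0 <= self.parent_fraction <= 1.0):
            raise ValueError("parent_fraction must lie in [0, 1]")


@dataclass
class InputFunction:
    """Parent radioligand concentration in arterial plasma vs time.

    ``free_fraction`` (f_P, the plasma free fraction measured by
    ultrafiltration) is carried as metadata only.  ``total_plasma`` and
    ``whole_blood`` are optional companion curves on the same time grid.
    """

    times: np.ndarray
    parent_plasma: np.ndarray
    free_fraction: Optional[float] = None
    total_plasma: Optional[np.ndarray] = None
    whole_blood: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.parent_plasma = np.asarray(self.parent_plasma, dtype=float)
        if self.times.shape != self.parent_plasma.shape or self.times.ndim != 1:
            raise ValueError("times and parent_plasma must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            bad = int(np.argmax(np.diff(self.times) <= 0)) + 1
            raise ValueError(f"times must be strictly ascending (index {bad})")
        if np.any(self.parent_plasma < -1e-12):
            raise ValueError("parent_plasma must be non-negative")
        if self.free_fraction is not None and not (0.0 < self.free_fraction <= 1.0):
            raise ValueError("free_fraction must lie in (0, 1]")
        for name in ("total_plasma", "whole_blood"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.times.shape:
                    raise ValueError(f"{name} must match times in length")
                setattr(self, name, arr)
        if self.total_plasma is not None and np.any(
            self.parent_plasma > self.total_plasma + 1e-9 * np.maximum(1.0, self.total_plasma)
        ):
            raise ValueError("parent_plasma cannot exceed total plasma")

    def at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation of parent plasma; 0 before the first sample
        (anchored through the origin), held constant past the last."""
        times, vals = self._anchored()
        return np.interp(np.asarray(t, dtype=float), times, vals)

    def cumulative(self, t: np.ndarray) -> np.ndarray:
        """Integral of parent plasma from 0 to each requested time (trapezoid
        on the native sample grid, linearly interpolated between samples)."""
        times, vals = self._anchored()
        cum = cumulative_trapezoid(vals, times, initial=0.0)
        return np.interp(np.asarray(t, dtype=float), times, cum)

    def _anchored(self) -> tuple[np.ndarray, np.ndarray]:
        if self.times[0] > 0:
            return (np.concatenate([[0.0], self.times]),
                    np.concatenate([[0.0], self.parent_plasma]))
        return self.times, self.parent_plasma

    @property
    def span(self) -> float:
        return float(self.times[-1])


class ParentFractionCurve:
    """Fitted parent-fraction curve pf(t) = (1 - c) exp(-rate t) + c."""

    def __init__(self, rate: float, plateau: float, residuals: Optional[np.ndarray] = None):
        if rate < 0:
            raise ValueError("rate must be >= 0")
        if not (0.0 <= plateau <= 1.0):
            raise ValueError("plateau must lie in [0, 1]")
        self.rate = float(rate)
        self.plateau = float(plateau)
        self.residuals = residuals

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        pf = (1.0 - self.plateau) * np.exp(-self.rate * t) + self.plateau
        out_of_range = (pf < -1e-12) | (pf > 1.0 + 1e-12)
        if np.any(out_of_range):
            log.warning("parent-fraction curve clamped to [0, 1] at %d points",
                        int(out_of_range.sum()))
        return np.clip(pf, 0.0, 1.0)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ParentFractionCurve(rate={self.rate:.4g}, plateau={self.plateau:.4g})"


def fit_parent_fraction(samples: Sequence[BloodSample]) -> ParentFractionCurve:
    """Least-squares fit of the plateau-exponential parent-fraction model.

    Requires at least three samples with a measured parent fraction.  The
    fitted curve is 1 at t = 0, monotone non-increasing, and bounded in
    [0, 1] by construction.
    """
    usable = [(s.time, s.parent_fraction) for s in samples if s.parent_fraction is not None]
    if len(usable) < 3:
        raise ValueError(
            f"need >= 3 samples with a measured parent fraction, got {len(usable)}"
        )
    t = np.array([u[0] for u in usable])
    pf = np.array([u[1] for u in usable])

    def model(tt, rate, plateau):
        return (1.0 - plateau) * np.exp(-rate * tt) + plateau

    try:
        popt, _ = curve_fit(
            model, t, pf, p0=(0.05, 0.05), bounds=([0.0, 0.0], [np.inf, 1.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise ValueError(f"parent-fraction fit did not converge: {exc}") from exc
    rate, plateau = popt
    resid = pf - model(t, *popt)
    return ParentFractionCurve(rate, plateau, residuals=resid)


def build_input(
    samples: Sequence[BloodSample],
    pf_curve: Callable[[np.ndarray], np.ndarray],
    free_fraction: Optional[float] = None,
) -> InputFunction:
    """Metabolite-correct the plasma curve: parent(t) = plasma(t) * pf(t).

    Values between samples are linearly interpolated; before the first
    sample the curve runs linearly from (0, 0).
    """
    if len(samples) == 0:
        raise ValueError("cannot build an input function from zero samples")
    ordered = sorted(samples, key=lambda s: s.time)
    times = np.array([s.time for s in ordered])
    plasma = np.array([s.plasma for s in ordered])
    wb = np.array([s.whole_blood for s in ordered])
    pf = np.asarray(pf_curve(times), dtype=float)
    parent = plasma * pf
    return InputFunction(
        times=times,
        parent_plasma=parent,
        free_fraction=free_fraction,
        total_plasma=plasma,
        whole_blood=wb,
    )


def default_sampling_times() -> np.ndarray:
    """The arterial sampling schedule used throughout: 15-s draws for the
    first 120 s, then samples at 3, 5, 10, 30, 60, 90, and 120 min."""
    early = np.arange(1, 9) * 0.25
    late = np.array([3.0, 5.0, 10.0, 30.0, 60.0, 90.0, 120.0])
    return np.concatenate([early, late])
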