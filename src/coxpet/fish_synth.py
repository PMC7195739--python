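"""Synthetic multiplex FISH scenes with known ground truth.

Each scene emulates a two-probe RNAscope field: a DAPI channel with
elliptical nuclei (a configurable fraction placed as touching pairs to
exercise watershed splitting), a Cy3 channel carrying Cox2 transcript
dots, a Cy5 channel carrying Eno2 (neuron-marker) dots, and a set of
autofluorescent blobs rendered at identical coordinates in both signal
channels.  Per-cell dot counts are Poisson; under the default
``neuron_weighted`` coexpression model a "neuron" subpopulation carries
the Eno2 signal and the Cox2 rate is reweighted between neurons and
non-neurons so that the expected Cox2+/Eno2+ colocalization fraction
matches a direct parameter (default 0.75).

Every generated feature is recorded in a truth sidecar so that the
quantification pipeline can be scored against known answers without
re-deriving truth from pixels.  A fixed seed reproduces a scene
byte-identically.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

log = logging.getLogger(__name__)

__all__ = [
    "SceneParams",
    "TruthNucleus",
    "TruthSpot",
    "SyntheticScene",
    "generate_scene",
    "scene_truth_summary",
    "expressing_probability",
    "expected_expressing_fraction",
    "calibrate_lambda",
    "fold_change_scenario",
]

MIN_SPOT_SEPARATION_PX = 6.0  # transcript dots are resolvable in-plane
PLACEMENT_RETRIES = 200


@dataclass(frozen=True)
class SceneParams:
    """Generator settings for one synthetic FISH scene."""

    shape: Tuple[int, int] = (384, 384)   # pixels (rows, cols)
    pixel_size: float = 0.31              # um per pixel
    n_nuclei: int = 80
    cluster_fraction: float = 0.25        # fraction of nuclei placed as touching pairs
    nucleus_radius_um: float = 3.5
    nucleus_radius_sd_um: float = 0.25
    lambda_cy3: float = 4.0               # mean Cox2 dots per cell
    lambda_cy5: float = 6.0               # mean Eno2 dots per neuron
    eno2_background_lambda: float = 0.2   # Eno2 rate in non-neurons
    coexpression: str = "neuron_weighted"  # or "independent"
    neuron_fraction: float = 0.6
    colocalization: float = 0.75          # target Cox2+&Eno2+ / Cox2+ fraction
    n_autofluor: int = 15
    spot_sigma_px: float = 1.0
    spot_snr: float = 10.0                # peak spot amplitude / background noise SD
    background: float = 100.0             # intensity offset, 16-bit counts
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0 or self.n_autofluor < 0:
            raise ValueError("counts must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if min(self.lambda_cy3, self.lambda_cy5, self.eno2_background_lambda) < 0:
            raise ValueError("Poisson rates must be >= 0")
        if not (0.0 <= self.cluster_fraction <= 1.0):
            raise ValueError("cluster_fraction must lie in [0, 1]")
        if not (0.0 < self.neuron_fraction < 1.0):
            raise ValueError("neuron_fraction must lie in (0, 1)")
        if not (0.0 <= self.colocalization <= 1.0):
            raise ValueError("colocalization must lie in [0, 1]")
        if self.coexpression not in ("neuron_weighted", "independent"):
            raise ValueError(f"unknown coexpression model {self.coexpression!r}")
        if self.spot_snr < 0 or self.noise_sd < 0 or self.background < 0:
            raise ValueError("intensity settings must be >= 0")


@dataclass(frozen=True)
class TruthNucleus:
    id: int
    center: Tuple[float, float]      # (row, col) px
    radii: Tuple[float, float]       # (r_row, r_col) px
    angle: float                     # radians
    cluster_id: Optional[int]
    is_neuron: bool


@dataclass(frozen=True)
class TruthSpot:
    channel: str                     # "cy3" | "cy5"
    center: Tuple[float, float]      # (row, col) px
    nucleus_id: int


@dataclass
class SyntheticScene:
    """Images plus the ground truth that produced them."""

    params: SceneParams
    dapi: np.ndarray
    cy3: np.ndarray
    cy5: np.ndarray
    nuclei: List[TruthNucleus]
    spots: List[TruthSpot]
    autofluor: List[Tuple[float, float]]

    @property
    def images(self) -> Dict[str, np.ndarray]:
        return {"dapi": self.dapi, "cy3": self.cy3, "cy5": self.cy5}

    def true_counts(self, channel: str) -> Dict[int, int]:
        counts = {n.id: 0 for n in self.nuclei}
        for s in self.spots:
            if s.channel == channel:
                counts[s.nucleus_id] += 1
        return counts


def expressing_probability(lam: float) -> float:
    """P(N >= 2) for N ~ Poisson(lam): 1 - e^-lam * (1 + lam)."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    return 1.0 - math.exp(-lam) * (1.0 + lam)


def _cox2_weights(params: SceneParams) -> Tuple[float, float]:
    """Neuron/non-neuron multipliers (a, b) on lambda_cy3.

    Chosen so that f*a + (1-f)*b = 1 (the marginal mean is preserved)
    and the expected colocalization fraction — Cox2+ cells that are also
    Eno2+, with Eno2+ meaning >= 2 Eno2 dots — matches the target.  When
    the target is outside the achievable range the nearest boundary is
    used and a warning is logged.
    """
    if params.coexpression == "independent" or params.lambda_cy3 == 0:
        return 1.0, 1.0
    f = params.neuron_fraction
    lam = params.lambda_cy3
    q_n = expressing_probability(params.lambda_cy5)
    q_o = expressing_probability(params.eno2_background_lambda)

    def coloc(a: float) -> float:
        b = (1.0 - f * a) / (1.0 - f)
        pa = expressing_probability(a * lam)
        pb = expressing_probability(b * lam)
        denom = f * pa + (1.0 - f) * pb
        if denom <= 0:
            return q_o
        return (f * pa * q_n + (1.0 - f) * pb * q_o) / denom

    eps = 1e-6
    lo, hi = eps, (1.0 - eps) / f
    c_lo, c_hi = coloc(lo), coloc(hi)
    target = params.colocalization
    if target <= min(c_lo, c_hi):
        log.warning("colocalization target %.2f below achievable range "
                    "[%.3f, %.3f]; clamped", target, c_lo, c_hi)
        return (lo, (1.0 - f * lo) / (1.0 - f))
    if target >= max(c_lo, c_hi):
        log.warning("colocalization target %.2f above achievable range "
                    "[%.3f, %.3f]; clamped", target, c_lo, c_hi)
        return (hi, (1.0 - f * hi) / (1.0 - f))
    a = brentq(lambda aa: coloc(aa) - target, lo, hi, xtol=1e-10)
    return a, (1.0 - f * a) / (1.0 - f)


def expected_expressing_fraction(params: SceneParams, channel: str = "cy3") -> float:
    """Expected fraction of cells with >= 2 dots in a channel under the
    scene's coexpression model."""
    f = params.neuron_fraction
    if channel == "cy5":
        if params.coexpression == "independent":
            return expressing_probability(params.lambda_cy5)
        return (f * expressing_probability(params.lambda_cy5)
                + (1 - f) * expressing_probability(params.eno2_background_lambda))
    a, b = _cox2_weights(params)
    return (f * expressing_probability(a * params.lambda_cy3)
            + (1 - f) * expressing_probability(b * params.lambda_cy3))


def calibrate_lambda(target_fraction: float, params: SceneParams) -> float:
    """Solve for lambda_cy3 giving a target expected expressing fraction."""
    if not (0.0 < target_fraction < 0.995):
        raise ValueError("target_fraction must lie in (0, 0.995)")

    def frac(lam: float) -> float:
        return expected_expressing_fraction(replace(params, lambda_cy3=lam))

    return float(brentq(lambda lam: frac(lam) - target_fraction, 1e-6, 60.0,
                        xtol=1e-9))


def fold_change_scenario(
    fold: float,
    base: Optional[SceneParams] = None,
    control_fraction: Optional[float] = None,
) -> Tuple[SceneParams, SceneParams]:
    """Control/treated scene parameters with a known expressing-fraction
    fold change.

    Defaults place the control fraction at 0.13 for a 6-fold scenario
    and 0.048 for 20-fold, chosen so that the treated fraction stays
    below saturation of the >= 2-dot rule while the control fraction is
    large enough to estimate from a few thousand pooled cells.  These
    mirror the transcript-induction magnitudes the pipeline is meant to
    resolve (6-fold in putamen, 20-fold in prefrontal cortex); they are
    synthetic anchors, not data reproductions.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if base is None:
        # Independent coexpression: the colocalization constraint caps the
        # achievable expressing fraction, which a strongly induced condition
        # would exceed; fold recovery does not need the coexpression structure.
        # Scene size chosen so a pooled condition holds a few thousand cells,
        # as a real per-area quantification does.
        base = SceneParams(shape=(1024, 1024), n_nuclei=700,
                           coexpression="independent", lambda_cy5=3.0)
    if control_fraction is None:
        control_fraction = {6: 0.13, 20: 0.048}.get(int(fold), 0.6 / fold)
    treated_fraction = control_fraction * fold
    if treated_fraction >= 0.97:
        raise ValueError("treated expressing fraction saturates the >=2-dot rule; "
                         "lower control_fraction")
    control = replace(base, lambda_cy3=calibrate_lambda(control_fraction, base))
    treated = replace(base, lambda_cy3=calibrate_lambda(treated_fraction, base))
    return control, treated


def _sample_radii(rng: np.random.Generator, params: SceneParams) -> Tuple[float, float, float]:
    # clip at -2/+3 SD so the smallest rendered nuclei stay plausibly sized
    r_um = rng.normal(params.nucleus_radius_um, params.nucleus_radius_sd_um)
    lo = max(1.0, params.nucleus_radius_um - 2 * params.nucleus_radius_sd_um)
    hi = params.nucleus_radius_um + 3 * params.nucleus_radius_sd_um
    r_px = float(np.clip(r_um, lo, hi)) / params.pixel_size
    ry = r_px * rng.uniform(0.9, 1.1)
    rx = r_px * rng.uniform(0.9, 1.1)
    angle = rng.uniform(0.0, math.pi)
    return ry, rx, angle


def _place_nuclei(rng: np.random.Generator, params: SceneParams) -> List[TruthNucleus]:
    h, w = params.shape
    n_pairs = int(params.n_nuclei * params.cluster_fraction / 2)
    n_single = params.n_nuclei - 2 * n_pairs
    nuclei: List[TruthNucleus] = []
    centers: List[Tuple[float, float]] = []
    rmax: List[float] = []

    def fits(cy: float, cx: float, r: float, allow: float = 1.05) -> bool:
        margin = r + 7.0  # room for the perinuclear dot band and blob tails
        if not (margin <= cy <= h - margin and margin <= cx <= w - margin):
            return False
        for (oy, ox), orr in zip(centers, rmax):
            if math.hypot(cy - oy, cx - ox) < allow * (r + orr):
                return False
        return True

    def add(cy, cx, ry, rx, angle, cluster_id, is_neuron):
        nuclei.append(TruthNucleus(len(nuclei), (cy, cx), (ry, rx), angle,
                                   cluster_id, is_neuron))
        centers.append((cy, cx))
        rmax.append(max(ry, rx))

    cluster_id = 0
    for _ in range(n_pairs):
        placed = False
        for _ in range(PLACEMENT_RETRIES):
            ry1, rx1, a1 = _sample_radii(rng, params)
            r1 = max(ry1, rx1)
            cy1, cx1 = rng.uniform(0, h), rng.uniform(0, w)
            if not fits(cy1, cx1, r1):
                continue
            ry2, rx2, a2 = _sample_radii(rng, params)
            r2 = max(ry2, rx2)
            theta = rng.uniform(0, 2 * math.pi)
            d = 0.85 * (r1 + r2)  # partial overlap: forces a watershed split
            cy2, cx2 = cy1 + d * math.sin(theta), cx1 + d * math.cos(theta)
            margin2 = r2 + 7.0
            if not (margin2 <= cy2 <= h - margin2 and margin2 <= cx2 <= w - margin2):
                continue
            ok = all(math.hypot(cy2 - oy, cx2 - ox) >= 1.05 * (r2 + orr)
                     for (oy, ox), orr in zip(centers, rmax))
            if not ok:
                continue
            neuron = bool(rng.random() < params.neuron_fraction)
            neuron2 = bool(rng.random() < params.neuron_fraction)
            add(cy1, cx1, ry1, rx1, a1, cluster_id, neuron)
            add(cy2, cx2, ry2, rx2, a2, cluster_id, neuron2)
            cluster_id += 1
            placed = True
            break
        if not placed:
            log.info("could not place a clustered pair after %d retries", PLACEMENT_RETRIES)

    for _ in range(n_single):
        placed = False
        for _ in range(PLACEMENT_RETRIES):
            ry, rx, a = _sample_radii(rng, params)
            r = max(ry, rx)
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            if fits(cy, cx, r):
                add(cy, cx, ry, rx, a, None, bool(rng.random() < params.neuron_fraction))
                placed = True
                break
        if not placed:
            log.info("could not place a nucleus after %d retries", PLACEMENT_RETRIES)
    return nuclei


def _point_in_ellipse(cy, cx, ry, rx, angle, y, x) -> bool:
    dy, dx = y - cy, x - cx
    ca, sa = math.cos(angle), math.sin(angle)
    u = ca * dy + sa * dx
    v = -sa * dy + ca * dx
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def _sample_spot_positions(
    rng: np.random.Generator, nucleus: TruthNucleus, n: int,
    occupied: List[Tuple[float, float]], dilate_px: float = 0.0,
) -> List[Tuple[float, float]]:
    """Uniform positions inside the (dilated) nucleus ellipse with a
    minimum separation from all other dots of the same cell (both
    channels).  Dilation mimics perinuclear labeling, which the 2-um
    search-region expansion is designed to capture."""
    cy, cx = nucleus.center
    ry, rx = nucleus.radii[0] + dilate_px, nucleus.radii[1] + dilate_px
    rmax = max(ry, rx)
    out: List[Tuple[float, float]] = []
    for _ in range(n):
        # crowded cells relax the separation gradually rather than ever
        # stacking dots on top of each other
        for min_sep in (MIN_SPOT_SEPARATION_PX, 4.0, 3.0, 0.0):
            placed = False
            for _ in range(80):
                y = rng.uniform(cy - rmax, cy + rmax)
                x = rng.uniform(cx - rmax, cx + rmax)
                if not _point_in_ellipse(cy, cx, ry, rx, nucleus.angle, y, x):
                    continue
                if all(math.hypot(y - oy, x - ox) >= min_sep
                       for oy, ox in occupied + out):
                    out.append((y, x))
                    placed = True
                    break
            if placed:
                break
    return out


def _render_gaussian(img: np.ndarray, cy: float, cx: float, amp: float, sigma: float) -> None:
    h, w = img.shape
    r = int(math.ceil(4 * sigma))
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amp * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma ** 2)
    )


def _render_ellipse(img: np.ndarray, nuc: TruthNucleus, value: float) -> None:
    from skimage.draw import ellipse

    cy, cx = nuc.center
    ry, rx = nuc.radii
    rr, cc = ellipse(cy, cx, ry, rx, shape=img.shape, rotation=nuc.angle)
    img[rr, cc] = np.maximum(img[rr, cc], value)


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Generate one scene: images (uint16) plus complete ground truth."""
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    nuclei = _place_nuclei(rng, params)
    a, b = _cox2_weights(params)

    dapi = np.zeros((h, w), dtype=float)
    cy3 = np.zeros((h, w), dtype=float)
    cy5 = np.zeros((h, w), dtype=float)

    for nuc in nuclei:
        _render_ellipse(dapi, nuc, 400.0 * rng.uniform(0.85, 1.15))

    amp = params.spot_snr * params.noise_sd
    spots: List[TruthSpot] = []
    for nuc in nuclei:
        if params.coexpression == "independent":
            lam3 = params.lambda_cy3
            lam5 = params.lambda_cy5
        else:
            lam3 = params.lambda_cy3 * (a if nuc.is_neuron else b)
            lam5 = params.lambda_cy5 if nuc.is_neuron else params.eno2_background_lambda
        n3 = int(rng.poisson(lam3))
        n5 = int(rng.poisson(lam5))
        occupied: List[Tuple[float, float]] = []
        pos3 = _sample_spot_positions(rng, nuc, n3, occupied)
        occupied.extend(pos3)
        pos5 = _sample_spot_positions(rng, nuc, n5, occupied)
        for (y, x) in pos3:
            spots.append(TruthSpot("cy3", (y, x), nuc.id))
            _render_gaussian(cy3, y, x, amp * rng.uniform(0.9, 1.1), params.spot_sigma_px)
        for (y, x) in pos5:
            spots.append(TruthSpot("cy5", (y, x), nuc.id))
            _render_gaussian(cy5, y, x, amp * rng.uniform(0.9, 1.1), params.spot_sigma_px)

    autofluor: List[Tuple[float, float]] = []
    for _ in range(params.n_autofluor):
        y = rng.uniform(4, h - 4)
        x = rng.uniform(4, w - 4)
        autofluor.append((y, x))
        a_amp = 1.1 * amp * rng.uniform(0.9, 1.1)
        # identical coordinates in both channels: the artifact signature
        _render_gaussian(cy3, y, x, a_amp, 1.5 * params.spot_sigma_px)
        _render_gaussian(cy5, y, x, a_amp, 1.5 * params.spot_sigma_px)

    out = {}
    for name, img in (("dapi", dapi), ("cy3", cy3), ("cy5", cy5)):
        img = img + params.background
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
        out[name] = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    return SyntheticScene(params=params, dapi=out["dapi"], cy3=out["cy3"],
                          cy5=out["cy5"], nuclei=nuclei, spots=spots,
                          autofluor=autofluor)


def scene_truth_summary(scene: SyntheticScene) -> Dict[str, Optional[float]]:
    """True per-scene expressing fractions and colocalization.

    A cell truly expresses a channel when it holds >= 2 true dots; the
    colocalization fraction is |Cox2+ and Eno2+| / |Cox2+| (None when no
    cell is Cox2+).
    """
    n = len(scene.nuclei)
    if n == 0:
        return {"n_cells": 0, "frac_cy3": 0.0, "frac_cy5": 0.0, "colocalization": None}
    c3 = scene.true_counts("cy3")
    c5 = scene.true_counts("cy5")
    pos3 = {i for i, c in c3.items() if c >= 2}
    pos5 = {i for i, c in c5.items() if c >= 2}
    coloc = len(pos3 & pos5) / len(pos3) if pos3 else None
    return {
        "n_cells": n,
        "frac_cy3": len(pos3) / n,
        "frac_cy5": len(pos5) / n,
        "colocalization": coloc,
    }
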