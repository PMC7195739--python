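"""RNAscope-style quantification: segment, detect, filter, score.

The pipeline follows the standard per-cell transcript-dot workflow:

1. nuclear segmentation on the DAPI channel — global threshold,
   connected components, shape-based watershed splitting of clustered
   nuclei, area filtering, removal of edge objects;
2. expansion of each surviving mask by 2 um into a per-cell search
   region (contested pixels go to the nearest nucleus centroid);
3. per-channel spot detection at a median + 2*SD intensity threshold
   with a pixel-size filter;
4. exclusion of spots that overlap spatially across the two signal
   channels (counted as autofluorescence);
5. scoring a cell as expressing a transcript when two or more dots fall
   in its search region, and region-level summaries (fractions, fold
   change against a reference, Cox2+/Eno2+ colocalization).

Everything here is deterministic; randomness lives only in the scene
generator.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import disk, remove_small_objects
from skimage.segmentation import watershed

log = logging.getLogger(__name__)

__all__ = [
    "QuantConfig",
    "NucleusMask",
    "SpotCall",
    "CellScore",
    "QuantResult",
    "PipelineResult",
    "segment_nuclei",
    "search_label_image",
    "detect_spots",
    "remove_autofluorescence",
    "score_cells",
    "summarize",
    "quantify_image",
    "run_pipeline",
]


@dataclass(frozen=True)
class QuantConfig:
    """Tunable settings of the quantification pipeline.

    ``min_area_um2``/``max_area_um2`` bound the accepted nucleus size
    (the literal upper-bound-only reading is available by setting
    ``min_area_um2=0`` and ``max_area_um2=20``).  ``threshold_scope``
    selects the pixel population for the spot threshold statistic:
    the union of search regions (default) or the whole image.
    """

    min_area_um2: float = 20.0
    max_area_um2: Optional[float] = None
    expand_um: float = 2.0
    cluster_area_factor: float = 1.5   # area ratio vs median flagging a cluster
    solidity_min: float = 0.92
    typical_radius_um: float = 3.0     # sets the watershed peak separation
    smooth_sigma_px: float = 1.0
    min_foreground_contrast: float = 4.0  # Otsu classes closer than this (in
    # background-SD units) are treated as an unstained/empty field
    threshold_scope: str = "search_regions"  # or "image"
    spot_min_px: int = 4
    spot_max_px: int = 50
    autofluor_tol_px: float = 2.0

    def __post_init__(self) -> None:
        if self.min_area_um2 < 0:
            raise ValueError("min_area_um2 must be >= 0")
        if self.max_area_um2 is not None and self.max_area_um2 <= self.min_area_um2:
            raise ValueError("max_area_um2 must exceed min_area_um2")
        if self.expand_um < 0:
            raise ValueError("expand_um must be >= 0")
        if self.threshold_scope not in ("search_regions", "image"):
            raise ValueError(f"unknown threshold_scope {self.threshold_scope!r}")
        if self.spot_min_px < 1 or self.spot_max_px < self.spot_min_px:
            raise ValueError("spot size bounds must satisfy 1 <= min <= max")
        if self.autofluor_tol_px < 0:
            raise ValueError("autofluor_tol_px must be >= 0")


@dataclass
class NucleusMask:
    """One segmented nucleus plus its dilated search region."""

    id: int
    pixels: Tuple[np.ndarray, np.ndarray]         # (rows, cols) of the core mask
    search_pixels: Tuple[np.ndarray, np.ndarray]  # core plus 2-um expansion
    area_um2: float
    centroid: Tuple[float, float]                 # (row, col), px
    touches_edge: bool
    image_shape: Tuple[int, int]


@dataclass
class SpotCall:
    channel: str
    centroid: Tuple[float, float]
    size: int                       # pixel count
    nucleus_id: Optional[int]
    autofluor: bool = False


@dataclass(frozen=True)
class CellScore:
    nucleus_id: int
    n_cy3: int
    n_cy5: int

    @property
    def expressing_cy3(self) -> bool:
        return self.n_cy3 >= 2

    @property
    def expressing_cy5(self) -> bool:
        return self.n_cy5 >= 2


@dataclass(frozen=True)
class QuantResult:
    """Region-level summary of per-cell scores."""

    region: str
    n_cells: int
    frac_cy3: Optional[float]
    frac_cy5: Optional[float]
    colocalization: Optional[float]   # Cox2+ cells also Eno2+, of Cox2+ cells
    fold_change_cy3: Optional[float] = None
    fold_change_cy5: Optional[float] = None


def segment_nuclei(
    dapi: np.ndarray, pixel_size: float, cfg: Optional[QuantConfig] = None
) -> List[NucleusMask]:
    """Segment nuclei on the DAPI channel.

    Global (Otsu) threshold, connected components, watershed splitting of
    components flagged as clusters by area or solidity, size filtering,
    removal of edge-touching masks, and 2-um expansion into search
    regions with contested pixels resolved to the nearest centroid.
    A blank image yields an empty list.
    """
    cfg = cfg or QuantConfig()
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    img = np.asarray(dapi, dtype=float)
    if img.ndim != 2:
        raise ValueError("DAPI image must be 2-D")
    if np.ptp(img) == 0:
        return []

    px_area = pixel_size * pixel_size
    min_area_px = cfg.min_area_um2 / px_area
    sm = gaussian(img, sigma=cfg.smooth_sigma_px, preserve_range=True)
    fg = sm > threshold_otsu(sm)
    if fg.all() or not fg.any():
        return []
    contrast = (sm[fg].mean() - sm[~fg].mean()) / max(float(sm[~fg].std()), 1e-9)
    if contrast < cfg.min_foreground_contrast:
        log.info("DAPI foreground/background contrast %.2f below %.2f; "
                 "treating the field as empty", contrast, cfg.min_foreground_contrast)
        return []
    fg = ndi.binary_fill_holes(fg)
    # drop sub-debris components before shape statistics
    lbl0, _ = ndi.label(fg)
    sizes = np.bincount(lbl0.ravel())
    keep0 = sizes >= max(4, int(min_area_px / 4))
    keep0[0] = False
    fg = keep0[lbl0]
    if not fg.any():
        return []

    lbl = sk_label(fg)
    props = regionprops(lbl)
    median_area = float(np.median([p.area for p in props]))
    final = np.zeros_like(lbl)
    next_id = 1
    r_px = cfg.typical_radius_um / pixel_size
    for p in props:
        comp = lbl[p.slice] == p.label
        is_cluster = (p.area > cfg.cluster_area_factor * median_area
                      or p.solidity < cfg.solidity_min)
        if is_cluster:
            dist = ndi.distance_transform_edt(comp)
            dist_s = gaussian(dist, sigma=1.0, preserve_range=True)
            peaks = peak_local_max(
                dist_s, min_distance=max(3, int(0.8 * r_px)),
                labels=comp, exclude_border=False,
            )
            if len(peaks) >= 2:
                markers = np.zeros(comp.shape, dtype=int)
                for k, (py, px_) in enumerate(peaks, start=1):
                    markers[py, px_] = k
                split = watershed(-dist_s, markers, mask=comp)
                for k in range(1, len(peaks) + 1):
                    final[p.slice][split == k] = next_id
                    next_id += 1
                continue
        final[p.slice][comp] = next_id
        next_id += 1

    # area filter and edge rule
    h, w = img.shape
    masks: List[NucleusMask] = []
    keep = np.zeros_like(final)
    kept_id = 0
    n_area, n_edge = 0, 0
    for p in regionprops(final):
        area_um2 = p.area * px_area
        if area_um2 < cfg.min_area_um2 or (
            cfg.max_area_um2 is not None and area_um2 > cfg.max_area_um2
        ):
            n_area += 1
            continue
        r0, c0, r1, c1 = p.bbox
        if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
            n_edge += 1
            continue
        kept_id += 1
        keep[p.slice][final[p.slice] == p.label] = kept_id
        masks.append(NucleusMask(
            id=kept_id,
            pixels=tuple(np.nonzero(final[p.slice] == p.label)),  # temp, fixed below
            search_pixels=(np.array([], int), np.array([], int)),
            area_um2=float(area_um2),
            centroid=(float(p.centroid[0]), float(p.centroid[1])),
            touches_edge=False,
            image_shape=(h, w),
        ))
    log.info("segmentation: %d masks kept, %d area-filtered, %d edge-removed",
             len(masks), n_area, n_edge)
    if not masks:
        return []

    # expansion by expand_um with nearest-centroid resolution of contested px
    expand_px = int(round(cfg.expand_um / pixel_size))
    search = np.zeros((h, w), dtype=int)
    owner_dist = np.full((h, w), np.inf)
    selem = disk(expand_px) if expand_px > 0 else None
    slices = ndi.find_objects(keep)
    for m in masks:
        sy, sx = slices[m.id - 1]
        y0 = max(sy.start - expand_px, 0)
        y1 = min(sy.stop + expand_px, h)
        x0 = max(sx.start - expand_px, 0)
        x1 = min(sx.stop + expand_px, w)
        core = keep[y0:y1, x0:x1] == m.id
        dil = ndi.binary_dilation(core, structure=selem) if selem is not None else core
        ys, xs = np.nonzero(dil)
        ys = ys + y0
        xs = xs + x0
        d = (ys - m.centroid[0]) ** 2 + (xs - m.centroid[1]) ** 2
        better = d < owner_dist[ys, xs]
        search[ys[better], xs[better]] = m.id
        owner_dist[ys[better], xs[better]] = d[better]
    # core pixels always belong to their own nucleus
    search[keep > 0] = keep[keep > 0]

    ys_all, xs_all = np.nonzero(search)
    labs = search[ys_all, xs_all]
    order = np.argsort(labs, kind="stable")
    ys_all, xs_all, labs = ys_all[order], xs_all[order], labs[order]
    bounds = np.searchsorted(labs, np.arange(1, len(masks) + 2))
    for m in masks:
        sy, sx = slices[m.id - 1]
        ys, xs = np.nonzero(keep[sy, sx] == m.id)
        m.pixels = (ys + sy.start, xs + sx.start)
        lo, hi = bounds[m.id - 1], bounds[m.id]
        m.search_pixels = (ys_all[lo:hi], xs_all[lo:hi])
    return masks


def search_label_image(masks: Sequence[NucleusMask], shape: Optional[Tuple[int, int]] = None) -> np.ndarray:
    """Label image of search regions (0 = background)."""
    if shape is None:
        if not masks:
            raise ValueError("shape required when no masks are given")
        shape = masks[0].image_shape
    out = np.zeros(shape, dtype=int)
    for m in masks:
        out[m.search_pixels] = m.id
    return out


def detect_spots(
    channel_image: np.ndarray,
    masks: Sequence[NucleusMask],
    cfg: Optional[QuantConfig] = None,
    channel: str = "cy3",
    return_stats: bool = False,
):
    """Threshold-based spot detection within nucleus search regions.

    The threshold is median + 2*SD of the pixel population selected by
    ``cfg.threshold_scope``.  Above-threshold 4-connected components are
    candidate spots; those outside [spot_min_px, spot_max_px] are
    discarded, and each survivor is assigned to the search region
    containing its centroid (spots whose centroid falls outside every
    region are dropped).  A constant image yields zero spots.
    """
    cfg = cfg or QuantConfig()
    img = np.asarray(channel_image, dtype=float)
    stats = {"candidates": 0, "size_filtered": 0, "outside": 0, "assigned": 0}
    if not masks:
        return ([], stats) if return_stats else []
    search = search_label_image(masks)
    if cfg.threshold_scope == "search_regions":
        pop = img[search > 0]
    else:
        pop = img.ravel()
    sd = float(pop.std())
    if sd == 0:
        log.info("degenerate spot threshold (SD = 0); no spots called")
        return ([], stats) if return_stats else []
    thr = float(np.median(pop)) + 2.0 * sd
    bw = img > thr
    lbl = sk_label(bw, connectivity=1)
    spots: List[SpotCall] = []
    for p in regionprops(lbl):
        stats["candidates"] += 1
        if p.area < cfg.spot_min_px or p.area > cfg.spot_max_px:
            stats["size_filtered"] += 1
            continue
        cy, cx = p.centroid
        nid = int(search[int(round(cy)), int(round(cx))])
        if nid == 0:
            stats["outside"] += 1
            continue
        stats["assigned"] += 1
        spots.append(SpotCall(channel=channel, centroid=(float(cy), float(cx)),
                              size=int(p.area), nucleus_id=nid))
    log.info("%s spots: %d candidates, %d size-filtered, %d outside regions, "
             "%d assigned", channel, stats["candidates"], stats["size_filtered"],
             stats["outside"], stats["assigned"])
    return (spots, stats) if return_stats else spots


def remove_autofluorescence(
    spots_cy3: Sequence[SpotCall],
    spots_cy5: Sequence[SpotCall],
    tol: float = 2.0,
) -> Tuple[List[SpotCall], List[SpotCall], List[Tuple[SpotCall, SpotCall]]]:
    """Exclude spots that overlap spatially across the two channels.

    Greedy nearest-pair matching of Cy3 vs Cy5 centroids within ``tol``
    pixels; each spot can be removed at most once.  Ties at equal
    distance break on the lower spot index (Cy3 first, then Cy5).
    Returns (kept Cy3, kept Cy5, removed pairs).
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if not spots_cy3 or not spots_cy5:
        return list(spots_cy3), list(spots_cy5), []
    p3 = np.array([s.centroid for s in spots_cy3])
    p5 = np.array([s.centroid for s in spots_cy5])
    d = cdist(p3, p5)
    cand = [(d[i, j], i, j) for i, j in zip(*np.nonzero(d <= tol + 1e-9))]
    cand.sort()
    used3: set = set()
    used5: set = set()
    removed: List[Tuple[SpotCall, SpotCall]] = []
    for dist, i, j in cand:
        if i in used3 or j in used5:
            continue
        used3.add(i)
        used5.add(j)
        spots_cy3[i].autofluor = True
        spots_cy5[j].autofluor = True
        removed.append((spots_cy3[i], spots_cy5[j]))
    kept3 = [s for k, s in enumerate(spots_cy3) if k not in used3]
    kept5 = [s for k, s in enumerate(spots_cy5) if k not in used5]
    log.info("autofluorescence: %d cross-channel pairs removed", len(removed))
    return kept3, kept5, removed


def score_cells(
    masks: Sequence[NucleusMask],
    spots_cy3: Sequence[SpotCall],
    spots_cy5: Sequence[SpotCall],
) -> List[CellScore]:
    """Per-nucleus dot counts; a cell expresses a channel at >= 2 dots.

    Spots must already be autofluorescence-filtered; a spot referencing
    an unknown nucleus id is an error.
    """
    ids = {m.id for m in masks}
    counts3: Dict[int, int] = {i: 0 for i in ids}
    counts5: Dict[int, int] = {i: 0 for i in ids}
    for spots, counts in ((spots_cy3, counts3), (spots_cy5, counts5)):
        for s in spots:
            if s.nucleus_id is None:
                continue
            if s.nucleus_id not in ids:
                raise ValueError(f"spot references unknown nucleus id {s.nucleus_id}")
            counts[s.nucleus_id] += 1
    return [CellScore(i, counts3[i], counts5[i]) for i in sorted(ids)]


def summarize(
    scores: Sequence[CellScore],
    region_label: str,
    reference: Optional[QuantResult] = None,
) -> QuantResult:
    """Region summary: expressing fractions, colocalization, fold change.

    Colocalization is |Cox2+ and Eno2+| / |Cox2+| and is reported as
    missing (None) when no cell is Cox2+.  Fold changes divide each
    fraction by the matching fraction of ``reference`` when supplied.
    """
    if len(scores) == 0:
        raise ValueError("cannot summarize zero cells")
    n = len(scores)
    pos3 = [s for s in scores if s.expressing_cy3]
    pos5 = {s.nucleus_id for s in scores if s.expressing_cy5}
    frac3 = len(pos3) / n
    frac5 = len(pos5) / n
    coloc = (sum(1 for s in pos3 if s.nucleus_id in pos5) / len(pos3)
             if pos3 else None)

    def fold(frac: float, ref: Optional[float]) -> Optional[float]:
        if reference is None or ref is None or ref == 0:
            return None
        return frac / ref

    return QuantResult(
        region=region_label,
        n_cells=n,
        frac_cy3=frac3,
        frac_cy5=frac5,
        colocalization=coloc,
        fold_change_cy3=fold(frac3, reference.frac_cy3 if reference else None),
        fold_change_cy5=fold(frac5, reference.frac_cy5 if reference else None),
    )


@dataclass
class PipelineResult:
    """All intermediates of one quantified image."""

    masks: List[NucleusMask]
    spots_cy3: List[SpotCall]
    spots_cy5: List[SpotCall]
    removed_autofluor: List[Tuple[SpotCall, SpotCall]]
    scores: List[CellScore]
    result: QuantResult
    stats: Dict[str, Dict[str, int]]


def run_pipeline(
    images: Union[Dict[str, np.ndarray], np.ndarray],
    pixel_size: float,
    cfg: Optional[QuantConfig] = None,
    region_label: str = "image",
    reference: Optional[QuantResult] = None,
) -> PipelineResult:
    """Chain the four stages on one multichannel image.

    ``images`` is either a dict with keys dapi/cy3/cy5 or an array of
    shape (3, H, W) in that channel order.  A scene with no detectable
    cells produces an empty (n_cells = 0) result rather than an error.
    """
    cfg = cfg or QuantConfig()
    if isinstance(images, np.ndarray):
        if images.ndim != 3 or images.shape[0] != 3:
            raise ValueError("expected channel-first array of shape (3, H, W)")
        images = {"dapi": images[0], "cy3": images[1], "cy5": images[2]}
    for key in ("dapi", "cy3", "cy5"):
        if key not in images:
            raise ValueError(f"missing channel {key!r}")

    masks = segment_nuclei(images["dapi"], pixel_size, cfg)
    s3, st3 = detect_spots(images["cy3"], masks, cfg, channel="cy3", return_stats=True)
    s5, st5 = detect_spots(images["cy5"], masks, cfg, channel="cy5", return_stats=True)
    k3, k5, removed = remove_autofluorescence(s3, s5, tol=cfg.autofluor_tol_px)
    if not masks:
        result = QuantResult(region=region_label, n_cells=0, frac_cy3=None,
                             frac_cy5=None, colocalization=None)
        scores: List[CellScore] = []
    else:
        scores = score_cells(masks, k3, k5)
        result = summarize(scores, region_label, reference=reference)
    return PipelineResult(
        masks=masks, spots_cy3=k3, spots_cy5=k5, removed_autofluor=removed,
        scores=scores, result=result, stats={"cy3": st3, "cy5": st5},
    )


def quantify_image(
    images: Union[Dict[str, np.ndarray], np.ndarray],
    pixel_size: float,
    cfg: Optional[QuantConfig] = None,
    region_label: str = "image",
    reference: Optional[QuantResult] = None,
) -> QuantResult:
    """Segment, detect, filter and score one image; return the summary."""
    return run_pipeline(images, pixel_size, cfg, region_label, reference).result
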