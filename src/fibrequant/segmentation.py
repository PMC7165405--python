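"""Tissue detection, artefact exclusion and myofibre segmentation from the membrane mask.

Stage 1 finds muscle tissue on the laminin (mask) channel and removes artefact
regions (saturated in two or more channels, e.g. tissue folds and debris).
Stage 2 thresholds the laminin band within tissue, grows fibre candidates from
enclosed interiors by watershed over the laminin landscape, and applies a
filter cascade (border contact, area, solidity, ring thickness) with per-candidate
rejection reasons.  Each accepted fibre is partitioned into a sarcolemmal ring
and sarcoplasm, with a closed ring mid-line path whose length is the
circumference used by the coverage statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .image_io import ChannelStack


class NoTissueError(RuntimeError):
    """Raised when no muscle tissue can be detected on the mask channel."""


@dataclass
class SegmentationParams:
    """Tunable segmentation parameters (lengths in um, areas in um^2)."""

    mask_threshold_method: str = "otsu"        # 'otsu' or 'fixed'
    fixed_mask_threshold: float | None = None
    tissue_smooth_sigma: float = 2.0
    # below min_fibre_area so an isolated small fibre still counts as tissue
    min_tissue_area_um2: float = 100.0
    min_tissue_contrast: float = 1000.0        # AU between tissue and background classes
    min_fibre_area_um2: float = 150.0
    max_fibre_area_um2: float = 12000.0
    min_solidity: float = 0.80
    max_mean_ring_thickness_um: float = 5.0
    ring_mode: str = "laminin-band"            # or 'fixed-band'
    fixed_band_width_um: float = 1.0
    min_seed_area_px: int = 25
    saturation_fraction: float = 0.9           # pixel saturated if >= fraction * saturation_value
    artefact_min_channels: int = 2

    def __post_init__(self) -> None:
        if not self.min_fibre_area_um2 < self.max_fibre_area_um2:
            raise ValueError("min_fibre_area_um2 must be < max_fibre_area_um2")
        if not 0 < self.min_solidity <= 1:
            raise ValueError("min_solidity must lie in (0, 1]")
        if self.ring_mode not in ("laminin-band", "fixed-band"):
            raise ValueError("ring_mode must be 'laminin-band' or 'fixed-band'")


@dataclass
class TissueMask:
    tissue: np.ndarray
    excluded: np.ndarray
    provenance: list[str] = field(default_factory=list)


@dataclass
class FibreLabelMap:
    """Per-fibre integer labels (0 = background) plus the rejection log."""

    labels: np.ndarray
    n_fibres: int
    rejected: list[tuple[int, str]] = field(default_factory=list)
    membrane: np.ndarray | None = None   # laminin-positive band within tissue


@dataclass
class FibrePartition:
    """Disjoint ring/sarcoplasm masks of one fibre, on a cropped window.

    ``region = ring | sarcoplasm`` tiles the fibre exactly.  ``midline`` is a
    closed sub-pixel path (row, col in crop coordinates) equidistant between the
    ring edges; ``circumference_px`` is its polyline length.  ``ring_edge_count``
    is the 4-neighbour pixel-edge count of the ring border, used by the
    paper-literal coverage estimator.
    """

    label: int
    offset: tuple[int, int]
    region: np.ndarray
    ring: np.ndarray
    sarcoplasm: np.ndarray
    midline: np.ndarray
    circumference_px: float
    ring_edge_count: int
    centroid: tuple[float, float]


def _drop_small_components(mask: np.ndarray, min_px: int) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[lab]


def _mask_threshold(values: np.ndarray, params: SegmentationParams) -> float:
    if params.mask_threshold_method == "fixed":
        if params.fixed_mask_threshold is None:
            raise ValueError("fixed_mask_threshold required with method='fixed'")
        return float(params.fixed_mask_threshold)
    return float(filters.threshold_otsu(values))


def detect_tissue(stack: ChannelStack, params: SegmentationParams | None = None) -> TissueMask:
    """Detect muscle tissue as the smoothed, thresholded mask channel.

    The threshold split must show real contrast (``min_tissue_contrast``)
    so pure-noise images do not yield spurious tissue.  The raw mask is closed,
    hole-filled, and components below the minimum tissue area are dropped.
    """
    params = params or SegmentationParams()
    m = stack.mask.astype(np.float64)
    smoothed = ndimage.gaussian_filter(m, params.tissue_smooth_sigma)
    if smoothed.max() == smoothed.min():
        raise NoTissueError("no tissue detected: mask channel is constant")
    thr = _mask_threshold(smoothed, params)
    raw = smoothed > thr
    if not raw.any() or raw.all():
        raise NoTissueError("no tissue detected: threshold does not separate the mask channel")
    contrast = smoothed[raw].mean() - smoothed[~raw].mean()
    if contrast < params.min_tissue_contrast:
        raise NoTissueError(
            f"no tissue detected: foreground/background contrast {contrast:.0f} AU "
            f"below {params.min_tissue_contrast:.0f} AU"
        )
    closed = morphology.closing(raw, morphology.disk(3))
    filled = ndimage.binary_fill_holes(closed)
    min_px = int(params.min_tissue_area_um2 / stack.pixel_size**2)
    tissue = _drop_small_components(filled, max(min_px, 1))
    if not tissue.any():
        raise NoTissueError("no tissue detected: all components below minimum tissue area")
    # smoothing pulls the detected edge inside the outer membrane band; grow the
    # mask back out so whole rings stay available to the fibre stage
    tissue = morphology.dilation(tissue, morphology.disk(3))
    return TissueMask(
        tissue=tissue,
        excluded=np.zeros_like(tissue),
        provenance=[f"threshold={thr:.1f}", "closing(r=3)", "fill_holes",
                    f"min_area={min_px}px", "dilation(r=3)"],
    )


def exclude_artefacts(stack: ChannelStack, tissue: TissueMask,
                      params: SegmentationParams | None = None) -> TissueMask:
    """Move artefact regions (saturated in >= ``artefact_min_channels``) to excluded.

    Tissue folds saturate all channels; debris typically saturates the mask and
    one stain channel.  Saturated cores are dilated by one pixel to catch their
    anti-aliased borders.  Whole tissue components that are mostly saturated are
    excluded outright.
    """
    params = params or SegmentationParams()
    sat_level = params.saturation_fraction * stack.saturation_value
    sat_count = (stack.pixels.astype(np.float64) >= sat_level).sum(axis=2)
    core = sat_count >= params.artefact_min_channels
    excluded = morphology.dilation(core, morphology.disk(1)) if core.any() else core
    comp_labels, n = ndimage.label(tissue.tissue)
    if n and core.any():
        sat_frac = ndimage.mean(core.astype(float), comp_labels, index=np.arange(1, n + 1))
        for i, frac in enumerate(sat_frac, start=1):
            if frac > 0.5:
                excluded = excluded | (comp_labels == i)
    new_tissue = tissue.tissue & ~excluded
    prov = tissue.provenance + [
        f"excluded saturated (>= {params.artefact_min_channels} channels at {sat_level:.0f} AU)"
    ]
    return TissueMask(tissue=new_tissue, excluded=excluded | tissue.excluded, provenance=prov)


def _edge_count(mask: np.ndarray) -> int:
    """4-neighbour pixel-edge count of a binary mask's border."""
    p = np.pad(mask, 1)
    edges = 0
    for ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        edges += int((p & ~np.roll(p, shift, axis=ax)).sum())
    return edges


def _polyline_length(path: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum())


def _smooth_closed_path(path: np.ndarray, window: int = 5) -> np.ndarray:
    """Circular moving average of a closed polyline (first point == last)."""
    pts = path[:-1] if np.allclose(path[0], path[-1]) and len(path) > 1 else path
    n = len(pts)
    if n < window:
        return np.vstack([pts, pts[:1]])
    kernel = np.ones(window) / window
    sm = np.empty_like(pts)
    for k in range(2):
        ext = np.concatenate([pts[-(window // 2):, k], pts[:, k], pts[: window // 2, k]])
        sm[:, k] = np.convolve(ext, kernel, mode="valid")
    return np.vstack([sm, sm[:1]])


def segment_fibres(stack: ChannelStack, tissue: TissueMask,
                   params: SegmentationParams | None = None) -> FibreLabelMap:
    """Segment individual transverse fibres within tissue.

    The laminin band is thresholded (Otsu within tissue by default); the
    membrane-enclosed laminin-negative pockets are the fibre interiors, and
    every remaining tissue pixel joins its nearest interior, so each fibre
    claims its own band and bands shared by touching fibres are separated
    along their skeleton.  Candidates then pass the filter cascade;
    failures are logged in ``rejected`` with a reason (border / area / shape /
    ring-thickness / ring-dominant).  Accepted fibres are relabelled as
    consecutive integers in scan order of their centroids.
    """
    params = params or SegmentationParams()
    active = tissue.tissue & ~tissue.excluded
    if not active.any():
        return FibreLabelMap(labels=np.zeros(stack.shape, dtype=np.int32), n_fibres=0,
                             rejected=[], membrane=np.zeros(stack.shape, dtype=bool))
    m = stack.mask.astype(np.float64)
    thr = _mask_threshold(m[active], params)
    membrane = active & (m > thr)
    # fibre interiors are the membrane-enclosed laminin-negative pockets;
    # open inter-fibre gaps reach the image border and are not filled
    enclosed = active & ~membrane & ndimage.binary_fill_holes(membrane)
    seeds, n_seeds = ndimage.label(enclosed)
    if n_seeds:
        sizes = np.bincount(seeds.ravel())
        small = np.flatnonzero(sizes < params.min_seed_area_px)
        seeds[np.isin(seeds, small[small > 0])] = 0
    # each active pixel joins its nearest interior, so a band shared by two
    # fibres is split along its skeleton (the equidistant line)
    _, (ir, ic) = ndimage.distance_transform_edt(seeds == 0, return_indices=True)
    ws = np.where(active & (seeds[ir, ic] > 0), seeds[ir, ic], 0).astype(np.int32)

    ps2 = stack.pixel_size**2
    H, W = stack.shape
    rejected: list[tuple[int, str]] = []
    accepted: list[tuple[tuple[float, float], np.ndarray, tuple[slice, slice]]] = []
    objects = ndimage.find_objects(ws)
    for cand_id, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sl = tuple(slice(max(0, s.start - 2), min(dim, s.stop + 2))
                   for s, dim in zip(sl, (H, W)))
        region_ws = ws[sl] == cand_id
        seed_here = seeds[sl] == cand_id
        trimmed = ndimage.binary_fill_holes(seed_here | (region_ws & membrane[sl]))
        trimmed &= region_ws | seed_here
        area_px = int(trimmed.sum())
        if area_px == 0:
            continue
        rr, cc = np.nonzero(trimmed)
        touches_border = (
            rr.min() + sl[0].start == 0 or cc.min() + sl[1].start == 0
            or rr.max() + sl[0].start == H - 1 or cc.max() + sl[1].start == W - 1
        )
        if touches_border:
            rejected.append((cand_id, "border"))
            continue
        area_um2 = area_px * ps2
        if not params.min_fibre_area_um2 <= area_um2 <= params.max_fibre_area_um2:
            rejected.append((cand_id, "area"))
            continue
        props = measure.regionprops(trimmed.astype(np.uint8))[0]
        if props.solidity < params.min_solidity:
            rejected.append((cand_id, "shape"))
            continue
        ring = trimmed & membrane[sl]
        if not ring.any():
            rejected.append((cand_id, "no-ring"))
            continue
        perim = measure.perimeter(trimmed)
        t_mean_um = ring.sum() / max(perim, 1.0) * stack.pixel_size
        if t_mean_um > params.max_mean_ring_thickness_um:
            rejected.append((cand_id, "ring-thickness"))
            continue
        if not (trimmed & ~ring).any():
            rejected.append((cand_id, "ring-dominant"))
            continue
        centroid = (rr.mean() + sl[0].start, cc.mean() + sl[1].start)
        accepted.append((centroid, trimmed, sl))

    accepted.sort(key=lambda t: (round(t[0][0], 3), round(t[0][1], 3)))
    labels = np.zeros((H, W), dtype=np.int32)
    for new_lab, (_, trimmed, sl) in enumerate(accepted, start=1):
        view = labels[sl]
        view[trimmed & (view == 0)] = new_lab
    return FibreLabelMap(labels=labels, n_fibres=len(accepted), rejected=rejected, membrane=membrane)


def partition_fibres(label_map: FibreLabelMap, stack: ChannelStack,
                     params: SegmentationParams | None = None
                     ) -> tuple[list[FibrePartition], list[tuple[int, str]]]:
    """Partition each labelled fibre into sarcolemmal ring and sarcoplasm.

    laminin-band mode takes the ring as the detected laminin-positive band along
    the fibre boundary; fixed-band mode takes a band of configured width inward
    from the boundary.  The mid-line is traced as the iso-contour of the
    fibre's interior distance transform at half the mean ring depth.  Fibres
    whose ring leaves no sarcoplasm, or whose mid-line cannot be closed, are
    returned in the rejection list instead.
    """
    params = params or SegmentationParams()
    parts: list[FibrePartition] = []
    dropped: list[tuple[int, str]] = []
    H, W = stack.shape
    slices = ndimage.find_objects(label_map.labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        sl = tuple(slice(max(0, s.start - 2), min(dim, s.stop + 2))
                   for s, dim in zip(sl, (H, W)))
        region = label_map.labels[sl] == lab
        if params.ring_mode == "laminin-band" and label_map.membrane is not None:
            ring = region & label_map.membrane[sl]
        else:
            w_px = max(1, int(round(params.fixed_band_width_um / stack.pixel_size)))
            dist_in = ndimage.distance_transform_edt(region)
            ring = region & (dist_in <= w_px + 0.5)
        sarcoplasm = region & ~ring
        if not ring.any() or not sarcoplasm.any():
            dropped.append((lab, "ring-dominant"))
            continue
        pad = np.pad(region, 1)
        # light smoothing irons out the EDT's discrete shells so the traced
        # mid-line does not zig-zag (which would inflate the circumference)
        dist = ndimage.gaussian_filter(ndimage.distance_transform_edt(pad), 0.8)
        outer_contours = measure.find_contours(pad.astype(float), 0.5)
        if not outer_contours:
            dropped.append((lab, "degenerate"))
            continue
        perim = max(_polyline_length(c) for c in outer_contours)
        t_half = max(1.0, ring.sum() / max(perim, 1.0) / 2.0)
        mids = measure.find_contours(dist, t_half)
        mids = [c for c in mids if len(c) >= 8 and np.allclose(c[0], c[-1])]
        if not mids:
            dropped.append((lab, "open-midline"))
            continue
        mid = _smooth_closed_path(max(mids, key=len) - 1.0)   # undo padding offset
        circ = _polyline_length(mid)
        if circ < 8:
            dropped.append((lab, "degenerate"))
            continue
        rr, cc = np.nonzero(region)
        parts.append(FibrePartition(
            label=lab,
            offset=(sl[0].start, sl[1].start),
            region=region,
            ring=ring,
            sarcoplasm=sarcoplasm,
            midline=mid,
            circumference_px=circ,
            ring_edge_count=_edge_count(ring),
            centroid=(float(rr.mean() + sl[0].start), float(cc.mean() + sl[1].start)),
        ))
    return parts, dropped
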