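"""Synthetic multiplexed IF muscle sections with exact per-fibre ground truth.

The generator emulates a transverse section: packed near-convex polygonal
fibres, each wrapped in a closed membrane ("laminin") ring painted on the mask
channel; a single contiguous sarcolemmal arc of controlled angular coverage on
the primary channel (trace to revertant-level intensities); a tertiary channel
that is either a second sarcolemmal stain whose intensity is coupled to primary
presence, or a sarcoplasmic regeneration marker carried by a controlled fraction
of fibres.  Additive Gaussian noise is applied and clipped to the 16-bit range.
High-intensity fold streaks and off-tissue debris blobs can be injected and are
recorded in the ground truth for artefact-exclusion testing.

What is deliberately not modelled: optical PSF, uneven illumination,
longitudinal fibres, Poisson photon statistics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw

from .image_io import ChannelStack, ROLES

FULL_SCALE = 65535.0


class PlacementError(ValueError):
    """Raised when the requested fibres cannot be placed without overlap."""


@dataclass
class SectionSpec:
    """Parameters of one synthetic section.

    Intensities are arbitrary fluorescence units (AU) on the 16-bit scale;
    geometric parameters are micrometres.  ``primary_coverage_fractions`` may be
    a scalar (applied to every fibre) or a sequence that is cycled over fibres
    in label order, so a coverage grid can be requested directly.
    """

    n_fibres: int = 100
    pixel_size: float = 0.5                      # um/px
    canvas_size: tuple[int, int] | None = None   # (H, W) px; auto-sized if None
    fibre_diameter_range: tuple[float, float] = (25.0, 45.0)   # um
    ring_thickness_range: tuple[float, float] = (1.25, 2.0)    # um
    mask_ring_intensity: float = 30000.0
    primary_arc_intensity: float = 30000.0
    primary_coverage_fractions: float | Sequence[float] = 1.0
    tertiary_mode: str = "sarcolemmal"           # or "sarcoplasmic"
    tertiary_intensity_pos: float = 24000.0      # on primary-positive arcs / myosin+ sarcoplasm
    tertiary_intensity_neg: float = 12000.0      # on primary-negative sarcolemma
    myosin_positive_fraction: float = 0.0
    sarcoplasm_background: float = 8000.0
    noise_sd: float = 500.0
    artefact_spec: list[dict] | None = None
    seed: int = 0
    # shape model: near-round perturbed ellipses so circumferential arc length
    # and swept angle stay interchangeable to well under a percentage point
    vertex_count_range: tuple[int, int] = (8, 16)
    max_aspect: float = 1.1
    radial_jitter: float = 0.05

    def coverage_for(self, i: int) -> float:
        f = self.primary_coverage_fractions
        if np.isscalar(f):
            return float(f)
        seq = list(f)
        return float(seq[i % len(seq)])

    def validate(self) -> None:
        if self.n_fibres < 1:
            raise ValueError("n_fibres must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for name in ("mask_ring_intensity", "primary_arc_intensity", "tertiary_intensity_pos",
                     "tertiary_intensity_neg", "sarcoplasm_background"):
            v = getattr(self, name)
            if not 0 <= v <= FULL_SCALE:
                raise ValueError(f"{name}={v} outside [0, {FULL_SCALE:.0f}]")
        fr = self.primary_coverage_fractions
        fr_list = [fr] if np.isscalar(fr) else list(fr)
        if not fr_list or any(not 0 <= f <= 1 for f in fr_list):
            raise ValueError("coverage fractions must lie in [0, 1]")
        if not 0 <= self.myosin_positive_fraction <= 1:
            raise ValueError("myosin_positive_fraction must lie in [0, 1]")
        if self.tertiary_mode not in ("sarcolemmal", "sarcoplasmic"):
            raise ValueError("tertiary_mode must be 'sarcolemmal' or 'sarcoplasmic'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.fibre_diameter_range
        if not 0 < lo <= hi:
            raise ValueError("invalid fibre_diameter_range")
        lo_t, hi_t = self.ring_thickness_range
        if not 0 < lo_t <= hi_t:
            raise ValueError("invalid ring_thickness_range")


@dataclass
class GroundTruth:
    """Exact truth for one synthetic section: one row per drawn fibre.

    ``fibres`` columns: label, centroid_r, centroid_c, true_coverage_fraction,
    true_primary_intensity, true_tertiary_pos_intensity,
    true_tertiary_neg_intensity, true_myosin_positive, ring_thickness_um,
    arc_start_angle.  ``polygons`` maps label -> (n, 2) vertex array (row, col).
    ``artefact_mask`` flags every injected artefact pixel.
    """

    fibres: pd.DataFrame
    polygons: dict[int, np.ndarray]
    artefact_mask: np.ndarray
    pixel_size: float = 0.5

    def to_csv(self, path: str | Path) -> None:
        df = self.fibres.copy()
        df["polygon"] = [
            ";".join(f"{r:.2f} {c:.2f}" for r, c in self.polygons[int(lab)])
            for lab in df["label"]
        ]
        df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def _fibre_polygon(rng: np.random.Generator, centre: tuple[float, float],
                   diameter_px: float, spec: SectionSpec) -> np.ndarray:
    """One near-round convex-ish polygon (row, col vertices) around ``centre``."""
    nv = int(rng.integers(spec.vertex_count_range[0], spec.vertex_count_range[1] + 1))
    aspect = rng.uniform(1.0, spec.max_aspect)
    phi = rng.uniform(0, 2 * np.pi)
    a = diameter_px / 2.0
    b = a / aspect
    base = 2 * np.pi * np.arange(nv) / nv
    ang = base + rng.uniform(-0.3, 0.3, nv) * (2 * np.pi / nv)
    t = ang - phi
    radius = a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)
    radius *= 1.0 + rng.uniform(-spec.radial_jitter, spec.radial_jitter, nv)
    rr = centre[0] + radius * np.sin(ang)
    cc = centre[1] + radius * np.cos(ang)
    return np.column_stack([rr, cc])


def _grid_layout(spec: SectionSpec) -> tuple[tuple[int, int], int, list[tuple[int, int]]]:
    """Cell size and available cell centres for non-overlapping placement."""
    max_d_px = spec.fibre_diameter_range[1] / spec.pixel_size
    max_t_px = np.ceil(spec.ring_thickness_range[1] / spec.pixel_size)
    cell = int(np.ceil(max_d_px + 2 * max_t_px)) + 8
    margin = 4
    if spec.canvas_size is None:
        nc = int(np.ceil(np.sqrt(spec.n_fibres)))
        nr = int(np.ceil(spec.n_fibres / nc))
        canvas = (nr * cell + 2 * margin, nc * cell + 2 * margin)
    else:
        canvas = tuple(spec.canvas_size)
        nr = (canvas[0] - 2 * margin) // cell
        nc = (canvas[1] - 2 * margin) // cell
    capacity = nr * nc
    if spec.n_fibres > capacity:
        raise PlacementError(
            f"cannot place fibre {capacity + 1} of {spec.n_fibres}: canvas {canvas} "
            f"holds at most {capacity} fibres of diameter up to "
            f"{spec.fibre_diameter_range[1]} um without overlap"
        )
    centres = [
        (margin + i * cell + cell // 2, margin + j * cell + cell // 2)
        for i in range(nr) for j in range(nc)
    ]
    return canvas, cell, centres


def generate_section(spec: SectionSpec) -> tuple[ChannelStack, GroundTruth, np.ndarray]:
    """Render one synthetic section.

    Returns the channel stack, the ground truth and the true label image
    (0 = background, labels match ``GroundTruth.fibres``).  Identical seeds give
    bit-identical outputs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    canvas, cell, centres = _grid_layout(spec)
    order = rng.permutation(len(centres))[: spec.n_fibres]

    H, W = canvas
    channels = {r: np.zeros((H, W), dtype=np.float64) for r in ROLES}
    labels = np.zeros((H, W), dtype=np.int32)
    artefact_mask = np.zeros((H, W), dtype=bool)

    if spec.tertiary_mode == "sarcoplasmic":
        n_pos = int(round(spec.myosin_positive_fraction * spec.n_fibres))
        myosin_pos = set(rng.choice(spec.n_fibres, size=n_pos, replace=False).tolist())
    else:
        myosin_pos = set()

    rows = []
    polygons: dict[int, np.ndarray] = {}
    for i in range(spec.n_fibres):
        lab = i + 1
        base_r, base_c = centres[order[i]]
        d_um = rng.uniform(*spec.fibre_diameter_range)
        t_um = rng.uniform(*spec.ring_thickness_range)
        d_px = d_um / spec.pixel_size
        # bands thinner than 3 px alias badly against the EDT shell structure
        t_px = max(3, int(round(t_um / spec.pixel_size)))
        jitter = max(0.0, (cell - d_px - 2 * t_px - 4) / 2)
        centre = (base_r + rng.uniform(-jitter, jitter), base_c + rng.uniform(-jitter, jitter))
        poly = _fibre_polygon(rng, centre, d_px, spec)
        coverage = spec.coverage_for(i)
        theta0 = rng.uniform(0, 2 * np.pi)

        # all raster work happens on a bounding-box crop of the fibre
        r0 = max(0, int(np.floor(poly[:, 0].min())) - 2)
        r1 = min(H, int(np.ceil(poly[:, 0].max())) + 3)
        c0 = max(0, int(np.floor(poly[:, 1].min())) - 2)
        c1 = min(W, int(np.ceil(poly[:, 1].max())) + 3)
        win = (slice(r0, r1), slice(c0, c1))
        rr, cc = draw.polygon(poly[:, 0] - r0, poly[:, 1] - c0, shape=(r1 - r0, c1 - c0))
        interior = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        interior[rr, cc] = True
        # band depth via Euclidean distance transform; the +0.25 centres the
        # discrete EDT shells on the continuous inward offset of depth t_px
        dist = ndimage.distance_transform_edt(interior)
        ring = interior & (dist <= t_px + 0.25)
        sarcoplasm = interior & ~ring
        labels[win][interior] = lab

        cr, cc_ = np.nonzero(interior)
        cent = (float(cr.mean()) + r0, float(cc_.mean()) + c0)
        ring_r, ring_c = np.nonzero(ring)
        ang = np.mod(np.arctan2(ring_r + r0 - cent[0], ring_c + c0 - cent[1]) - theta0, 2 * np.pi)
        if coverage >= 1.0:
            in_arc = np.ones(ang.shape, dtype=bool)
        else:
            in_arc = ang < coverage * 2 * np.pi

        bg = spec.sarcoplasm_background
        channels["mask"][win][ring] = spec.mask_ring_intensity
        channels["mask"][win][sarcoplasm] = bg
        channels["primary"][win][sarcoplasm] = bg
        channels["primary"][win][ring_r, ring_c] = np.where(
            in_arc, spec.primary_arc_intensity, bg)
        if spec.tertiary_mode == "sarcolemmal":
            channels["tertiary"][win][sarcoplasm] = bg
            channels["tertiary"][win][ring_r, ring_c] = np.where(
                in_arc, spec.tertiary_intensity_pos, spec.tertiary_intensity_neg
            )
        else:
            channels["tertiary"][win][ring] = bg
            channels["tertiary"][win][sarcoplasm] = \
                spec.tertiary_intensity_pos if i in myosin_pos else bg

        polygons[lab] = poly
        rows.append({
            "label": lab,
            "centroid_r": cent[0],
            "centroid_c": cent[1],
            "true_coverage_fraction": coverage,
            "true_primary_intensity": spec.primary_arc_intensity,
            "true_tertiary_pos_intensity": spec.tertiary_intensity_pos,
            "true_tertiary_neg_intensity": spec.tertiary_intensity_neg,
            "true_myosin_positive": bool(i in myosin_pos),
            "ring_thickness_um": t_px * spec.pixel_size,
            "arc_start_angle": theta0,
        })

    for art in spec.artefact_spec or []:
        _inject_artefact(art, rng, channels, artefact_mask, spec)

    stack_px = np.zeros((H, W, 3), dtype=np.uint16)
    for idx, role in enumerate(ROLES):
        img = channels[role]
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        stack_px[:, :, idx] = np.clip(np.rint(img), 0, FULL_SCALE).astype(np.uint16)

    stack = ChannelStack(
        pixels=stack_px,
        channel_roles={r: i for i, r in enumerate(ROLES)},
        tertiary_kind=spec.tertiary_mode,
        pixel_size=spec.pixel_size,
    )
    truth = GroundTruth(
        fibres=pd.DataFrame(rows),
        polygons=polygons,
        artefact_mask=artefact_mask,
        pixel_size=spec.pixel_size,
    )
    return stack, truth, labels


def _inject_artefact(art: dict, rng: np.random.Generator, channels: dict[str, np.ndarray],
                     artefact_mask: np.ndarray, spec: SectionSpec) -> None:
    H, W = artefact_mask.shape
    kind = art.get("kind", "fold")
    intensity = float(art.get("intensity", 64000.0))
    if kind == "fold":
        width_px = max(2.0, float(art.get("width_um", 3.0)) / spec.pixel_size)
        theta = rng.uniform(0, np.pi)
        n = np.array([np.sin(theta), np.cos(theta)])
        centre = np.array([rng.uniform(0.2 * H, 0.8 * H), rng.uniform(0.2 * W, 0.8 * W)])
        yy, xx = np.mgrid[0:H, 0:W]
        dist = np.abs((yy - centre[0]) * n[0] + (xx - centre[1]) * n[1])
        streak = dist <= width_px / 2
        for role in ROLES:
            channels[role][streak] = intensity
        artefact_mask |= streak
    elif kind == "debris":
        r_px = max(2.0, float(art.get("radius_um", 6.0)) / spec.pixel_size)
        cr = rng.uniform(r_px, H - r_px)
        cc = rng.uniform(r_px, W - r_px)
        rr, cc_ = draw.disk((cr, cc), r_px, shape=(H, W))
        blob = np.zeros((H, W), dtype=bool)
        blob[rr, cc_] = True
        # debris is bright in the mask and tertiary channels (>= 2 saturated channels)
        channels["mask"][blob] = intensity
        channels["tertiary"][blob] = intensity
        artefact_mask |= blob
    else:
        raise ValueError(f"unknown artefact kind {kind!r}")


def generate_control_panel(spec: SectionSpec, n_sections: int) -> list[tuple[ChannelStack, GroundTruth]]:
    """Replicate negative-baseline control sections for myosin-threshold derivation.

    Controls must be myosin-free: ``tertiary_mode='sarcoplasmic'`` and
    ``myosin_positive_fraction=0``.  Sections differ only by sub-seeds derived
    deterministically from the master seed.
    """
    if spec.tertiary_mode != "sarcoplasmic":
        raise ValueError("control panels require tertiary_mode='sarcoplasmic'")
    if spec.myosin_positive_fraction != 0:
        raise ValueError("control sections must be a negative baseline (myosin_positive_fraction=0)")
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    sub_seeds = np.random.SeedSequence(spec.seed).generate_state(n_sections)
    out = []
    for s in sub_seeds:
        sub = dataclasses.replace(spec, seed=int(s))
        stack, truth, _ = generate_section(sub)
        out.append((stack, truth))
    return out
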