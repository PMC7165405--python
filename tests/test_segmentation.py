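"""Tissue detection, artefact exclusion, fibre segmentation and partition."""

import numpy as np
import pytest
from scipy import ndimage
from skimage import draw

import fibrequant as fq
from fibrequant.evaluation import jaccard_per_truth_fibre
from fibrequant.segmentation import NoTissueError


def _stack_from(pixels, pixel_size=0.5, tertiary_kind="sarcolemmal"):
    return fq.ChannelStack(pixels=pixels, channel_roles={"mask": 0, "primary": 1, "tertiary": 2},
                           pixel_size=pixel_size, tertiary_kind=tertiary_kind)


def test_tissue_covers_fibres(noisy_section):
    _, stack, truth, labels = noisy_section
    tissue = fq.detect_tissue(stack)
    fibre_px = labels > 0
    assert (tissue.tissue & fibre_px).sum() / fibre_px.sum() >= 0.99


def test_blank_image_raises():
    with pytest.raises(NoTissueError):
        fq.detect_tissue(_stack_from(np.zeros((64, 64, 3), dtype=np.uint16)))


def test_pure_noise_yields_no_tissue():
    rng = np.random.default_rng(0)
    noise = np.clip(rng.normal(8000, 500, (128, 128, 3)), 0, 65535).astype(np.uint16)
    with pytest.raises(NoTissueError):
        fq.detect_tissue(_stack_from(noise))


def test_no_artefacts_means_empty_exclusion(noisy_section):
    _, stack, _, _ = noisy_section
    tissue = fq.detect_tissue(stack)
    out = fq.exclude_artefacts(stack, tissue)
    assert not out.excluded.any()
    assert any("saturated" in p for p in out.provenance)


def test_fold_streak_excluded_with_little_collateral():
    spec = fq.SectionSpec(n_fibres=25, seed=5,
                          artefact_spec=[{"kind": "fold", "width_um": 3.0}])
    stack, truth, labels = fq.generate_section(spec)
    tissue = fq.exclude_artefacts(stack, fq.detect_tissue(stack))
    art = truth.artefact_mask
    assert (tissue.excluded & art).sum() / art.sum() >= 0.90
    fibre = labels > 0
    assert (tissue.excluded & fibre & ~art).sum() / fibre.sum() < 0.01


def test_all_saturated_image_excluded_everywhere():
    px = np.full((96, 96, 3), 65535, dtype=np.uint16)
    stack = _stack_from(px)
    tissue = fq.segmentation.TissueMask(tissue=np.ones((96, 96), dtype=bool),
                                        excluded=np.zeros((96, 96), dtype=bool))
    out = fq.exclude_artefacts(stack, tissue)
    assert out.excluded.all()
    assert fq.segment_fibres(stack, out).n_fibres == 0


def test_segmentation_recovers_fibres(noisy_section, noisy_result):
    _, stack, truth, labels = noisy_section
    jac = jaccard_per_truth_fibre(labels, noisy_result.label_map.labels)
    assert (jac >= 0.8).mean() >= 0.95
    assert noisy_result.label_map.n_fibres >= 0.95 * len(truth.fibres)


def test_labels_consecutive_and_disjoint_from_excluded(noisy_result):
    lm = noisy_result.label_map
    present = np.unique(lm.labels)
    assert present[0] == 0
    assert list(present[1:]) == list(range(1, lm.n_fibres + 1))
    assert not (lm.labels[noisy_result.tissue.excluded] > 0).any()


def test_small_fibres_rejected_with_area_reason():
    spec = fq.SectionSpec(n_fibres=6, fibre_diameter_range=(8.0, 10.0),
                          ring_thickness_range=(1.0, 1.5), noise_sd=0, seed=13)
    stack, _, _ = fq.generate_section(spec)
    params = fq.SegmentationParams(min_tissue_area_um2=30.0)
    tissue = fq.exclude_artefacts(stack, fq.detect_tissue(stack, params), params)
    lm = fq.segment_fibres(stack, tissue, params)
    assert lm.n_fibres == 0
    assert "area" in {reason for _, reason in lm.rejected}


def test_elongated_low_solidity_region_rejected_as_shape():
    # crescent: a longitudinal/oblique fibre profile with a membrane outline
    shape = (160, 160)
    big = np.zeros(shape, dtype=bool)
    rr, cc = draw.disk((80, 80), 50, shape=shape)
    big[rr, cc] = True
    cut = np.zeros(shape, dtype=bool)
    rr, cc = draw.disk((80, 110), 45, shape=shape)
    cut[rr, cc] = True
    crescent = big & ~cut
    d = ndimage.distance_transform_edt(crescent)
    ring = crescent & (d <= 3.25)
    px = np.zeros(shape + (3,), dtype=np.uint16)
    for ch in range(3):
        px[:, :, ch][crescent] = 8000
        px[:, :, ch][ring] = 30000 if ch == 0 else 8000
    stack = _stack_from(px)
    tissue = fq.exclude_artefacts(stack, fq.detect_tissue(stack))
    lm = fq.segment_fibres(stack, tissue)
    assert lm.n_fibres == 0
    assert "shape" in {reason for _, reason in lm.rejected}


def test_min_area_monotonicity(noisy_section):
    _, stack, _, _ = noisy_section
    tissue = fq.exclude_artefacts(stack, fq.detect_tissue(stack))
    counts = []
    for min_area in (150.0, 600.0, 1200.0, 5000.0):
        params = fq.SegmentationParams(min_fibre_area_um2=min_area)
        counts.append(fq.segment_fibres(stack, tissue, params).n_fibres)
    assert counts == sorted(counts, reverse=True)


def test_segmentation_deterministic(noisy_section):
    _, stack, _, _ = noisy_section
    t1 = fq.exclude_artefacts(stack, fq.detect_tissue(stack))
    t2 = fq.exclude_artefacts(stack, fq.detect_tissue(stack))
    l1 = fq.segment_fibres(stack, t1)
    l2 = fq.segment_fibres(stack, t2)
    assert np.array_equal(l1.labels, l2.labels)


def test_partition_tiles_every_fibre(noisy_result):
    assert noisy_result.partitions, "no fibres partitioned"
    for part in noisy_result.partitions:
        assert not (part.ring & part.sarcoplasm).any()
        assert np.array_equal(part.ring | part.sarcoplasm, part.region)
        assert part.circumference_px >= 8
        assert np.allclose(part.midline[0], part.midline[-1])  # closed loop


def test_laminin_band_ring_area_close_to_annulus(clean_section, clean_result):
    spec, _, truth, labels = clean_section
    from shapely.geometry import Polygon

    by_label = truth.fibres.set_index("label")
    for part in clean_result.partitions:
        d2 = (by_label.centroid_r - part.centroid[0]) ** 2 + (by_label.centroid_c - part.centroid[1]) ** 2
        lab = int(d2.idxmin())
        t_px = by_label.loc[lab].ring_thickness_um / spec.pixel_size
        poly = Polygon([(c, r) for r, c in truth.polygons[lab]])
        analytic = poly.area - poly.buffer(-t_px).area
        assert part.ring.sum() == pytest.approx(analytic, rel=0.15)


def test_fixed_band_circle_circumference_closed_form():
    from conftest import make_disk_stack

    stack, interior = make_disk_stack(radius_px=40, pixel_size=0.5)
    lm = fq.FibreLabelMap(labels=interior.astype(np.int32), n_fibres=1, rejected=[], membrane=None)
    params = fq.SegmentationParams(ring_mode="fixed-band", fixed_band_width_um=1.0)
    parts, _ = fq.partition_fibres(lm, stack, params)
    assert len(parts) == 1
    # mid-line of a 1 um band on a radius-20 um fibre sits near radius 19.5 um
    expected = 2 * np.pi * 19.5 / 0.5
    assert parts[0].circumference_px == pytest.approx(expected, rel=0.05)
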