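"""Shared fixtures: small synthetic sections analysed once per session."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage
from skimage import draw

import fibrequant as fq

COVERAGE_GRID = [i / 10 for i in range(11)]


@pytest.fixture(scope="session")
def noisy_section():
    """33 fibres over the full coverage grid at realistic noise (sd 500 on bg 8000)."""
    spec = fq.SectionSpec(n_fibres=33, primary_coverage_fractions=COVERAGE_GRID, seed=42)
    stack, truth, labels = fq.generate_section(spec)
    return spec, stack, truth, labels


@pytest.fixture(scope="session")
def noisy_result(noisy_section):
    _, stack, _, _ = noisy_section
    return fq.analyse_section(stack)


@pytest.fixture(scope="session")
def clean_section():
    """22 noise-free fibres, two per coverage grid point."""
    spec = fq.SectionSpec(n_fibres=22, primary_coverage_fractions=COVERAGE_GRID,
                          noise_sd=0.0, seed=11)
    stack, truth, labels = fq.generate_section(spec)
    return spec, stack, truth, labels


@pytest.fixture(scope="session")
def clean_result(clean_section):
    _, stack, _, _ = clean_section
    return fq.analyse_section(stack)


def make_disk_stack(radius_px: int = 40, band_px: float = 3.0, pixel_size: float = 0.5,
                    ring_intensity: float = 30000.0, background: float = 8000.0,
                    shape: tuple[int, int] = (141, 141)) -> tuple[fq.ChannelStack, np.ndarray]:
    """A single circular fibre drawn by hand; returns (stack, interior mask)."""
    interior = np.zeros(shape, dtype=bool)
    rr, cc = draw.disk((shape[0] // 2, shape[1] // 2), radius_px, shape=shape)
    interior[rr, cc] = True
    d = ndimage.distance_transform_edt(interior)
    ring = interior & (d <= band_px + 0.25)
    img = np.zeros(shape + (3,), dtype=np.uint16)
    for ch in range(3):
        img[:, :, ch][interior] = int(background)
        img[:, :, ch][ring] = int(ring_intensity) if ch != 2 else int(background)
    stack = fq.ChannelStack(pixels=img, channel_roles={"mask": 0, "primary": 1, "tertiary": 2},
                            pixel_size=pixel_size)
    return stack, interior


def single_partition(region: np.ndarray, stack_pixel_size: float = 0.5,
                     band_um: float = 1.5) -> fq.segmentation.FibrePartition:
    """Build one FibrePartition from a bare region mask via the fixed-band path."""
    labels = region.astype(np.int32)
    lm = fq.FibreLabelMap(labels=labels, n_fibres=1, rejected=[], membrane=None)
    img = np.zeros(region.shape + (3,), dtype=np.uint16)
    stack = fq.ChannelStack(pixels=img, channel_roles={"mask": 0, "primary": 1, "tertiary": 2},
                            pixel_size=stack_pixel_size)
    params = fq.SegmentationParams(ring_mode="fixed-band", fixed_band_width_um=band_um)
    parts, dropped = fq.partition_fibres(lm, stack, params)
    assert parts, f"partition failed: {dropped}"
    return parts[0]
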