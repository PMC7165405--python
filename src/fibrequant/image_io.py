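"""Reading/writing of multichannel stacks, per-fibre tables and classification maps.

Conventions fixed here for reproducible morphometrics: row-major, 0-based pixel
indices; area = pixel count x pixel_size^2.  Channel roles are ``mask`` (the
membrane stain outlining every fibre, laminin alpha-2 in the intended assay),
``primary`` (the sarcolemmal protein of interest, dystrophin) and ``tertiary``
(either a second sarcolemmal marker or a sarcoplasmic regeneration marker).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

ROLES = ("mask", "primary", "tertiary")
TERTIARY_KINDS = ("sarcolemmal", "sarcoplasmic")

#: default pixel pitch (um/px) for a typical 20x fluorescence scan, used with a
#: warning when the file carries no pixel-size metadata.
DEFAULT_PIXEL_SIZE = 0.325

#: refuse images above this many pixels; the pipeline operates on loaded arrays,
#: not tiled whole-slide pyramids.
MAX_PIXELS = 36_000_000

COVERAGE_CLASSES = ("0-25", "25-50", "50-75", "75-100")

#: classification-map palette: one colour per coverage class, plus yellow for
#: unrecognised regions / connective tissue; background renders black.
DEFAULT_CLASS_PALETTE: dict[str, tuple[int, int, int]] = {
    "0-25": (202, 0, 32),      # protein negative
    "25-50": (244, 165, 130),
    "50-75": (146, 197, 222),
    "75-100": (5, 113, 176),
}
UNRECOGNISED_COLOUR = (255, 255, 0)


class ReadError(RuntimeError):
    """Raised when an image file cannot be interpreted as a channel stack."""


@dataclass
class ChannelStack:
    """Co-registered multichannel 16-bit image with channel-role metadata.

    pixels: (H, W, C) uint16 array.
    channel_roles: role -> channel index, one channel per role.
    """

    pixels: np.ndarray
    channel_roles: Mapping[str, int]
    tertiary_kind: str = "sarcolemmal"
    pixel_size: float = DEFAULT_PIXEL_SIZE
    saturation_value: int = 65535

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be H x W x C")
        if set(self.channel_roles) != set(ROLES):
            raise ValueError(f"channel_roles must define exactly {ROLES}")
        if len(set(self.channel_roles.values())) != len(ROLES):
            raise ValueError("channel_roles indices must be distinct")
        if self.tertiary_kind not in TERTIARY_KINDS:
            raise ValueError(f"tertiary_kind must be one of {TERTIARY_KINDS}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    def channel(self, role: str) -> np.ndarray:
        return self.pixels[:, :, self.channel_roles[role]]

    @property
    def mask(self) -> np.ndarray:
        return self.channel("mask")

    @property
    def primary(self) -> np.ndarray:
        return self.channel("primary")

    @property
    def tertiary(self) -> np.ndarray:
        return self.channel("tertiary")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class ChannelConfig:
    """Binding of channel roles to pages of an image file."""

    roles: Mapping[str, int] = field(default_factory=lambda: {"mask": 1, "primary": 0, "tertiary": 2})
    tertiary_kind: str = "sarcolemmal"
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        if set(self.roles) != set(ROLES):
            raise ValueError(f"config must bind exactly the roles {ROLES}")
        if len(set(self.roles.values())) != len(ROLES):
            raise ValueError("page indices must be distinct")


def read_channel_stack(path: str | Path, config: ChannelConfig) -> ChannelStack:
    """Read a single- or multi-page TIFF/OME-TIFF into a :class:`ChannelStack`.

    8-bit inputs are promoted to 16-bit by left shift (with a warning); pages are
    routed to roles per ``config``.
    """
    path = Path(path)
    try:
        pages = tifffile.imread(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise ReadError(f"cannot read {path}: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ReadError(f"{path}: expected 2-D pages, got array of shape {pages.shape}")
    # accept either (pages, H, W) or (H, W, pages) layouts
    if pages.shape[0] > 8 and pages.shape[-1] <= 8:
        pages = np.moveaxis(pages, -1, 0)
    n_pages = pages.shape[0]
    for role, idx in config.roles.items():
        if not 0 <= idx < n_pages:
            raise ReadError(f"role '{role}' requests page {idx} of a {n_pages}-page file {path}")
    if pages.dtype == np.uint8:
        warnings.warn("8-bit input promoted to 16-bit by left shift", stacklevel=2)
        pages = pages.astype(np.uint16) << 8
    elif pages.dtype != np.uint16:
        raise ReadError(f"{path}: unsupported dtype {pages.dtype}; expected uint8 or uint16")
    if pages.shape[1] * pages.shape[2] > MAX_PIXELS:
        raise ReadError(
            f"{path}: image has {pages.shape[1]}x{pages.shape[2]} pixels, above the "
            f"{MAX_PIXELS}-pixel bound; tile or downsample the slide before analysis"
        )
    pixel_size = config.pixel_size
    meta = _read_metadata(path)
    if pixel_size is None:
        pixel_size = meta.get("pixel_size")
    if pixel_size is None:
        warnings.warn(
            f"no pixel size in metadata; assuming {DEFAULT_PIXEL_SIZE} um/px", stacklevel=2
        )
        pixel_size = DEFAULT_PIXEL_SIZE
    stack = np.stack([pages[config.roles[r]] for r in ROLES], axis=-1)
    return ChannelStack(
        pixels=stack,
        channel_roles={r: i for i, r in enumerate(ROLES)},
        tertiary_kind=config.tertiary_kind,
        pixel_size=float(pixel_size),
    )


def _read_metadata(path: Path) -> dict:
    try:
        with tifffile.TiffFile(path) as tif:
            desc = tif.pages[0].description
        if desc:
            meta = json.loads(desc)
            if isinstance(meta, dict):
                return meta
    except (json.JSONDecodeError, UnicodeDecodeError, tifffile.TiffFileError):
        pass
    return {}


def write_channel_stack(stack: ChannelStack, path: str | Path) -> None:
    """Write a stack as a multipage uint16 TIFF, one page per role in canonical order."""
    path = Path(path)
    pages = np.stack([stack.channel(r) for r in ROLES], axis=0)
    meta = {
        "channel_roles": {r: i for i, r in enumerate(ROLES)},
        "tertiary_kind": stack.tertiary_kind,
        "pixel_size": stack.pixel_size,
        "saturation_value": int(stack.saturation_value),
    }
    tifffile.imwrite(path, pages, photometric="minisblack", description=json.dumps(meta, sort_keys=True))


def write_fibre_table(records: Sequence, path: str | Path) -> None:
    """Write per-fibre records as CSV with a fixed, documented column order.

    One row per fibre; column order is the declaration order of the record's
    fields; floats rendered at 6 significant digits; byte-identical across runs
    on identical input.
    """
    if not records:
        raise ValueError("records must be non-empty")
    import pandas as pd

    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=list(rows[0].keys()))
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def write_section_summary(summary_dict: dict, path: str | Path) -> None:
    """Serialise a section summary dict as stable (sorted-key) JSON."""
    Path(path).write_text(json.dumps(summary_dict, sort_keys=True, indent=2, allow_nan=False) + "\n")


def render_classification_map(
    labels: np.ndarray,
    classes: Mapping[int, str],
    unrecognised_regions: np.ndarray | None = None,
    palette: Mapping[str, tuple[int, int, int]] | None = None,
) -> np.ndarray:
    """Render a coverage classification map as an RGB uint8 image.

    Every labelled fibre is painted with its class colour; unrecognised/connective
    tissue renders yellow; background black.  Raises if any labelled fibre lacks
    a class.
    """
    palette = dict(DEFAULT_CLASS_PALETTE if palette is None else palette)
    if set(palette) != set(COVERAGE_CLASSES) or len(set(palette.values())) != len(COVERAGE_CLASSES):
        raise ValueError(f"palette must be a bijection with classes {COVERAGE_CLASSES}")
    present = np.unique(labels)
    present = present[present > 0]
    missing = [int(l) for l in present if int(l) not in classes]
    if missing:
        raise ValueError(f"fibres lacking a coverage class: {missing}")
    for cls in classes.values():
        if cls not in palette:
            raise ValueError(f"unknown coverage class {cls!r}")
    rgb = np.zeros(labels.shape + (3,), dtype=np.uint8)
    if unrecognised_regions is not None:
        rgb[unrecognised_regions.astype(bool)] = UNRECOGNISED_COLOUR
    lut = np.zeros((int(present.max()) + 1 if present.size else 1, 3), dtype=np.uint8)
    for lab in present:
        lut[int(lab)] = palette[classes[int(lab)]]
    fg = labels > 0
    rgb[fg] = lut[labels[fg]]
    return rgb
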