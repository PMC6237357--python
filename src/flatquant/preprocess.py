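"""Channel handling, background subtraction, intensity rescaling and QC.

The preprocessing contract mirrors the standard FIJI-style workflow for
whole-flatmount fluorescence: split a multi-channel acquisition into its
component channels, subtract a smoothly varying background, stretch the
intensity histogram so that 99% of the signal occupies the dynamic range of
a 16-bit image, convert to 8-bit, and reject images whose *original*
intensity spread covers less than 5% of the dynamic range (no usable
signal-to-noise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from skimage.morphology import disk, opening

logger = logging.getLogger("flatquant")

#: channel roles the pipeline understands
CHANNEL_ROLES = ("reporter", "nuclei", "junction")

#: minimum fraction of the dynamic range the original histogram must span
QC_MIN_DYNAMIC_RANGE_FRACTION = 0.05

#: fraction of the signal mapped inside the dynamic range when rescaling
DEFAULT_RESCALE_COVERAGE = 0.99


@dataclass
class FlatmountImage:
    """A flatmounted-epithelium acquisition split into role-named channels.

    Parameters
    ----------
    channels
        Mapping from role (``reporter`` — the recombination reporter, e.g.
        tdTomato; ``nuclei`` — DAPI; ``junction`` — ZO-1) to a 2-D intensity
        raster. All rasters must share one shape.
    bit_depth
        8 or 16; intensities must lie in ``[0, 2**bit_depth - 1]``.
    pixel_size
        Optional physical pixel pitch (microns per pixel); informational.
    provenance
        Free-text origin of the image (file path, simulator spec, ...).
    """

    channels: dict[str, np.ndarray]
    bit_depth: int = 16
    pixel_size: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not self.channels:
            raise ValueError("image has no channels")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel rasters differ in shape: {shapes}")
        for role, ch in self.channels.items():
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
            if ch.ndim != 2:
                raise ValueError(f"channel {role!r} is not a 2-D raster")
            vmax = 2**self.bit_depth - 1
            if ch.size and (ch.min() < 0 or ch.max() > vmax):
                raise ValueError(f"channel {role!r} intensities outside [0, {vmax}]")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class QCReport:
    """Signal-to-noise gate for one channel.

    ``dynamic_range_fraction`` is ``(max - min) / (2**bit_depth - 1)`` of the
    ORIGINAL (pre-rescaling) intensities; an image passes iff that fraction
    is at least :data:`QC_MIN_DYNAMIC_RANGE_FRACTION`.
    """

    channel_role: str
    dynamic_range_fraction: float
    passed: bool
    reason: str = ""


def split_channels(
    raw: np.ndarray,
    channel_map: Mapping[int, str],
    *,
    pixel_size: float | None = None,
    provenance: str = "",
) -> FlatmountImage:
    """Separate a multi-plane raster into role-named channels.

    ``raw`` may be a single 2-D plane, a plane-first stack ``(C, H, W)`` or a
    plane-last stack ``(H, W, C)``; the channel axis is taken to be whichever
    trailing/leading axis has length <= 8. ``channel_map`` maps plane index to
    role; unmapped planes are ignored with a logged warning.
    """
    if raw.ndim == 2:
        planes = [raw]
    elif raw.ndim == 3:
        if raw.shape[0] <= 8:
            planes = [raw[i] for i in range(raw.shape[0])]
        elif raw.shape[2] <= 8:
            planes = [raw[..., i] for i in range(raw.shape[2])]
        else:
            raise ValueError(f"cannot locate channel axis in shape {raw.shape}")
    else:
        raise ValueError(f"expected 2-D or 3-D raster, got ndim={raw.ndim}")
    if len(planes) < 1:
        raise ValueError("raster has no planes")

    roles = list(channel_map.values())
    if len(roles) != len(set(roles)):
        raise ValueError(f"duplicate role assignment in channel map: {channel_map}")
    if "reporter" not in roles:
        raise ValueError("channel map must assign the reporter channel")

    channels: dict[str, np.ndarray] = {}
    for idx, role in channel_map.items():
        if idx < 0 or idx >= len(planes):
            raise ValueError(f"channel map references plane {idx}, image has {len(planes)}")
        channels[role] = planes[idx]
    unmapped = sorted(set(range(len(planes))) - set(channel_map.keys()))
    if unmapped:
        logger.warning("ignoring unmapped image planes %s", unmapped)

    bit_depth = 8 if planes[0].dtype == np.uint8 else 16
    return FlatmountImage(
        channels=channels,
        bit_depth=bit_depth,
        pixel_size=pixel_size,
        provenance=provenance,
    )


def qc_dynamic_range(
    channel: np.ndarray,
    bit_depth: int,
    *,
    channel_role: str = "reporter",
    min_fraction: float = QC_MIN_DYNAMIC_RANGE_FRACTION,
) -> QCReport:
    """Gate a channel on the spread of its original intensity distribution.

    Must be applied to the raw intensities, before any rescaling: rescaling
    always fills the dynamic range and would defeat the gate. A constant
    raster yields fraction 0 and fails (it is not an error).
    """
    if channel.size == 0:
        raise ValueError("empty raster")
    span = float(channel.max()) - float(channel.min())
    fraction = span / (2**bit_depth - 1)
    passed = fraction >= min_fraction
    reason = (
        ""
        if passed
        else f"intensity spread {fraction:.4f} of dynamic range < {min_fraction}"
    )
    return QCReport(channel_role, fraction, passed, reason)


def subtract_background(channel: np.ndarray, radius: int) -> np.ndarray:
    """Remove a smoothly varying background by morphological opening.

    The background estimate is a grayscale opening with a disk structuring
    element of the given radius (the rolling-ball equivalent for features
    much smaller than the disk); it is subtracted pixelwise. Because an
    opening never exceeds the image, the result is non-negative and bounded
    above by the input.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if radius >= min(channel.shape):
        raise ValueError(
            f"background radius too large: {radius} >= min dimension {min(channel.shape)}"
        )
    footprint = disk(radius, decomposition="sequence")
    background = opening(channel, footprint)
    return channel - background


def rescale_to_dynamic_range(
    channel: np.ndarray,
    coverage: float = DEFAULT_RESCALE_COVERAGE,
    bit_depth: int = 16,
) -> np.ndarray:
    """Linearly stretch intensities so ``coverage`` of the signal fills the range.

    The ``[(1-coverage)/2, 1-(1-coverage)/2]`` percentiles (default 0.5th and
    99.5th) are mapped onto ``[0, 2**bit_depth - 1]``; values outside are
    clipped. Percentiles are taken at actual sample values (lower/higher
    order statistics) so that a second application is an exact identity on
    the first pass's output.
    """
    if not 0 < coverage <= 1:
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    tail = (1.0 - coverage) / 2.0 * 100.0
    p_low = float(np.percentile(channel, tail, method="lower"))
    p_high = float(np.percentile(channel, 100.0 - tail, method="higher"))
    if p_low == p_high:
        raise ValueError("no contrast: degenerate percentile interval")
    vmax = 2**bit_depth - 1
    scaled = (channel.astype(np.float64) - p_low) / (p_high - p_low)
    out = np.rint(np.clip(scaled, 0.0, 1.0) * vmax)
    return out.astype(np.uint8 if bit_depth == 8 else np.uint16)


def convert_to_8bit(channel: np.ndarray) -> np.ndarray:
    """Fixed linear 16-bit to 8-bit conversion, ``v -> floor(v / 257)``.

    257 = 65535/255, so 0 -> 0 and 65535 -> 255. Deliberately NOT a
    re-stretch: contrast stretching has already been done by
    :func:`rescale_to_dynamic_range`.
    """
    arr = np.asarray(channel)
    if arr.size and (arr.min() < 0 or arr.max() > 65535):
        raise ValueError("input not a 16-bit raster")
    return (arr.astype(np.uint32) // 257).astype(np.uint8)
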