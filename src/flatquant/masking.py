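"""Background-mask bookkeeping and the total measurable area A_Tot.

The measurable-area accounting works on a duplicated "background image":
every pixel first gains one intensity unit (so no pixel is 0), then every
excluded region — no tissue, bubbles, damage — is set to 0. A pixel is
background if and only if it is exactly 0 afterwards, which makes the
accounting exact: A_Tot = image area - background pixels, always.

Exclusion regions arrive as machine-readable inputs (boolean/label rasters
or pixel-coordinate polygons) rather than interactive ROIs, so the whole
procedure is reproducible; the arithmetic is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from skimage.draw import polygon as draw_polygon


@dataclass
class BackgroundMask:
    """Boolean raster of non-measurable pixels (True = excluded)."""

    mask: np.ndarray
    n_background_pixels: int
    source: str = "provided_raster"  # manual_rois | provided_raster | synthetic_truth

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            raise ValueError("mask must be boolean")
        actual = int(self.mask.sum())
        if actual != self.n_background_pixels:
            raise ValueError(
                f"n_background_pixels={self.n_background_pixels} but mask has {actual}"
            )


@dataclass
class MeasurableArea:
    """Total possible area of expression, in pixels."""

    a_tot: int
    image_area: int

    def __post_init__(self) -> None:
        if not 0 <= self.a_tot <= self.image_area:
            raise ValueError(f"a_tot={self.a_tot} outside [0, {self.image_area}]")


ExclusionRegion = "np.ndarray | Sequence[tuple[float, float]]"


def rasterize_exclusions(
    shape: tuple[int, int],
    exclusion_regions: Iterable[np.ndarray | Sequence[tuple[float, float]]],
) -> np.ndarray:
    """Union exclusion inputs into one boolean raster.

    Each region is either a raster of the image shape (boolean, or a label
    raster where nonzero means exclude) or a polygon given as (row, col)
    vertices in 0-based pixel coordinates.
    """
    out = np.zeros(shape, dtype=bool)
    for region in exclusion_regions:
        arr = np.asarray(region)
        if arr.ndim == 2 and arr.shape == shape:
            out |= arr != 0 if arr.dtype != bool else arr
        elif arr.ndim == 2 and arr.shape[1] == 2:
            if (
                arr[:, 0].min() < 0
                or arr[:, 1].min() < 0
                or arr[:, 0].max() > shape[0] - 1
                or arr[:, 1].max() > shape[1] - 1
            ):
                raise ValueError("exclusion polygon outside image bounds")
            rr, cc = draw_polygon(arr[:, 0], arr[:, 1], shape=shape)
            out[rr, cc] = True
        else:
            raise ValueError(
                f"exclusion region must match image shape {shape} or be an (n, 2) "
                f"polygon; got shape {arr.shape}"
            )
    return out


def build_background_image(
    channel: np.ndarray,
    exclusion_regions: Iterable[np.ndarray | Sequence[tuple[float, float]]] = (),
) -> np.ndarray:
    """Add one intensity unit everywhere, then zero the excluded regions.

    The +1 (saturating at 255 — wrapping would create spurious zeros)
    guarantees that afterwards a pixel is 0 exactly when it was excluded.
    An empty exclusion set is legal: every pixel is then measurable.
    """
    if channel.dtype != np.uint8:
        raise ValueError("background image is built from an 8-bit channel")
    bg = np.minimum(channel.astype(np.uint16) + 1, 255).astype(np.uint8)
    excl = rasterize_exclusions(channel.shape, exclusion_regions)
    bg[excl] = 0
    return bg


def build_background_mask(
    background_image: np.ndarray, *, source: str = "provided_raster"
) -> BackgroundMask:
    """Mark every 0-value pixel of the background image as non-measurable."""
    mask = background_image == 0
    return BackgroundMask(mask=mask, n_background_pixels=int(mask.sum()), source=source)


def apply_mask_to_foreground(
    foreground: np.ndarray, mask: BackgroundMask
) -> tuple[np.ndarray, MeasurableArea]:
    """Zero the foreground under the mask and account the measurable area.

    Pixels outside the mask are returned bit-identical — the foreground is
    what gets quantified and must not be edited further. Applying the same
    mask twice is a no-op.
    """
    if foreground.shape != mask.mask.shape:
        raise ValueError(
            f"dimension mismatch: foreground {foreground.shape} vs mask {mask.mask.shape}"
        )
    out = foreground.copy()
    out[mask.mask] = 0
    image_area = int(foreground.size)
    area = MeasurableArea(a_tot=image_area - mask.n_background_pixels, image_area=image_area)
    return out, area
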