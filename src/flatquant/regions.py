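"""Regional partition of a flatmount: quadrants and central/peripheral.

The optic-nerve head is the origin of flatmount geometry. Two partition
families are defined over the tissue pixels:

* quadrants — dorsal/ventral about the horizontal axis through the center
  and nasal/temporal about the vertical axis (which image side is nasal
  depends on eye laterality: left and right eyes mirror);
* radial — a central ellipse whose diameter along each orthogonal axis is
  half the tissue's full diameter along that axis, everything outside being
  periphery. On an idealized solid-ellipse flatmount the central region is
  exactly (1/2)^2 = 25% of the total area.

Replacing the manual cropping of regions with these deterministic
constructions is what makes regional measurements reproducible; a
user-supplied region raster can still override them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .masking import BackgroundMask, MeasurableArea
from .quantify import ExpressionMeasurement, percent_area

#: radial label codes
CENTRAL, PERIPHERAL = 1, 2
#: quadrant label codes (dorsal/ventral x nasal/temporal)
DORSAL_NASAL, DORSAL_TEMPORAL, VENTRAL_NASAL, VENTRAL_TEMPORAL = 1, 2, 3, 4

QUADRANT_REGIONS = ("dorsal", "ventral", "nasal", "temporal")
RADIAL_REGIONS = ("central", "peripheral")
ALL_REGIONS = ("total",) + QUADRANT_REGIONS + RADIAL_REGIONS


@dataclass
class RegionPartition:
    """Label rasters assigning each tissue pixel to its regions.

    ``radial_labels``: 0 outside tissue, 1 central, 2 peripheral.
    ``quadrant_labels``: 0 outside tissue, 1..4 for the four quadrant
    combinations (dorsal/ventral x nasal/temporal).
    """

    center: tuple[float, float]
    radial_labels: np.ndarray | None = None
    quadrant_labels: np.ndarray | None = None
    central_semiaxes: tuple[float, float] | None = None  # (row, col) semiaxes
    nasal_side: str | None = None

    def region_mask(self, region: str) -> np.ndarray:
        """Boolean raster of one named region (or the whole tissue for 'total')."""
        if region == "total":
            basis = self.radial_labels if self.radial_labels is not None else self.quadrant_labels
            if basis is None:
                raise ValueError("partition holds no labels")
            return basis > 0
        if region in RADIAL_REGIONS:
            if self.radial_labels is None:
                raise ValueError("radial partition not built")
            return self.radial_labels == (CENTRAL if region == "central" else PERIPHERAL)
        if region in QUADRANT_REGIONS:
            if self.quadrant_labels is None:
                raise ValueError("quadrant partition not built")
            codes = {
                "dorsal": (DORSAL_NASAL, DORSAL_TEMPORAL),
                "ventral": (VENTRAL_NASAL, VENTRAL_TEMPORAL),
                "nasal": (DORSAL_NASAL, VENTRAL_NASAL),
                "temporal": (DORSAL_TEMPORAL, VENTRAL_TEMPORAL),
            }[region]
            return np.isin(self.quadrant_labels, codes)
        raise ValueError(f"unknown region {region!r}")


def nasal_side_for_eye(eye: str) -> str:
    """Image side of the nasal retina by laterality.

    Convention (fixed, documented): flatmounts are imaged apical side up, so
    the nasal side of a right eye (OD) appears on the image left, and of a
    left eye (OS) on the image right.
    """
    eye = eye.upper()
    if eye in ("OD", "RIGHT", "R"):
        return "left"
    if eye in ("OS", "LEFT", "L"):
        return "right"
    raise ValueError(f"eye laterality required: unknown eye {eye!r}")


def _check_center(tissue_mask: np.ndarray, center: tuple[float, float]) -> None:
    """The center must lie within the tissue's extent on both axis lines.

    Interior holes (excluded bubbles, damage) under the center itself are
    tolerated: they are gaps in the measurable area, not in the anatomy.
    """
    cr, cc = center
    ri, ci = int(round(cr)), int(round(cc))
    if not (0 <= ri < tissue_mask.shape[0] and 0 <= ci < tissue_mask.shape[1]):
        raise ValueError("center outside image")
    cols = np.flatnonzero(tissue_mask[ri, :])
    rows = np.flatnonzero(tissue_mask[:, ci])
    if (
        len(cols) == 0
        or len(rows) == 0
        or not (cols.min() <= ci <= cols.max())
        or not (rows.min() <= ri <= rows.max())
    ):
        raise ValueError("center outside tissue")


def _axis_extents(tissue_mask: np.ndarray, center: tuple[float, float]) -> tuple[float, float]:
    """Tissue diameter along the vertical and horizontal axes through center.

    The extent is the distance between the extreme tissue pixels on the
    1-pixel axis line through the center, interior holes ignored — the
    "total" extent of the butterflied eyecup along that direction.
    """
    cr, cc = center
    cols = np.flatnonzero(tissue_mask[int(round(cr)), :])
    rows = np.flatnonzero(tissue_mask[:, int(round(cc))])
    extent_h = float(cols.max() - cols.min())
    extent_v = float(rows.max() - rows.min())
    return extent_v, extent_h


def define_central_ellipse(
    tissue_mask: np.ndarray, center: tuple[float, float]
) -> RegionPartition:
    """Build the central/peripheral partition about the optic-nerve center.

    The central region is the ellipse centered at the optic nerve whose
    diameter along each orthogonal axis (dorsal/ventral and nasal/temporal)
    is half of the tissue's measured diameter along that axis; a tissue
    pixel is central iff its normalized elliptical radius is <= 1 (boundary
    inclusive). All remaining tissue is periphery.
    """
    cr, cc = center
    _check_center(tissue_mask, center)
    extent_v, extent_h = _axis_extents(tissue_mask, center)
    if extent_v <= 0 or extent_h <= 0:
        raise ValueError("zero tissue extent along an axis")
    semi_v = extent_v / 2.0 / 2.0
    semi_h = extent_h / 2.0 / 2.0

    rr, cc_grid = np.indices(tissue_mask.shape)
    radius2 = ((rr - cr) / semi_v) ** 2 + ((cc_grid - cc) / semi_h) ** 2
    radial = np.zeros(tissue_mask.shape, dtype=np.uint8)
    radial[tissue_mask] = np.where(radius2[tissue_mask] <= 1.0, CENTRAL, PERIPHERAL)
    return RegionPartition(
        center=(float(cr), float(cc)),
        radial_labels=radial,
        central_semiaxes=(semi_v, semi_h),
    )


def define_quadrants(
    tissue_mask: np.ndarray,
    center: tuple[float, float],
    nasal_side: str | None = None,
    *,
    eye: str | None = None,
) -> RegionPartition:
    """Build the dorsal/ventral x nasal/temporal partition.

    Half-planes about the axes through the optic-nerve center: dorsal is
    the image top. Which image side is nasal comes from ``nasal_side``
    ("left"/"right") or is derived from the eye laterality; left and right
    eyes mirror. Pixels exactly on an axis go to the nasal and dorsal sides
    (deterministic tie-break).
    """
    if nasal_side is None:
        if eye is None:
            raise ValueError("eye laterality required")
        nasal_side = nasal_side_for_eye(eye)
    if nasal_side not in ("left", "right"):
        raise ValueError(f"nasal_side must be 'left' or 'right', got {nasal_side!r}")
    cr, cc = center
    _check_center(tissue_mask, center)

    rr, cc_grid = np.indices(tissue_mask.shape)
    dorsal = (rr - cr) <= 0  # boundary row -> dorsal
    if nasal_side == "left":
        nasal = (cc_grid - cc) <= 0
    else:
        nasal = (cc_grid - cc) >= 0
    # boundary column is nasal under both lateralities

    quad = np.zeros(tissue_mask.shape, dtype=np.uint8)
    quad[tissue_mask & dorsal & nasal] = DORSAL_NASAL
    quad[tissue_mask & dorsal & ~nasal] = DORSAL_TEMPORAL
    quad[tissue_mask & ~dorsal & nasal] = VENTRAL_NASAL
    quad[tissue_mask & ~dorsal & ~nasal] = VENTRAL_TEMPORAL
    return RegionPartition(
        center=(float(cr), float(cc)), quadrant_labels=quad, nasal_side=nasal_side
    )


def partition_flatmount(
    tissue_mask: np.ndarray,
    center: tuple[float, float],
    nasal_side: str | None = None,
    *,
    eye: str | None = None,
) -> RegionPartition:
    """Both partition families (radial + quadrants) in one object."""
    radial = define_central_ellipse(tissue_mask, center)
    quad = define_quadrants(tissue_mask, center, nasal_side, eye=eye)
    return RegionPartition(
        center=radial.center,
        radial_labels=radial.radial_labels,
        quadrant_labels=quad.quadrant_labels,
        central_semiaxes=radial.central_semiaxes,
        nasal_side=quad.nasal_side,
    )


def regional_measurements(
    foreground: np.ndarray,
    mask: BackgroundMask,
    partition: RegionPartition,
    threshold: float | str = "auto",
    *,
    eye_id: str = "",
    regions: tuple[str, ...] = ALL_REGIONS,
) -> list[ExpressionMeasurement]:
    """Percent-area expression for the whole eye and each named region.

    The segmentation threshold is computed once (or given once) and shared
    by every region of the eye, so regional values decompose the whole-eye
    measurement exactly: within each partition family the regional A_Exp
    and A_Tot sum to the whole-eye values. A region with no measurable
    pixels yields a measurement marked missing rather than an error; the
    downstream mixed model accepts unbalanced data.
    """
    from .quantify import segment_expression

    seg, thr = segment_expression(foreground, threshold, mask=mask)
    seg = seg & ~mask.mask  # segmentation never counts background pixels
    measurable = ~mask.mask
    out: list[ExpressionMeasurement] = []
    for region in regions:
        rmask = partition.region_mask(region) if region != "total" else measurable
        rmeasurable = rmask & measurable
        a_tot = int(rmeasurable.sum())
        if a_tot == 0:
            out.append(
                ExpressionMeasurement(
                    a_tot=0, a_exp=0, a_per=float("nan"), threshold_used=thr,
                    eye_id=eye_id, region_label=region, missing=True,
                )
            )
            continue
        area = MeasurableArea(a_tot=a_tot, image_area=int(foreground.size))
        out.append(
            percent_area(
                seg & rmeasurable, area, threshold_used=thr,
                eye_id=eye_id, region_label=region,
            )
        )
    return out
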