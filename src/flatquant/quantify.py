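"""Expression segmentation and the two recombination-efficiency statistics.

Two ways of scoring Cre-reporter recombination on a flatmount:

* percent area, ``A_Per = A_Exp / A_Tot * 100`` — reporter-segmented pixels
  over measurable tissue pixels; the workhorse for adult eyes with
  cytoplasmic reporter signal;
* percent nuclei, ``N_Per = N_Exp / N_Nuc * 100`` — reporter-positive
  nucleus count over total nucleus count; used for fetal-style images where
  the reporter is nuclear-localized. ``N_Per`` may legitimately exceed 100%
  when reporter-positive objects are counted independently of nuclei; such
  values are preserved and flagged, never clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .masking import BackgroundMask, MeasurableArea

logger = logging.getLogger("flatquant")

#: montage panel separation, pixels
MONTAGE_PAD = 8


@dataclass
class ExpressionMeasurement:
    """Per-eye / per-region percent-area record (A_Tot, A_Exp, A_Per)."""

    a_tot: int
    a_exp: int
    a_per: float
    threshold_used: float = 0.0
    eye_id: str = ""
    region_label: str = "total"
    missing: bool = False

    def __post_init__(self) -> None:
        if self.missing:
            return
        if self.a_tot <= 0:
            raise ValueError("no measurable tissue")
        expected = 100.0 * self.a_exp / self.a_tot
        if abs(self.a_per - expected) > 1e-9:
            raise ValueError(f"a_per={self.a_per} inconsistent with counts ({expected})")


@dataclass
class NucleiMeasurement:
    """Per-eye percent-nuclei record (N_Nuc, N_Exp, N_Per)."""

    n_nuc: int
    n_exp: int
    n_per: float
    eye_id: str = ""
    mode: str = "nucleus_anchored"  # or "independent_objects"
    over_100: bool = False

    def __post_init__(self) -> None:
        if self.n_nuc < 0 or self.n_exp < 0:
            raise ValueError("counts must be non-negative")
        expected = 100.0 * self.n_exp / self.n_nuc
        if abs(self.n_per - expected) > 1e-9:
            raise ValueError(f"n_per={self.n_per} inconsistent with counts ({expected})")


@dataclass
class NucleusRecord:
    """One detected nucleus: label, centroid and its pixel set."""

    label: int
    centroid: tuple[float, float]
    pixels: tuple[np.ndarray, np.ndarray]

    @property
    def area(self) -> int:
        return len(self.pixels[0])


def percent_nuclei(n_nuc: int, n_exp: int, *, eye_id: str = "", mode: str = "nucleus_anchored") -> NucleiMeasurement:
    """N_Per = N_Exp / N_Nuc * 100; values over 100% are kept and flagged."""
    if n_nuc == 0:
        raise ValueError("no nuclei detected")
    n_per = 100.0 * n_exp / n_nuc
    return NucleiMeasurement(
        n_nuc=n_nuc, n_exp=n_exp, n_per=n_per, eye_id=eye_id, mode=mode, over_100=n_per > 100.0
    )


def segment_expression(
    foreground: np.ndarray,
    threshold: float | str = "auto",
    mask: "BackgroundMask | np.ndarray | None" = None,
) -> tuple[np.ndarray, float]:
    """Threshold the masked foreground into an expressing-pixel raster.

    A pixel is expressing iff its intensity is strictly above the threshold.
    ``"auto"`` computes Otsu's threshold over the non-background pixels —
    the reproducible stand-in for a manually validated threshold; a fixed
    8-bit value may be passed instead. ``mask`` identifies the background
    pixels to exclude from the Otsu histogram (dark but measurable tissue
    stays in); without it, only zero-valued pixels are excluded. Returns
    the boolean raster and the threshold actually used.
    """
    if threshold == "auto":
        if mask is None:
            tissue_vals = foreground[foreground > 0]
        else:
            bg = mask.mask if isinstance(mask, BackgroundMask) else mask
            tissue_vals = foreground[~bg]
        if tissue_vals.size == 0 or tissue_vals.max() == 0:
            return np.zeros(foreground.shape, dtype=bool), 0.0
        if tissue_vals.min() == tissue_vals.max():
            raise ValueError("degenerate histogram: constant nonzero foreground")
        thr = float(threshold_otsu(tissue_vals))
    else:
        thr = float(threshold)
    return foreground > thr, thr


def percent_area(
    segmentation: np.ndarray,
    area: MeasurableArea,
    *,
    threshold_used: float = 0.0,
    eye_id: str = "",
    region_label: str = "total",
) -> ExpressionMeasurement:
    """A_Per = A_Exp / A_Tot * 100 from a segmentation and the measurable area."""
    if area.a_tot == 0:
        raise ValueError("no measurable tissue")
    a_exp = int(segmentation.sum())
    return ExpressionMeasurement(
        a_tot=area.a_tot,
        a_exp=a_exp,
        a_per=100.0 * a_exp / area.a_tot,
        threshold_used=threshold_used,
        eye_id=eye_id,
        region_label=region_label,
    )


def percent_area_nuclear(
    reporter_segmentation: np.ndarray,
    nuclei_segmentation: np.ndarray,
    *,
    threshold_used: float = 0.0,
    eye_id: str = "",
) -> ExpressionMeasurement:
    """Percent area with nuclear area as the denominator.

    For images where the reporter is nuclear-localized the measurable basis
    is the total nuclear area rather than the tissue area: A_Per = (reporter
    area) / (nuclear area) * 100.
    """
    if reporter_segmentation.shape != nuclei_segmentation.shape:
        raise ValueError("segmentations differ in shape")
    a_tot = int(nuclei_segmentation.sum())
    if a_tot == 0:
        raise ValueError("zero nuclear area")
    a_exp = int(reporter_segmentation.sum())
    return ExpressionMeasurement(
        a_tot=a_tot,
        a_exp=a_exp,
        a_per=100.0 * a_exp / a_tot,
        threshold_used=threshold_used,
        eye_id=eye_id,
        region_label="total",
    )


def detect_nuclei(
    nuclei_channel: np.ndarray,
    mask: BackgroundMask,
    min_area: int = 4,
    min_separation: int = 5,
    *,
    doublet_factor: float = 1.5,
) -> list[NucleusRecord]:
    """Segment and count DAPI nuclei inside the measurable tissue.

    Otsu threshold over tissue pixels, connected-component labelling, and a
    local-maximum-seeded watershed split of components larger than a doublet
    criterion (``doublet_factor`` times the median component area).
    Components smaller than ``min_area`` and nuclei overlapping the
    background mask by more than half are discarded.
    """
    tissue = ~mask.mask
    vals = nuclei_channel[tissue]
    if vals.size == 0 or vals.max() == 0 or vals.min() == vals.max():
        return []
    thr = threshold_otsu(vals)
    binary = (nuclei_channel > thr) & tissue
    if not binary.any():
        return []

    comp, n_comp = ndi.label(binary)
    areas = ndi.sum_labels(binary, comp, index=np.arange(1, n_comp + 1))
    doublet_area = doublet_factor * float(np.median(areas))

    # split only oversized components; well-separated singlets stay intact
    big = np.isin(comp, np.flatnonzero(areas > doublet_area) + 1)
    labels, next_id = ndi.label(binary & ~big)
    if big.any():
        dist = ndi.distance_transform_edt(big)
        peaks = peak_local_max(
            dist, min_distance=min_separation, labels=comp * big, exclude_border=False
        )
        if len(peaks):
            markers = np.zeros_like(comp)
            markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
            split = watershed(-dist, markers, mask=big)
            labels = labels + np.where(split > 0, split + next_id, 0)
            next_id += int(split.max())
        else:  # no usable seeds: keep the oversized components whole
            bl, nb = ndi.label(big)
            labels = labels + np.where(bl > 0, bl + next_id, 0)
            next_id += nb

    records: list[NucleusRecord] = []
    out_label = 0
    for lab, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        rr, cc = np.nonzero(labels[sl] == lab)
        if len(rr) < min_area:
            continue
        rr = rr + sl[0].start
        cc = cc + sl[1].start
        bg_overlap = mask.mask[rr, cc].mean()
        if bg_overlap > 0.5:
            continue
        out_label += 1
        records.append(
            NucleusRecord(
                label=out_label,
                centroid=(float(rr.mean()), float(cc.mean())),
                pixels=(rr, cc),
            )
        )
    logger.info("detected %d nuclei", len(records))
    return records


def classify_nuclei_expression(
    nuclei: list[NucleusRecord],
    reporter: np.ndarray,
    positivity_threshold: float | str = "auto",
    *,
    mask: "BackgroundMask | np.ndarray | None" = None,
    mode: str = "nucleus_anchored",
    min_area: int = 4,
    eye_id: str = "",
) -> NucleiMeasurement:
    """Score each nucleus for reporter expression and form N_Per.

    A nucleus is positive iff the MEAN reporter intensity over its pixel set
    exceeds the threshold (mean, not max: robust to single hot pixels). In
    the default ``nucleus_anchored`` mode N_Exp counts positive nuclei and
    cannot exceed N_Nuc. In ``independent_objects`` mode reporter-positive
    blobs are counted on their own, which can exceed the nucleus count and
    push N_Per over 100% — the measurement keeps such values and raises its
    ``over_100`` flag.
    """
    if not nuclei:
        raise ValueError("no nuclei detected")
    if positivity_threshold == "auto":
        _, thr = segment_expression(reporter, "auto", mask=mask)
    else:
        thr = float(positivity_threshold)

    n_nuc = len(nuclei)
    if mode == "nucleus_anchored":
        n_exp = sum(1 for nuc in nuclei if reporter[nuc.pixels].mean() > thr)
    elif mode == "independent_objects":
        seg = reporter > thr
        labels, n_comp = ndi.label(seg)
        areas = ndi.sum_labels(seg, labels, index=np.arange(1, n_comp + 1))
        n_exp = int((areas >= min_area).sum())
    else:
        raise ValueError(f"unknown counting mode {mode!r}")
    meas = percent_nuclei(n_nuc, n_exp, eye_id=eye_id, mode=mode)
    if meas.over_100:
        logger.warning(
            "N_Per over 100%% (%d reporter objects vs %d nuclei)", n_exp, n_nuc
        )
    return meas


def make_validation_montage(
    raw: np.ndarray,
    processed: np.ndarray,
    area_basis: np.ndarray,
    segmentation: np.ndarray,
    out_path: str | None = None,
    *,
    pad: int = MONTAGE_PAD,
) -> np.ndarray:
    """Assemble the 4-panel human-validation montage.

    Panels (2 x 2): raw | processed / measurable-area mask | segmentation
    overlay. In the overlay, segmented pixels are pure red (255, 0, 0) on a
    grayscale backdrop, so the count of pure-red pixels equals A_Exp
    exactly. Written as PNG when ``out_path`` is given; the montage array is
    returned either way.
    """
    shapes = {raw.shape, processed.shape, area_basis.shape, segmentation.shape}
    if len(shapes) != 1:
        raise ValueError(f"panel geometries differ: {shapes}")
    h, w = raw.shape

    def to_gray8(img: np.ndarray) -> np.ndarray:
        img = img.astype(np.float64)
        top = img.max() or 1.0
        return np.rint(img / top * 255).astype(np.uint8)

    def gray_rgb(g8: np.ndarray) -> np.ndarray:
        return np.stack([g8, g8, g8], axis=-1)

    overlay = gray_rgb(to_gray8(processed))
    # gray pixels have r==g==b, so only segmented pixels can be pure red
    overlay[segmentation] = (255, 0, 0)

    panels = [
        gray_rgb(to_gray8(raw)),
        gray_rgb(to_gray8(processed)),
        gray_rgb((area_basis != 0).astype(np.uint8) * 255),
        overlay,
    ]
    H = 2 * h + 3 * pad
    W = 2 * w + 3 * pad
    montage = np.full((H, W, 3), 32, dtype=np.uint8)
    for k, panel in enumerate(panels):
        r0 = pad + (k // 2) * (h + pad)
        c0 = pad + (k % 2) * (w + pad)
        montage[r0 : r0 + h, c0 : c0 + w] = panel
    if out_path is not None:
        import imageio.v3 as iio

        iio.imwrite(out_path, montage)
    return montage
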