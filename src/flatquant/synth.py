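"""Synthetic flatmount images with known ground truth.

Emulates the features of a flatmounted epithelial monolayer (a butterflied
eyecup) that the quantification pipeline must cope with: a tissue
silhouette with relief cuts, a Voronoi cell mosaic with a known fraction of
reporter-expressing cells (optionally higher centrally than peripherally),
nuclear- or cytoplasm-localized reporter signal, bubble/damage artifacts,
multiplicative vignetting, Poisson-Gaussian camera noise, and 16-bit
quantization. Every run is fully determined by the spec and its seed, and
the returned ground truth (cell labels, expressing flags, nuclei centroids,
artifact mask, true fractions) is exact — so downstream stages can be
validated by parameter recovery without any real microscopy data.

Also provides the hierarchical study-table generator used to calibrate the
statistics stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.draw import disk as draw_disk
from skimage.segmentation import find_boundaries

from .preprocess import FlatmountImage
from .regions import define_central_ellipse, CENTRAL

logger = logging.getLogger("flatquant")

# --- fixed rendering constants (clean-signal amplitudes, 16-bit units) ---
SIGNAL_AMPLITUDE = 20000  # reporter (tdTomato)
NUCLEUS_AMPLITUDE = 24000  # DAPI blob peak
JUNCTION_AMPLITUDE = 12000  # ZO-1 cell-border skeleton
#: the butterfly silhouette removes 4 wedges of this half-angle (degrees)
WEDGE_HALF_ANGLE_DEG = 12.0
#: wedges are cut only beyond this fraction of the radius (keeps the optic
#: nerve region intact, like the uncut center of a real butterflied eyecup)
WEDGE_INNER_FRACTION = 0.2


@dataclass
class FlatmountSpec:
    """Parameters of one synthetic flatmount eye.

    Defaults emulate the study conditions the pipeline targets: a
    butterflied adult eyecup with ~60% of cells recombined, more centrally
    (0.65) than peripherally (0.53), cytoplasmic reporter, a couple of
    bubble artifacts, mild vignetting and realistic camera noise.
    """

    image_height: int = 512
    image_width: int = 512
    silhouette: str = "butterfly4"  # or "ellipse"
    n_cells: int = 600
    cell_diameter_mean: float = 16.0
    cell_diameter_sd: float = 2.0
    expressing_fraction_central: float = 0.65
    expressing_fraction_peripheral: float = 0.53
    reporter_localization: str = "cytoplasmic"  # or "nuclear"
    n_artifacts: int = 2
    artifact_radius_range: tuple[float, float] = (8.0, 20.0)
    noise_gain: float = 0.01  # photons per intensity unit; 0 disables shot noise
    read_noise_sd: float = 100.0  # intensity units; 0 disables read noise
    vignette_strength: float = 0.2
    bit_depth: int = 16
    seed: int = 0

    def validate(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.silhouette not in ("ellipse", "butterfly4"):
            raise ValueError(f"unknown silhouette {self.silhouette!r}")
        for name in ("expressing_fraction_central", "expressing_fraction_peripheral"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.reporter_localization not in ("cytoplasmic", "nuclear"):
            raise ValueError(f"unknown localization {self.reporter_localization!r}")
        if not 0.0 <= self.vignette_strength < 1.0:
            raise ValueError("vignette_strength must be in [0, 1)")
        if self.noise_gain < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.n_artifacts < 0:
            raise ValueError("n_artifacts must be non-negative")
        if self.bit_depth != 16:
            raise ValueError("only 16-bit rendering is supported")

    @property
    def nucleus_sigma(self) -> float:
        """Gaussian blob sigma for one nucleus, tied to the cell size."""
        return self.cell_diameter_mean / 6.0


@dataclass
class GroundTruth:
    """Exact per-pixel and per-cell truth behind one rendered flatmount."""

    tissue_mask: np.ndarray
    cell_label_raster: np.ndarray  # 0 = non-tissue, 1..n_cells
    expressing_flags: np.ndarray  # bool, one per cell
    nuclei_centroids: np.ndarray  # (n_cells, 2) row/col
    artifact_mask: np.ndarray
    true_fraction_overall: float
    true_fraction_central: float
    true_fraction_peripheral: float
    optic_nerve_center: tuple[float, float]

    @property
    def n_cells(self) -> int:
        return len(self.expressing_flags)

    def expressing_pixel_mask(self) -> np.ndarray:
        """Pixels belonging to expressing cells (the area-recovery oracle)."""
        lut = np.zeros(self.n_cells + 1, dtype=bool)
        lut[1:] = self.expressing_flags
        return lut[self.cell_label_raster]


def silhouette_mask(spec: FlatmountSpec) -> np.ndarray:
    """Tissue silhouette: an ellipse, optionally with 4 wedge relief cuts.

    The butterfly4 variant removes 4 symmetric wedges along the diagonals
    (so the orthogonal axes through the optic nerve stay intact), emulating
    a flattened, butterflied eyecup.
    """
    h, w = spec.image_height, spec.image_width
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    semi_v, semi_h = 0.45 * h, 0.45 * w
    rr, cc_grid = np.indices((h, w))
    dy = rr - cr
    dx = cc_grid - cc
    radius2 = (dy / semi_v) ** 2 + (dx / semi_h) ** 2
    mask = radius2 <= 1.0
    if spec.silhouette == "butterfly4":
        angle = np.degrees(np.arctan2(dy, dx))  # [-180, 180]
        half = WEDGE_HALF_ANGLE_DEG
        in_wedge = np.zeros_like(mask)
        for diag in (-135.0, -45.0, 45.0, 135.0):
            delta = np.abs((angle - diag + 180.0) % 360.0 - 180.0)
            in_wedge |= delta <= half
        outer = radius2 > WEDGE_INNER_FRACTION**2
        mask &= ~(in_wedge & outer)
    return mask


def generate_mosaic(spec: FlatmountSpec) -> GroundTruth:
    """Lay down the cell mosaic and decide which cells express the reporter.

    Cell centers are seeded uniformly over the tissue pixels and the tissue
    is tiled by nearest-center (Voronoi) assignment. Each cell is flagged
    expressing with the central probability if its center lies inside the
    central ellipse, else with the peripheral probability.
    """
    spec.validate()
    if spec.n_cells == 0:
        raise ValueError("empty mosaic: n_cells must be positive")
    rng = np.random.default_rng(spec.seed)
    tissue = silhouette_mask(spec)
    tissue_idx = np.flatnonzero(tissue)
    if len(tissue_idx) < 4 * spec.n_cells:
        raise ValueError(
            f"silhouette area {len(tissue_idx)} px too small for {spec.n_cells} cells"
        )

    chosen = rng.choice(tissue_idx, size=spec.n_cells, replace=False)
    centers = np.column_stack(np.unravel_index(chosen, tissue.shape)).astype(float)

    tissue_coords = np.column_stack(np.nonzero(tissue))
    _, nearest = cKDTree(centers).query(tissue_coords, k=1)
    labels = np.zeros(tissue.shape, dtype=np.int32)
    labels[tissue_coords[:, 0], tissue_coords[:, 1]] = nearest + 1

    # the nucleus sits at the centroid of its (Voronoi) cell, not at the
    # random seed: centroids are near-regularly spaced like a real monolayer
    from scipy import ndimage as ndi

    centroids = np.asarray(
        ndi.center_of_mass(tissue, labels, index=np.arange(1, spec.n_cells + 1))
    )

    center = ((spec.image_height - 1) / 2.0, (spec.image_width - 1) / 2.0)
    radial = define_central_ellipse(tissue, center)
    cr_idx = np.clip(np.rint(centroids[:, 0]).astype(int), 0, tissue.shape[0] - 1)
    cc_idx = np.clip(np.rint(centroids[:, 1]).astype(int), 0, tissue.shape[1] - 1)
    cell_central = radial.radial_labels[cr_idx, cc_idx] == CENTRAL
    p = np.where(
        cell_central, spec.expressing_fraction_central, spec.expressing_fraction_peripheral
    )
    flags = rng.random(spec.n_cells) < p

    artifact = np.zeros(tissue.shape, dtype=bool)
    for _ in range(spec.n_artifacts):
        idx = rng.choice(tissue_idx)
        ar, ac = np.unravel_index(idx, tissue.shape)
        radius = rng.uniform(*spec.artifact_radius_range)
        rr, cc = draw_disk((ar, ac), radius, shape=tissue.shape)
        artifact[rr, cc] = True

    def frac(sel: np.ndarray) -> float:
        return float(flags[sel].mean()) if sel.any() else float("nan")

    truth = GroundTruth(
        tissue_mask=tissue,
        cell_label_raster=labels,
        expressing_flags=flags,
        nuclei_centroids=centroids,
        artifact_mask=artifact,
        true_fraction_overall=float(flags.mean()),
        true_fraction_central=frac(cell_central),
        true_fraction_peripheral=frac(~cell_central),
        optic_nerve_center=center,
    )
    logger.info(
        "mosaic: %d cells, %.3f expressing (central %.3f, peripheral %.3f)",
        truth.n_cells, truth.true_fraction_overall,
        truth.true_fraction_central, truth.true_fraction_peripheral,
    )
    return truth


def _blob_field(
    shape: tuple[int, int], centers: np.ndarray, sigma: float, amplitude: float
) -> np.ndarray:
    """Sum of Gaussian blobs with unit-normalized peak = amplitude."""
    field_ = np.zeros(shape, dtype=np.float64)
    if len(centers):
        ri = np.clip(np.rint(centers[:, 0]).astype(int), 0, shape[0] - 1)
        ci = np.clip(np.rint(centers[:, 1]).astype(int), 0, shape[1] - 1)
        np.add.at(field_, (ri, ci), amplitude * 2.0 * np.pi * sigma**2)
        field_ = gaussian_filter(field_, sigma)
    return field_


def render_image(truth: GroundTruth, spec: FlatmountSpec) -> FlatmountImage:
    """Render the 3-channel 16-bit image for a generated mosaic.

    Blue (nuclei): one Gaussian blob per cell at its centroid. Red
    (reporter): the whole cell for cytoplasmic localization, the nucleus
    blob only for nuclear localization, over expressing cells. Green
    (junction): the cell-border skeleton. Half of the artifact discs are
    rendered saturated, half zero-signal. Vignetting is multiplicative;
    noise is Poisson shot noise (disabled when ``noise_gain`` is 0 — the
    infinite-photon limit) plus Gaussian read noise; everything is clipped
    to [0, 65535] and quantized. No signal is rendered outside
    tissue ∪ artifacts.
    """
    spec.validate()
    shape = truth.tissue_mask.shape
    sigma = spec.nucleus_sigma

    nuclei_clean = _blob_field(shape, truth.nuclei_centroids, sigma, NUCLEUS_AMPLITUDE)

    expressing_centers = truth.nuclei_centroids[truth.expressing_flags]
    if spec.reporter_localization == "cytoplasmic":
        reporter_clean = SIGNAL_AMPLITUDE * truth.expressing_pixel_mask().astype(np.float64)
    else:
        reporter_clean = _blob_field(shape, expressing_centers, sigma, SIGNAL_AMPLITUDE)

    borders = find_boundaries(truth.cell_label_raster, mode="inner") & truth.tissue_mask
    junction_clean = JUNCTION_AMPLITUDE * borders.astype(np.float64)

    cr, cc = truth.optic_nerve_center
    rr, cc_grid = np.indices(shape)
    d2 = ((rr - cr) / (shape[0] / 2.0)) ** 2 + ((cc_grid - cc) / (shape[1] / 2.0)) ** 2
    vignette = 1.0 - spec.vignette_strength * np.clip(d2, 0.0, 1.0)

    rng = np.random.default_rng([spec.seed, 1])
    channels: dict[str, np.ndarray] = {}
    for role, clean in (
        ("reporter", reporter_clean),
        ("nuclei", nuclei_clean),
        ("junction", junction_clean),
    ):
        img = clean * vignette
        if spec.noise_gain > 0:
            img = rng.poisson(img * spec.noise_gain) / spec.noise_gain
        if spec.read_noise_sd > 0:
            img = img + rng.normal(0.0, spec.read_noise_sd, size=shape)
        img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
        img[~(truth.tissue_mask | truth.artifact_mask)] = 0
        channels[role] = img

    # artifacts override signal: alternate saturated / zero-signal discs
    art_labels, n_art = _label_artifacts(truth.artifact_mask)
    for k in range(1, n_art + 1):
        sel = art_labels == k
        value = 65535 if k % 2 == 1 else 0
        for ch in channels.values():
            ch[sel] = value

    return FlatmountImage(
        channels=channels,
        bit_depth=16,
        provenance=f"flatquant.synth seed={spec.seed}",
    )


def _label_artifacts(artifact_mask: np.ndarray) -> tuple[np.ndarray, int]:
    from scipy import ndimage as ndi

    return ndi.label(artifact_mask)


def write_flatmount(
    image: FlatmountImage, truth: GroundTruth, outdir: str | Path, stem: str = "eye"
) -> dict[str, str]:
    """Write a rendered eye and its ground-truth bundle to disk.

    Image and label rasters go to 16-bit TIFF, the per-cell table to CSV,
    and scalar truth (fractions, center, seed-free metadata) to JSON.
    """
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack = np.stack(
        [image.channels[r] for r in ("reporter", "nuclei", "junction") if r in image.channels]
    )
    paths = {
        "image": str(outdir / f"{stem}_image.tif"),
        "tissue_mask": str(outdir / f"{stem}_tissue_mask.tif"),
        "cell_labels": str(outdir / f"{stem}_cell_labels.tif"),
        "artifact_mask": str(outdir / f"{stem}_artifact_mask.tif"),
        "exclusions": str(outdir / f"{stem}_exclusions.tif"),
        "cells": str(outdir / f"{stem}_cells.csv"),
        "truth": str(outdir / f"{stem}_truth.json"),
    }
    tifffile.imwrite(paths["image"], stack, photometric="minisblack")
    tifffile.imwrite(paths["tissue_mask"], truth.tissue_mask.astype(np.uint16))
    if truth.cell_label_raster.max() > 65535:
        raise ValueError("too many cells for a 16-bit label raster")
    tifffile.imwrite(paths["cell_labels"], truth.cell_label_raster.astype(np.uint16))
    tifffile.imwrite(paths["artifact_mask"], truth.artifact_mask.astype(np.uint16))
    # ready-made exclusion raster: everything that is not measurable tissue
    tifffile.imwrite(
        paths["exclusions"],
        (~truth.tissue_mask | truth.artifact_mask).astype(np.uint16),
    )
    pd.DataFrame(
        {
            "cell": np.arange(1, truth.n_cells + 1),
            "row": truth.nuclei_centroids[:, 0],
            "col": truth.nuclei_centroids[:, 1],
            "expressing": truth.expressing_flags,
        }
    ).to_csv(paths["cells"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "true_fraction_overall": truth.true_fraction_overall,
                "true_fraction_central": truth.true_fraction_central,
                "true_fraction_peripheral": truth.true_fraction_peripheral,
                "optic_nerve_center": list(truth.optic_nerve_center),
                "n_cells": truth.n_cells,
            },
            fh,
            indent=2,
        )
    return paths


# ---------------------------------------------------------------------------
# hierarchical study generator (for the statistics stage)
# ---------------------------------------------------------------------------

STUDY_REGIONS = ("dorsal", "ventral", "nasal", "temporal", "central", "peripheral")


@dataclass
class StudyDesign:
    """Design of a synthetic multi-group study of per-eye percent values.

    Values are drawn hierarchically: group mean + mouse-level normal
    deviate + eye-level normal deviate, truncated to [0, 100]. Eyes are
    dropped independently with ``missing_eye_probability`` (the unbalanced
    design the mixed model must tolerate). Regional rows share their eye's
    deviates plus an optional region-level deviate (``region_sd``).
    """

    group_mean_percents: tuple[float, ...] = (50.0, 70.0)
    between_mouse_sd: float = 5.0
    between_eye_sd: float = 3.0
    mice_per_group: int = 10
    missing_eye_probability: float = 0.1
    region_sd: float = 0.0
    group_labels: tuple[str, ...] | None = None
    seed: int = 0

    @property
    def n_groups(self) -> int:
        return len(self.group_mean_percents)


def generate_study(design: StudyDesign) -> pd.DataFrame:
    """Draw a long-format study table (mouse, eye, region rows) from a design."""
    if design.mice_per_group < 2:
        raise ValueError("degenerate design: need at least 2 mice per group")
    for m in design.group_mean_percents:
        if not 0.0 <= m <= 100.0:
            raise ValueError(f"group mean {m} outside [0, 100]")
    if design.between_mouse_sd < 0 or design.between_eye_sd < 0 or design.region_sd < 0:
        raise ValueError("SDs must be non-negative")
    if not 0.0 <= design.missing_eye_probability < 1.0:
        raise ValueError("missing_eye_probability must be in [0, 1)")
    labels = design.group_labels or tuple(
        f"group{i + 1}" for i in range(design.n_groups)
    )
    if len(labels) != design.n_groups:
        raise ValueError("group_labels length must match group_mean_percents")

    rng = np.random.default_rng(design.seed)
    rows = []
    for g, (label, mean) in enumerate(zip(labels, design.group_mean_percents)):
        for m in range(design.mice_per_group):
            mouse_id = f"g{g + 1}m{m + 1}"
            sex = "F" if rng.random() < 0.5 else "M"
            route = "IP" if rng.random() < 0.5 else "OG"
            mouse_dev = rng.normal(0.0, design.between_mouse_sd) if design.between_mouse_sd else 0.0
            for eye in ("OD", "OS"):
                eye_dev = rng.normal(0.0, design.between_eye_sd) if design.between_eye_sd else 0.0
                dropped = rng.random() < design.missing_eye_probability
                region_devs = (
                    rng.normal(0.0, design.region_sd, size=len(STUDY_REGIONS))
                    if design.region_sd
                    else np.zeros(len(STUDY_REGIONS))
                )
                if dropped:
                    continue
                base = mean + mouse_dev + eye_dev
                eye_id = f"{mouse_id}-{eye}"
                rows.append(
                    dict(
                        mouse_id=mouse_id, eye_id=eye_id, eye=eye, sex=sex,
                        route=route, group=label, region_label="total",
                        percent=float(np.clip(base, 0.0, 100.0)),
                    )
                )
                for region, rdev in zip(STUDY_REGIONS, region_devs):
                    rows.append(
                        dict(
                            mouse_id=mouse_id, eye_id=eye_id, eye=eye, sex=sex,
                            route=route, group=label, region_label=region,
                            percent=float(np.clip(base + rdev, 0.0, 100.0)),
                        )
                    )
    return pd.DataFrame(rows)
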