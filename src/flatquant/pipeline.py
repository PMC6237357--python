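"""End-to-end wiring: config, per-eye analysis, study runs, reports.

One eye travels: QC gate on the original reporter channel -> per-channel
preprocessing (optional background subtraction, 99%-coverage rescale,
16->8-bit) -> background-mask accounting -> expression segmentation and
percent-area (plus percent-nuclei when a nuclei channel is present) ->
regional partition and per-region measurements -> one block of rows in the
study table. A study run then feeds the table to the mixed-model stage and
writes CSVs, montages and a machine-readable manifest. Eyes failing QC are
excluded from analysis (and from the table) but logged; a failure in one
eye never aborts the others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import masking, preprocess, quantify, regions, stats
from .preprocess import FlatmountImage

logger = logging.getLogger("flatquant")


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults are the documented constants.

    ``background_radius`` None means 1/20 of the smaller image dimension.
    ``threshold`` is "auto" (Otsu over non-background pixels) or a fixed
    8-bit value — the reproducible counterpart of a manually validated
    threshold, with the montage as the validation surface.
    """

    channel_map: dict[int, str] = field(
        default_factory=lambda: {0: "reporter", 1: "nuclei", 2: "junction"}
    )
    background_subtraction: bool = True
    background_radius: int | None = None
    rescale_coverage: float = preprocess.DEFAULT_RESCALE_COVERAGE
    qc_min_fraction: float = preprocess.QC_MIN_DYNAMIC_RANGE_FRACTION
    threshold: float | str = "auto"
    nuclei_min_area: int = 4
    nuclei_min_separation: int = 5
    region_mode: str = "computed"  # or "user_masks"
    seed: int = 0
    output_dir: str = "flatquant_out"


def validate_config(config: RunConfig) -> list[str]:
    """Return every out-of-range field at once (empty list = valid)."""
    v: list[str] = []
    roles = list(config.channel_map.values())
    if "reporter" not in roles:
        v.append("channel_map must assign the reporter channel")
    if len(roles) != len(set(roles)):
        v.append("channel_map assigns a role twice")
    if not 0.0 < config.rescale_coverage <= 1.0:
        v.append(f"rescale_coverage={config.rescale_coverage} outside (0, 1]")
    if not 0.0 <= config.qc_min_fraction <= 1.0:
        v.append(f"qc_min_fraction={config.qc_min_fraction} outside [0, 1]")
    if config.threshold != "auto":
        try:
            t = float(config.threshold)
            if not 0 <= t <= 255:
                v.append(f"threshold={config.threshold} outside [0, 255]")
        except (TypeError, ValueError):
            v.append(f"threshold={config.threshold!r} is neither 'auto' nor a number")
    if config.background_radius is not None and config.background_radius <= 0:
        v.append("background_radius must be positive")
    if config.nuclei_min_area < 1:
        v.append("nuclei_min_area must be >= 1")
    if config.nuclei_min_separation < 1:
        v.append("nuclei_min_separation must be >= 1")
    if config.region_mode not in ("computed", "user_masks"):
        v.append(f"unknown region_mode {config.region_mode!r}")
    return v


@dataclass
class EyeInput:
    """One eye: its image, exclusions, anatomy metadata and identifiers."""

    image: FlatmountImage
    eye_id: str
    mouse_id: str
    group: str
    eye: str = "OD"  # laterality, OD/OS
    sex: str = ""
    route: str = ""
    optic_nerve_center: tuple[float, float] | None = None
    exclusion_regions: tuple = ()  # rasters or polygons, see masking
    region_masks: dict[str, np.ndarray] | None = None  # user override


@dataclass
class EyeResult:
    """Everything measured on one eye, or the reason it was excluded."""

    eye_id: str
    qc: preprocess.QCReport
    measurements: list[quantify.ExpressionMeasurement] = field(default_factory=list)
    nuclei_measurement: quantify.NucleiMeasurement | None = None
    error: str | None = None

    @property
    def included(self) -> bool:
        return self.qc.passed and self.error is None


def preprocess_channels(
    image: FlatmountImage, config: RunConfig
) -> dict[str, np.ndarray]:
    """Background-subtract, rescale and convert each channel to 8-bit."""
    out: dict[str, np.ndarray] = {}
    for role, channel in image.channels.items():
        work = channel
        if config.background_subtraction:
            radius = config.background_radius or max(1, min(channel.shape) // 20)
            work = preprocess.subtract_background(work, radius)
        work = preprocess.rescale_to_dynamic_range(
            work, coverage=config.rescale_coverage, bit_depth=16
        )
        out[role] = preprocess.convert_to_8bit(work)
    return out


def analyze_eye(
    inp: EyeInput,
    config: RunConfig,
    *,
    montage_path: str | None = None,
) -> EyeResult:
    """Run the full quantification on one eye.

    QC is computed on the ORIGINAL reporter channel and gates the whole
    image. The measurable-area bookkeeping, segmentation, Eq-style percent
    statistics and the regional breakdown all run on the preprocessed 8-bit
    channels.
    """
    image = inp.image
    qc = preprocess.qc_dynamic_range(
        image.channels["reporter"], image.bit_depth, min_fraction=config.qc_min_fraction
    )
    if not qc.passed:
        logger.info("eye %s excluded by QC: %s", inp.eye_id, qc.reason)
        return EyeResult(eye_id=inp.eye_id, qc=qc)

    channels8 = preprocess_channels(image, config)
    reporter8 = channels8["reporter"]

    bg_image = masking.build_background_image(reporter8, inp.exclusion_regions)
    mask = masking.build_background_mask(
        bg_image, source="provided_raster" if inp.exclusion_regions else "manual_rois"
    )
    foreground, area = masking.apply_mask_to_foreground(reporter8, mask)
    if area.a_tot == 0:
        return EyeResult(eye_id=inp.eye_id, qc=qc, error="no measurable tissue")

    tissue = ~mask.mask
    center = inp.optic_nerve_center
    if center is None:
        rr, cc = np.nonzero(tissue)
        center = (float(rr.mean()), float(cc.mean()))

    measurements: list[quantify.ExpressionMeasurement]
    if inp.region_masks is not None and config.region_mode == "user_masks":
        seg, thr = quantify.segment_expression(foreground, config.threshold, mask=mask)
        seg &= tissue
        measurements = [
            quantify.percent_area(
                seg & tissue, area, threshold_used=thr, eye_id=inp.eye_id
            )
        ]
        for label, rmask in inp.region_masks.items():
            rmeasurable = rmask & tissue
            a_tot = int(rmeasurable.sum())
            if a_tot == 0:
                continue
            measurements.append(
                quantify.percent_area(
                    seg & rmeasurable,
                    masking.MeasurableArea(a_tot=a_tot, image_area=int(tissue.size)),
                    threshold_used=thr,
                    eye_id=inp.eye_id,
                    region_label=label,
                )
            )
    else:
        partition = regions.partition_flatmount(tissue, center, eye=inp.eye)
        measurements = regions.regional_measurements(
            foreground, mask, partition, config.threshold, eye_id=inp.eye_id
        )

    nuclei_meas = None
    if "nuclei" in channels8:
        nuclei = quantify.detect_nuclei(
            channels8["nuclei"],
            mask,
            min_area=config.nuclei_min_area,
            min_separation=config.nuclei_min_separation,
        )
        if nuclei:
            nuclei_meas = quantify.classify_nuclei_expression(
                nuclei, foreground, config.threshold, mask=mask, eye_id=inp.eye_id
            )

    if montage_path is not None:
        total = next(m for m in measurements if m.region_label == "total")
        seg, _ = quantify.segment_expression(foreground, total.threshold_used, mask=mask)
        seg &= tissue
        quantify.make_validation_montage(
            image.channels["reporter"], foreground, tissue, seg, montage_path
        )

    logger.info(
        "eye %s: a_tot=%d, total A_Per=%.2f%%, %s nuclei",
        inp.eye_id,
        area.a_tot,
        next(m.a_per for m in measurements if m.region_label == "total"),
        nuclei_meas.n_nuc if nuclei_meas else "no",
    )
    return EyeResult(
        eye_id=inp.eye_id, qc=qc, measurements=measurements, nuclei_measurement=nuclei_meas
    )


def results_to_table(eyes: list[EyeInput], results: list[EyeResult]) -> pd.DataFrame:
    """Long-format study table from per-eye results; QC failures contribute nothing."""
    meta = {e.eye_id: e for e in eyes}
    rows = []
    for res in results:
        if not res.included:
            continue
        e = meta[res.eye_id]
        for m in res.measurements:
            if m.missing:
                continue
            rows.append(
                dict(
                    mouse_id=e.mouse_id, eye_id=e.eye_id, eye=e.eye, sex=e.sex,
                    route=e.route, group=e.group, region_label=m.region_label,
                    percent=m.a_per, a_tot=m.a_tot, a_exp=m.a_exp,
                    threshold_used=m.threshold_used,
                    n_nuc=res.nuclei_measurement.n_nuc if res.nuclei_measurement else np.nan,
                    n_exp=res.nuclei_measurement.n_exp if res.nuclei_measurement else np.nan,
                    n_per=res.nuclei_measurement.n_per if res.nuclei_measurement else np.nan,
                    qc_passed=True,
                )
            )
    columns = [
        "mouse_id", "eye_id", "eye", "sex", "route", "group", "region_label",
        "percent", "a_tot", "a_exp", "threshold_used", "n_nuc", "n_exp", "n_per",
        "qc_passed",
    ]
    return pd.DataFrame(rows, columns=columns)


@dataclass
class RunResults:
    """Bundle a study run hands back (and writes to the output directory)."""

    study_table: pd.DataFrame
    eye_results: list[EyeResult]
    comparisons: list[stats.ComparisonResult] | None
    lme: stats.LMEFit | None
    ks: stats.KSResult | None
    summary: stats.GroupSummary | None
    stats_message: str = ""


def run_pipeline(
    config: RunConfig,
    eyes: list[EyeInput],
    *,
    write_outputs: bool = True,
    write_montages: bool = False,
) -> RunResults:
    """Quantify every eye, assemble the study table and run the statistics.

    Per-eye fault isolation: an error on one eye is recorded in its result
    and the run continues. The statistics stage runs only when at least two
    groups with at least two measured mice each survive QC; otherwise it is
    skipped with an explicit message. Outputs (CSVs, model report, manifest)
    land in ``config.output_dir``.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    outdir = Path(config.output_dir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    results: list[EyeResult] = []
    for inp in eyes:
        montage = (
            str(outdir / f"montage_{inp.eye_id}.png")
            if (write_outputs and write_montages)
            else None
        )
        try:
            results.append(analyze_eye(inp, config, montage_path=montage))
        except Exception as exc:  # fault isolation: record and continue
            logger.error("eye %s failed: %s", inp.eye_id, exc)
            results.append(
                EyeResult(
                    eye_id=inp.eye_id,
                    qc=preprocess.QCReport("reporter", float("nan"), False, "stage error"),
                    error=str(exc),
                )
            )

    table = results_to_table(eyes, results)

    comparisons = lme = ks = summary = None
    message = ""
    if table.empty:
        message = "statistics skipped: no eyes passed QC"
        logger.warning(message)
    else:
        summary = stats.group_summary(table)
        try:
            lme = stats.fit_lme(table, "group", region="total")
            comparisons = stats.tukey_posttest(lme)
            ks = stats.ks_normality(lme.residuals)
        except (ValueError, RuntimeError) as exc:
            message = f"statistics skipped: {exc}"
            logger.warning(message)

    run = RunResults(
        study_table=table,
        eye_results=results,
        comparisons=comparisons,
        lme=lme,
        ks=ks,
        summary=summary,
        stats_message=message,
    )
    if write_outputs:
        _write_outputs(run, config, outdir)
    return run


def _write_outputs(run: RunResults, config: RunConfig, outdir: Path) -> None:
    run.study_table.to_csv(outdir / "study_table.csv", index=False)
    qc_rows = [
        dict(
            eye_id=r.eye_id,
            dynamic_range_fraction=r.qc.dynamic_range_fraction,
            qc_passed=r.qc.passed,
            reason=r.qc.reason,
            error=r.error or "",
        )
        for r in run.eye_results
    ]
    pd.DataFrame(qc_rows).to_csv(outdir / "qc_report.csv", index=False)
    if run.comparisons is not None:
        pd.DataFrame([dataclasses.asdict(c) for c in run.comparisons]).to_csv(
            outdir / "comparisons.csv", index=False
        )
        with open(outdir / "model_report.txt", "w") as fh:
            fh.write(str(run.lme.result.summary()))
            if run.ks is not None:
                fh.write(
                    f"\nKS normality of residuals: D={run.ks.statistic:.4f}, "
                    f"p={run.ks.pvalue:.4f} (normal parameters estimated from sample)\n"
                )
    if run.summary is not None:
        run.summary.table.to_csv(outdir / "group_summary.csv", index=False)
    manifest = {
        "config": {
            k: (v if not isinstance(v, dict) else {str(i): r for i, r in v.items()})
            for k, v in dataclasses.asdict(config).items()
        },
        "n_eyes": len(run.eye_results),
        "n_included": sum(r.included for r in run.eye_results),
        "stats_message": run.stats_message,
        "versions": _versions(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _versions() -> dict[str, str]:
    import numpy, pandas, scipy, skimage, statsmodels

    from . import __version__

    return {
        "flatquant": __version__,
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
        "statsmodels": statsmodels.__version__,
    }
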