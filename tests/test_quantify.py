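import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import flatquant as fq
from flatquant.synth import SIGNAL_AMPLITUDE

from conftest import SYNTH_CONFIG, eye_input, make_spec, noiseless, oracle_area_share


def measurable(truth):
    return fq.build_background_mask(
        np.where(truth.tissue_mask & ~truth.artifact_mask, 1, 0).astype(np.uint8),
        source="synthetic_truth",
    )


class TestSegmentExpression:
    def test_threshold_zero_catches_any_positive_pixel(self):
        fg = np.zeros((8, 8), dtype=np.uint8)
        fg[3, 3] = 1
        seg, thr = fq.segment_expression(fg, 0)
        assert seg.sum() == 1 and seg[3, 3] and thr == 0

    def test_threshold_255_is_empty(self):
        fg = np.full((8, 8), 255, dtype=np.uint8)
        seg, _ = fq.segment_expression(fg, 255)
        assert not seg.any()

    def test_all_zero_foreground_not_an_error(self):
        seg, thr = fq.segment_expression(np.zeros((8, 8), dtype=np.uint8), "auto")
        assert not seg.any()

    def test_constant_nonzero_auto_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fq.segment_expression(np.full((8, 8), 9, dtype=np.uint8), "auto")

    def test_noiseless_half_amplitude_recovers_truth_exactly(self, noiseless_eye):
        _, truth, image = noiseless_eye
        seg, _ = fq.segment_expression(
            image.channels["reporter"], SIGNAL_AMPLITUDE / 2
        )
        np.testing.assert_array_equal(seg, truth.expressing_pixel_mask())

    def test_lowering_threshold_never_shrinks_segmentation(self):
        fg = np.random.default_rng(0).integers(0, 255, (64, 64)).astype(np.uint8)
        areas = [fq.segment_expression(fg, t)[0].sum() for t in (200, 150, 100, 50, 0)]
        assert (np.diff(areas) >= 0).all()


class TestPercentArea:
    def test_simple_ratio(self):
        seg = np.zeros((10, 10), dtype=bool)
        seg.ravel()[:50] = True
        m = fq.percent_area(seg, fq.MeasurableArea(a_tot=100, image_area=100))
        assert m.a_per == 50.0

    def test_empty_segmentation_is_zero_percent(self):
        m = fq.percent_area(
            np.zeros((10, 10), dtype=bool), fq.MeasurableArea(a_tot=80, image_area=100)
        )
        assert m.a_per == 0.0

    def test_no_measurable_tissue_rejected(self):
        with pytest.raises(ValueError, match="no measurable tissue"):
            fq.percent_area(
                np.zeros((4, 4), dtype=bool), fq.MeasurableArea(a_tot=0, image_area=16)
            )

    def test_ratio_exact_to_machine_precision(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a_tot = int(rng.integers(1, 10_000))
            a_exp = int(rng.integers(0, a_tot + 1))
            m = fq.ExpressionMeasurement(a_tot=a_tot, a_exp=a_exp, a_per=100.0 * a_exp / a_tot)
            assert abs(m.a_per * m.a_tot - 100.0 * m.a_exp) < 1e-9 * max(1, m.a_tot)

    def test_cytoplasmic_recovery_within_5_points(self, default_eye):
        _, truth, image = default_eye
        res = fq.analyze_eye(eye_input(truth, image), SYNTH_CONFIG)
        total = next(m for m in res.measurements if m.region_label == "total")
        assert abs(total.a_per - oracle_area_share(truth)) <= 5.0


class TestDetectNuclei:
    def test_blank_channel_gives_no_nuclei(self):
        mask = fq.build_background_mask(np.ones((32, 32), dtype=np.uint8))
        assert fq.detect_nuclei(np.zeros((32, 32), dtype=np.uint8), mask) == []

    def test_well_separated_blobs_counted_exactly(self):
        # 7x7 grid of identical blobs on a blank field
        shape = (160, 160)
        img = np.zeros(shape)
        centers = [(20 + 20 * i, 20 + 20 * j) for i in range(7) for j in range(7)]
        for r, c in centers:
            img[r, c] = 200 * 2 * np.pi * 2.5**2
        img = gaussian_filter(img, 2.5)
        img8 = np.clip(img, 0, 255).astype(np.uint8)
        mask = fq.build_background_mask(np.ones(shape, dtype=np.uint8))
        nuclei = fq.detect_nuclei(img8, mask)
        assert len(nuclei) == 49
        found = np.array([n.centroid for n in nuclei])
        for r, c in centers:
            assert np.min(np.hypot(found[:, 0] - r, found[:, 1] - c)) <= 2.5

    def test_recall_precision_on_default_noise_render(self, nuclear_eye):
        spec, truth, image = nuclear_eye
        nuclei8 = fq.convert_to_8bit(
            fq.rescale_to_dynamic_range(image.channels["nuclei"])
        )
        nuclei = fq.detect_nuclei(nuclei8, measurable(truth))
        found = np.array([n.centroid for n in nuclei])
        tol = 2.0 * spec.nucleus_sigma
        d = np.hypot(
            truth.nuclei_centroids[:, None, 0] - found[None, :, 0],
            truth.nuclei_centroids[:, None, 1] - found[None, :, 1],
        )
        # greedy one-to-one matching by distance
        matched_true, matched_found = set(), set()
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
        for ti, fi in order:
            if d[ti, fi] > tol:
                break
            if ti not in matched_true and fi not in matched_found:
                matched_true.add(int(ti))
                matched_found.add(int(fi))
        # nuclei under excluded regions (artifacts, off-tissue) are
        # unmeasurable by construction and do not count against recall
        excluded = ~truth.tissue_mask | truth.artifact_mask
        centroid_px = np.rint(truth.nuclei_centroids).astype(int)
        detectable = [
            i for i in range(truth.n_cells) if not excluded[tuple(centroid_px[i])]
        ]
        recall = sum(i in matched_true for i in detectable) / len(detectable)
        precision = len(matched_found) / len(found)
        assert recall >= 0.95
        assert precision >= 0.95


class TestClassifyNuclei:
    def test_worked_example_ratio(self):
        m = fq.percent_nuclei(235, 183)
        assert round(m.n_per, 2) == 77.87
        assert not m.over_100

    def test_zero_reporter_means_zero_percent(self):
        nuc = [fq.NucleusRecord(1, (2.0, 2.0), (np.array([2]), np.array([2])))]
        m = fq.classify_nuclei_expression(nuc, np.zeros((5, 5), dtype=np.uint8), 10)
        assert m.n_per == 0.0

    def test_no_nuclei_rejected(self):
        with pytest.raises(ValueError, match="no nuclei"):
            fq.classify_nuclei_expression([], np.zeros((5, 5), dtype=np.uint8), 10)

    def test_nuclear_render_recovery_within_3_points(self, nuclear_eye):
        _, truth, image = nuclear_eye
        res = fq.analyze_eye(eye_input(truth, image), SYNTH_CONFIG)
        nm = res.nuclei_measurement
        assert nm is not None
        assert abs(nm.n_per / 100 - truth.true_fraction_overall) <= 0.03

    def test_independent_object_mode_can_exceed_100_and_is_preserved(self):
        # 2 nuclei but 3 reporter blobs: the independent count goes over 100%
        shape = (40, 40)
        reporter = np.zeros(shape, dtype=np.uint8)
        for r, c in ((10, 10), (10, 30), (30, 10)):
            reporter[r - 2 : r + 3, c - 2 : c + 3] = 200
        nuclei = [
            fq.NucleusRecord(1, (10.0, 10.0), tuple(np.nonzero(reporter[:20, :20]))),
            fq.NucleusRecord(2, (10.0, 30.0), (np.array([10]), np.array([30]))),
        ]
        m = fq.classify_nuclei_expression(
            nuclei, reporter, 100, mode="independent_objects"
        )
        assert m.n_per == 150.0
        assert m.over_100
        anchored = fq.classify_nuclei_expression(nuclei, reporter, 100)
        assert anchored.n_per <= 100.0


class TestPercentAreaNuclear:
    def test_half_coverage(self):
        nuc = np.zeros((10, 10), dtype=bool)
        nuc[:4] = True
        rep = nuc.copy()
        rep[2:4] = False
        m = fq.percent_area_nuclear(rep, nuc)
        assert m.a_per == 50.0

    def test_full_coverage(self):
        nuc = np.zeros((10, 10), dtype=bool)
        nuc[3:7, 3:7] = True
        assert fq.percent_area_nuclear(nuc, nuc).a_per == 100.0

    def test_zero_nuclear_area_rejected(self):
        with pytest.raises(ValueError, match="zero nuclear"):
            fq.percent_area_nuclear(
                np.zeros((5, 5), dtype=bool), np.zeros((5, 5), dtype=bool)
            )

    def test_area_and_count_methods_agree_on_nuclear_render(self, nuclear_eye):
        """The two fetal-eye quantification routes give concordant percents."""
        _, truth, image = nuclear_eye
        rep8 = fq.convert_to_8bit(fq.rescale_to_dynamic_range(image.channels["reporter"]))
        nuc8 = fq.convert_to_8bit(fq.rescale_to_dynamic_range(image.channels["nuclei"]))
        mask = measurable(truth)
        rep_fg, _ = fq.apply_mask_to_foreground(rep8, mask)
        nuc_fg, _ = fq.apply_mask_to_foreground(nuc8, mask)
        rep_seg, thr = fq.segment_expression(rep_fg, "auto", mask=mask)
        nuc_seg, _ = fq.segment_expression(nuc_fg, "auto", mask=mask)
        area_method = fq.percent_area_nuclear(rep_seg, nuc_seg).a_per
        nuclei = fq.detect_nuclei(nuc_fg, mask)
        count_method = fq.classify_nuclei_expression(nuclei, rep_fg, thr).n_per
        assert abs(area_method - count_method) <= 3.0


class TestMontage:
    def test_montage_geometry_and_exact_overlay_count(self, tmp_path, noiseless_eye):
        _, truth, image = noiseless_eye
        reporter = image.channels["reporter"]
        seg, _ = fq.segment_expression(reporter, SIGNAL_AMPLITUDE / 2)
        out = tmp_path / "montage.png"
        montage = fq.make_validation_montage(
            reporter, reporter, truth.tissue_mask, seg, str(out)
        )
        h, w = reporter.shape
        assert out.exists()
        assert montage.shape == (2 * h + 3 * 8, 2 * w + 3 * 8, 3)
        pure_red = (
            (montage[..., 0] == 255) & (montage[..., 1] == 0) & (montage[..., 2] == 0)
        )
        assert pure_red.sum() == seg.sum()
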