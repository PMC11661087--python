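import numpy as np
import pytest

from axoncaliber.linescan import (
    CaliberMeasurement,
    CenterlineAnnotation,
    FlatProfileError,
    ImageFrame,
    LineScanProfile,
    MeasurementConfig,
    MeasurementSet,
    ScanOutOfBoundsError,
    apply_exclusion_rules,
    centerline_from_truth,
    extract_profile,
    measure_along_segment,
    measure_caliber,
)
from axoncaliber.synthetic import (
    SceneConfig,
    analytic_linescan_profile,
    make_branched_truth,
    make_straight_tube_truth,
    render_membrane_frame,
)


def _profile_from_analytic(diameter, sigma, half=0.8, step=0.005):
    n = int(round(half / step))
    offsets = np.arange(-n, n + 1) * step
    vals = analytic_linescan_profile(diameter, sigma, offsets)
    return LineScanProfile(
        center=np.zeros(2), direction=np.array([0.0, 1.0]), offsets=offsets, intensities=vals
    )


class TestExtractProfile:
    def test_constant_image_gives_constant_profile(self):
        frame = ImageFrame(np.full((50, 50), 7.0), pixel_size=0.1)
        prof = extract_profile(
            frame, center=(2.5, 2.5), normal=(0, 1),
            config=MeasurementConfig(scan_half_length=1.0, smoothing_sd=0.0),
        )
        assert np.allclose(prof.intensities, 7.0)

    def test_pixel_center_scan_reproduces_pixel_values(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(40, 40))
        px = 0.05
        frame = ImageFrame(img, pixel_size=px)
        cfg = MeasurementConfig(scan_half_length=5 * px, scan_step=px, smoothing_sd=0.0)
        prof = extract_profile(frame, center=(20 * px, 20 * px), normal=(0, 1), config=cfg)
        expect = img[15:26, 20]
        assert np.allclose(prof.intensities, expect, atol=1e-12)

    def test_scan_through_rendered_tube_matches_analytic_oracle(self):
        scene = SceneConfig(background=0.0, read_noise_sd=0.0)
        truth = make_straight_tube_truth(diameter=0.6, config=scene, length=10.0)
        frame = ImageFrame(render_membrane_frame(truth, scene), pixel_size=scene.pixel_size)
        center = truth.segments[0][len(truth.segments[0]) // 2]
        cfg = MeasurementConfig(scan_half_length=1.0, smoothing_sd=0.0)
        prof = extract_profile(frame, center, (0, 1), cfg)
        rendered = prof.intensities / prof.intensities.max()
        oracle = analytic_linescan_profile(0.6, scene.psf_sigma, prof.offsets)
        rms = np.sqrt(np.mean((rendered - oracle) ** 2))
        assert rms < 0.02

    def test_scan_exiting_image_lists_offsets(self):
        frame = ImageFrame(np.zeros((20, 20)), pixel_size=0.1)
        with pytest.raises(ScanOutOfBoundsError, match="offsets"):
            extract_profile(
                frame, center=(1.0, 0.1), normal=(0, 1),
                config=MeasurementConfig(scan_half_length=1.5),
            )


class TestMeasureCaliber:
    def test_two_sharp_peaks_distance(self):
        offsets = np.linspace(-0.75, 0.75, 61)  # step 0.025, peaks land on samples
        vals = np.zeros_like(offsets)
        vals[np.isclose(offsets, -0.25)] = 1.0
        vals[np.isclose(offsets, 0.25)] = 1.0
        prof = LineScanProfile(np.zeros(2), np.array([0.0, 1.0]), offsets, vals)
        m = measure_caliber(prof, MeasurementConfig(subpixel=False))
        assert m.caliber == pytest.approx(0.50, abs=1e-9)

    def test_analytic_profile_recovers_diameter(self):
        prof = _profile_from_analytic(0.6, 0.06)
        m = measure_caliber(prof, MeasurementConfig())
        assert m.caliber == pytest.approx(0.600, abs=0.005)
        assert not m.single_peak and not m.below_resolution

    def test_merged_peaks_flagged_single_peak(self):
        prof = _profile_from_analytic(0.10, 0.0595)
        m = measure_caliber(prof, MeasurementConfig())
        assert m.single_peak
        assert m.caliber is None

    def test_flat_profile_is_an_error(self):
        offsets = np.linspace(-1, 1, 21)
        prof = LineScanProfile(np.zeros(2), np.array([0.0, 1.0]), offsets, np.ones(21))
        with pytest.raises(FlatProfileError):
            measure_caliber(prof)

    def test_nearest_peaks_chosen_over_global_maxima(self):
        # a brighter neighboring structure farther out must not hijack the pair
        offsets = np.linspace(-1.5, 1.5, 301)
        sigma = 0.05
        vals = (
            np.exp(-((offsets - 0.3) ** 2) / (2 * sigma**2))
            + np.exp(-((offsets + 0.3) ** 2) / (2 * sigma**2))
            + 1.05 * np.exp(-((offsets - 1.2) ** 2) / (2 * sigma**2))
        )
        prof = LineScanProfile(np.zeros(2), np.array([0.0, 1.0]), offsets, vals)
        m = measure_caliber(prof, MeasurementConfig())
        assert m.caliber == pytest.approx(0.6, abs=0.01)
        # the same-side candidate within 10% height makes the pick ambiguous
        assert m.ambiguous_peaks

    def test_rotation_leaves_caliber_invariant(self, measure_tube):
        base = [m.caliber for m in measure_tube(0.6, positions=np.arange(2.0, 8.5))]
        rot = [
            m.caliber
            for m in measure_tube(0.6, angle_deg=30.0, positions=np.arange(2.0, 8.5))
        ]
        assert abs(np.mean(base) - np.mean(rot)) < 0.04  # one pixel


class TestMeasureAlongSegment:
    def test_noiseless_tube_recovery_at_one_micron_increments(self, measure_tube):
        ms = measure_tube(0.6, positions=np.arange(0.0, 10.5))
        assert len(ms) == 11
        for m in ms:
            assert m.caliber == pytest.approx(0.60, abs=0.01)

    def test_positions_near_branch_point_dropped(self):
        scene = SceneConfig(image_shape=(300, 420), seed=0)
        truth = make_branched_truth(scene)
        frame = ImageFrame(render_membrane_frame(truth, scene), pixel_size=scene.pixel_size)
        cl = centerline_from_truth(truth)
        # child segment 1 starts at the branch point: 1 and 2 um excluded
        ms = measure_along_segment(frame, cl, 1, [1.0, 2.0, 3.0, 4.0], MeasurementConfig())
        assert [m.arc_pos for m in ms] == [3.0, 4.0]

    def test_empty_retained_set_is_not_an_error(self):
        scene = SceneConfig(image_shape=(300, 420), seed=0)
        truth = make_branched_truth(scene)
        frame = ImageFrame(render_membrane_frame(truth, scene), pixel_size=scene.pixel_size)
        cl = centerline_from_truth(truth)
        ms = measure_along_segment(frame, cl, 1, [1.0, 2.0], MeasurementConfig())
        assert ms == []


class TestBranchedRecovery:
    def test_branched_scene_segment_calibers(self):
        scene = SceneConfig(image_shape=(300, 420), seed=0)
        truth = make_branched_truth(
            scene, primary_diameter=0.6, s1_diameter=0.44, s2_diameter=0.32
        )
        frame = ImageFrame(render_membrane_frame(truth, scene), pixel_size=scene.pixel_size)
        cl = centerline_from_truth(truth)
        cfg = MeasurementConfig()
        for sid, true_d, positions in (
            (0, 0.6, [2.0, 3.0, 4.0]),  # primary, measured away from its end branch point
            (1, 0.44, [3.0, 4.0, 5.0]),
            (2, 0.32, [3.0, 4.0, 5.0]),
        ):
            ms = measure_along_segment(frame, cl, sid, positions, cfg)
            for m in ms:
                assert m.caliber == pytest.approx(true_d, abs=0.04)


class TestExclusionRules:
    @staticmethod
    def _meas(n_total, n_below):
        out = []
        for i in range(n_total):
            if i < n_below:
                out.append(CaliberMeasurement(0, float(i), None, single_peak=True))
            else:
                out.append(CaliberMeasurement(0, float(i), 0.4))
        return out

    def test_fraction_below_resolution_rule(self):
        bad = MeasurementSet("axon1", self._meas(10, 3))  # 30% > 20%
        ok = MeasurementSet("axon2", self._meas(10, 2))  # 20% is not > 20%
        retained, log = apply_exclusion_rules([bad, ok])
        assert [m.set_id for m in retained] == ["axon2"]
        assert log[0].rule == "fraction_below_resolution"

    def test_primary_below_resolution_excludes_branch_point(self):
        ms = MeasurementSet("bp1", self._meas(5, 0), primary_below_resolution=True)
        retained, log = apply_exclusion_rules([ms])
        assert retained == []
        assert log[0].rule == "primary_below_resolution"

    def test_branch_spacing_rule_uses_configured_distance(self):
        ms = MeasurementSet("bp1", self._meas(5, 0), branch_spacing_um=4.0)
        retained, _ = apply_exclusion_rules([ms], min_branch_spacing=3.0)
        assert len(retained) == 1  # fine for general analysis
        retained, log = apply_exclusion_rules([ms], min_branch_spacing=5.0)
        assert retained == [] and log[0].rule == "branch_spacing"  # symmetry analysis

    def test_all_rules_pass_is_identity(self):
        sets = [MeasurementSet("a", self._meas(10, 1))]
        retained, log = apply_exclusion_rules(sets)
        assert retained == sets and log == []
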