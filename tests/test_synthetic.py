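import numpy as np
import pytest
from scipy.signal import argrelmax

from axoncaliber.synthetic import (
    AxonGroundTruth,
    DynamicsScript,
    GeometryOutOfBoundsError,
    RoundingScenario,
    SceneConfig,
    analytic_linescan_profile,
    make_division_series,
    make_dynamics_series,
    make_pearled_radius_profile,
    make_sinusoidal_radius_profile,
    make_straight_tube_truth,
    render_membrane_frame,
)


class TestPearledRadiusProfile:
    def test_no_pearls_is_constant(self):
        s, r = make_pearled_radius_profile(0.15, [], length=10.0)
        assert np.all(r == 0.15)

    def test_gaussian_bump_values(self):
        # r(center) = base + a; r(center +- w) = base + a * exp(-1/2)
        s, r = make_pearled_radius_profile(0.15, [(5.0, 0.10, 1.0)], length=10.0)
        assert np.interp(5.0, s, r) == pytest.approx(0.25, abs=1e-9)
        expected_at_w = 0.15 + 0.10 * np.exp(-0.5)
        assert np.interp(4.0, s, r) == pytest.approx(expected_at_w, abs=1e-9)
        assert np.interp(6.0, s, r) == pytest.approx(expected_at_w, abs=1e-9)

    def test_negative_radius_rejected_with_diagnostic(self):
        with pytest.raises(ValueError, match="not positive"):
            make_pearled_radius_profile(0.10, [(5.0, -0.12, 1.0)], length=10.0)

    def test_sinusoidal_preset_amplitude(self):
        s, r = make_sinusoidal_radius_profile(0.2, 0.05, wavelength=3.0, length=12.0)
        assert r.max() == pytest.approx(0.25, abs=1e-3)
        assert r.min() == pytest.approx(0.15, abs=1e-3)


class TestAnalyticProfile:
    def test_well_separated_peaks_at_half_diameter(self):
        # separation 10 sigma: peak shift is negligible
        x = np.linspace(-0.6, 0.6, 24001)
        prof = analytic_linescan_profile(0.6, 0.06, x)
        peaks = argrelmax(prof)[0]
        assert len(peaks) == 2
        assert abs(x[peaks[0]] + 0.300) < 1e-4
        assert abs(x[peaks[1]] - 0.300) < 1e-4

    def test_coincident_sources_single_peak(self):
        x = np.linspace(-0.5, 0.5, 2001)
        prof = analytic_linescan_profile(0.0, 0.06, x)
        assert len(argrelmax(prof)[0]) == 1
        assert x[np.argmax(prof)] == pytest.approx(0.0, abs=1e-6)

    def test_below_merge_threshold_is_unimodal(self):
        # two equal Gaussians merge into one mode when separation < 2 sigma
        x = np.linspace(-0.5, 0.5, 4001)
        prof = analytic_linescan_profile(0.10, 0.0595, x)
        assert len(argrelmax(prof)[0]) == 1


class TestRenderMembraneFrame:
    def test_small_psf_ridges_at_boundaries(self):
        # center chosen so boundary lines land on pixel rows exactly
        scene = SceneConfig(psf_fwhm=0.02, background=0.0, read_noise_sd=0.0)
        w, h = scene.extent
        truth = make_straight_tube_truth(diameter=0.6, config=scene, length=10.0)
        # shift centerline so y = 80.5 px -> boundaries at rows 73 and 88
        truth.segments[0][:, 1] = 80.5 * scene.pixel_size
        truth = AxonGroundTruth(
            segments=truth.segments, radius_profiles=truth.radius_profiles
        )
        img = render_membrane_frame(truth, scene)
        col = img[:, img.shape[1] // 2]
        rows = np.sort(np.argsort(col)[-2:])
        assert (rows[1] - rows[0]) * scene.pixel_size == pytest.approx(0.6, abs=scene.pixel_size)

    def test_profile_matches_analytic_oracle(self):
        # tube centered on a pixel row, boundaries on pixel centers, so the
        # sampled column aligns exactly with the closed-form two-Gaussian oracle
        scene = SceneConfig(background=0.0, read_noise_sd=0.0)
        row = 80
        d = 0.64  # boundaries at +-8 px
        truth = make_straight_tube_truth(diameter=d, config=scene, length=10.0)
        truth.segments[0][:, 1] = row * scene.pixel_size
        truth = AxonGroundTruth(
            segments=truth.segments, radius_profiles=truth.radius_profiles
        )
        img = render_membrane_frame(truth, scene)
        col = img[:, img.shape[1] // 2].astype(float)
        rows_um = (np.arange(len(col)) - row) * scene.pixel_size
        keep = np.abs(rows_um) <= 1.0
        rendered = col[keep] / col[keep].max()
        oracle = analytic_linescan_profile(d, scene.psf_sigma, rows_um[keep])
        rms = np.sqrt(np.mean((rendered - oracle) ** 2))
        assert rms < 0.02

    def test_noise_determinism_contract(self):
        truth_cfg = dict(diameter=0.6, length=8.0)
        a = SceneConfig(seed=5, poisson_noise=True)
        b = SceneConfig(seed=5, poisson_noise=True)
        c = SceneConfig(seed=6, poisson_noise=True)
        ta = make_straight_tube_truth(config=a, **truth_cfg)
        img1 = render_membrane_frame(ta, a)
        img2 = render_membrane_frame(ta, b)
        img3 = render_membrane_frame(ta, c)
        assert np.array_equal(img1, img2)
        assert not np.array_equal(img1, img3)

    def test_out_of_bounds_names_segment(self):
        scene = SceneConfig(image_shape=(60, 60))
        truth = make_straight_tube_truth(diameter=0.6, config=scene, length=10.0)
        with pytest.raises(GeometryOutOfBoundsError, match="segment 0"):
            render_membrane_frame(truth, scene)


class TestDynamicsSeries:
    def test_traveling_pearl_advances_at_scripted_speed(self):
        script = DynamicsScript(behavior="traveling_pearl", speed=0.4, n_frames=5)
        series = make_dynamics_series(script, SceneConfig(seed=0))
        centers = []
        for truth in series.truths:
            s, r = truth.radius_profiles[0]
            centers.append(s[np.argmax(r)])
        steps = np.diff(centers)
        assert np.allclose(steps, 0.4, atol=0.06)

    def test_zero_amplitude_frames_identical_without_noise(self):
        script = DynamicsScript(behavior="focal_inflation_deflation", amplitude=0.0, n_frames=4)
        scene = SceneConfig(seed=0, read_noise_sd=0.0, poisson_noise=False)
        series = make_dynamics_series(script, scene)
        for f in series.frames[1:]:
            assert np.array_equal(f, series.frames[0])

    def test_constriction_reaches_scripted_minimum(self):
        script = DynamicsScript(
            behavior="constriction_point", base_radius=0.15, amplitude=-0.08,
            onset=3, offset=3, n_frames=5,
        )
        series = make_dynamics_series(script, SceneConfig(seed=0))
        _, r3 = series.truths[3].radius_profiles[0]
        assert r3.min() == pytest.approx(0.15 - 0.08, abs=1e-9)
        _, r0 = series.truths[0].radius_profiles[0]
        assert r0.min() == pytest.approx(0.15, abs=1e-9)

    def test_frame_times_use_five_minute_default(self):
        script = DynamicsScript(behavior="traveling_pearl", n_frames=3)
        series = make_dynamics_series(script, SceneConfig(seed=0))
        assert np.allclose(series.frame_times, [0, 5, 10])
        assert [t.frame_time for t in series.truths] == [0.0, 5.0, 10.0]


class TestDivisionSeries:
    def test_flat_cell_degenerates_to_chord(self):
        sc = RoundingScenario(flat_length=12, rounded_extent=10, rounded_height=0.0)
        series = make_division_series(sc, SceneConfig(seed=0, image_shape=(160, 640)))
        assert series.true_path_lengths[sc.round_frame] == pytest.approx(10.0)

    def test_semicircular_round_path(self):
        sc = RoundingScenario(flat_length=12, rounded_extent=10, rounded_height=5.0)
        series = make_division_series(sc, SceneConfig(seed=0, image_shape=(160, 640)))
        assert series.true_path_lengths[sc.round_frame] == pytest.approx(5 * np.pi, rel=1e-9)

    def test_border_length_drops_then_recovers(self):
        sc = RoundingScenario(flat_length=12, rounded_extent=9, rounded_height=3.0)
        series = make_division_series(sc, SceneConfig(seed=0, image_shape=(160, 640)))
        bl = series.border_lengths
        rf = sc.round_frame
        assert bl[rf] < bl[rf - 1]
        assert bl[rf + 1] > bl[rf]
        assert np.all(np.diff(bl[: rf + 1]) < 0)

    def test_invalid_scenario_rejected(self):
        with pytest.raises(ValueError):
            RoundingScenario(flat_length=8.0, rounded_extent=10.0, rounded_height=1.0)


class TestGroundTruthInvariants:
    def test_child_must_originate_at_branch_point(self):
        from axoncaliber.synthetic import BranchPoint

        segs = {
            0: np.array([[1.0, 1.0], [3.0, 1.0]]),
            1: np.array([[3.5, 1.0], [5.0, 2.0]]),  # offset from the branch point
        }
        radii = {k: (np.array([0.0, 2.0]), np.array([0.1, 0.1])) for k in segs}
        bp = BranchPoint(location=(3.0, 1.0), parent_id=0, child_ids=(1,))
        with pytest.raises(ValueError, match="originate"):
            AxonGroundTruth(segments=segs, radius_profiles=radii, branch_points=[bp])

    def test_non_positive_radius_rejected(self):
        segs = {0: np.array([[1.0, 1.0], [3.0, 1.0]])}
        radii = {0: (np.array([0.0, 2.0]), np.array([0.1, 0.0]))}
        with pytest.raises(ValueError, match="positive"):
            AxonGroundTruth(segments=segs, radius_profiles=radii)
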