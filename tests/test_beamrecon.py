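import numpy as np
import pytest

from lingualsonar import beamrecon as br
from lingualsonar.acoustics import AcousticMedium, DirectionGrid
from oracles import cap_mic_directions, gaussian_beam_db


class TestHeadPose:
    def test_marker_construction_example(self):
        pose = br.head_pose_from_markers([1, 0, 0], [-1, 1, 0], [-1, -1, 0])
        np.testing.assert_allclose(pose.aim, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(pose.normal, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(pose.left, [0, 1, 0], atol=1e-12)

    def test_pose_equivariant_under_rotation(self, rng):
        a, b, c = np.array([1.0, 0, 0]), np.array([-1.0, 1, 0]), \
            np.array([-1.0, -1, 0])
        ang = 0.7
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        p1 = br.head_pose_from_markers(a, b, c)
        p2 = br.head_pose_from_markers(rot @ a, rot @ b, rot @ c)
        np.testing.assert_allclose(p2.aim, rot @ p1.aim, atol=1e-12)
        np.testing.assert_allclose(p2.normal, rot @ p1.normal, atol=1e-12)

    def test_collinear_markers_rejected(self):
        with pytest.raises(ValueError):
            br.head_pose_from_markers([0, 0, 0], [1, 0, 0], [2, 0, 0])

    def test_fallback_straight_level_flight(self):
        t = np.linspace(0, 1, 21)
        pos = np.stack([2.0 * t, np.zeros_like(t), np.ones_like(t)], -1)
        pose = br.head_pose_fallback(t, pos, 0.5)
        np.testing.assert_allclose(pose.aim, [1, 0, 0], atol=1e-9)
        np.testing.assert_allclose(pose.normal, [0, 0, 1], atol=1e-12)

    def test_fallback_climbing_flight_projects_horizontally(self):
        t = np.linspace(0, 1, 21)
        pos = np.stack([1.5 * t, 0.5 * t, 2.0 * t], -1)
        pose = br.head_pose_fallback(t, pos, 0.5)
        expected = np.array([1.5, 0.5, 0.0])
        np.testing.assert_allclose(pose.aim, expected / np.linalg.norm(
            expected), atol=1e-9)

    def test_fallback_circular_flight_tangent(self):
        t = np.linspace(0, 2, 81)
        omega = np.pi
        pos = np.stack([np.cos(omega * t), np.sin(omega * t),
                        np.ones_like(t)], -1)
        t0 = 0.5
        pose = br.head_pose_fallback(t, pos, t0, window=0.05)
        tangent = np.array([-np.sin(omega * t0), np.cos(omega * t0), 0.0])
        assert pose.aim @ tangent > np.cos(np.radians(2.0))

    def test_fallback_stationary_rejected(self):
        t = np.linspace(0, 1, 11)
        pos = np.ones((11, 3))
        with pytest.raises(ValueError):
            br.head_pose_fallback(t, pos, 0.5)


class TestCompensation:
    def test_round_trip_restores_source_level(self, medium, rng):
        mic = br.MicrophoneSpec(0, [1.0, 1.0, 1.0], [1, 0, 0])
        f = np.array([25e3, 35e3, 55e3])
        true = rng.uniform(-30, 0, 3)
        r = 1.7
        raw = (true - 20 * np.log10(r / 0.1)
               - medium.absorption_db_per_m(f) * r)
        got = br.compensate_esd(raw, mic, r, f, medium)
        np.testing.assert_allclose(got, true, atol=1e-9)

    def test_pure_spreading_term(self, medium):
        mic = br.MicrophoneSpec(0, [0, 0, 0], [1, 0, 0])
        out = br.compensate_esd(np.array([0.0]), mic, 2.0,
                                np.array([35e3]), medium, absorption=False)
        assert out[0] == pytest.approx(20 * np.log10(20.0), abs=1e-9)

    def test_band_limited_sensitivity(self, medium):
        mic = br.MicrophoneSpec(0, [0, 0, 0], [1, 0, 0])
        with pytest.raises(ValueError):
            br.compensate_esd(np.array([0.0]), mic, 1.0,
                              np.array([150e3]), medium)

    def test_range_below_reference_rejected(self, medium):
        mic = br.MicrophoneSpec(0, [0, 0, 0], [1, 0, 0])
        with pytest.raises(ValueError):
            br.compensate_esd(np.array([0.0]), mic, 0.05,
                              np.array([35e3]), medium)


class TestBatFrameProjection:
    def setup_method(self):
        self.pose = br.BatPose([0, 0, 0], [1, 0, 0], [0, 0, 1])

    def test_cardinal_directions(self):
        az, el, _ = br.project_mics_to_bat_frame(
            [[2, 0, 0], [0, 0, 3], [0, 1, 0]], self.pose)
        np.testing.assert_allclose(az[[0, 2]], [0.0, 90.0], atol=1e-9)
        np.testing.assert_allclose(el, [0.0, 90.0, 0.0], atol=1e-9)

    def test_coincident_mic_rejected(self):
        with pytest.raises(ValueError):
            br.project_mics_to_bat_frame([[0, 0, 0]], self.pose)

    def test_invariant_under_mic_relabeling(self, rng):
        mics = rng.uniform(-2, 2, (10, 3)) + [5, 0, 0]
        az1, el1, r1 = br.project_mics_to_bat_frame(mics, self.pose)
        perm = rng.permutation(10)
        az2, el2, r2 = br.project_mics_to_bat_frame(mics[perm], self.pose)
        np.testing.assert_allclose(az2, az1[perm])
        np.testing.assert_allclose(el2, el1[perm])


class TestRBF:
    def test_constant_samples_give_constant_field(self, grid1):
        az, el = cap_mic_directions(20, 120.0)
        lev, off, mask = br.rbf_interpolate(az, el, np.full(20, -7.0), grid1)
        assert np.allclose(lev[mask], 0.0, atol=1e-8)

    def test_samples_reproduced_exactly(self, grid1, rng):
        az, el = cap_mic_directions(34, 110.0)
        vals = rng.uniform(-35, 0, 34)
        rbf = br.SphericalRBF(az, el, 10 ** (vals / 10))
        got = 10 * np.log10(rbf(az, el))
        np.testing.assert_allclose(got, vals, atol=1e-9)

    def test_duplicate_directions_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            br.SphericalRBF([0, 0, 10, 20, 30], [0, 0, 5, 5, 5],
                            [1, 1, 1, 1, 1])

    def test_gaussian_beam_peak_recovery(self, grid1):
        az, el = cap_mic_directions(34, 90.0)
        vals = gaussian_beam_db(az, el, az0=15.0, el0=-5.0)
        lev, _, _ = br.rbf_interpolate(az, el, vals, grid1)
        imax = np.unravel_index(np.argmax(lev), lev.shape)
        peak = (grid1.azimuth[imax[1]], grid1.elevation[imax[0]])
        assert np.hypot(peak[0] - 15.0, peak[1] + 5.0) <= 5.0

    def test_too_few_samples_rejected(self, grid1):
        with pytest.raises(ValueError):
            br.rbf_interpolate([0, 50, 100, -50], [0, 0, 0, 0],
                               [0, -3, -9, -3], grid1)


class TestContourAndCenter:
    def _beam(self, grid, az0=0.0, el0=0.0, waz=40.0, wel=40.0):
        azg, elg = np.meshgrid(grid.azimuth, grid.elevation)
        lev = gaussian_beam_db(azg, elg, az0, el0, waz, wel, floor_db=-50)
        return lev - lev.max()

    def test_circular_gaussian_contour_radius(self, grid1):
        lev = self._beam(grid1, waz=40.0, wel=40.0)
        poly, open_flag = br.contour_minus3db(lev, grid1)
        assert not open_flag
        fit = br.fit_ellipse(poly)
        # -3 dB radius of the synthetic beam is 20 deg
        assert fit.az_extent == pytest.approx(40.0, abs=1.5)
        assert fit.el_extent == pytest.approx(40.0, abs=1.5)

    def test_beam_above_threshold_everywhere_flagged(self, grid1):
        lev = np.zeros(grid1.shape)
        with pytest.raises(br.ContourError):
            br.contour_minus3db(lev, grid1)

    def test_two_lobes_contour_encloses_taller(self, grid1):
        azg, elg = np.meshgrid(grid1.azimuth, grid1.elevation)
        tall = gaussian_beam_db(azg, elg, 40.0, 0.0, 30, 30, floor_db=-60)
        small = gaussian_beam_db(azg, elg, -60.0, 0.0, 30, 30,
                                 floor_db=-60) - 6.0
        lev = 10 * np.log10(10 ** (tall / 10) + 10 ** (small / 10))
        lev -= lev.max()
        poly, _ = br.contour_minus3db(lev, grid1)
        fit = br.fit_ellipse(poly)
        assert abs(fit.center_az - 40.0) < 3.0

    def test_beam_center_matches_construction(self, grid1):
        lev = self._beam(grid1, az0=15.0, el0=-5.0, waz=24.0, wel=36.0)
        az, el = br.beam_center(lev, grid1)
        assert abs(az - 15.0) < 1.0 and abs(el + 5.0) < 1.0

    def test_center_close_to_bright_mean_direction(self, grid1):
        lev = self._beam(grid1, az0=10.0, el0=8.0, waz=30.0, wel=42.0)
        c = br.beam_center(lev, grid1)
        m = br.mean_bright_direction(lev, grid1, threshold=-1.0)
        assert np.hypot(c[0] - m[0], c[1] - m[1]) < 5.0

    def test_aspect_ratio_of_elongated_beam(self, grid1):
        lev = self._beam(grid1, waz=24.0, wel=36.0)
        poly, _ = br.contour_minus3db(lev, grid1)
        fit = br.fit_ellipse(poly)
        assert fit.aspect_ratio == pytest.approx(1.5, rel=0.05)


class TestQualityFilter:
    def _click(self, bundle, i=0):
        return bundle.clicks[i]

    def test_dense_click_passes_defaults(self, clean_bundle):
        mics = {m.mic_id: m for m in clean_bundle.mics}
        crit = br.QualityCriteria()
        results = [br.quality_filter(c, mics, crit)
                   for c in clean_bundle.clicks]
        assert any(r.passed for r in results)

    def test_missing_criteria_rejected(self, clean_bundle):
        mics = {m.mic_id: m for m in clean_bundle.mics}
        with pytest.raises(ValueError):
            br.quality_filter(clean_bundle.clicks[0], mics, None)

    def test_low_snr_fails_criterion_five(self, clean_bundle):
        import dataclasses
        mics = {m.mic_id: m for m in clean_bundle.mics}
        click = dataclasses.replace(clean_bundle.clicks[0],
                                    noise_floor_db=1000.0)
        rep = br.quality_filter(click, mics, br.QualityCriteria())
        assert not rep.snr_ok and not rep.passed

    def test_few_neighbors_fails_criterion_four(self, clean_bundle):
        import dataclasses
        mics = {m.mic_id: m for m in clean_bundle.mics}
        crit = br.QualityCriteria(min_neighbors=5, neighbor_radius=1.0)
        rep = br.quality_filter(clean_bundle.clicks[0], mics, crit)
        assert not rep.neighbors_ok
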