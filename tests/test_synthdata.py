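import numpy as np
import pytest

from lingualsonar import beamrecon as br
from lingualsonar import synthdata as sd


class TestMicArray:
    def test_default_count_and_bounds(self):
        cfg = sd.SessionConfig()
        mics = sd.make_mic_array(cfg)
        assert len(mics) == 34
        pos = np.array([m.position for m in mics])
        room = np.array(cfg.room)
        assert np.all(pos >= -1e-9) and np.all(pos <= room + 1e-9)

    def test_mics_face_room_center(self):
        cfg = sd.SessionConfig()
        mics = sd.make_mic_array(cfg)
        center = np.array(cfg.room) / 2
        for m in mics:
            to_center = center - m.position
            assert m.facing @ (to_center / np.linalg.norm(to_center)) > 0.99

    def test_angular_coverage_exceeds_three_pi(self):
        cfg = sd.SessionConfig()
        mics = sd.make_mic_array(cfg)
        sr = sd.angular_coverage_sr(mics, np.array(cfg.room) / 2)
        assert sr >= 3 * np.pi

    def test_deterministic_under_seed(self):
        a = sd.make_mic_array(sd.SessionConfig(seed=5))
        b = sd.make_mic_array(sd.SessionConfig(seed=5))
        np.testing.assert_array_equal(
            np.array([m.position for m in a]),
            np.array([m.position for m in b]))


class TestTrajectory:
    def test_markers_recover_exact_pose_without_dropout(self):
        cfg = sd.SessionConfig(seed=2, marker_dropout=0.0, duration=2.0)
        traj = sd.make_trajectory(cfg)
        i = len(traj.times) // 2
        pose = sd.head_pose_from_markers(*traj.markers[i])
        assert pose.aim @ traj.aims[i] > np.cos(np.radians(0.1))
        assert pose.normal @ traj.normals[i] > np.cos(np.radians(0.1))

    def test_full_dropout_forces_fallback(self):
        cfg = sd.SessionConfig(seed=2, marker_dropout=1.0, duration=2.0)
        bundle = sd.generate_session(cfg)
        assert all(c.pose_source == "trajectory-fallback"
                   for c in bundle.clicks)

    def test_trajectory_stays_inside_room(self):
        cfg = sd.SessionConfig(seed=7, duration=6.0)
        traj = sd.make_trajectory(cfg)
        room = np.array(cfg.room)
        assert np.all(traj.positions > 0) and np.all(
            traj.positions < room)


class TestClickTrain:
    def test_pairs_alternate_left_right(self):
        cfg = sd.SessionConfig(seed=3, duration=6.0)
        traj = sd.make_trajectory(cfg)
        events = sd.make_click_train(cfg, traj)
        assert len(events) >= 4
        for first, second in zip(events[::2], events[1::2]):
            assert first.side == "left" and second.side == "right"
            assert second.time - first.time == pytest.approx(0.020)
            # symmetric split about the head aim
            assert first.aim_offset_deg == pytest.approx(
                -second.aim_offset_deg)

    def test_inter_click_angles_within_support(self):
        cfg = sd.SessionConfig(seed=3, duration=20.0)
        traj = sd.make_trajectory(cfg)
        events = sd.make_click_train(cfg, traj)
        angles = np.array([e1.aim_offset_deg - e2.aim_offset_deg
                           for e1, e2 in zip(events[::2], events[1::2])])
        assert np.all(angles >= 20.0) and np.all(angles <= 60.0)
        # the sample mean approaches the configured mean of 40 deg
        assert abs(angles.mean() - 40.0) < 4.0


class TestSynthesizeEsd:
    def test_sigma_zero_round_trip_exact(self, clean_bundle, medium):
        click = clean_bundle.clicks[0]
        positions = np.array([m.position for m in clean_bundle.mics])
        az, el, rng_m = br.project_mics_to_bat_frame(positions, click.pose)
        offset = clean_bundle.true_aim_offsets[0]
        az_beam = (az - offset + 180.0) % 360.0 - 180.0
        for j, f in enumerate(click.frequencies):
            comp = np.array([
                br.compensate_esd(click.esd_db[i, j],
                                  clean_bundle.mics[i], rng_m[i], f, medium)
                for i in range(len(clean_bundle.mics))]).ravel()
            truth = clean_bundle.truth.level_db(az_beam, el, float(f))
            np.testing.assert_allclose(comp, truth, atol=1e-9)

    def test_symmetric_mics_receive_equal_levels(self, medium):
        # symmetric beam, two mirrored microphones, no noise
        cfg = sd.SessionConfig(seed=4, noise_sigma_db=0.0)
        truth = sd.TruthModel("gaussian")
        pose = br.BatPose([1.0, 1.15, 1.2], [1, 0, 0], [0, 0, 1])
        mics = [br.MicrophoneSpec(0, [2.0, 1.65, 1.2], [-1, 0, 0]),
                br.MicrophoneSpec(1, [2.0, 0.65, 1.2], [-1, 0, 0])]
        ev = sd.ClickEvent(0, 0.0, "left", 0.0)
        rng = np.random.default_rng(0)
        click = sd.synthesize_esd(truth, ev, pose, mics, cfg, medium, rng)
        np.testing.assert_allclose(click.esd_db[0], click.esd_db[1],
                                   atol=1e-9)

    def test_noise_standard_deviation_calibrated(self, medium):
        cfg = sd.SessionConfig(seed=5, noise_sigma_db=1.0)
        truth = sd.TruthModel("gaussian")
        pose = br.BatPose([1.0, 1.15, 1.2], [1, 0, 0], [0, 0, 1])
        mics = [br.MicrophoneSpec(0, [2.2, 1.15, 1.2], [-1, 0, 0])]
        ev = sd.ClickEvent(0, 0.0, "left", 0.0)
        rng = np.random.default_rng(99)
        reps = np.array([
            sd.synthesize_esd(truth, ev, pose, mics, cfg, medium,
                              rng).esd_db[0, 0]
            for _ in range(1000)])
        assert abs(reps.std(ddof=1) - 1.0) < 0.05


class TestDeterminism:
    def test_identical_config_identical_bundle_bytes(self, tmp_path):
        cfg = sd.SessionConfig(seed=9, duration=2.0)
        p1, p2 = tmp_path / "a.h5", tmp_path / "b.h5"
        sd.generate_session(cfg).to_hdf5(p1)
        sd.generate_session(cfg).to_hdf5(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_different_noise(self):
        b1 = sd.generate_session(sd.SessionConfig(seed=1, duration=2.0))
        b2 = sd.generate_session(sd.SessionConfig(seed=2, duration=2.0))
        assert not np.allclose(b1.clicks[0].esd_db, b2.clicks[0].esd_db)


class TestSerialization:
    def test_hdf5_session_reload_supports_pipeline(self, clean_bundle,
                                                   tmp_path):
        from lingualsonar.synthdata import load_session_hdf5
        p = tmp_path / "session.h5"
        clean_bundle.to_hdf5(p)
        mics, clicks = load_session_hdf5(p)
        assert len(mics) == len(clean_bundle.mics)
        assert len(clicks) == len(clean_bundle.clicks)
        orig = clean_bundle.clicks[0]
        np.testing.assert_allclose(clicks[0].esd_db, orig.esd_db)
        np.testing.assert_allclose(clicks[0].pose.aim, orig.pose.aim)
        assert clicks[0].side == orig.side

    def test_yaml_config_round_trip(self, tmp_path):
        from lingualsonar.synthdata import config_from_yaml, config_to_yaml
        cfg = sd.SessionConfig(seed=77, duration=3.5, truth_model="piston",
                               inter_click_angle=(25.0, 55.0))
        p = tmp_path / "session.yaml"
        config_to_yaml(cfg, p)
        assert config_from_yaml(p) == cfg


class TestTruthPool:
    def test_per_click_truth_drawn_from_pool(self):
        pool = [sd.TruthModel("gaussian", az_width=20.0),
                sd.TruthModel("gaussian", az_width=40.0)]
        cfg = sd.SessionConfig(seed=6, duration=6.0, noise_sigma_db=0.0)
        bundle = sd.generate_session(cfg, truth_pool=pool)
        idx = bundle.truth_pool_indices
        assert len(idx) == len(bundle.clicks)
        assert set(idx) == {0, 1}
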