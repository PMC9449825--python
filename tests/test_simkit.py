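"""Simulator physics and determinism."""

import numpy as np
import pytest

from imurehab import quat
from imurehab.simkit import (
    ActivityClass,
    ConfigurationError,
    NoiseModel,
    ParticipantParams,
    QuaternionSeries,
    default_protocol,
    draw_participants,
    exercise_classes,
    orientation_trajectory,
    posture_classes,
    simulate_dataset,
    synthesize_channels,
)

NEUTRAL = ParticipantParams("p0")


def _activity(name):
    return next(a for a in default_protocol() if a.name == name)


class TestProtocol:
    def test_default_protocol_composition(self):
        proto = default_protocol()
        kinds = [a.kind for a in proto]
        assert len(proto) == 11
        assert kinds.count("dynamic_exercise") == 6
        assert kinds.count("static_exercise") == 1
        assert kinds.count("posture") == 3
        assert kinds.count("adl") == 1
        assert len(exercise_classes(proto)) == 8
        assert len(posture_classes(proto)) == 3

    def test_good_and_forced_good_postures_differ_by_small_offset(self):
        # the two non-slouched postures are deliberately hard to separate
        good = _activity("sitting_good")
        forced = _activity("sitting_forced_good")
        poor = _activity("sitting_poor")
        gap = abs(good.lumbar_pitch_rad - forced.lumbar_pitch_rad)
        assert gap <= np.deg2rad(3.0)
        assert poor.lumbar_pitch_rad >= np.deg2rad(15.0)

    def test_invalid_activities_rejected(self):
        with pytest.raises(ConfigurationError):
            ActivityClass("x", "dynamic_exercise", "sagittal", 10.0, n_reps=0)
        with pytest.raises(ConfigurationError):
            ActivityClass("x", "posture", "none", -1.0)


class TestOrientationTrajectory:
    def test_static_posture_has_zero_excursion(self):
        traj = orientation_trajectory(_activity("sitting_good"), "lower_back", NEUTRAL, 0)
        assert np.allclose(traj.values, traj.values[0])
        assert np.allclose(np.linalg.norm(traj.values, axis=1), 1.0, atol=1e-9)

    def test_zero_amplitude_dynamic_is_constant_baseline(self):
        p = ParticipantParams("p0", amplitude_scale=0.0)
        traj = orientation_trajectory(_activity("supine_flexion"), "lower_back", p, 0)
        assert np.allclose(traj.values, traj.values[0], atol=1e-12)

    def test_deterministic_given_seed(self):
        a = orientation_trajectory(_activity("prone_extension"), "left_thigh", NEUTRAL, 42)
        b = orientation_trajectory(_activity("prone_extension"), "left_thigh", NEUTRAL, 42)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.timestamps, b.timestamps)

    def test_unknown_location_rejected(self):
        with pytest.raises(ConfigurationError):
            orientation_trajectory(_activity("adl"), "left_elbow", NEUTRAL, 0)

    def test_dynamic_motion_is_in_declared_plane(self):
        # seated rotation is a yaw movement: angular velocity z dominates
        act = _activity("seated_rotation")
        traj = orientation_trajectory(act, "lower_back", NEUTRAL, 0)
        omega = quat.angular_velocity(traj.values, traj.qdot)
        energy = (omega**2).sum(axis=0)
        assert energy[2] > 10 * energy[0]
        assert energy[2] > 10 * energy[1]


class TestSynthesizeChannels:
    def test_gravity_at_rest_under_identity_orientation(self):
        n = 101
        series = QuaternionSeries(
            timestamps=np.arange(n) / 50.0,
            values=np.tile([1.0, 0, 0, 0], (n, 1)),
            qdot=np.zeros((n, 4)),
        )
        streams = synthesize_channels(
            series, _activity("sitting_good"), NoiseModel.zero(), 0, heading_rad=0.0
        )
        accel = next(s for s in streams if s.channel == "accelerometer")
        gyro = next(s for s in streams if s.channel == "gyroscope")
        assert np.allclose(accel.values, [0.0, 0.0, -9.81])
        assert np.allclose(gyro.values, 0.0)

    def test_magnetometer_norm_is_field_magnitude(self):
        traj = orientation_trajectory(_activity("supine_flexion"), "lower_back", NEUTRAL, 1)
        streams = synthesize_channels(traj, _activity("supine_flexion"), NoiseModel.zero(), 1)
        mag = next(s for s in streams if s.channel == "magnetometer")
        assert np.allclose(np.linalg.norm(mag.values, axis=1), 50.0, atol=1e-9)

    def test_gyro_matches_finite_difference_of_orientation(self):
        # independent oracle: central differences on the sampled quaternions
        act = _activity("standing_extension")
        traj = orientation_trajectory(act, "lower_back", NEUTRAL, 5)
        streams = synthesize_channels(traj, act, NoiseModel.zero(), 5)
        gyro = next(s for s in streams if s.channel == "gyroscope")
        omega_fd = quat.finite_difference_omega(traj.values, 1 / 50.0)
        for j in range(3):
            expected = np.interp(gyro.timestamps, traj.timestamps, omega_fd[:, j])
            assert np.abs(expected - gyro.values[:, j])[2:-2].max() < 1e-3

    def test_channel_layout_and_rates(self):
        traj = orientation_trajectory(_activity("adl"), "right_ankle", NEUTRAL, 2)
        streams = synthesize_channels(traj, _activity("adl"), NoiseModel(), 2,
                                      location="right_ankle")
        by_channel = {s.channel: s for s in streams}
        assert set(by_channel) == {
            "accelerometer", "gyroscope", "magnetometer", "quaternion", "pressure"
        }
        assert by_channel["accelerometer"].rate_hz == 25.0
        assert by_channel["quaternion"].rate_hz == 50.0
        assert by_channel["pressure"].rate_hz == 13.0
        assert by_channel["quaternion"].values.shape[1] == 4
        assert np.allclose(
            np.linalg.norm(by_channel["quaternion"].values, axis=1), 1.0, atol=1e-9
        )


class TestSimulateDataset:
    def test_recording_count(self):
        ds = simulate_dataset(2, seed=0, locations=("lower_back",))
        assert len(ds) == 2 * 11

    def test_same_seed_identical(self):
        a = simulate_dataset(1, seed=3, locations=("lower_back",))
        b = simulate_dataset(1, seed=3, locations=("lower_back",))
        for ra, rb in zip(a.recordings, b.recordings):
            for sa, sb in zip(ra.streams, rb.streams):
                assert np.array_equal(sa.values, sb.values)

    def test_participants_differ_in_amplitude_and_period(self):
        ds = simulate_dataset(2, seed=1, locations=("lower_back",))
        recs = [r for r in ds.recordings if r.label == "supine_flexion"]
        stats = []
        for r in recs:
            gyro = r.stream("lower_back", "gyroscope")
            stats.append(np.sqrt((gyro.values[:, 1] ** 2).mean()))
        assert abs(stats[0] - stats[1]) > 1e-3

    def test_all_quaternions_unit_norm(self, small_dataset):
        for rec in small_dataset.recordings:
            for s in rec.streams:
                if s.channel == "quaternion":
                    assert np.allclose(np.linalg.norm(s.values, axis=1), 1.0, atol=1e-9)

    def test_stationary_accel_magnitude_with_zero_noise(self):
        proto = [a for a in default_protocol() if a.name == "prone_lying"]
        ds = simulate_dataset(1, protocol=proto, noise=NoiseModel.zero(), seed=0,
                              locations=("lower_back",))
        accel = ds.recordings[0].stream("lower_back", "accelerometer")
        assert np.allclose(np.linalg.norm(accel.values, axis=1), 9.81, atol=1e-9)

    def test_dynamic_classes_separable_by_gyro_plane_energy(self):
        # planted-effect check: distinct movement planes concentrate
        # angular-rate energy on distinct axes
        ds = simulate_dataset(1, seed=0, locations=("lower_back",))
        by_label = {r.label: r for r in ds.recordings}
        def plane_energy(label):
            g = by_label[label].stream("lower_back", "gyroscope").values
            return (g**2).sum(axis=0)
        flex = plane_energy("supine_flexion")  # sagittal -> y
        glide = plane_energy("side_glide_left")  # frontal -> x
        twist = plane_energy("seated_rotation")  # transverse -> z
        assert flex[1] == max(flex)
        assert glide[0] == max(glide)
        assert twist[2] == max(twist)

    def test_empty_protocol_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_dataset(1, protocol=[], seed=0)

    def test_cohort_sex_ratio(self):
        participants = draw_participants(19, seed=0)
        assert sum(p.sex == "M" for p in participants) == 12
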