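"""Synthetic multi-IMU session generator.

Generates physically consistent sensor data for a protocol of low back
rehabilitation activities: directional lumbar exercises (flexion,
extension, rotation, side glide), a static lying position, sitting
postures, and a pooled activities-of-daily-living (walking-like) class.
Eight body-worn devices are simulated; each emits accelerometer,
gyroscope and magnetometer streams at 25 Hz, a fused orientation
quaternion stream at 50 Hz, and barometric pressure at 13 Hz.

The generative model is kinematic, not musculoskeletal:

* each activity defines a baseline body pose and, for dynamic classes,
  a quasi-sinusoidal rotation about the plane-appropriate axis
  (sagittal -> pitch, frontal -> roll, transverse -> yaw);
* each simulated participant carries random effects (amplitude and
  period multipliers, small baseline orientation offsets, a phase
  offset, and a noise multiplier) drawn once per participant, which is
  what makes participant-grouped cross-validation meaningful;
* raw channels are derived from the orientation: the gyroscope is the
  analytic quaternion-derivative rate, the accelerometer is specific
  force (gravity plus a class-dependent linear-acceleration term,
  rotated into the sensor frame), and the magnetometer is a fixed
  earth field rotated into the sensor frame;
* sensor imperfections are additive Gaussian noise, a per-session
  bias, and a slow random-walk drift on the fused quaternion channel.

Conventions: earth frame NED (z down), Hamilton scalar-first
quaternions mapping earth to sensor coordinates, accelerometer reading
(0, 0, -9.81) m/s^2 at rest under identity orientation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import quat
from .sensordata import (
    CHANNEL_RATES,
    LOCATIONS,
    Dataset,
    Recording,
    SensorStream,
    ValidationError,
)

__all__ = [
    "ActivityClass",
    "ParticipantParams",
    "NoiseModel",
    "QuaternionSeries",
    "ConfigurationError",
    "default_protocol",
    "exercise_classes",
    "posture_classes",
    "orientation_trajectory",
    "synthesize_channels",
    "simulate_dataset",
]

GRAVITY = 9.81  # m/s^2
MAG_FIELD_UT = 50.0  # earth magnetic field magnitude, microtesla
MAG_DIP_RAD = np.deg2rad(60.0)  # inclination of the field below horizontal
PRESSURE_BASELINE_PA = 101_325.0
QUAT_RATE_HZ = CHANNEL_RATES["quaternion"]

# How strongly each device location expresses trunk-driven exercise
# motion.  The three lower-body devices move with the lumbar spine and
# lower limbs; upper-body devices receive attenuated copies, so they
# stay informative but less so -- the qualitative importance ordering
# the sensor-selection stage is expected to recover.
LOCATION_GAIN: dict[str, float] = {
    "lower_back": 1.0,
    "left_thigh": 0.85,
    "right_ankle": 0.70,
    "upper_back": 0.55,
    "left_shoulder": 0.45,
    "right_shoulder": 0.40,
    "wrist": 0.35,
    "right_ear": 0.30,
}

# Gait expression for the walking-dominated ADL class: lower-limb
# devices swing, the trunk bobs slightly.
GAIT_GAIN: dict[str, float] = {
    "left_thigh": 1.0,
    "right_ankle": 1.25,
    "lower_back": 0.18,
    "upper_back": 0.12,
    "left_shoulder": 0.10,
    "right_shoulder": 0.10,
    "wrist": 0.30,
    "right_ear": 0.08,
}

_PLANE_AXIS = {
    "sagittal": np.array([0.0, 1.0, 0.0]),  # pitch
    "frontal": np.array([1.0, 0.0, 0.0]),  # roll
    "transverse": np.array([0.0, 0.0, 1.0]),  # yaw
}

# Devices on free or loosely coupled segments (arm, head): their
# mounting orientation is only weakly determined by the activity, so
# each recording draws an extra orientation offset of this SD (rad).
# This is what makes upper-body devices genuinely less informative
# across participants than the strapped lower-body devices.
FREE_LIMB_ORIENT_SD: dict[str, float] = {
    "wrist": np.deg2rad(25.0),
    "right_ear": np.deg2rad(15.0),
    "left_shoulder": np.deg2rad(12.0),
    "right_shoulder": np.deg2rad(12.0),
}

# Fraction of the lumbar posture offset expressed at the upper back:
# a slouch is a lumbar flexion, which the upper-back device sees only
# partially.
UPPER_BACK_LUMBAR_COUPLING = 0.4


class ConfigurationError(Exception):
    """Unknown activity/location or inconsistent simulator configuration."""


@dataclass(frozen=True)
class ActivityClass:
    """One labeled activity in the recording protocol.

    ``kind`` distinguishes dynamic exercises (repeated end-range
    movements), the static lying exercise, sitting postures and the
    pooled ADL class.  ``amplitude_rad`` is the peak excursion of the
    movement; ``signed_excursion`` selects a one-sided (move out and
    return, e.g. a side glide held to one side) versus a symmetric
    (twist both ways) angle profile.  ``lumbar_pitch_rad`` is the
    constant lumbar flexion offset applied at trunk devices and is what
    separates poor from good sitting posture.
    """

    name: str
    kind: str  # dynamic_exercise | static_exercise | posture | adl
    motion_plane: str  # sagittal | frontal | transverse | mixed | none
    duration_s: float
    n_reps: int = 0
    base_pose: str = "standing"
    amplitude_rad: float = 0.0
    signed_excursion: bool = True
    lumbar_pitch_rad: float = 0.0
    lever_m: float = 0.25

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError(f"{self.name}: duration_s must be > 0")
        if self.kind == "dynamic_exercise" and self.n_reps < 1:
            raise ConfigurationError(f"{self.name}: dynamic classes need n_reps >= 1")
        if self.kind not in {"dynamic_exercise", "static_exercise", "posture", "adl"}:
            raise ConfigurationError(f"{self.name}: unknown kind {self.kind!r}")


def default_protocol() -> list[ActivityClass]:
    """The default 11-class protocol: 6 dynamic lumbar exercises, 1
    static lying exercise, 3 sitting postures, and 1 pooled ADL class.

    Dynamic exercises run 6 repetitions at roughly 4 s per repetition;
    static holds and postures last 40 s; the ADL bout lasts 180 s.
    Exercise names are descriptive of the movement performed.
    """
    dyn = dict(kind="dynamic_exercise", n_reps=6, duration_s=24.0)
    sit = dict(kind="posture", motion_plane="none", duration_s=40.0, base_pose="sitting")
    return [
        ActivityClass("prone_lying", "static_exercise", "none", 40.0, base_pose="prone"),
        ActivityClass("prone_extension", motion_plane="sagittal", base_pose="prone",
                      amplitude_rad=np.deg2rad(35.0), **dyn),
        ActivityClass("standing_extension", motion_plane="sagittal", base_pose="standing",
                      amplitude_rad=np.deg2rad(-20.0), **dyn),
        ActivityClass("supine_flexion", motion_plane="sagittal", base_pose="supine",
                      amplitude_rad=np.deg2rad(45.0), **dyn),
        ActivityClass("side_glide_left", motion_plane="frontal", base_pose="standing",
                      amplitude_rad=np.deg2rad(15.0), **dyn),
        ActivityClass("side_glide_right", motion_plane="frontal", base_pose="standing",
                      amplitude_rad=np.deg2rad(-15.0), **dyn),
        ActivityClass("seated_rotation", motion_plane="transverse", base_pose="sitting",
                      amplitude_rad=np.deg2rad(40.0), signed_excursion=False, **dyn),
        ActivityClass("adl", "adl", "mixed", 180.0),
        ActivityClass("sitting_poor", lumbar_pitch_rad=np.deg2rad(20.0), **sit),
        ActivityClass("sitting_good", lumbar_pitch_rad=0.0, **sit),
        ActivityClass("sitting_forced_good", lumbar_pitch_rad=np.deg2rad(-2.5), **sit),
    ]


def exercise_classes(protocol: Sequence[ActivityClass] | None = None) -> list[str]:
    """Labels of the exercise task (dynamic + static exercises + ADL)."""
    protocol = list(protocol) if protocol is not None else default_protocol()
    return [a.name for a in protocol if a.kind != "posture"]


def posture_classes(protocol: Sequence[ActivityClass] | None = None) -> list[str]:
    """Labels of the posture task."""
    protocol = list(protocol) if protocol is not None else default_protocol()
    return [a.name for a in protocol if a.kind == "posture"]


@dataclass(frozen=True)
class ParticipantParams:
    """Per-participant random effects (drawn once per participant)."""

    participant_id: str
    amplitude_scale: float = 1.0
    period_scale: float = 1.0
    phase_offset: float = 0.0
    noise_scale: float = 1.0
    sex: str = "M"
    # location -> (roll, pitch, yaw) baseline mounting offset, radians
    baseline_orientation_offset: dict[str, tuple[float, float, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        # amplitude_scale = 0 is allowed as the degenerate "no movement" case
        if self.amplitude_scale < 0 or self.period_scale <= 0 or self.noise_scale <= 0:
            raise ConfigurationError("participant multipliers must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Additive sensor imperfection model.

    ``*_sd`` are white-noise standard deviations; ``*_bias_sd`` scale a
    per-session constant offset; ``quat_drift_rad_per_sqrt_s`` is the
    random-walk rate of the fused orientation channel (the raw channels
    are derived from the undrifted orientation, mirroring how fusion
    output drifts relative to the raw sensors).
    """

    accel_sd: float = 0.3  # m/s^2
    gyro_sd: float = 0.05  # rad/s
    mag_sd: float = 1.5  # microtesla
    pressure_sd: float = 5.0  # Pa
    accel_bias_sd: float = 0.1
    gyro_bias_sd: float = 0.02
    mag_bias_sd: float = 0.5
    pressure_bias_sd: float = 20.0
    quat_drift_rad_per_sqrt_s: float = np.deg2rad(0.5)
    # ambient (hard-iron / building steel) field disturbance: an
    # earth-frame offset drawn once per recording, microtesla per axis
    mag_disturbance_sd: float = 6.0

    def __post_init__(self) -> None:
        for name in (
            "accel_sd", "gyro_sd", "mag_sd", "pressure_sd",
            "accel_bias_sd", "gyro_bias_sd", "mag_bias_sd",
            "pressure_bias_sd", "quat_drift_rad_per_sqrt_s",
            "mag_disturbance_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class QuaternionSeries:
    """Uniform 50 Hz unit-quaternion series with analytic extras.

    ``qdot`` (analytic time derivative) and ``lin_accel_earth``
    (earth-frame linear acceleration of the device, m/s^2) are carried
    along so channel synthesis does not need to re-differentiate.  Both
    fall back to sensible defaults when absent.
    """

    timestamps: np.ndarray
    values: np.ndarray  # (n, 4) scalar-first unit quaternions
    qdot: np.ndarray | None = None
    lin_accel_earth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        norms = np.linalg.norm(self.values, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValidationError("quaternion series is not unit-norm within 1e-9")

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(self.timestamps[1] - self.timestamps[0])


def _child_rng(seed: int, *scope: str) -> np.random.Generator:
    """Deterministic child generator from a stable hash of the scope."""
    digest = hashlib.sha256(("|".join(map(str, (seed,) + scope))).encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _euler_quat(roll: float, pitch: float, yaw: float) -> np.ndarray:
    qz = quat.from_axis_angle([0, 0, 1], yaw)
    qy = quat.from_axis_angle([0, 1, 0], pitch)
    qx = quat.from_axis_angle([1, 0, 0], roll)
    return quat.multiply(qz, quat.multiply(qy, qx))


def _base_orientation(activity: ActivityClass, location: str,
                      params: ParticipantParams) -> np.ndarray:
    pose = activity.base_pose
    pitch = 0.0
    if pose == "prone":
        pitch = np.pi / 2
    elif pose == "supine":
        pitch = -np.pi / 2
    elif pose == "sitting" and location == "left_thigh":
        pitch = np.pi / 2  # thigh horizontal when seated
    q0 = quat.from_axis_angle([0, 1, 0], pitch)
    if activity.lumbar_pitch_rad:
        if location == "lower_back":
            q0 = quat.multiply(
                quat.from_axis_angle([0, 1, 0], activity.lumbar_pitch_rad), q0
            )
        elif location == "upper_back":
            q0 = quat.multiply(
                quat.from_axis_angle(
                    [0, 1, 0], UPPER_BACK_LUMBAR_COUPLING * activity.lumbar_pitch_rad
                ),
                q0,
            )
    offset = params.baseline_orientation_offset.get(location)
    if offset is not None:
        q0 = quat.multiply(q0, _euler_quat(*offset))
    return q0


def _motion_components(activity: ActivityClass, location: str,
                       params: ParticipantParams, t: np.ndarray,
                       mod: np.ndarray, dmod: np.ndarray):
    """Yield (axis, angle(t), dangle(t)) rotation components about q0.

    ``mod``/``dmod`` is a slow multiplicative execution-jitter envelope
    (people do not perform repetitions identically); it multiplies the
    movement angle, so the analytic derivative uses the product rule.
    """
    if activity.kind == "adl":
        gain = GAIT_GAIN.get(location, 0.1)
        f_stride = 0.9 / params.period_scale  # Hz
        w = 2 * np.pi * f_stride
        phase = params.phase_offset
        lag = {"right_ankle": np.pi, "left_thigh": 0.0}.get(location, np.pi / 3)
        swing = np.deg2rad(28.0) * params.amplitude_scale * gain
        base = np.sin(w * t + phase + lag)
        dbase = w * np.cos(w * t + phase + lag)
        yield (
            _PLANE_AXIS["sagittal"],
            swing * mod * base,
            swing * (dmod * base + mod * dbase),
        )
        sway = np.deg2rad(6.0) * params.amplitude_scale * gain
        yield (
            _PLANE_AXIS["frontal"],
            sway * np.sin(0.5 * w * t + phase),
            sway * 0.5 * w * np.cos(0.5 * w * t + phase),
        )
        return
    if activity.kind != "dynamic_exercise":
        return
    axis = _PLANE_AXIS[activity.motion_plane]
    gain = LOCATION_GAIN.get(location, 0.3)
    amp = activity.amplitude_rad * params.amplitude_scale * gain
    freq = activity.n_reps / activity.duration_s / params.period_scale
    w = 2 * np.pi * freq
    ph = params.phase_offset * 0.2  # mild phase variability between participants
    if activity.signed_excursion:
        # move to end range and back: angle stays on one side of neutral
        base = 0.5 * (1.0 - np.cos(w * t + ph) * np.cos(ph))
        dbase = 0.5 * w * np.sin(w * t + ph) * np.cos(ph)
    else:
        base = np.sin(w * t + ph)
        dbase = w * np.cos(w * t + ph)
    yield (axis, amp * mod * base, amp * (dmod * base + mod * dbase))


def orientation_trajectory(
    activity: ActivityClass,
    location: str,
    params: ParticipantParams,
    seed: int = 0,
) -> QuaternionSeries:
    """Simulate the 50 Hz orientation of one device for one activity.

    Dynamic classes produce a quasi-sinusoidal rotation about the
    plane-appropriate axis; static/posture classes produce a constant
    orientation; the ADL class produces a gait-like mixture dominated
    by the lower limbs.  Deterministic given all arguments.
    """
    if location not in LOCATIONS:
        raise ConfigurationError(f"unknown location {location!r}")
    n = int(round(activity.duration_s * QUAT_RATE_HZ)) + 1
    t = np.arange(n) / QUAT_RATE_HZ
    rng = np.random.default_rng(seed)
    q0 = _base_orientation(activity, location, params)

    # free-limb devices: arm/head placement is only loosely coupled to
    # the activity, so each recording draws its own mounting offset
    free_sd = FREE_LIMB_ORIENT_SD.get(location)
    if free_sd is not None:
        q0 = quat.multiply(q0, _euler_quat(*rng.normal(0.0, free_sd, size=3)))

    # slow execution-jitter envelope shared by this recording's movement
    jit_depth = rng.uniform(0.05, 0.20)
    jit_freq = rng.uniform(0.05, 0.12)  # Hz, slower than any repetition
    jit_phase = rng.uniform(-np.pi, np.pi)
    w_j = 2 * np.pi * jit_freq
    mod = 1.0 + jit_depth * np.sin(w_j * t + jit_phase)
    dmod = jit_depth * w_j * np.cos(w_j * t + jit_phase)

    q = np.broadcast_to(q0, (n, 4)).copy()
    qdot = np.zeros((n, 4))
    lin = np.zeros((n, 3))
    for axis, angle, dangle in _motion_components(activity, location, params, t, mod, dmod):
        dq = quat.from_axis_angle(axis, angle)
        ddq = quat.axis_angle_derivative(axis, angle, dangle)
        # product rule across successive components: d(dq ⊗ q) = ddq⊗q + dq⊗qdot
        qdot = quat.multiply(ddq, q) + quat.multiply(dq, qdot)
        q = quat.multiply(dq, q)
        # class-dependent linear acceleration: tangential term of the
        # segment swinging on an effective lever, in the horizontal
        # earth plane of the motion axis
        horiz = np.array([axis[1], axis[0], 0.0])
        if np.linalg.norm(horiz) > 0:
            # second derivative of angle for the two supported profiles
            d2angle = np.gradient(dangle, 1.0 / QUAT_RATE_HZ)
            lin += activity.lever_m * d2angle[:, None] * horiz[None, :]
    if activity.kind == "adl":
        gain = GAIT_GAIN.get(location, 0.1)
        w = 2 * np.pi * 2 * 0.9 / params.period_scale  # vertical bob at step rate
        lin[:, 2] += -1.8 * gain * params.amplitude_scale * np.sin(
            w * t + params.phase_offset
        )
    return QuaternionSeries(timestamps=t, values=quat.normalize(q),
                            qdot=qdot, lin_accel_earth=lin)


def _resample_to(values: np.ndarray, t_src: np.ndarray, rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    span = t_src[-1] - t_src[0]
    n_out = int(np.floor(span * rate_hz + 1e-9)) + 1
    grid = t_src[0] + np.arange(n_out) / rate_hz
    out = np.empty((n_out, values.shape[1]))
    for j in range(values.shape[1]):
        out[:, j] = np.interp(grid, t_src, values[:, j])
    return grid, out


def synthesize_channels(
    orientation: QuaternionSeries,
    activity: ActivityClass,
    noise: NoiseModel,
    seed: int = 0,
    *,
    location: str = "lower_back",
    noise_scale: float = 1.0,
    heading_rad: float | None = None,
) -> list[SensorStream]:
    """Derive the five raw sensor streams of one device from its orientation.

    Gyroscope: vector part of ``2 qdot ⊗ q*`` at 25 Hz.  Accelerometer:
    specific force (earth-frame linear acceleration minus gravity,
    rotated into the sensor frame) at 25 Hz.  Magnetometer: fixed earth
    field rotated into the sensor frame at 25 Hz.  Quaternion channel:
    the fused orientation plus slow random-walk drift at 50 Hz.
    Pressure: barometric baseline plus session bias at 13 Hz.  White
    noise and biases follow the NoiseModel scaled by ``noise_scale``.

    ``heading_rad`` is the participant's facing direction for this
    recording (drawn uniformly when None): gravity-referenced channels
    are unaffected, but the magnetometer and the north-referenced
    fused quaternion see it, which is what makes absolute-yaw features
    unreliable across recordings, as they are in real sessions.
    """
    q = orientation.values
    t = orientation.timestamps
    if q.shape[0] < 2:
        raise ValidationError("orientation series must have at least 2 samples")
    dt = t[1] - t[0]
    qdot = orientation.qdot
    if qdot is None:
        qdot = np.gradient(q, dt, axis=0)
    lin = orientation.lin_accel_earth
    if lin is None:
        lin = np.zeros((q.shape[0], 3))

    rng = _child_rng(seed, "channels", location, activity.name)
    ns = noise_scale
    if heading_rad is None:
        heading_rad = float(rng.uniform(-np.pi, np.pi))
    q_head = quat.from_axis_angle([0, 0, 1], heading_rad)
    # earth->sensor including the facing direction (earth->body-aligned
    # frame is a yaw; kinematics were generated in the body-aligned frame)
    q_ns = quat.multiply(q, np.broadcast_to(q_head, q.shape))

    # ambient magnetic disturbance (hard iron / building steel), drawn
    # once per recording in the earth frame; it corrupts the raw
    # magnetometer AND the fused heading, which is magnetometer-slaved
    mag_dist = (
        rng.normal(0.0, noise.mag_disturbance_sd * ns, size=3)
        if noise.mag_disturbance_sd > 0
        else np.zeros(3)
    )

    omega = quat.angular_velocity(q, qdot)
    f_earth = lin + np.array([0.0, 0.0, -GRAVITY])
    accel = quat.rotate(q, f_earth)
    b_earth = MAG_FIELD_UT * np.array(
        [np.cos(MAG_DIP_RAD), 0.0, np.sin(MAG_DIP_RAD)]
    ) + mag_dist
    mag = quat.rotate(q_ns, np.broadcast_to(b_earth, (q.shape[0], 3)))

    streams: list[SensorStream] = []
    for channel, values in (("accelerometer", accel), ("gyroscope", omega),
                            ("magnetometer", mag)):
        rate = CHANNEL_RATES[channel]
        grid, resampled = _resample_to(values, t, rate)
        sd = {"accelerometer": noise.accel_sd, "gyroscope": noise.gyro_sd,
              "magnetometer": noise.mag_sd}[channel]
        bias_sd = {"accelerometer": noise.accel_bias_sd,
                   "gyroscope": noise.gyro_bias_sd,
                   "magnetometer": noise.mag_bias_sd}[channel]
        bias = rng.normal(0.0, bias_sd * ns, size=3) if bias_sd > 0 else np.zeros(3)
        noisy = resampled + bias
        if sd > 0:
            noisy = noisy + rng.normal(0.0, sd * ns, size=resampled.shape)
        streams.append(SensorStream(location, channel, rate, grid, noisy))

    # fused quaternion channel: the sensor-fusion heading is slaved to
    # the (disturbed) local magnetic north, so the disturbance shows up
    # as a per-recording yaw error; on top of that, slow random-walk
    # drift accumulates between calibrations
    q_out = q_ns
    if noise.mag_disturbance_sd > 0:
        b_h = MAG_FIELD_UT * np.cos(MAG_DIP_RAD)
        yaw_err = np.arctan2(mag_dist[1], b_h + mag_dist[0])
        q_out = quat.multiply(q_out, quat.from_axis_angle([0, 0, 1], yaw_err))
    if noise.quat_drift_rad_per_sqrt_s > 0:
        step_sd = noise.quat_drift_rad_per_sqrt_s * ns * np.sqrt(dt)
        walk = np.cumsum(rng.normal(0.0, step_sd, size=(q.shape[0], 3)), axis=0)
        half = 0.5 * walk
        drift = np.concatenate(
            [np.cos(np.linalg.norm(half, axis=1, keepdims=True)),
             np.sinc(np.linalg.norm(half, axis=1, keepdims=True) / np.pi) * half],
            axis=1,
        )
        q_out = quat.normalize(quat.multiply(drift, q_out))
    streams.append(SensorStream(location, "quaternion", QUAT_RATE_HZ, t.copy(), q_out))

    # barometer: baseline + per-session bias + white noise (the default
    # protocol's activities are all floor-level, so elevation is not
    # modeled and this channel carries no class information)
    rate_p = CHANNEL_RATES["pressure"]
    n_p = int(np.floor((t[-1] - t[0]) * rate_p + 1e-9)) + 1
    t_p = t[0] + np.arange(n_p) / rate_p
    p_bias = rng.normal(0.0, noise.pressure_bias_sd * ns) if noise.pressure_bias_sd > 0 else 0.0
    p = np.full((n_p, 1), PRESSURE_BASELINE_PA + p_bias)
    if noise.pressure_sd > 0:
        p = p + rng.normal(0.0, noise.pressure_sd * ns, size=p.shape)
    streams.append(SensorStream(location, "pressure", rate_p, t_p, p))
    return streams


def draw_participants(
    n_participants: int, seed: int = 0,
    locations: Sequence[str] = LOCATIONS,
    amplitude_sigma: float = 0.15,
    period_sigma: float = 0.10,
    offset_sd_deg: float = 5.0,
    noise_sigma: float = 0.10,
) -> list[ParticipantParams]:
    """Draw per-participant random effects.

    amplitude_scale ~ LogNormal(0, amplitude_sigma), period_scale ~
    LogNormal(0, period_sigma), baseline mounting offsets ~ Normal(0,
    offset_sd_deg) per axis and location, phase ~ Uniform(-pi, pi),
    noise_scale ~ LogNormal(0, noise_sigma).  Sex is assigned to
    emulate a 12:7 male:female cohort ratio.
    """
    n_male = int(round(n_participants * 12 / 19))
    out = []
    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        rng = _child_rng(seed, "participant", pid)
        offsets = {
            loc: tuple(rng.normal(0.0, np.deg2rad(offset_sd_deg), size=3))
            for loc in locations
        }
        out.append(
            ParticipantParams(
                participant_id=pid,
                amplitude_scale=float(rng.lognormal(0.0, amplitude_sigma)),
                period_scale=float(rng.lognormal(0.0, period_sigma)),
                phase_offset=float(rng.uniform(-np.pi, np.pi)),
                noise_scale=float(rng.lognormal(0.0, noise_sigma)),
                sex="M" if i < n_male else "F",
                baseline_orientation_offset=offsets,
            )
        )
    return out


def protocol_from_config(entries: Sequence[dict]) -> list[ActivityClass]:
    """Build a protocol from config dicts (angles given in degrees)."""
    out = []
    for entry in entries:
        kw = dict(entry)
        for deg_key, rad_key in (("amplitude_deg", "amplitude_rad"),
                                 ("lumbar_pitch_deg", "lumbar_pitch_rad")):
            if deg_key in kw:
                kw[rad_key] = float(np.deg2rad(kw.pop(deg_key)))
        out.append(ActivityClass(**kw))
    return out


def simulate_dataset(
    n_participants: int = 19,
    protocol: Sequence[ActivityClass] | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    locations: Sequence[str] = LOCATIONS,
    participant_effects: dict | None = None,
) -> Dataset:
    """Simulate one recording per participant x activity.

    Fully deterministic given ``seed``: participant effects and every
    per-recording noise draw come from child generators derived by
    stable hashing of (seed, participant, activity, location).
    ``participant_effects`` overrides the effect hyperparameters of
    :func:`draw_participants`.
    """
    if n_participants < 1:
        raise ConfigurationError("n_participants must be >= 1")
    protocol = list(protocol) if protocol is not None else default_protocol()
    if not protocol:
        raise ConfigurationError("protocol must contain at least one activity")
    noise = noise if noise is not None else NoiseModel()
    participants = draw_participants(n_participants, seed, locations,
                                     **(participant_effects or {}))

    recordings = []
    for params in participants:
        for activity in protocol:
            streams: list[SensorStream] = []
            rec_rng = _child_rng(seed, params.participant_id, activity.name)
            heading = float(rec_rng.uniform(-np.pi, np.pi))
            for loc in locations:
                child = _child_rng(seed, params.participant_id, activity.name, loc)
                sub_seed = int(child.integers(0, 2**31 - 1))
                traj = orientation_trajectory(activity, loc, params, sub_seed)
                streams.extend(
                    synthesize_channels(
                        traj, activity, noise, sub_seed,
                        location=loc, noise_scale=params.noise_scale,
                        heading_rad=heading,
                    )
                )
            recordings.append(
                Recording(
                    participant_id=params.participant_id,
                    label=activity.name,
                    streams=streams,
                )
            )
    meta = {
        "seed": seed,
        "n_participants": n_participants,
        "locations": list(locations),
        "protocol": [a.name for a in protocol],
        "participants": {
            p.participant_id: {"sex": p.sex, "amplitude_scale": p.amplitude_scale,
                               "period_scale": p.period_scale}
            for p in participants
        },
    }
    return Dataset(recordings=recordings, metadata=meta)
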