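"""Synthetic multi-subject, multi-activity articulated motion.

The generator emulates the statistical structure a sparse-sensor pose
estimator relies on: joint angles across the whole body are driven by a
shared periodic phase (plus per-joint harmonics), so the five instrumented
segments carry enough information to recover the remaining eighteen — the
"redundancy of human motion" assumption holds by construction.  Subjects
differ systematically: each subject draws its own fundamental frequency,
per-joint amplitudes and phase offsets once, making subject-wise
cross-validation meaningful.

Three activity classes with distinct dynamics are provided:

``gait``
    cyclic locomotion, contralateral anti-phase arm/leg swing, forward
    pelvis progression with double-support vertical bobbing;
``sports``
    high-dynamic movement (larger excursions at higher fundamental
    frequency, ballistic vertical pelvis excursions);
``adl``
    activities of daily living: slow, small-amplitude reaching/posture
    changes, near-stationary pelvis.

Raw kinematics are synthesized at ``fs_raw`` (default 240 Hz) from sums of
harmonics (infinitely differentiable), sensor accelerations are derived from
the global motion by exact finite differencing, measurement noise is applied
last, and sequences are decimated to the working rate (default 60 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from . import quatkin
from .quatkin import (
    SEGMENTS,
    SEGMENT_INDEX,
    SENSOR_SEGMENTS,
    Skeleton,
    axis_angle_quat,
    default_skeleton,
    qconj,
    qmul,
    qnormalize,
    rotate_vec,
)
from .windowing import downsample

__all__ = [
    "SyntheticConfig",
    "MotionSequence",
    "generate_subject",
    "generate_dataset",
    "simulate_sensor_accelerations",
    "GRAVITY",
]

#: Global gravity vector, z-up, m/s^2.
GRAVITY = np.array([0.0, 0.0, -9.81])

# Per-class motion parameters: fundamental frequency range (Hz), overall
# excursion scale multiplier, harmonic count, pelvis trajectory style.
# Velocity scale ~ amplitude x frequency: sports >= 2x gait by construction;
# adl fundamental <= 0.5x gait's.
_CLASS_PARAMS = {
    "gait": dict(f0=(0.85, 1.05), amp_scale=1.0, harmonics=2, speed=1.2, bob=0.025, jump=0.0),
    "sports": dict(f0=(1.30, 1.70), amp_scale=1.9, harmonics=3, speed=1.8, bob=0.03, jump=0.18),
    "adl": dict(f0=(0.28, 0.42), amp_scale=0.55, harmonics=2, speed=0.1, bob=0.005, jump=0.0),
}

# Primary rotation axis and base amplitude (rad) per joint; y = pitch axis
# (sagittal-plane flexion), z = yaw, x = roll.  Right-side sagittal swings
# are anti-phase to left-side ones (contralateral coordination).
_JOINT_MOTION = {
    # segment: (axis, base amplitude rad, phase lag vs stride phase)
    "L5": ("z", 0.06, 0.0),
    "L3": ("z", 0.06, 0.0),
    "T12": ("z", 0.07, 0.0),
    "T8": ("z", 0.08, 0.0),
    "Neck": ("y", 0.06, 0.0),
    "Head": ("y", 0.05, 0.0),
    "RightShoulder": ("y", 0.06, 0.0),
    "RightUpperArm": ("y", 0.35, 0.0),
    "RightForearm": ("y", 0.40, 0.35),
    "RightHand": ("y", 0.10, 0.5),
    "LeftShoulder": ("y", 0.06, np.pi),
    "LeftUpperArm": ("y", 0.35, np.pi),
    "LeftForearm": ("y", 0.40, np.pi + 0.35),
    "LeftHand": ("y", 0.10, np.pi + 0.5),
    # legs: right leg in phase with LEFT arm (contralateral gait pattern)
    "RightUpperLeg": ("y", 0.45, np.pi),
    "RightLowerLeg": ("y", 0.55, np.pi + 0.45),
    "RightFoot": ("y", 0.25, np.pi + 0.7),
    "RightToe": ("y", 0.10, np.pi + 0.9),
    "LeftUpperLeg": ("y", 0.45, 0.0),
    "LeftLowerLeg": ("y", 0.55, 0.45),
    "LeftFoot": ("y", 0.25, 0.7),
    "LeftToe": ("y", 0.10, 0.9),
}

_AXES = {"x": np.array([1.0, 0.0, 0.0]), "y": np.array([0.0, 1.0, 0.0]), "z": np.array([0.0, 0.0, 1.0])}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults emulate a six-subject movement study."""

    n_subjects: int = 6
    trials: Tuple[Tuple[str, float], ...] = (("gait", 60.0),)  # (class, seconds)
    fs_raw: float = 240.0
    downsample_factor: int = 4
    stature_range: Tuple[float, float] = (1.60, 1.95)
    excursion_scale: float = 1.0  # multiplies every class's excursion amplitudes
    orientation_noise_deg: float = 0.5
    accel_noise_std: float = 0.2  # m/s^2
    smooth_noise_rad: float = 0.02  # low-frequency joint-angle wander
    smooth_noise_hz: float = 0.15
    seed: int = 0

    def __post_init__(self):
        for activity, dur in self.trials:
            if activity not in _CLASS_PARAMS:
                raise ValueError(f"unknown activity class {activity!r}")
            if dur <= 0:
                raise ValueError("trial duration must be positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")


@dataclass
class MotionSequence:
    """Per-subject, per-trial time series of global segment orientations.

    ``quaternions`` is ``(n, 23, 4)`` in canonical segment order (global
    frame, body-to-global); ``accelerations`` is ``(n, 5, 3)`` sensor-frame
    specific force for the five instrumented segments (order of
    ``SENSOR_SEGMENTS``); ``pelvis_position`` is the global pelvis
    trajectory in metres when known.
    """

    subject_id: str
    activity_label: str
    fs: float
    quaternions: np.ndarray
    accelerations: Optional[np.ndarray] = None
    pelvis_position: Optional[np.ndarray] = None
    stature_m: float = 1.75

    def __post_init__(self):
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        if self.quaternions.ndim != 3 or self.quaternions.shape[1:] != (23, 4):
            raise ValueError("quaternions must have shape (n, 23, 4)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = len(self.quaternions)
        if self.accelerations is not None:
            self.accelerations = np.asarray(self.accelerations, dtype=float)
            if self.accelerations.shape != (n, 5, 3):
                raise ValueError("accelerations must have shape (n, 5, 3)")
        if self.pelvis_position is not None:
            self.pelvis_position = np.asarray(self.pelvis_position, dtype=float)
            if self.pelvis_position.shape != (n, 3):
                raise ValueError("pelvis_position must have shape (n, 3)")

    @property
    def n_frames(self) -> int:
        return len(self.quaternions)


def _subject_rng(seed: int, subject_index: int, trial_index: int = 0) -> np.random.Generator:
    """Deterministic stream per (seed, subject, trial)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(subject_index, trial_index))
    )


def _slow_wander(rng, n: int, fs: float) -> np.ndarray:
    """Smooth intensity profile in [-1, 1]-ish: a few very-low-frequency
    sinusoids (10-30 s periods) emulating walk/jog/sprint-like sections."""
    t = np.arange(n) / fs
    out = np.zeros(n)
    for _ in range(3):
        f = rng.uniform(0.03, 0.1)
        out += rng.uniform(0.3, 0.7) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return np.clip(out, -1.0, 1.0)


def _smooth_noise(rng, n: int, fs: float, amp: float, bandwidth_hz: float) -> np.ndarray:
    """Band-limited smooth wander: a few random low-frequency sinusoids."""
    if amp == 0.0:
        return np.zeros(n)
    t = np.arange(n) / fs
    out = np.zeros(n)
    for _ in range(3):
        f = rng.uniform(0.02, bandwidth_hz)
        out += rng.normal(0.0, amp / np.sqrt(3)) * np.sin(
            2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)
        )
    return out


def _joint_angles(rng, params, n: int, fs: float, cfg: SyntheticConfig):
    """Per-segment joint-angle time series (rad) driven by a shared phase.

    The coordination pattern (phase lags between joints, harmonic phases) is
    a class-level constant; subjects differ in fundamental frequency, an
    overall excursion factor and mild per-joint amplitude/phase jitter.
    This keeps the inter-joint coupling shared across subjects — the
    redundancy a sparse-sensor estimator exploits — while making held-out
    subjects genuinely new.
    """
    t = np.arange(n) / fs
    f0 = rng.uniform(*params["f0"])
    phase0 = rng.uniform(0, 2 * np.pi)
    # trials sweep through intensities (walk/jog/sprint-like sections):
    # tempo and whole-body excursion drift slowly within the trial, so each
    # subject covers a band of dynamics rather than a single operating point
    tempo = 1.0 + 0.25 * _slow_wander(rng, n, fs)
    envelope = 1.0 + 0.25 * _slow_wander(rng, n, fs)
    theta = phase0 + 2 * np.pi * np.cumsum(f0 * tempo) / fs
    subject_factor = rng.uniform(0.85, 1.15)  # one draw for the whole body
    angles = {}
    params["_theta"] = theta
    params["_envelope"] = envelope
    params["_subject_factor"] = subject_factor
    for seg, (axis, base_amp, lag) in _JOINT_MOTION.items():
        amp = base_amp * params["amp_scale"] * subject_factor * rng.uniform(0.92, 1.08)
        series = amp * np.sin(theta - lag + rng.normal(0.0, 0.05))
        for k in range(2, params["harmonics"] + 1):
            # fixed per-harmonic phase offset + small subject jitter
            series += (amp / (2.0 ** (k - 1))) * np.sin(
                k * (theta - lag) + 0.9 * k + rng.normal(0.0, 0.1)
            )
        series = envelope * series
        series += _smooth_noise(rng, n, fs, cfg.smooth_noise_rad, cfg.smooth_noise_hz)
        angles[seg] = (axis, series)
    return angles, f0


def _pelvis_motion(rng, params, n: int, fs: float):
    """Global pelvis orientation (n, 4), trajectory (n, 3) and roll series.

    All pelvis motion is phase-locked to the stride phase with class-level
    lags (plus mild subject jitter): pelvic rotation, list and the vertical
    bob are features of the movement cycle, not independent oscillators.
    """
    t = np.arange(n) / fs
    theta = params["_theta"]
    env = params.get("_envelope", 1.0)
    amp = params["amp_scale"] * params.get("_subject_factor", 1.0) * env
    heading = rng.uniform(0, 2 * np.pi)
    yaw = heading + 0.08 * amp * np.sin(theta + 0.6 + rng.normal(0.0, 0.1))
    roll = 0.05 * amp * np.sin(theta + 2.1 + rng.normal(0.0, 0.1))
    q_yaw = axis_angle_quat(_AXES["z"], yaw)
    q_roll = axis_angle_quat(_AXES["x"], roll)
    quat = qmul(q_yaw, q_roll)

    direction = np.array([np.cos(heading), np.sin(heading), 0.0])
    pos = np.outer(params["speed"] * t, direction)
    pos[:, 2] = 1.0 + params["bob"] * env * np.sin(2.0 * theta + 1.2 + rng.normal(0.0, 0.1))
    if params["jump"] > 0.0:
        pos[:, 2] += params["jump"] * env**2 * np.sin(0.5 * theta + rng.normal(0.0, 0.1)) ** 2
    return quat, pos, roll


def generate_subject(cfg: SyntheticConfig, subject_index: int) -> List[MotionSequence]:
    """All trials for one subject at the raw rate, noise applied.

    Deterministic given ``(cfg.seed, subject_index)``: the random stream for
    each trial is keyed on exactly those values.
    """
    out = []
    stature_rng = _subject_rng(cfg.seed, subject_index, trial_index=10_000)
    stature = stature_rng.uniform(*cfg.stature_range)
    skel = default_skeleton(stature)
    for trial_index, (activity, duration_s) in enumerate(cfg.trials):
        rng = _subject_rng(cfg.seed, subject_index, trial_index)
        n = int(round(duration_s * cfg.fs_raw))
        params = dict(_CLASS_PARAMS[activity])
        params["amp_scale"] *= cfg.excursion_scale
        angles, f0 = _joint_angles(rng, params, n, cfg.fs_raw, cfg)
        params["_f0"] = f0
        q_pelvis, pelvis_pos, roll = _pelvis_motion(rng, params, n, cfg.fs_raw)

        quats = np.empty((n, 23, 4))
        quats[:, SEGMENT_INDEX["Pelvis"]] = q_pelvis
        for seg in SEGMENTS[1:]:
            axis, series = angles[seg]
            q_joint = axis_angle_quat(_AXES[axis], series)
            # head stabilization: neck/head counter-rotate against pelvic
            # list so the head stays closer to vertical
            if seg in ("Neck", "Head"):
                q_joint = qmul(q_joint, axis_angle_quat(_AXES["x"], -0.4 * roll))
            parent = quats[:, SEGMENT_INDEX[quatkin._PARENT[seg]]]
            quats[:, SEGMENT_INDEX[seg]] = qmul(parent, q_joint)

        seq = MotionSequence(
            subject_id=f"S{subject_index}",
            activity_label=activity,
            fs=cfg.fs_raw,
            quaternions=quats,
            pelvis_position=pelvis_pos,
            stature_m=stature,
        )
        seq.accelerations = simulate_sensor_accelerations(seq, skel, cfg.fs_raw)
        _apply_noise(seq, rng, cfg)
        out.append(seq)
    return out


def _apply_noise(seq: MotionSequence, rng, cfg: SyntheticConfig) -> None:
    """Measurement noise: small random rotations on every segment
    orientation, additive white noise on sensor accelerations."""
    if cfg.orientation_noise_deg > 0.0:
        sigma = np.deg2rad(cfg.orientation_noise_deg)
        axes = rng.normal(size=seq.quaternions.shape[:-1] + (3,))
        axes /= np.linalg.norm(axes, axis=-1, keepdims=True)
        angs = rng.normal(0.0, sigma, size=seq.quaternions.shape[:-1])
        seq.quaternions = qnormalize(qmul(axis_angle_quat(axes, angs), seq.quaternions))
    if seq.accelerations is not None and cfg.accel_noise_std > 0.0:
        seq.accelerations = seq.accelerations + rng.normal(
            0.0, cfg.accel_noise_std, size=seq.accelerations.shape
        )


def simulate_sensor_accelerations(
    seq: MotionSequence, skel: Skeleton, fs: float
) -> np.ndarray:
    """Specific force each of the five sensors would measure, (n, 5, 3).

    Global sensor positions come from the pelvis trajectory plus forward
    kinematics with the *global* orientations; linear acceleration is a
    second central difference; gravity is subtracted (an accelerometer at
    rest reads the upward reaction ``-g``); the result is rotated into each
    sensor's own frame.  End frames are padded by repetition.
    """
    n = seq.n_frames
    if n < 5:
        raise ValueError("need at least 5 frames to simulate accelerations")
    quats = seq.quaternions
    pelvis_pos = (
        seq.pelvis_position if seq.pelvis_position is not None else np.zeros((n, 3))
    )
    parents = skel.parent_index
    offsets = skel.offsets_array
    # global FK (root at the pelvis trajectory, global orientations)
    pos = np.zeros((n, 23, 3))
    pos[:, 0] = pelvis_pos
    for i in range(1, 23):
        p = parents[i]
        pos[:, i] = pos[:, p] + rotate_vec(quats[:, p], offsets[i])

    h = 1.0 / fs
    sensor_idx = [SEGMENT_INDEX[s] for s in SENSOR_SEGMENTS]
    acc = np.empty((n, 5, 3))
    p_s = pos[:, sensor_idx]  # (n, 5, 3)
    lin = np.empty_like(p_s)
    lin[1:-1] = (p_s[2:] - 2 * p_s[1:-1] + p_s[:-2]) / h**2
    lin[0] = lin[1]
    lin[-1] = lin[-2]
    for j, si in enumerate(sensor_idx):
        q = quats[:, si]
        acc[:, j] = rotate_vec(qconj(q), lin[:, j] - GRAVITY)
    return acc


def generate_dataset(cfg: SyntheticConfig) -> List[MotionSequence]:
    """All subjects x trials, decimated to ``fs_raw / downsample_factor``.

    Returns sequences with noise applied after the clean kinematics; the
    manifest of seeds/parameters is the (frozen) ``cfg`` itself, which the
    io module serializes alongside written datasets.
    """
    out = []
    for s in range(cfg.n_subjects):
        for seq in generate_subject(cfg, s):
            out.append(downsample(seq, cfg.downsample_factor))
    return out
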