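"""Pelvis-relative input features from the five sensor-bearing segments.

Per frame, the features for one body half are the two distal-limb
orientations expressed relative to the pelvis (2 quaternions = 8 values,
left limb first), optionally followed by the two pelvis-relative
accelerations (2 x 3 = 6 values, 14 total).

The acceleration pipeline rotates each sensor-frame specific force to the
global frame using that sensor's orientation, subtracts the pelvis sensor's
global acceleration (which cancels gravity and any common-mode motion), and
rotates the difference into the pelvis frame.  Every feature is therefore
invariant to rigid rotation of the whole body in the world.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .quatkin import (
    SENSOR_SEGMENTS,
    UPPER_OUTPUT_SEGMENTS,
    LOWER_OUTPUT_SEGMENTS,
    SEGMENT_INDEX,
    canonicalize_sequence,
    qconj,
    qmul,
    qrelative,
    rotate_vec,
)

__all__ = [
    "SensorFrame",
    "FeatureFrame",
    "orientation_features",
    "acceleration_features",
    "build_feature_sequence",
    "feature_matrix",
    "pose_targets",
    "LIMB_PAIRS",
]

#: limb pair -> (left segment, right segment)
LIMB_PAIRS = {
    "upper": ("LeftForearm", "RightForearm"),
    "lower": ("LeftLowerLeg", "RightLowerLeg"),
}

_SENSOR_INDEX = {s: i for i, s in enumerate(SENSOR_SEGMENTS)}


@dataclass
class SensorFrame:
    """Global orientations (and optional sensor-frame specific forces) of
    the five instrumented segments at one time sample."""

    orientations: dict  # sensor segment -> (4,) global quaternion
    accelerations: Optional[dict] = None  # sensor segment -> (3,) m/s^2, sensor frame
    timestamp_index: int = 0
    fs: float = 60.0

    def __post_init__(self):
        if set(self.orientations) != set(SENSOR_SEGMENTS):
            raise ValueError(
                f"sensor frame must contain exactly {SENSOR_SEGMENTS}"
            )
        for seg, q in self.orientations.items():
            q = np.asarray(q, dtype=float)
            if abs(np.linalg.norm(q) - 1.0) > 1e-6:
                raise ValueError(f"non-unit sensor quaternion for {seg}")
            self.orientations[seg] = q
        if self.accelerations is not None:
            if set(self.accelerations) != set(SENSOR_SEGMENTS):
                raise ValueError("accelerations must cover all five sensor segments")
            self.accelerations = {
                s: np.asarray(a, dtype=float) for s, a in self.accelerations.items()
            }


@dataclass
class FeatureFrame:
    """Per-frame features for one body half (upper or lower)."""

    limb_pair: str  # "upper" | "lower"
    rel_orientations: np.ndarray  # (2, 4): left, right limb vs pelvis
    rel_accelerations: Optional[np.ndarray] = None  # (2, 3) pelvis frame, m/s^2

    @property
    def dimensionality(self) -> int:
        return 8 + (6 if self.rel_accelerations is not None else 0)

    def as_vector(self) -> np.ndarray:
        parts = [self.rel_orientations.reshape(-1)]
        if self.rel_accelerations is not None:
            parts.append(self.rel_accelerations.reshape(-1))
        return np.concatenate(parts)


def orientation_features(frame: SensorFrame, limb_pair: str) -> FeatureFrame:
    """Pelvis-relative orientations of the selected limb pair, left first."""
    left, right = _limb_segments(limb_pair)
    q_pelvis = frame.orientations["Pelvis"]
    rel = np.stack(
        [
            qrelative(q_pelvis, frame.orientations[left]),
            qrelative(q_pelvis, frame.orientations[right]),
        ]
    )
    return FeatureFrame(limb_pair=limb_pair, rel_orientations=rel)


def acceleration_features(frame: SensorFrame, limb_pair: str) -> np.ndarray:
    """Pelvis-relative limb accelerations, (2, 3), left limb first.

    Each sensor acceleration is rotated to the global frame, the pelvis
    acceleration is subtracted (removing gravity and common-mode motion),
    and the result is rotated into the pelvis frame.
    """
    if frame.accelerations is None:
        raise ValueError("sensor frame carries no accelerations")
    left, right = _limb_segments(limb_pair)
    q_pelvis = frame.orientations["Pelvis"]
    a_g_pelvis = rotate_vec(q_pelvis, frame.accelerations["Pelvis"])
    out = []
    for seg in (left, right):
        a_g = rotate_vec(frame.orientations[seg], frame.accelerations[seg])
        out.append(rotate_vec(qconj(q_pelvis), a_g - a_g_pelvis))
    return np.stack(out)


def build_feature_sequence(frames, limb_pair: str, use_accel: bool = False):
    """FeatureFrames for a time-ordered sensor sequence.

    Relative orientations are canonicalized as a temporal sequence so that
    consecutive feature vectors never jump across the quaternion double
    cover; dimensionality is constant across the output.
    """
    frames = list(frames)
    if not frames:
        return []
    if use_accel and any(f.accelerations is None for f in frames):
        raise ValueError("use_accel requires accelerations in every frame")
    feats = [orientation_features(f, limb_pair) for f in frames]
    rel = canonicalize_sequence(np.stack([f.rel_orientations for f in feats]))
    out = []
    for t, f in enumerate(frames):
        accel = acceleration_features(f, limb_pair) if use_accel else None
        out.append(
            FeatureFrame(
                limb_pair=limb_pair,
                rel_orientations=rel[t],
                rel_accelerations=accel,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Array fast paths used by the training/evaluation pipeline
# ---------------------------------------------------------------------------

def feature_matrix(seq, limb_pair: str, use_accel: bool = False) -> np.ndarray:
    """(n, D) feature matrix for a MotionSequence (D = 8 or 14).

    Columns: left-limb quaternion (4), right-limb quaternion (4), then, when
    ``use_accel``, left and right pelvis-relative accelerations (3 + 3).
    """
    left, right = _limb_segments(limb_pair)
    quats = seq.quaternions  # (n, 23, 4), global frame
    q_pelvis = quats[:, SEGMENT_INDEX["Pelvis"]]
    rel = np.stack(
        [
            qmul(qconj(q_pelvis), quats[:, SEGMENT_INDEX[left]]),
            qmul(qconj(q_pelvis), quats[:, SEGMENT_INDEX[right]]),
        ],
        axis=1,
    )  # (n, 2, 4)
    rel = canonicalize_sequence(rel)
    parts = [rel.reshape(len(quats), 8)]
    if use_accel:
        if seq.accelerations is None:
            raise ValueError("sequence carries no accelerations")
        acc = seq.accelerations  # (n, 5, 3), sensor frames
        a_g_pelvis = rotate_vec(q_pelvis, acc[:, _SENSOR_INDEX["Pelvis"]])
        rels = []
        for segname in (left, right):
            q_seg = quats[:, SEGMENT_INDEX[segname]]
            a_g = rotate_vec(q_seg, acc[:, _SENSOR_INDEX[segname]])
            rels.append(rotate_vec(qconj(q_pelvis), a_g - a_g_pelvis))
        parts.append(np.concatenate(rels, axis=1))
    return np.concatenate(parts, axis=1)


def pose_targets(seq, body_half: str) -> np.ndarray:
    """(n, 4*m) regression targets: pelvis-relative output-segment
    quaternions, canonicalized in time (m = 12 upper, 6 lower)."""
    segs = (
        UPPER_OUTPUT_SEGMENTS if body_half == "upper" else LOWER_OUTPUT_SEGMENTS
    )
    quats = seq.quaternions
    q_pelvis = quats[:, SEGMENT_INDEX["Pelvis"]]
    rel = np.stack(
        [qmul(qconj(q_pelvis), quats[:, SEGMENT_INDEX[s]]) for s in segs], axis=1
    )
    rel = canonicalize_sequence(rel)
    return rel.reshape(len(quats), 4 * len(segs))


def _limb_segments(limb_pair: str):
    try:
        return LIMB_PAIRS[limb_pair]
    except KeyError:
        raise ValueError(f"limb_pair must be 'upper' or 'lower', got {limb_pair!r}")
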