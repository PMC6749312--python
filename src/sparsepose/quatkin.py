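"""Quaternion algebra and forward kinematics over a 23-segment body model.

Orientations are unit quaternions in Hamilton convention, scalar first
``(w, x, y, z)``, acting on column vectors in right-handed frames.  A segment
quaternion is *body-to-global*: ``rotate_vec(q, v_local)`` expresses a vector
given in the segment frame in the global frame.  All array functions are
vectorized over leading axes; a quaternion array has shape ``(..., 4)``.

The skeleton is a tree rooted at the pelvis.  Each segment stores the offset
of its origin (the joint connecting it to its parent) expressed in the
parent's local frame, so forward kinematics is the usual chain

    p(seg) = p(parent) + R(q_parent) @ offset(seg)

with the pelvis pinned at the origin when working pelvis-relative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SEGMENTS",
    "SENSOR_SEGMENTS",
    "UPPER_OUTPUT_SEGMENTS",
    "LOWER_OUTPUT_SEGMENTS",
    "Skeleton",
    "FramePose",
    "qmul",
    "qconj",
    "qnormalize",
    "qcanonical",
    "rotate_vec",
    "qrelative",
    "canonicalize_sequence",
    "quat_to_matrix",
    "axis_angle_quat",
    "forward_kinematics",
    "fk_positions",
    "default_skeleton",
]

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])

#: Canonical segment order (fixes array layout everywhere in the package).
SEGMENTS = (
    "Pelvis",
    "L5",
    "L3",
    "T12",
    "T8",
    "Neck",
    "Head",
    "RightShoulder",
    "RightUpperArm",
    "RightForearm",
    "RightHand",
    "LeftShoulder",
    "LeftUpperArm",
    "LeftForearm",
    "LeftHand",
    "RightUpperLeg",
    "RightLowerLeg",
    "RightFoot",
    "RightToe",
    "LeftUpperLeg",
    "LeftLowerLeg",
    "LeftFoot",
    "LeftToe",
)

#: The five sensor-bearing segments (pelvis + distal limb segments).
SENSOR_SEGMENTS = (
    "Pelvis",
    "LeftForearm",
    "RightForearm",
    "LeftLowerLeg",
    "RightLowerLeg",
)

#: Twelve upper-body segments estimated from the forearm pair.
UPPER_OUTPUT_SEGMENTS = (
    "L5",
    "L3",
    "T12",
    "T8",
    "Neck",
    "Head",
    "RightShoulder",
    "RightUpperArm",
    "RightHand",
    "LeftShoulder",
    "LeftUpperArm",
    "LeftHand",
)

#: Six lower-body segments estimated from the lower-leg pair.
LOWER_OUTPUT_SEGMENTS = (
    "RightUpperLeg",
    "RightFoot",
    "RightToe",
    "LeftUpperLeg",
    "LeftFoot",
    "LeftToe",
)

SEGMENT_INDEX = {name: i for i, name in enumerate(SEGMENTS)}

# Parent of each segment in the kinematic tree (pelvis is the root).
_PARENT = {
    "Pelvis": None,
    "L5": "Pelvis",
    "L3": "L5",
    "T12": "L3",
    "T8": "T12",
    "Neck": "T8",
    "Head": "Neck",
    "RightShoulder": "T8",
    "RightUpperArm": "RightShoulder",
    "RightForearm": "RightUpperArm",
    "RightHand": "RightForearm",
    "LeftShoulder": "T8",
    "LeftUpperArm": "LeftShoulder",
    "LeftForearm": "LeftUpperArm",
    "LeftHand": "LeftForearm",
    "RightUpperLeg": "Pelvis",
    "RightLowerLeg": "RightUpperLeg",
    "RightFoot": "RightLowerLeg",
    "RightToe": "RightFoot",
    "LeftUpperLeg": "Pelvis",
    "LeftLowerLeg": "LeftUpperLeg",
    "LeftFoot": "LeftLowerLeg",
    "LeftToe": "LeftFoot",
}

# Segment-origin offsets in the parent frame as fractions of stature, for a
# neutral standing pose: x forward, y left, z up.  Proportions follow the
# classical anthropometric segment-length tables (Winter-style), adapted so
# the head-to-toe chain sums to ~1.04 x stature.
_OFFSET_FRACTIONS = {
    "Pelvis": (0.0, 0.0, 0.0),
    "L5": (0.0, 0.0, 0.055),
    "L3": (0.0, 0.0, 0.055),
    "T12": (0.0, 0.0, 0.055),
    "T8": (0.0, 0.0, 0.055),
    "Neck": (0.0, 0.0, 0.068),
    "Head": (0.0, 0.0, 0.052),
    "RightShoulder": (0.0, -0.129, 0.068),
    "RightUpperArm": (0.0, -0.040, 0.0),
    "RightForearm": (0.0, 0.0, -0.186),
    "RightHand": (0.0, 0.0, -0.146),
    "LeftShoulder": (0.0, 0.129, 0.068),
    "LeftUpperArm": (0.0, 0.040, 0.0),
    "LeftForearm": (0.0, 0.0, -0.186),
    "LeftHand": (0.0, 0.0, -0.146),
    "RightUpperLeg": (0.0, -0.0955, 0.0),
    "RightLowerLeg": (0.0, 0.0, -0.245),
    "RightFoot": (0.0, 0.0, -0.246),
    "RightToe": (0.110, 0.0, -0.039),
    "LeftUpperLeg": (0.0, 0.0955, 0.0),
    "LeftLowerLeg": (0.0, 0.0, -0.245),
    "LeftFoot": (0.0, 0.0, -0.246),
    "LeftToe": (0.110, 0.0, -0.039),
}


# ---------------------------------------------------------------------------
# Quaternion algebra
# ---------------------------------------------------------------------------

def _check_finite(q: np.ndarray, name: str = "quaternion") -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError(f"non-finite {name}")
    return q


def qmul(a, b) -> np.ndarray:
    """Hamilton product ``a ⊗ b`` (apply ``b`` first, then ``a``)."""
    a = _check_finite(a)
    b = _check_finite(b)
    aw, ax, ay, az = np.moveaxis(a, -1, 0)
    bw, bx, by, bz = np.moveaxis(b, -1, 0)
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def qconj(q) -> np.ndarray:
    """Quaternion conjugate ``(w, -x, -y, -z)`` (inverse for unit input)."""
    q = _check_finite(q)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def qnormalize(q) -> np.ndarray:
    """Rescale to unit norm; zero-norm input raises."""
    q = _check_finite(q)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n == 0.0):
        raise ValueError("zero-norm quaternion cannot be normalized")
    return q / n


def qcanonical(q) -> np.ndarray:
    """Map to the w >= 0 hemisphere (ties on w == 0 broken so the first
    nonzero component is >= 0)."""
    q = np.asarray(q, dtype=float)
    out = q.copy()
    flat = out.reshape(-1, 4)
    for row in flat:
        for c in row:
            if c > 0.0:
                break
            if c < 0.0:
                row *= -1.0
                break
    return out


def rotate_vec(q, v) -> np.ndarray:
    """Rotate 3-vector(s) ``v`` by unit quaternion(s) ``q``."""
    q = _check_finite(q)
    v = _check_finite(np.asarray(v, dtype=float), "vector")
    n = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(n - 1.0) > 1e-6):
        raise ValueError("rotate_vec requires unit quaternions (|norm-1| <= 1e-6)")
    w = q[..., :1]
    u = q[..., 1:]
    # v' = v + 2 w (u x v) + 2 u x (u x v)
    uv = np.cross(u, v)
    return v + 2.0 * (w * uv + np.cross(u, uv))


def qrelative(reference, q) -> np.ndarray:
    """Orientation of ``q`` relative to ``reference``: conj(ref) ⊗ q,
    canonicalized to the w >= 0 hemisphere."""
    reference = _check_finite(reference)
    q = _check_finite(q)
    for arr in (reference, q):
        n = np.linalg.norm(arr, axis=-1)
        if np.any(np.abs(n - 1.0) > 1e-6):
            raise ValueError("qrelative requires unit quaternions")
    return qcanonical(qmul(qconj(reference), q))


def canonicalize_sequence(qs) -> np.ndarray:
    """Resolve the q/-q double cover along the time axis (axis 0).

    The first frame is mapped to the w >= 0 hemisphere; each later frame is
    sign-flipped whenever its dot product with the previous output frame is
    negative, so consecutive quaternions never jump across the cover.
    Accepts shape ``(n, 4)`` or ``(n, m, 4)``.
    """
    qs = np.asarray(qs, dtype=float)
    if qs.size == 0:
        return qs.copy()
    out = qs.copy()
    out[0] = qcanonical(out[0])
    for t in range(1, out.shape[0]):
        dot = np.sum(out[t] * out[t - 1], axis=-1, keepdims=True)
        out[t] = np.where(dot < 0.0, -out[t], out[t])
    return out


def quat_to_matrix(q) -> np.ndarray:
    """Unit quaternion(s) to 3x3 rotation matrix(es)."""
    q = qnormalize(q)
    w, x, y, z = np.moveaxis(q, -1, 0)
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - w * z)
    m[..., 0, 2] = 2 * (x * z + w * y)
    m[..., 1, 0] = 2 * (x * y + w * z)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - w * x)
    m[..., 2, 0] = 2 * (x * z - w * y)
    m[..., 2, 1] = 2 * (y * z + w * x)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def axis_angle_quat(axis, angle) -> np.ndarray:
    """Unit quaternion for rotation(s) of ``angle`` radians about ``axis``.

    ``angle`` may be an array; the result broadcasts to ``angle.shape + (4,)``.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis, axis=-1, keepdims=True)
    angle = np.asarray(angle, dtype=float)
    half = angle / 2.0
    s = np.sin(half)
    return np.concatenate(
        [np.cos(half)[..., None], s[..., None] * axis], axis=-1
    )


# ---------------------------------------------------------------------------
# Skeleton and forward kinematics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Skeleton:
    """23-segment kinematic tree with per-segment parent offsets (metres)."""

    segment_ids: tuple = SEGMENTS
    parent: dict = field(default_factory=lambda: dict(_PARENT))
    offset: dict = None  # segment -> 3-vector, metres, parent frame
    input_segments: tuple = SENSOR_SEGMENTS
    upper_output_segments: tuple = UPPER_OUTPUT_SEGMENTS
    lower_output_segments: tuple = LOWER_OUTPUT_SEGMENTS
    stature_m: float = 1.75

    def __post_init__(self):
        if len(self.segment_ids) != 23:
            raise ValueError("skeleton must have exactly 23 segments")
        groups = (
            set(self.input_segments)
            | set(self.upper_output_segments)
            | set(self.lower_output_segments)
        )
        if groups != set(self.segment_ids) or (
            len(self.input_segments)
            + len(self.upper_output_segments)
            + len(self.lower_output_segments)
        ) != 23:
            raise ValueError("segment groups must partition the 23 segments (5+12+6)")
        for seg in self.segment_ids:
            if self.parent[seg] is None:
                continue
            if np.linalg.norm(self.offset[seg]) == 0.0:
                raise ValueError(f"zero-length offset for non-root segment {seg}")

    @property
    def parent_index(self) -> np.ndarray:
        """Parent index per segment (-1 for the root), canonical order."""
        return np.array(
            [
                -1 if self.parent[s] is None else self.segment_ids.index(self.parent[s])
                for s in self.segment_ids
            ]
        )

    @property
    def offsets_array(self) -> np.ndarray:
        """(23, 3) offsets in canonical segment order."""
        return np.array([self.offset[s] for s in self.segment_ids])


@dataclass
class FramePose:
    """One pelvis-relative body pose: all 23 segment orientations.

    The pelvis entry is the identity by construction; every quaternion is
    unit-norm.
    """

    orientations: dict  # segment name -> (4,) quaternion
    timestamp_index: int = 0
    fs: float = 60.0

    def __post_init__(self):
        missing = set(SEGMENTS) - set(self.orientations)
        if missing:
            raise ValueError(f"pose missing segments: {sorted(missing)}")
        for seg, q in self.orientations.items():
            q = np.asarray(q, dtype=float)
            if abs(np.linalg.norm(q) - 1.0) > 1e-6:
                raise ValueError(f"non-unit quaternion for segment {seg}")
            self.orientations[seg] = q
        if not np.allclose(np.abs(self.orientations["Pelvis"]), IDENTITY, atol=1e-9):
            raise ValueError("pelvis orientation must be the identity (pose is pelvis-relative)")

    def as_array(self) -> np.ndarray:
        """(23, 4) quaternions in canonical segment order."""
        return np.stack([self.orientations[s] for s in SEGMENTS])

    @classmethod
    def from_array(cls, quats, timestamp_index: int = 0, fs: float = 60.0) -> "FramePose":
        quats = np.asarray(quats, dtype=float)
        return cls(
            orientations={s: quats[i] for i, s in enumerate(SEGMENTS)},
            timestamp_index=timestamp_index,
            fs=fs,
        )


def default_skeleton(stature_m: float = 1.75) -> Skeleton:
    """Skeleton with anthropometric proportional offsets scaled by stature.

    Offsets are stature fractions from published segment-length proportion
    tables; only relative geometry matters for the error metrics, so this
    proportional model stands in for any subject-specific calibration.
    """
    if not (1.0 <= stature_m <= 2.5):
        raise ValueError(f"stature {stature_m} m outside the supported range [1.0, 2.5]")
    offset = {
        seg: stature_m * np.array(frac) for seg, frac in _OFFSET_FRACTIONS.items()
    }
    return Skeleton(offset=offset, stature_m=stature_m)


def fk_positions(skel: Skeleton, quats: np.ndarray) -> np.ndarray:
    """Joint (segment-origin) positions from pelvis-relative quaternions.

    Parameters
    ----------
    quats
        ``(..., 23, 4)`` pelvis-relative orientations in canonical order.

    Returns
    -------
    ``(..., 23, 3)`` positions in the pelvis frame, pelvis at the origin.
    """
    quats = np.asarray(quats, dtype=float)
    if quats.shape[-2:] != (23, 4):
        raise ValueError("expected (..., 23, 4) quaternion array")
    parents = skel.parent_index
    offsets = skel.offsets_array
    pos = np.zeros(quats.shape[:-1] + (3,))
    for i in range(1, 23):
        p = parents[i]
        pos[..., i, :] = pos[..., p, :] + rotate_vec(quats[..., p, :], offsets[i])
    return pos


def forward_kinematics(skel: Skeleton, pose: FramePose) -> dict:
    """Joint positions (pelvis frame, pelvis at origin) for one pose."""
    pos = fk_positions(skel, pose.as_array())
    return {seg: pos[i] for i, seg in enumerate(SEGMENTS)}
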