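"""File formats: the package's self-describing motion text format and a
read-only BVH importer.

Motion format (version 1): a header block of ``# key: value`` lines followed
by one whitespace-delimited data row per frame.  Columns are the frame
index, then ``w x y z`` per segment in the header's segment order, then
``ax ay az`` per sensor when accelerations are stored, then the global
pelvis position when stored.  Floats are written with ``repr`` precision so
a write/read round-trip is bit-exact.  Readers are strict by default:
malformed rows, wrong segment counts and non-unit quaternions are rejected
rather than repaired (``lenient=True`` renormalizes near-unit quaternions).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from .quatkin import SEGMENTS, SENSOR_SEGMENTS, qnormalize, qmul, axis_angle_quat
from .synthetic import MotionSequence

__all__ = ["write_motion", "read_motion", "import_bvh", "FORMAT_VERSION"]

FORMAT_VERSION = 1

_AXIS_VECS = {
    "X": np.array([1.0, 0.0, 0.0]),
    "Y": np.array([0.0, 1.0, 0.0]),
    "Z": np.array([0.0, 0.0, 1.0]),
}


def write_motion(path, seq: MotionSequence) -> None:
    """Write a MotionSequence to the motion text format (lossless)."""
    path = Path(path)
    has_accel = seq.accelerations is not None
    has_pelvis = seq.pelvis_position is not None
    lines = [
        f"# sparsepose-motion v{FORMAT_VERSION}",
        f"# fs: {seq.fs!r}",
        f"# subject_id: {seq.subject_id}",
        f"# activity: {seq.activity_label}",
        f"# stature_m: {seq.stature_m!r}",
        f"# has_accel: {str(has_accel).lower()}",
        f"# has_pelvis_position: {str(has_pelvis).lower()}",
        f"# segments: {','.join(SEGMENTS)}",
        f"# sensors: {','.join(SENSOR_SEGMENTS)}",
    ]
    n = seq.n_frames
    for t in range(n):
        row = [str(t)]
        row += [repr(float(v)) for v in seq.quaternions[t].reshape(-1)]
        if has_accel:
            row += [repr(float(v)) for v in seq.accelerations[t].reshape(-1)]
        if has_pelvis:
            row += [repr(float(v)) for v in seq.pelvis_position[t]]
        lines.append(" ".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_motion(path, lenient: bool = False) -> MotionSequence:
    """Read a motion file; strict validation unless ``lenient``."""
    path = Path(path)
    header: Dict[str, str] = {}
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if lineno == 1:
                    m = re.match(r"#\s*sparsepose-motion\s+v(\d+)", line)
                    if not m:
                        raise ValueError(f"{path}: not a sparsepose motion file")
                    if int(m.group(1)) != FORMAT_VERSION:
                        raise ValueError(
                            f"{path}: unsupported format version {m.group(1)}"
                        )
                    continue
                key, _, value = line.lstrip("# ").partition(":")
                header[key.strip()] = value.strip()
                continue
            parts = line.split()
            rows.append((lineno, parts))

    segments = header.get("segments", "").split(",")
    if segments != list(SEGMENTS):
        raise ValueError(
            f"{path}: segment list must be the 23 canonical segments in order "
            f"(got {len(segments)})"
        )
    fs = float(header["fs"])
    if fs <= 0:
        raise ValueError(f"{path}: fs must be positive")
    has_accel = header.get("has_accel", "false") == "true"
    has_pelvis = header.get("has_pelvis_position", "false") == "true"
    ncol = 1 + 23 * 4 + (15 if has_accel else 0) + (3 if has_pelvis else 0)

    n = len(rows)
    quats = np.empty((n, 23, 4))
    accels = np.empty((n, 5, 3)) if has_accel else None
    pelvis = np.empty((n, 3)) if has_pelvis else None
    for i, (lineno, parts) in enumerate(rows):
        if len(parts) != ncol:
            raise ValueError(
                f"{path}:{lineno}: expected {ncol} columns, got {len(parts)}"
            )
        try:
            vals = np.array([float(p) for p in parts[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        quats[i] = vals[: 23 * 4].reshape(23, 4)
        off = 23 * 4
        if has_accel:
            accels[i] = vals[off : off + 15].reshape(5, 3)
            off += 15
        if has_pelvis:
            pelvis[i] = vals[off : off + 3]

    norms = np.linalg.norm(quats, axis=-1)
    bad = np.abs(norms - 1.0) > 1e-3
    if bad.any():
        frames = sorted(set(np.nonzero(bad)[0].tolist()))
        raise ValueError(
            f"{path}: non-unit quaternions beyond 1e-3 at frames {frames[:10]}"
        )
    if lenient:
        quats = qnormalize(quats)
    return MotionSequence(
        subject_id=header.get("subject_id", ""),
        activity_label=header.get("activity", ""),
        fs=fs,
        quaternions=quats,
        accelerations=accels,
        pelvis_position=pelvis,
        stature_m=float(header.get("stature_m", 1.75)),
    )


# ---------------------------------------------------------------------------
# BVH import
# ---------------------------------------------------------------------------

def import_bvh(path, mapping: Dict[str, str], fs: Optional[float] = None) -> MotionSequence:
    """Import a BVH file, mapping BVH joint names to canonical segments.

    Euler-angle motion channels are composed in the file's per-joint channel
    order into global quaternions; unmapped canonical segments are filled
    with the identity orientation.  Accelerations are absent.
    """
    path = Path(path)
    joints, frame_time, frames = _parse_bvh(path)
    if frame_time <= 0:
        raise ValueError(f"{path}: non-positive frame time {frame_time}")
    for bvh_name in mapping:
        if bvh_name not in joints:
            raise ValueError(f"{path}: mapped joint {bvh_name!r} not in hierarchy")

    n = len(frames)
    # local quaternions per joint per frame
    local = {}
    for name, joint in joints.items():
        q = np.tile(np.array([1.0, 0.0, 0.0, 0.0]), (n, 1))
        for ch, col in joint["channels"]:
            if not ch.endswith("rotation"):
                continue
            axis = _AXIS_VECS[ch[0].upper()]
            angles = np.deg2rad(frames[:, col])
            q = qmul(q, axis_angle_quat(axis, angles))
        local[name] = q
    # compose down the hierarchy: global = parent_global x local
    global_q = {}
    for name in joints:  # parsed in hierarchy order (parents first)
        parent = joints[name]["parent"]
        if parent is None:
            global_q[name] = local[name]
        else:
            global_q[name] = qmul(global_q[parent], local[name])

    quats = np.tile(np.array([1.0, 0.0, 0.0, 0.0]), (n, 23, 1))
    mapped = set()
    for bvh_name, seg in mapping.items():
        if seg not in SEGMENTS:
            raise ValueError(f"unknown canonical segment {seg!r}")
        quats[:, SEGMENTS.index(seg)] = qnormalize(global_q[bvh_name])
        mapped.add(seg)
    unmapped = [s for s in SEGMENTS if s not in mapped]
    return MotionSequence(
        subject_id=path.stem,
        activity_label="bvh-import" + ("" if not unmapped else f" ({len(unmapped)} segments unmapped)"),
        fs=fs if fs is not None else 1.0 / frame_time,
        quaternions=quats,
    )


def _parse_bvh(path: Path):
    """Minimal BVH reader: hierarchy (names, parents, channels) + motion."""
    tokens = path.read_text().split()
    joints: Dict[str, dict] = {}
    stack = []
    channel_count = 0

    def expect(tok, want):
        if tok.upper() != want:
            raise ValueError(f"{path}: expected {want}, got {tok!r}")

    pos = 0
    toks = tokens
    if not toks or toks[0].upper() != "HIERARCHY":
        raise ValueError(f"{path}: missing HIERARCHY")
    pos = 1
    while pos < len(toks) and toks[pos].upper() != "MOTION":
        t = toks[pos].upper()
        if t in ("ROOT", "JOINT"):
            name = toks[pos + 1]
            joints[name] = {
                "parent": stack[-1] if stack else None,
                "channels": [],
            }
            stack.append(name)
            pos += 2
        elif t == "END":  # End Site
            stack.append(None)
            pos += 2
        elif t == "{":
            pos += 1
        elif t == "}":
            stack.pop()
            pos += 1
        elif t == "OFFSET":
            pos += 4
        elif t == "CHANNELS":
            cnum = int(toks[pos + 1])
            names = toks[pos + 2 : pos + 2 + cnum]
            cur = stack[-1]
            for cname in names:
                joints[cur]["channels"].append((cname.lower(), channel_count))
                channel_count += 1
            pos += 2 + cnum
        else:
            raise ValueError(f"{path}: unexpected token {toks[pos]!r} in hierarchy")
    if pos >= len(toks):
        raise ValueError(f"{path}: missing MOTION section")
    pos += 1  # MOTION
    expect(toks[pos], "FRAMES:")
    nframes = int(toks[pos + 1])
    pos += 2
    # "Frame Time: <t>"
    expect(toks[pos], "FRAME")
    frame_time = float(toks[pos + 2])
    pos += 3
    data = np.array([float(v) for v in toks[pos:]])
    if data.size != nframes * channel_count:
        raise ValueError(
            f"{path}: motion data size {data.size} != frames x channels "
            f"{nframes}x{channel_count}"
        )
    return joints, frame_time, data.reshape(nframes, channel_count)
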