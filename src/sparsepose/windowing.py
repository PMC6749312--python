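"""Stacked input windows over feature sequences.

One training example is built around a centre sample ``t_i``: the window
collects the ``P`` past and ``F`` future feature frames at multiples of the
sample interval ``I`` (offsets ``{-P*I, ..., -I, 0, +I, ..., +F*I}``) and
pairs them with the pose target at ``t_i`` alone.  The stacked input length
is ``SIL = P + 1 + F`` frames spaced ``dt = I/fs`` seconds apart.  Using
future frames delays the output by the acquisition delay ``F*I/fs``.

Frames are stacked oldest first.  The flat vector (length ``D*SIL``) feeds
the stacked-input network; the same data reshaped to ``(D, SIL)`` feeds the
recurrent baseline.  Centres lacking full context are dropped, never padded,
so a sequence of ``n`` frames yields ``max(n - (P+F)*I, 0)`` samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List

import numpy as np

__all__ = [
    "WindowConfig",
    "StackedSample",
    "downsample",
    "downsample_array",
    "build_windows",
    "build_window_arrays",
    "delay_seconds",
    "enumerate_configs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowConfig:
    """Window geometry: past count P, future count F, interval I, rate fs."""

    P: int = 2
    F: int = 2
    I: int = 2
    fs: float = 60.0

    def __post_init__(self):
        if self.P < 0 or self.F < 0:
            raise ValueError(f"P and F must be >= 0 (got P={self.P}, F={self.F})")
        if self.I < 1:
            raise ValueError(f"I must be >= 1 (got I={self.I})")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive (got fs={self.fs})")

    @property
    def dt(self) -> float:
        """Seconds between stacked frames: I / fs."""
        return self.I / self.fs

    @property
    def sil(self) -> int:
        """Stacked input length: P + 1 + F frames."""
        return self.P + 1 + self.F

    @property
    def offsets(self) -> np.ndarray:
        """Frame offsets from the centre index, oldest first."""
        return np.arange(-self.P, self.F + 1) * self.I

    @property
    def acquisition_delay(self) -> float:
        """Output delay caused by waiting for future frames: F * I / fs."""
        return self.F * self.I / self.fs


@dataclass
class StackedSample:
    """One example: a stacked feature window and its centre pose target."""

    input_matrix: np.ndarray  # (D, SIL), columns ordered oldest first
    target: np.ndarray  # (4*m,) centre-frame pose target
    centre_index: int
    subject_id: str = ""
    activity_label: str = ""

    @property
    def input_stacked(self) -> np.ndarray:
        """Column-major flattening (frame-by-frame) of ``input_matrix``."""
        return self.input_matrix.reshape(-1, order="F")


def downsample(seq, factor: int):
    """Keep every ``factor``-th frame (starting at index 0) of a
    MotionSequence; plain decimation, no filtering."""
    if factor < 1:
        raise ValueError(f"downsample factor must be >= 1 (got {factor})")
    if factor == 1:
        return seq
    return replace(
        seq,
        quaternions=seq.quaternions[::factor].copy(),
        accelerations=None
        if seq.accelerations is None
        else seq.accelerations[::factor].copy(),
        pelvis_position=None
        if seq.pelvis_position is None
        else seq.pelvis_position[::factor].copy(),
        fs=seq.fs / factor,
    )


def downsample_array(arr: np.ndarray, factor: int) -> np.ndarray:
    """Decimate an array along axis 0 keeping indices {0, factor, 2*factor, ...}."""
    if factor < 1:
        raise ValueError(f"downsample factor must be >= 1 (got {factor})")
    return np.asarray(arr)[::factor]


def build_window_arrays(features: np.ndarray, targets: np.ndarray, cfg: WindowConfig):
    """Vectorized windowing: (n, D) features -> (m, D, SIL) plus targets.

    Returns ``(inputs, targets_out, centre_indices)`` where
    ``m = max(n - (P+F)*I, 0)`` and centre indices run from ``P*I`` to
    ``n - 1 - F*I``.
    """
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if len(features) != len(targets):
        raise ValueError("features and targets must be aligned and equal length")
    n = len(features)
    span = (cfg.P + cfg.F) * cfg.I
    if n <= span:
        logger.warning(
            "sequence of %d frames too short for window span %d; no samples", n, span
        )
        d = features.shape[1] if features.ndim == 2 else 0
        return (
            np.empty((0, d, cfg.sil)),
            np.empty((0,) + targets.shape[1:]),
            np.empty(0, dtype=int),
        )
    centres = np.arange(cfg.P * cfg.I, n - cfg.F * cfg.I)
    idx = centres[:, None] + cfg.offsets[None, :]  # (m, SIL)
    inputs = features[idx]  # (m, SIL, D)
    return np.transpose(inputs, (0, 2, 1)), targets[centres], centres


def build_windows(
    features,
    targets,
    cfg: WindowConfig,
    subject_id: str = "",
    activity_label: str = "",
) -> List[StackedSample]:
    """StackedSamples for every centre index with full (P, F, I) context.

    ``features`` may be a list of FeatureFrames or an ``(n, D)`` array;
    ``targets`` an aligned list/array of target vectors.
    """
    if len(features) and hasattr(features[0], "as_vector"):
        features = np.stack([f.as_vector() for f in features])
    inputs, targs, centres = build_window_arrays(features, np.asarray(targets), cfg)
    return [
        StackedSample(
            input_matrix=inputs[k],
            target=targs[k],
            centre_index=int(centres[k]),
            subject_id=subject_id,
            activity_label=activity_label,
        )
        for k in range(len(centres))
    ]


def delay_seconds(cfg: WindowConfig) -> float:
    """Acquisition delay of the estimate behind real time: F * I / fs."""
    return cfg.acquisition_delay


def enumerate_configs(sils, intervals, fs: float = 60.0) -> List[WindowConfig]:
    """All (P, F) splits of each stacked input length, crossed with each
    interval; ordered by ascending SIL, then P, then I."""
    configs = []
    for sil in sorted(sils):
        if sil < 1:
            raise ValueError(f"SIL must be >= 1 (got {sil})")
        for p in range(sil):
            f = sil - 1 - p
            for i in sorted(intervals):
                configs.append(WindowConfig(P=p, F=f, I=i, fs=fs))
    return configs
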