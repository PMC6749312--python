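"""Pose-accuracy metrics and subject-wise cross-validation.

Two complementary error measures are computed from forward kinematics of
truth and estimated poses (both pelvis-relative, pelvis at the origin, so
every number is invariant to where the body is and which way it faces):

* mean joint position error — the Euclidean distance between true and
  estimated joint positions, averaged over the 23 joints of a frame (m);
* joint jerk error — the Euclidean norm of the difference between true and
  estimated joint jerk (third time derivative of joint position), averaged
  over joints (m/s^3).  Jerk uses one five-point central stencil,

      jerk(t) = [p(t+2h) - 2 p(t+h) + 2 p(t-h) - p(t-2h)] / (2 h^3),

  which is exact on cubics and O(h^2) accurate in general; a series of n
  frames yields n - 4 jerk frames.

Cross-validation is subject-wise: each fold holds out one subject entirely,
trains upper- and lower-body networks on the rest, and scores the held-out
subject.  A constant-mean-pose baseline (predicting the training-set mean
pose everywhere) is evaluated on every fold for reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .quatkin import FramePose, Skeleton, fk_positions
from .features import feature_matrix, pose_targets
from .windowing import WindowConfig, StackedSample, build_window_arrays
from .models import (
    ModelSpec,
    assemble_full_pose_array,
    renormalize_quaternions,
    train_rnn,
    train_sinn,
)

__all__ = [
    "EvalResult",
    "CVSummary",
    "joint_position_error",
    "position_error_series",
    "jerk",
    "joint_jerk_error",
    "subject_wise_cv",
    "config_sweep",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def position_error_series(skel: Skeleton, truth_quats, est_quats) -> np.ndarray:
    """Per-frame mean-over-joints position error (m) for (n, 23, 4) arrays."""
    truth_quats = np.asarray(truth_quats, dtype=float)
    est_quats = np.asarray(est_quats, dtype=float)
    if truth_quats.shape != est_quats.shape:
        raise ValueError("truth and estimate must have equal shapes")
    p_t = fk_positions(skel, truth_quats)
    p_e = fk_positions(skel, est_quats)
    return np.linalg.norm(p_t - p_e, axis=-1).mean(axis=-1)


def joint_position_error(skel: Skeleton, truth: FramePose, estimate: FramePose) -> float:
    """Mean over the 23 joints of the Euclidean position error (m)."""
    return float(
        position_error_series(
            skel, truth.as_array()[None], estimate.as_array()[None]
        )[0]
    )


def jerk(positions, fs: float) -> np.ndarray:
    """Third time derivative of a position series by 5-point central
    differences; input (n, ..., 3), output (n-4, ..., 3) in m/s^3."""
    p = np.asarray(positions, dtype=float)
    if len(p) < 5:
        raise ValueError(f"jerk needs >= 5 frames, got {len(p)}")
    h = 1.0 / fs
    return (p[4:] - 2.0 * p[3:-1] + 2.0 * p[1:-3] - p[:-4]) / (2.0 * h**3)


def joint_jerk_error(skel: Skeleton, truth_seq, estimate_seq, fs: float) -> np.ndarray:
    """Per-frame (interior) mean-over-joints jerk error (m/s^3).

    Accepts (n, 23, 4) quaternion arrays or sequences of FramePose; the
    output has length n - 4.
    """
    truth_q = _as_quat_array(truth_seq)
    est_q = _as_quat_array(estimate_seq)
    if truth_q.shape != est_q.shape:
        raise ValueError("sequences must be aligned and of equal length")
    j_t = jerk(fk_positions(skel, truth_q), fs)
    j_e = jerk(fk_positions(skel, est_q), fs)
    return np.linalg.norm(j_t - j_e, axis=-1).mean(axis=-1)


def _as_quat_array(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    return np.stack([p.as_array() if isinstance(p, FramePose) else np.asarray(p) for p in seq])


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    """Errors for one held-out subject (one CV fold)."""

    test_subject: str
    position_errors: np.ndarray  # pooled per-frame errors, m
    jerk_errors: np.ndarray  # pooled per-frame errors, m/s^3
    per_sequence: List[dict] = field(default_factory=list)
    baseline_position_error: float = np.nan
    config: dict = field(default_factory=dict)

    @property
    def mean_position_error(self) -> float:
        return float(np.mean(self.position_errors))

    @property
    def mean_jerk_error(self) -> float:
        return float(np.mean(self.jerk_errors))

    def activity_medians(self) -> Dict[str, dict]:
        """Median per-frame position/jerk error per activity class."""
        out: Dict[str, dict] = {}
        for act in sorted({s["activity"] for s in self.per_sequence}):
            pos = np.concatenate(
                [s["position_errors"] for s in self.per_sequence if s["activity"] == act]
            )
            jrk = np.concatenate(
                [s["jerk_errors"] for s in self.per_sequence if s["activity"] == act]
            )
            out[act] = {
                "median_position_error": float(np.median(pos)),
                "median_jerk_error": float(np.median(jrk)),
            }
        return out


@dataclass
class CVSummary:
    """All folds of one subject-wise cross-validation run."""

    folds: List[EvalResult]
    config: dict = field(default_factory=dict)

    @property
    def mean_position_error(self) -> float:
        return float(np.mean([f.mean_position_error for f in self.folds]))

    @property
    def std_position_error(self) -> float:
        return float(np.std([f.mean_position_error for f in self.folds]))

    @property
    def mean_jerk_error(self) -> float:
        return float(np.mean([f.mean_jerk_error for f in self.folds]))

    @property
    def std_jerk_error(self) -> float:
        return float(np.std([f.mean_jerk_error for f in self.folds]))

    def activity_medians(self) -> Dict[str, dict]:
        out: Dict[str, dict] = {}
        acts = sorted({a for f in self.folds for a in f.activity_medians()})
        for act in acts:
            pos = np.concatenate(
                [
                    s["position_errors"]
                    for f in self.folds
                    for s in f.per_sequence
                    if s["activity"] == act
                ]
            )
            jrk = np.concatenate(
                [
                    s["jerk_errors"]
                    for f in self.folds
                    for s in f.per_sequence
                    if s["activity"] == act
                ]
            )
            out[act] = {
                "median_position_error": float(np.median(pos)),
                "median_jerk_error": float(np.median(jrk)),
            }
        return out

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "test_subject": f.test_subject,
                "mean_position_error_m": f.mean_position_error,
                "mean_jerk_error_m_s3": f.mean_jerk_error,
                "baseline_position_error_m": f.baseline_position_error,
                **{f"cfg_{k}": v for k, v in f.config.items()},
            }
            for f in self.folds
        ]
        return pd.DataFrame(rows)


def _prepare_sequence(seq, cfg: WindowConfig, use_accel: bool):
    """Features, targets and assembly inputs for one motion sequence."""
    Xu = feature_matrix(seq, "upper", use_accel)
    Xl = feature_matrix(seq, "lower", use_accel)
    Yu = pose_targets(seq, "upper")
    Yl = pose_targets(seq, "lower")
    n = len(Xu)
    inputs = np.zeros((n, 5, 4))
    inputs[:, 0, 0] = 1.0  # pelvis relative to itself
    inputs[:, 1] = Xu[:, 0:4]  # LeftForearm
    inputs[:, 2] = Xu[:, 4:8]  # RightForearm
    inputs[:, 3] = Xl[:, 0:4]  # LeftLowerLeg
    inputs[:, 4] = Xl[:, 4:8]  # RightLowerLeg
    truth = assemble_full_pose_array(Yu, Yl, inputs)
    return {"Xu": Xu, "Xl": Xl, "Yu": Yu, "Yl": Yl, "inputs": inputs, "truth": truth}


def _windows_for(prep, key_x, key_y, cfg, subject, activity):
    inputs, targets, centres = build_window_arrays(prep[key_x], prep[key_y], cfg)
    return (
        [
            StackedSample(
                input_matrix=inputs[k],
                target=targets[k],
                centre_index=int(centres[k]),
                subject_id=subject,
                activity_label=activity,
            )
            for k in range(len(centres))
        ],
        centres,
    )


class _MeanPoseModel:
    """Predicts the (renormalized) training-set mean pose everywhere."""

    def __init__(self, targets: np.ndarray):
        self.mean_pose = renormalize_quaternions(targets.mean(axis=0))

    def predict_batch(self, samples_matrix, samples_stacked):
        n = len(samples_stacked)
        return np.tile(self.mean_pose, (n, 1))


class _OracleModel:
    """Memorizes ground truth; returns the true targets (sanity checks)."""

    def predict_batch(self, samples_matrix, samples_stacked, true_targets=None):
        return renormalize_quaternions(true_targets)


def _fit_half(train_samples, model_type, spec):
    if model_type == "sinn":
        return train_sinn(train_samples, spec)
    if model_type == "rnn":
        return train_rnn(train_samples, spec)
    if model_type == "mean":
        return _MeanPoseModel(np.stack([s.target for s in train_samples]))
    if model_type == "oracle":
        return _OracleModel()
    raise ValueError(f"unknown model_type {model_type!r}")


def _predict_half(model, inputs_matrix, inputs_stacked, true_targets):
    if isinstance(model, _OracleModel):
        return model.predict_batch(inputs_matrix, inputs_stacked, true_targets)
    if isinstance(model, _MeanPoseModel):
        return model.predict_batch(inputs_matrix, inputs_stacked)
    if model.spec.kind == "sinn":
        return model.predict(inputs_stacked)
    return model.predict(inputs_matrix)


def subject_wise_cv(
    dataset,
    skel: Skeleton,
    cfg: WindowConfig,
    model_type: str = "sinn",
    use_accel: bool = False,
    upper_spec: Optional[ModelSpec] = None,
    lower_spec: Optional[ModelSpec] = None,
    seed: int = 0,
    test_subjects: Optional[Sequence[str]] = None,
) -> CVSummary:
    """Leave-one-subject-out evaluation over a list of MotionSequences.

    Returns one :class:`EvalResult` per subject with any data; subjects with
    no frames are excluded with a warning.  ``test_subjects`` restricts the
    folds that are actually run (each still trains on all other subjects).
    """
    subjects = sorted({s.subject_id for s in dataset})
    subjects = [
        s
        for s in subjects
        if any(q.n_frames > 0 for q in dataset if q.subject_id == s)
        or logger.warning("subject %s has no data; excluded", s)
    ]
    if len(subjects) < 2:
        raise ValueError("subject-wise CV needs at least 2 subjects")
    fold_subjects = subjects if test_subjects is None else [
        s for s in subjects if s in set(test_subjects)
    ]

    d = 14 if use_accel else 8
    preps = {
        id(seq): _prepare_sequence(seq, cfg, use_accel) for seq in dataset
    }
    folds = []
    meta = {
        "P": cfg.P, "F": cfg.F, "I": cfg.I, "fs": cfg.fs,
        "use_accel": use_accel, "model_type": model_type,
    }
    for test_subject in fold_subjects:
        train_seqs = [s for s in dataset if s.subject_id != test_subject]
        test_seqs = [s for s in dataset if s.subject_id == test_subject]
        halves = {}
        for half, kx, ky in (("upper", "Xu", "Yu"), ("lower", "Xl", "Yl")):
            train_samples = []
            for seq in train_seqs:
                smp, _ = _windows_for(
                    preps[id(seq)], kx, ky, cfg, seq.subject_id, seq.activity_label
                )
                train_samples.extend(smp)
            spec = upper_spec if half == "upper" else lower_spec
            if spec is None:
                spec = ModelSpec(body_half=half, seed=seed)
            else:
                spec = ModelSpec(**{**spec.__dict__, "body_half": half})
            spec.kind = model_type if model_type in ("sinn", "rnn") else spec.kind
            spec.input_dim = d * cfg.sil if spec.kind == "sinn" else d
            spec.sil = cfg.sil
            spec.centre_step = cfg.P
            if model_type in ("sinn", "rnn"):
                spec.kind = model_type
            halves[half] = (
                _fit_half(train_samples, model_type, spec),
                np.stack([s.target for s in train_samples]),
            )

        pos_all, jerk_all, per_sequence = [], [], []
        baseline_pos = []
        for seq in test_seqs:
            prep = preps[id(seq)]
            su, centres = _windows_for(prep, "Xu", "Yu", cfg, seq.subject_id, seq.activity_label)
            sl, _ = _windows_for(prep, "Xl", "Yl", cfg, seq.subject_id, seq.activity_label)
            if not su:
                continue
            Xu_m = np.stack([s.input_matrix for s in su])
            Xu_s = np.stack([s.input_stacked for s in su])
            Xl_m = np.stack([s.input_matrix for s in sl])
            Xl_s = np.stack([s.input_stacked for s in sl])
            yu = prep["Yu"][centres]
            yl = prep["Yl"][centres]
            pred_u = _predict_half(halves["upper"][0], Xu_m, Xu_s, yu)
            pred_l = _predict_half(halves["lower"][0], Xl_m, Xl_s, yl)
            est = assemble_full_pose_array(pred_u, pred_l, prep["inputs"][centres])
            truth = prep["truth"][centres]
            pos_err = position_error_series(skel, truth, est)
            jerk_err = (
                joint_jerk_error(skel, truth, est, cfg.fs)
                if len(truth) >= 5
                else np.empty(0)
            )
            pos_all.append(pos_err)
            jerk_all.append(jerk_err)
            per_sequence.append(
                {
                    "subject": seq.subject_id,
                    "activity": seq.activity_label,
                    "n_frames": len(truth),
                    "position_errors": pos_err,
                    "jerk_errors": jerk_err,
                }
            )
            # constant-mean-pose reference on the same frames
            mean_u = _MeanPoseModel(halves["upper"][1]).predict_batch(Xu_m, Xu_s)
            mean_l = _MeanPoseModel(halves["lower"][1]).predict_batch(Xl_m, Xl_s)
            base_est = assemble_full_pose_array(mean_u, mean_l, prep["inputs"][centres])
            baseline_pos.append(position_error_series(skel, truth, base_est))

        folds.append(
            EvalResult(
                test_subject=test_subject,
                position_errors=np.concatenate(pos_all) if pos_all else np.empty(0),
                jerk_errors=np.concatenate(jerk_all) if jerk_all else np.empty(0),
                per_sequence=per_sequence,
                baseline_position_error=float(
                    np.mean(np.concatenate(baseline_pos))
                )
                if baseline_pos
                else np.nan,
                config=dict(meta),
            )
        )
    return CVSummary(folds=folds, config=dict(meta))


def config_sweep(
    dataset,
    skel: Skeleton,
    configs: Sequence[WindowConfig],
    use_accel_options: Sequence[bool] = (False,),
    model_type: str = "sinn",
    seed: int = 0,
    upper_spec: Optional[ModelSpec] = None,
    lower_spec: Optional[ModelSpec] = None,
) -> pd.DataFrame:
    """Pooled CV errors for every (window config, feature flag) cell."""
    rows = []
    for cfg in configs:
        for accel in use_accel_options:
            summary = subject_wise_cv(
                dataset,
                skel,
                cfg,
                model_type=model_type,
                use_accel=accel,
                upper_spec=upper_spec,
                lower_spec=lower_spec,
                seed=seed,
            )
            rows.append(
                {
                    "P": cfg.P,
                    "F": cfg.F,
                    "I": cfg.I,
                    "fs": cfg.fs,
                    "SIL": cfg.sil,
                    "use_accel": accel,
                    "model_type": model_type,
                    "mean_position_error_m": summary.mean_position_error,
                    "std_position_error_m": summary.std_position_error,
                    "mean_jerk_error_m_s3": summary.mean_jerk_error,
                    "std_jerk_error_m_s3": summary.std_jerk_error,
                    "baseline_position_error_m": float(
                        np.mean([f.baseline_position_error for f in summary.folds])
                    ),
                }
            )
    return pd.DataFrame(rows)
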