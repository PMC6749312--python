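"""Regression networks mapping stacked sensor windows to body poses.

Two estimators share one contract.  The stacked-input network (SINN) is a
shallow fully-connected net fed the flattened window ``(D*SIL,)``; the
recurrent baseline (RNN) is a bidirectional LSTM fed the same window as a
``(D, SIL)`` sequence, read out at the centre step.  Both are trained per
body half (upper: 12 segments -> 48 outputs; lower: 6 segments -> 24
outputs) with mean-squared error on raw quaternion components; predictions
are renormalized to unit quaternions afterwards.

Training is deterministic given the spec seed (weight init, batch order and
dropout all derive from it).  Input standardization constants are computed
from training subjects only; early stopping monitors one held-out training
subject (or a fixed 10% tail split when only one subject is present).

The recurrent network is implemented directly in numpy (forward pass and
backpropagation through time, Adam updates); the shallow network wraps
``sklearn.neural_network.MLPRegressor`` driven one epoch at a time so the
same subject-wise early stopping applies.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence

import numpy as np
from sklearn.neural_network import MLPRegressor

from .quatkin import (
    SEGMENT_INDEX,
    SENSOR_SEGMENTS,
    UPPER_OUTPUT_SEGMENTS,
    LOWER_OUTPUT_SEGMENTS,
)
from .windowing import StackedSample

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "train_sinn",
    "train_rnn",
    "predict_sinn",
    "predict_rnn",
    "assemble_full_pose",
    "assemble_full_pose_array",
    "renormalize_quaternions",
    "parameter_count",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1

_OUTPUT_SEGMENTS = {"upper": UPPER_OUTPUT_SEGMENTS, "lower": LOWER_OUTPUT_SEGMENTS}


@dataclass
class ModelSpec:
    """Architecture and training settings for one body-half network."""

    body_half: str  # "upper" | "lower"
    kind: str = "sinn"  # "sinn" | "rnn"
    input_dim: int = 40  # D*SIL (sinn) or D (rnn, per step)
    sil: int = 5
    centre_step: Optional[int] = None  # index of the target frame in the window (= P)
    hidden_sizes: Sequence[int] = (256, 256)  # sinn layer widths
    rnn_hidden: int = 128  # memory cells per direction
    rnn_layers: int = 2
    dropout: float = 0.2  # rnn inter-layer dropout
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 50
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.body_half not in _OUTPUT_SEGMENTS:
            raise ValueError("body_half must be 'upper' or 'lower'")
        if self.kind not in ("sinn", "rnn"):
            raise ValueError("kind must be 'sinn' or 'rnn'")

    @property
    def output_dim(self) -> int:
        return 4 * len(_OUTPUT_SEGMENTS[self.body_half])


@dataclass
class TrainedModel:
    """A fitted network plus everything needed to reproduce its output."""

    spec: ModelSpec
    weights: object  # estimator-specific parameter container
    training_history: List[dict] = field(default_factory=list)
    norm_mean: Optional[np.ndarray] = None
    norm_scale: Optional[np.ndarray] = None
    format_version: int = FORMAT_VERSION

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        if self.spec.kind == "sinn":
            return predict_sinn(self, inputs)
        return predict_rnn(self, inputs)


# ---------------------------------------------------------------------------
# Shared plumbing
# ---------------------------------------------------------------------------

def _collect(samples: Sequence[StackedSample], spec: ModelSpec):
    """Stack sample arrays, validating dimensions against the spec."""
    if not samples:
        raise ValueError("no training samples")
    X = np.stack([s.input_stacked for s in samples])
    Xm = np.stack([s.input_matrix for s in samples])
    y = np.stack([s.target for s in samples])
    subjects = np.array([s.subject_id for s in samples])
    d_sil = Xm.shape[1] * Xm.shape[2]
    if spec.kind == "sinn" and spec.input_dim != d_sil:
        raise ValueError(
            f"spec.input_dim {spec.input_dim} != stacked dimension {d_sil}"
        )
    if spec.kind == "rnn" and spec.input_dim != Xm.shape[1]:
        raise ValueError(
            f"spec.input_dim {spec.input_dim} != per-step dimension {Xm.shape[1]}"
        )
    if y.shape[1] != spec.output_dim:
        raise ValueError(
            f"target dimension {y.shape[1]} != spec output_dim {spec.output_dim}"
        )
    return X, Xm, y, subjects


def _validation_split(subjects: np.ndarray, n: int, seed: int):
    """Boolean mask of validation rows: one held-out training subject, or
    the last 10% of rows when only one subject is present."""
    unique = sorted(set(subjects))
    if len(unique) >= 2:
        rng = np.random.default_rng(seed)
        val_subject = unique[int(rng.integers(len(unique)))]
        mask = subjects == val_subject
        logger.info("early stopping on held-out subject %s", val_subject)
    else:
        mask = np.zeros(n, dtype=bool)
        mask[int(n * 0.9):] = True
    if mask.all() or not mask.any():
        raise ValueError("validation split degenerate; need more data")
    return mask


def _standardize_fit(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0
    return mean, scale


def renormalize_quaternions(raw: np.ndarray) -> np.ndarray:
    """Reshape ``(..., 4*m)`` to quaternions and rescale each to unit norm;
    zero-norm outputs are replaced by the identity with a warning."""
    raw = np.asarray(raw, dtype=float)
    shaped = raw.reshape(raw.shape[:-1] + (-1, 4)).copy()
    norms = np.linalg.norm(shaped, axis=-1)
    bad = norms == 0.0
    if bad.any():
        logger.warning("%d zero-norm quaternion outputs replaced by identity", bad.sum())
        shaped[bad] = np.array([1.0, 0.0, 0.0, 0.0])
        norms = np.linalg.norm(shaped, axis=-1)
    shaped /= norms[..., None]
    return shaped.reshape(raw.shape)


# ---------------------------------------------------------------------------
# SINN: shallow stacked-input network
# ---------------------------------------------------------------------------

def train_sinn(samples: Sequence[StackedSample], spec: ModelSpec) -> TrainedModel:
    """Fit the shallow stacked-input network with Adam + early stopping."""
    spec = copy.deepcopy(spec)
    spec.kind = "sinn"
    X, _, y, subjects = _collect(samples, spec)
    val = _validation_split(subjects, len(X), spec.seed)
    mean, scale = _standardize_fit(X)
    Xs = (X - mean) / scale
    Xtr, ytr = Xs[~val], y[~val]
    Xva, yva = Xs[val], y[val]

    mlp = MLPRegressor(
        hidden_layer_sizes=tuple(spec.hidden_sizes),
        activation="relu",
        solver="adam",
        learning_rate_init=spec.learning_rate,
        batch_size=min(spec.batch_size, len(Xtr)),
        shuffle=True,
        random_state=spec.seed,
    )
    history, best = [], None
    best_loss, since_best = np.inf, 0
    for epoch in range(spec.max_epochs):
        mlp.partial_fit(Xtr, ytr)
        train_loss = float(mlp.loss_)
        if not np.isfinite(train_loss):
            raise RuntimeError(f"training diverged (non-finite loss at epoch {epoch + 1})")
        val_loss = float(np.mean((mlp.predict(Xva) - yva) ** 2))
        history.append({"epoch": epoch + 1, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_loss - 1e-7:
            best_loss, since_best = val_loss, 0
            best = (
                [c.copy() for c in mlp.coefs_],
                [b.copy() for b in mlp.intercepts_],
                epoch + 1,
            )
        else:
            since_best += 1
            if since_best >= spec.patience:
                break
    if best is not None:
        mlp.coefs_, mlp.intercepts_ = best[0], best[1]
        logger.info("best epoch %d (val loss %.3e)", best[2], best_loss)
    return TrainedModel(
        spec=spec, weights=mlp, training_history=history,
        norm_mean=mean, norm_scale=scale,
    )


def predict_sinn(model: TrainedModel, input_stacked: np.ndarray) -> np.ndarray:
    """Pose vector(s) with unit-norm quaternions from stacked input(s)."""
    X = np.atleast_2d(np.asarray(input_stacked, dtype=float))
    if X.shape[1] != model.spec.input_dim:
        raise ValueError(
            f"input length {X.shape[1]} != expected {model.spec.input_dim}"
        )
    Xs = (X - model.norm_mean) / model.norm_scale
    raw = model.weights.predict(Xs)
    out = renormalize_quaternions(raw)
    return out[0] if np.asarray(input_stacked).ndim == 1 else out


# ---------------------------------------------------------------------------
# RNN: bidirectional LSTM in numpy
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _LSTMDirection:
    """One LSTM direction: gates (i, f, g, o) stacked in W (4H x (D+H))."""

    def __init__(self, rng, d_in: int, hidden: int):
        s = 1.0 / np.sqrt(d_in + hidden)
        self.W = rng.uniform(-s, s, size=(4 * hidden, d_in + hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.H = hidden

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        """x: (T, B, D) -> h: (T, B, H); caches for backward."""
        T, B, _ = x.shape
        H = self.H
        h = np.zeros((T + 1, B, H))
        c = np.zeros((T + 1, B, H))
        cache = []
        for t in range(T):
            z = np.concatenate([x[t], h[t]], axis=1) @ self.W.T + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c[t + 1] = f * c[t] + i * g
            h[t + 1] = o * np.tanh(c[t + 1])
            cache.append((np.concatenate([x[t], h[t]], axis=1), i, f, g, o, c[t], c[t + 1]))
        self._cache = cache
        return h[1:]

    def backward(self, dh_seq):
        """dh_seq: (T, B, H) upstream gradient per step; returns dx (T, B, D)
        and accumulates dW, db."""
        T, B, H = dh_seq.shape
        d_in = self.W.shape[1] - H
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        dx = np.zeros((T, B, d_in))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in reversed(range(T)):
            xh, i, f, g, o, c_prev, c_new = self._cache[t]
            dh = dh_seq[t] + dh_next
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c**2) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            self.dW += dz.T @ xh
            self.db += dz.sum(axis=0)
            dxh = dz @ self.W
            dx[t] = dxh[:, :d_in]
            dh_next = dxh[:, d_in:]
        return dx


class BiLSTMNet:
    """Stacked bidirectional LSTM with a linear readout at the centre step."""

    def __init__(self, spec: ModelSpec):
        rng = np.random.default_rng(spec.seed)
        self.spec = spec
        self.layers = []
        d = spec.input_dim
        for _ in range(spec.rnn_layers):
            fwd = _LSTMDirection(rng, d, spec.rnn_hidden)
            bwd = _LSTMDirection(rng, d, spec.rnn_hidden)
            self.layers.append((fwd, bwd))
            d = 2 * spec.rnn_hidden
        s = 1.0 / np.sqrt(d)
        self.Wo = rng.uniform(-s, s, size=(d, spec.output_dim))
        self.bo = np.zeros(spec.output_dim)
        self._rng = rng

    def params(self):
        out = []
        for fwd, bwd in self.layers:
            out += fwd.params() + bwd.params()
        out += [self.Wo, self.bo]
        return out

    def forward(self, x, training=False):
        """x: (B, D, SIL) -> (B, output_dim); reads out the centre step."""
        h = np.transpose(x, (2, 0, 1))  # (T, B, D)
        self._drop_masks = []
        for li, (fwd, bwd) in enumerate(self.layers):
            hf = fwd.forward(h)
            hb = bwd.forward(h[::-1])[::-1]
            h = np.concatenate([hf, hb], axis=2)
            if training and self.spec.dropout > 0.0 and li < len(self.layers) - 1:
                keep = 1.0 - self.spec.dropout
                mask = (self._rng.random(h.shape) < keep) / keep
                h = h * mask
                self._drop_masks.append(mask)
            else:
                self._drop_masks.append(None)
        centre = (
            self.spec.centre_step
            if self.spec.centre_step is not None
            else (self.spec.sil - 1) // 2
        )
        self._h_top = h
        self._centre = centre
        return h[centre] @ self.Wo + self.bo

    def backward(self, dout):
        """dout: (B, output_dim); returns list of gradients matching params()."""
        dh_top = np.zeros_like(self._h_top)
        dh_top[self._centre] = dout @ self.Wo.T
        dWo = self._h_top[self._centre].T @ dout
        dbo = dout.sum(axis=0)
        dh = dh_top
        grads_layers = []
        for li in reversed(range(len(self.layers))):
            mask = self._drop_masks[li]
            if mask is not None:
                dh = dh * mask
            fwd, bwd = self.layers[li]
            H = self.spec.rnn_hidden
            dxf = fwd.backward(dh[:, :, :H])
            dxb = bwd.backward(dh[::-1][:, :, H:])[::-1]
            dh = dxf + dxb
            grads_layers.append([fwd.dW, fwd.db, bwd.dW, bwd.db])
        grads = []
        for g4 in reversed(grads_layers):
            grads += g4
        grads += [dWo, dbo]
        return grads


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def train_rnn(samples: Sequence[StackedSample], spec: ModelSpec) -> TrainedModel:
    """Fit the bidirectional-LSTM baseline on (D, SIL) window matrices."""
    spec = copy.deepcopy(spec)
    spec.kind = "rnn"
    _, Xm, y, subjects = _collect(samples, spec)
    spec.sil = Xm.shape[2]
    val = _validation_split(subjects, len(Xm), spec.seed)
    mean, scale = _standardize_fit(Xm.transpose(0, 2, 1).reshape(-1, Xm.shape[1]))
    Xs = (Xm - mean[None, :, None]) / scale[None, :, None]
    Xtr, ytr = Xs[~val], y[~val]
    Xva, yva = Xs[val], y[val]

    net = BiLSTMNet(spec)
    opt = _Adam(net.params(), spec.learning_rate)
    shuffle_rng = np.random.default_rng(spec.seed + 1)
    history, best = [], None
    best_loss, since_best = np.inf, 0
    n = len(Xtr)
    bs = min(spec.batch_size, n)
    for epoch in range(spec.max_epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            pred = net.forward(Xtr[idx], training=True)
            err = pred - ytr[idx]
            losses.append(float(np.mean(err**2)))
            grads = net.backward(2.0 * err / err.size)
            opt.step(net.params(), grads)
        train_loss = float(np.mean(losses))
        if not np.isfinite(train_loss):
            raise RuntimeError(f"training diverged (non-finite loss at epoch {epoch + 1})")
        val_loss = float(np.mean((net.forward(Xva) - yva) ** 2))
        history.append({"epoch": epoch + 1, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_loss - 1e-7:
            best_loss, since_best = val_loss, 0
            best = [p.copy() for p in net.params()]
        else:
            since_best += 1
            if since_best >= spec.patience:
                break
    if best is not None:
        for p, bp in zip(net.params(), best):
            p[...] = bp
    return TrainedModel(
        spec=spec, weights=net, training_history=history,
        norm_mean=mean, norm_scale=scale,
    )


def predict_rnn(model: TrainedModel, input_matrix: np.ndarray) -> np.ndarray:
    """Pose vector(s) with unit-norm quaternions from (D, SIL) input(s)."""
    X = np.asarray(input_matrix, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[None]
    if X.shape[1] != model.spec.input_dim:
        raise ValueError(
            f"per-step dimension {X.shape[1]} != expected {model.spec.input_dim}"
        )
    Xs = (X - model.norm_mean[None, :, None]) / model.norm_scale[None, :, None]
    raw = model.weights.forward(Xs)
    out = renormalize_quaternions(raw)
    return out[0] if single else out


def parameter_count(model_or_spec) -> int:
    """Number of trained parameters of a model or (default-initialised) spec."""
    if isinstance(model_or_spec, TrainedModel):
        spec, weights = model_or_spec.spec, model_or_spec.weights
    else:
        spec, weights = model_or_spec, None
    if spec.kind == "sinn":
        dims = [spec.input_dim, *spec.hidden_sizes, spec.output_dim]
        return sum(a * b + b for a, b in zip(dims[:-1], dims[1:]))
    net = weights if isinstance(weights, BiLSTMNet) else BiLSTMNet(spec)
    return sum(p.size for p in net.params())


# ---------------------------------------------------------------------------
# Pose assembly
# ---------------------------------------------------------------------------

def assemble_full_pose_array(
    upper_pred: np.ndarray,
    lower_pred: np.ndarray,
    input_rel_orientations: np.ndarray,
) -> np.ndarray:
    """Full 23-segment pelvis-relative quaternion array(s).

    ``upper_pred``: (..., 48), ``lower_pred``: (..., 24),
    ``input_rel_orientations``: (..., 5, 4) measured pelvis-relative
    quaternions ordered as SENSOR_SEGMENTS.  The pelvis entry of the result
    is the identity; the four limb inputs are passed through bit-identical.
    """
    upper_pred = np.asarray(upper_pred, dtype=float)
    lower_pred = np.asarray(lower_pred, dtype=float)
    inputs = np.asarray(input_rel_orientations, dtype=float)
    if upper_pred.shape[-1] != 48 or lower_pred.shape[-1] != 24:
        raise ValueError("expected 48 upper and 24 lower prediction components")
    if inputs.shape[-2:] != (5, 4):
        raise ValueError("expected (..., 5, 4) measured input orientations")
    lead = upper_pred.shape[:-1]
    out = np.zeros(lead + (23, 4))
    out[..., SEGMENT_INDEX["Pelvis"], :] = np.array([1.0, 0.0, 0.0, 0.0])
    for j, seg in enumerate(SENSOR_SEGMENTS):
        if seg == "Pelvis":
            continue
        out[..., SEGMENT_INDEX[seg], :] = inputs[..., j, :]
    up = upper_pred.reshape(lead + (12, 4))
    for j, seg in enumerate(UPPER_OUTPUT_SEGMENTS):
        out[..., SEGMENT_INDEX[seg], :] = up[..., j, :]
    lo = lower_pred.reshape(lead + (6, 4))
    for j, seg in enumerate(LOWER_OUTPUT_SEGMENTS):
        out[..., SEGMENT_INDEX[seg], :] = lo[..., j, :]
    return out


def assemble_full_pose(upper_pred, lower_pred, input_rel_orientations, timestamp_index=0, fs=60.0):
    """FramePose from per-half predictions plus the measured limb inputs."""
    from .quatkin import FramePose

    arr = assemble_full_pose_array(upper_pred, lower_pred, input_rel_orientations)
    if arr.ndim != 2:
        raise ValueError("assemble_full_pose expects a single pose; use the array variant")
    # predictions are already unit-norm (renormalized); measured inputs are unit
    return FramePose.from_array(arr, timestamp_index=timestamp_index, fs=fs)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path) -> None:
    """Write a versioned container (.npz) with spec, normalization,
    weights, seed and history."""
    arrays = {"norm_mean": model.norm_mean, "norm_scale": model.norm_scale}
    if model.spec.kind == "sinn":
        mlp = model.weights
        for i, c in enumerate(mlp.coefs_):
            arrays[f"coef_{i}"] = c
        for i, b in enumerate(mlp.intercepts_):
            arrays[f"intercept_{i}"] = b
    else:
        for i, p in enumerate(model.weights.params()):
            arrays[f"param_{i}"] = p
    meta = {
        "format_version": model.format_version,
        "spec": {**asdict(model.spec), "hidden_sizes": list(model.spec.hidden_sizes)},
        "training_history": model.training_history,
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]))
        if meta["format_version"] != FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {meta['format_version']}")
        spec = ModelSpec(**{**meta["spec"], "hidden_sizes": tuple(meta["spec"]["hidden_sizes"])})
        if spec.kind == "sinn":
            coefs, intercepts = [], []
            i = 0
            while f"coef_{i}" in data:
                coefs.append(data[f"coef_{i}"])
                intercepts.append(data[f"intercept_{i}"])
                i += 1
            mlp = MLPRegressor(hidden_layer_sizes=tuple(spec.hidden_sizes), activation="relu")
            mlp.coefs_, mlp.intercepts_ = coefs, intercepts
            mlp.n_layers_ = len(coefs) + 1
            mlp.n_outputs_ = spec.output_dim
            mlp.out_activation_ = "identity"
            mlp.n_features_in_ = spec.input_dim
            weights = mlp
        else:
            net = BiLSTMNet(spec)
            for i, p in enumerate(net.params()):
                p[...] = data[f"param_{i}"]
            weights = net
        return TrainedModel(
            spec=spec,
            weights=weights,
            training_history=meta["training_history"],
            norm_mean=data["norm_mean"],
            norm_scale=data["norm_scale"],
        )
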