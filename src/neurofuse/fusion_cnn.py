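"""Voxel-level modality fusion via a width-1 1D convolution network.

Input is laid out as [modality-channels x voxels].  The convolutional layer
has kernel width 1 along the voxel axis, so each of its filters produces a
new map whose value at voxel v is a learned linear combination of the
modality values at that same voxel.  A fully connected ReLU layer (50 units)
and a two-node softmax output follow.  Training is plain SGD with momentum,
weight decay and cross-entropy loss.

The network is small enough that it is implemented directly on numpy
arrays; this keeps the package free of a deep-learning runtime and makes
single-threaded reproducibility exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from neurofuse.cohort import MultimodalCohort
from neurofuse.confounds import fit_confounds, remove_confounds
from neurofuse.crossval import FoldPlan, prediction_rows, standardize_fit
from neurofuse.errors import ConfigurationError, IncompatibleDataError


@dataclass(frozen=True)
class CNNSpec:
    n_filters: int = 10
    kernel_width_voxels: int = 1
    hidden_units: int = 50
    epochs: int = 50
    batch_size: int = 4
    learning_rate: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_filters", "kernel_width_voxels", "hidden_units", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("learning_rate", "momentum", "weight_decay"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.kernel_width_voxels != 1:
            raise ConfigurationError("only kernel width 1 (per-voxel channel mixing) is supported")


@dataclass
class CNNModel:
    """Weights of the three-layer network plus its training log."""

    n_voxels: int
    n_modalities: int
    spec: CNNSpec
    conv_w: np.ndarray  # [n_filters, n_modalities]
    conv_b: np.ndarray  # [n_filters]
    hidden_w: np.ndarray  # [hidden_units, n_filters * n_voxels]
    hidden_b: np.ndarray  # [hidden_units]
    out_w: np.ndarray  # [2, hidden_units]
    out_b: np.ndarray  # [2]
    modality_order: tuple[str, ...] = ()
    loss_log: list[float] = field(default_factory=list)

    def parameter_count(self) -> int:
        return sum(
            int(np.prod(w.shape))
            for w in (self.conv_w, self.conv_b, self.hidden_w, self.hidden_b, self.out_w, self.out_b)
        )

    def parameters(self):
        return [self.conv_w, self.conv_b, self.hidden_w, self.hidden_b, self.out_w, self.out_b]


def expected_parameter_count(n_voxels: int, n_modalities: int, spec: CNNSpec) -> int:
    """Closed-form trainable parameter count for the architecture."""
    f, k, h = spec.n_filters, spec.kernel_width_voxels, spec.hidden_units
    return f * (n_modalities * k + 1) + h * (f * n_voxels + 1) + 2 * (h + 1)


def build_model(
    n_voxels: int, n_modalities: int, spec: CNNSpec, modality_order: tuple[str, ...] = ()
) -> CNNModel:
    """Deterministically initialized model (He-style normal weights, zero biases)."""
    if n_voxels < 1 or n_modalities < 1:
        raise ConfigurationError("n_voxels and n_modalities must be >= 1")
    rng = np.random.default_rng(spec.seed)
    f, h = spec.n_filters, spec.hidden_units

    def he(shape, fan_in):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    return CNNModel(
        n_voxels=n_voxels,
        n_modalities=n_modalities,
        spec=spec,
        conv_w=he((f, n_modalities), n_modalities),
        conv_b=np.zeros(f),
        hidden_w=he((h, f * n_voxels), f * n_voxels),
        hidden_b=np.zeros(h),
        out_w=he((2, h), h),
        out_b=np.zeros(2),
        modality_order=tuple(modality_order),
    )


def _forward(model: CNNModel, x: np.ndarray):
    """x: [n, M, V] -> caches for backprop and softmax probabilities."""
    if x.ndim != 3 or x.shape[1] != model.n_modalities or x.shape[2] != model.n_voxels:
        raise IncompatibleDataError(
            f"expected input [n, {model.n_modalities}, {model.n_voxels}], got {x.shape}"
        )
    z1 = np.einsum("fm,nmv->nfv", model.conv_w, x) + model.conv_b[None, :, None]
    a1 = np.maximum(z1, 0.0)
    flat = a1.reshape(x.shape[0], -1)
    z2 = flat @ model.hidden_w.T + model.hidden_b
    a2 = np.maximum(z2, 0.0)
    z3 = a2 @ model.out_w.T + model.out_b
    z3 = z3 - z3.max(axis=1, keepdims=True)
    e = np.exp(z3)
    p = e / e.sum(axis=1, keepdims=True)
    return z1, flat, z2, a2, p


def _backward(model: CNNModel, x, y, z1, flat, z2, a2, p):
    n = x.shape[0]
    gz3 = p.copy()
    gz3[np.arange(n), y] -= 1.0
    gz3 /= n
    g_out_w = gz3.T @ a2
    g_out_b = gz3.sum(axis=0)
    gz2 = (gz3 @ model.out_w) * (z2 > 0)
    g_hidden_w = gz2.T @ flat
    g_hidden_b = gz2.sum(axis=0)
    gflat = gz2 @ model.hidden_w
    gz1 = gflat.reshape(n, model.spec.n_filters, model.n_voxels) * (z1 > 0)
    g_conv_w = np.einsum("nfv,nmv->fm", gz1, x)
    g_conv_b = gz1.sum(axis=(0, 2))
    return [g_conv_w, g_conv_b, g_hidden_w, g_hidden_b, g_out_w, g_out_b]


def train_cnn(
    x: np.ndarray, y: np.ndarray, spec: CNNSpec, modality_order: tuple[str, ...] = ()
) -> CNNModel:
    """Train from scratch on tensors [n, M, V] with SGD + momentum.

    The per-epoch mean cross-entropy is logged; non-finite loss aborts with
    a diagnostic rather than silently continuing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    if set(np.unique(y)) - {0, 1}:
        raise ConfigurationError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ConfigurationError("both classes must be present for training")
    model = build_model(x.shape[2], x.shape[1], spec, modality_order)
    rng = np.random.default_rng(spec.seed + 1)  # shuffling stream, distinct from init
    velocity = [np.zeros_like(w) for w in model.parameters()]
    n = x.shape[0]
    for _epoch in range(spec.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, spec.batch_size):
            batch = order[start:start + spec.batch_size]
            xb, yb = x[batch], y[batch]
            z1, flat, z2, a2, p = _forward(model, xb)
            loss = float(-np.log(np.clip(p[np.arange(len(batch)), yb], 1e-12, None)).mean())
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {_epoch}"
                )
            epoch_loss += loss * len(batch)
            grads = _backward(model, xb, yb, z1, flat, z2, a2, p)
            params = model.parameters()
            for w, v, g in zip(params, velocity, grads):
                v *= spec.momentum
                v -= spec.learning_rate * (g + spec.weight_decay * w)
                w += v
        model.loss_log.append(epoch_loss / n)
    return model


def predict_cnn(model: CNNModel, x: np.ndarray) -> np.ndarray:
    """Patient-node softmax probability per subject."""
    *_, p = _forward(model, np.asarray(x, dtype=float))
    return p[:, 1]


def _fold_tensors(cohort: MultimodalCohort, plan: FoldPlan, fold: int):
    """Residualize and per-voxel-channel standardize all modalities for one fold."""
    tr = plan.train_indices(fold)
    te = plan.test_indices(fold)
    train_ch, test_ch = [], []
    for modality in cohort.modalities:
        xm = cohort.data[modality]
        confound = fit_confounds(xm[tr], cohort.age[tr], cohort.sex[tr])
        train_r = remove_confounds(confound, xm[tr], cohort.age[tr], cohort.sex[tr])
        test_r = remove_confounds(confound, xm[te], cohort.age[te], cohort.sex[te])
        center, scale = standardize_fit(train_r)
        train_ch.append((train_r - center) / scale)
        test_ch.append((test_r - center) / scale)
    return np.stack(train_ch, axis=1), np.stack(test_ch, axis=1), tr, te


def cross_validate_cnn(
    cohort: MultimodalCohort, spec: CNNSpec, plan: FoldPlan
) -> tuple[pd.DataFrame, list[CNNModel]]:
    """Per-fold train/score of the fusion network over the shared fold plan."""
    frames = []
    models = []
    order = tuple(cohort.modalities)
    for fold in range(plan.n_folds):
        train_x, test_x, tr, te = _fold_tensors(cohort, plan, fold)
        model = train_cnn(train_x, cohort.labels[tr], spec, modality_order=order)
        probs = predict_cnn(model, test_x)
        models.append(model)
        frames.append(
            prediction_rows(
                cohort.subject_ids,
                te,
                np.full(len(te), fold),
                "cnn",
                "cnn",
                probs,
                cohort.labels[te],
            )
        )
    return pd.concat(frames, ignore_index=True), models
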