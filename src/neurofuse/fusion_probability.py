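"""Post-classification integration of unimodal outcome probabilities.

Three rules: the mean of the per-modality patient probabilities, the
probability of the most confident modality (largest |p - 0.5|), and a
logistic stack fitted on the log-odds of in-sample training probabilities.
All three reuse the fold plan of the unimodal runs and emit standard
PredictionTable rows (sources ``fusion_mean`` / ``fusion_max`` /
``fusion_logistic``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from neurofuse.crossval import (
    FoldPlan,
    UnimodalCVResult,
    labels_from_probs,
    prediction_rows,
)
from neurofuse.errors import ConfigurationError, IncompatibleDataError


def _check_probs(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        raise ConfigurationError("no modality probabilities supplied")
    if np.isnan(probs).any():
        raise IncompatibleDataError("missing modality probability; no silent imputation")
    if np.any(probs < 0) or np.any(probs > 1):
        raise IncompatibleDataError("probabilities must lie in [0, 1]")
    return probs


def fuse_mean(probs) -> tuple[float, int]:
    """Arithmetic mean of modality probabilities; ties at 0.5 predict control."""
    probs = _check_probs(probs)
    p = float(probs.mean())
    return p, int(p > 0.5)


def fuse_max(probs) -> tuple[float, int]:
    """Probability of the most confident modality (largest |p - 0.5|).

    Confidence ties are broken by the fixed modality order of ``probs``.
    """
    probs = _check_probs(probs)
    k = int(np.argmax(np.abs(probs - 0.5)))
    p = float(probs[k])
    return p, int(p > 0.5)


@dataclass
class StackModel:
    """Logistic model on clipped log-odds of per-modality probabilities."""

    intercept: float
    coefs: np.ndarray
    eps: float
    ridge_fallback: bool = False

    def predict(self, probs: np.ndarray) -> np.ndarray:
        z = _log_odds(np.atleast_2d(probs), self.eps)
        eta = self.intercept + z @ self.coefs
        return 1.0 / (1.0 + np.exp(-eta))


def _log_odds(probs: np.ndarray, eps: float) -> np.ndarray:
    p = np.clip(probs, eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


def fit_stack(train_probs: np.ndarray, train_labels: np.ndarray, eps: float = 1e-6) -> StackModel:
    """Maximum-likelihood logistic fit of labels on modality log-odds.

    Perfect separation makes the unpenalized fit diverge; in that case a
    ridge-stabilized logistic fit is used instead and a warning is issued.
    """
    if not 0.0 < eps < 0.5:
        raise ConfigurationError("eps must be in (0, 0.5)")
    train_probs = np.atleast_2d(np.asarray(train_probs, dtype=float))
    y = np.asarray(train_labels)
    if train_probs.shape[0] != y.shape[0]:
        raise IncompatibleDataError("probability rows must match label count")
    z = _log_odds(train_probs, eps)
    ridge_fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            lr = LogisticRegression(C=np.inf, max_iter=2000)
            lr.fit(z, y)
            fitted = np.clip(lr.predict_proba(z)[:, list(lr.classes_).index(1)], 1e-15, 1 - 1e-15)
            log_loss = float(-np.mean(y * np.log(fitted) + (1 - y) * np.log(1 - fitted)))
            # near-zero training deviance or exploding coefficients indicate separation
            if np.abs(lr.coef_).max() > 1e3 or log_loss < 1e-4:
                raise RuntimeError("perfect separation")
        except Exception:
            ridge_fallback = True
    if ridge_fallback:
        warnings.warn(
            "perfect separation in stack training; falling back to ridge-stabilized logistic fit"
        )
        lr = LogisticRegression(C=1.0, max_iter=2000)
        lr.fit(z, y)
    col = list(lr.classes_).index(1)
    sign = 1.0 if col == 1 else -1.0
    return StackModel(
        intercept=float(lr.intercept_[0] * sign),
        coefs=lr.coef_[0] * sign,
        eps=eps,
        ridge_fallback=ridge_fallback,
    )


def predict_stack(model: StackModel, probs) -> tuple[float, int]:
    probs = _check_probs(probs)
    p = float(model.predict(probs)[0])
    return p, int(p > 0.5)


def probability_fusion_cv(
    unimodal: dict[str, UnimodalCVResult],
    labels: np.ndarray,
    plan: FoldPlan,
    subject_ids: list[str],
    algorithm: str,
    eps: float = 1e-6,
) -> pd.DataFrame:
    """All three probability-fusion rules over the shared fold plan.

    ``unimodal`` maps modality name to its CV result (same plan, same
    algorithm).  Stack training uses each fold's in-sample training
    probabilities, as produced by the unimodal models on their own training
    subjects.
    """
    modalities = list(unimodal.keys())
    if not modalities:
        raise ConfigurationError("no unimodal results supplied")
    labels = np.asarray(labels)

    frames = []
    for fold in range(plan.n_folds):
        te = plan.test_indices(fold)
        tr = plan.train_indices(fold)
        test_p = np.column_stack([unimodal[m].folds[fold].test_probs for m in modalities])
        train_p = np.column_stack([unimodal[m].folds[fold].train_probs for m in modalities])

        mean_p = np.array([fuse_mean(row)[0] for row in test_p])
        max_p = np.array([fuse_max(row)[0] for row in test_p])
        stack = fit_stack(train_p, labels[tr], eps=eps)
        stack_p = stack.predict(test_p)

        folds_col = np.full(len(te), fold)
        for source, probs in (
            ("fusion_mean", mean_p),
            ("fusion_max", max_p),
            ("fusion_logistic", stack_p),
        ):
            frames.append(
                prediction_rows(
                    subject_ids, te, folds_col, source, algorithm, probs, labels[te]
                )
            )
    return pd.concat(frames, ignore_index=True)


def fused_labels(probs: np.ndarray) -> np.ndarray:
    return labels_from_probs(probs)
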