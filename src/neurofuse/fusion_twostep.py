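"""Two-step sequential integration: per-modality voxel selection, merged refit.

Step 1 reuses the unimodal fits of each fold to rank voxels (|coefficient|
for linear families, importance for tree families); step 2 concatenates the
selected, residualized, training-standardized columns across modalities and
refits the same classifier family on the merged matrix.  Selection is redone
inside every fold so no test-row information leaks into the voxel choice.
Overlap between per-modality selections is reported under both
normalizations (fraction of all voxels, and fraction of the smaller mask).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from neurofuse.cohort import MultimodalCohort
from neurofuse.crossval import (
    ClassifierSpec,
    FoldPlan,
    UnimodalCVResult,
    fit_classifier,
    model_scores,
    predict_prob_patient,
    prediction_rows,
    prepare_fold_features,
)
from neurofuse.errors import ConfigurationError, UndefinedStatisticError

#: Default selection mode per classifier family.
DEFAULT_RULES = {
    "ridge": ("top_fraction", 0.2),
    "lasso": ("nonzero", None),
    "random_forest": ("top_fraction", 0.2),
    "gradient_boosting": ("nonzero", None),
}


@dataclass(frozen=True)
class SelectionRule:
    family: str
    mode: str
    fraction: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("top_fraction", "nonzero"):
            raise ConfigurationError("mode must be 'top_fraction' or 'nonzero'")
        if self.mode == "top_fraction":
            if self.fraction is None or not 0.0 < self.fraction <= 1.0:
                raise ConfigurationError("top_fraction requires fraction in (0, 1]")

    @classmethod
    def default_for(cls, family: str) -> "SelectionRule":
        mode, q = DEFAULT_RULES[family]
        return cls(family=family, mode=mode, fraction=q)


@dataclass
class SelectionMask:
    """Voxel indices chosen for one modality in one fold, with their scores."""

    modality: str
    fold: int
    indices: np.ndarray
    scores: np.ndarray

    @property
    def size(self) -> int:
        return int(self.indices.size)


def select_voxels(model, rule: SelectionRule, modality: str = "", fold: int = -1) -> SelectionMask:
    """Apply a selection rule to a fitted model's per-voxel scores.

    Ties at the top-fraction boundary are broken toward the lower voxel
    index (stable sort on descending score).
    """
    scores = model_scores(model)
    if rule.mode == "top_fraction":
        k = ceil(rule.fraction * scores.size)
        order = np.argsort(-scores, kind="stable")
        idx = np.sort(order[:k])
    else:
        idx = np.flatnonzero(scores != 0)
        if idx.size == 0:
            warnings.warn(f"all scores zero for {modality!r} fold {fold}; empty selection")
    return SelectionMask(modality=modality, fold=fold, indices=idx, scores=scores[idx])


def merge_and_refit(
    cohort: MultimodalCohort,
    masks: dict[str, SelectionMask],
    spec: ClassifierSpec,
    plan: FoldPlan,
    fold: int,
) -> tuple[np.ndarray, object]:
    """Refit ``spec.family`` on the merged selected columns of one fold.

    Returns (test patient probabilities, fitted merged model).  Confound
    removal and standardization are redone per modality from training rows;
    an empty per-modality mask simply contributes no columns.
    """
    if all(m.size == 0 for m in masks.values()):
        raise ConfigurationError("all selection masks are empty; nothing to merge")
    tr = plan.train_indices(fold)
    train_blocks, test_blocks = [], []
    for modality, mask in masks.items():
        if mask.size == 0:
            warnings.warn(f"modality {modality!r} contributes no columns in fold {fold}")
            continue
        train_z, test_z, *_ = prepare_fold_features(cohort, modality, plan, fold)
        train_blocks.append(train_z[:, mask.indices])
        test_blocks.append(test_z[:, mask.indices])
    train_x = np.hstack(train_blocks)
    test_x = np.hstack(test_blocks)
    model = fit_classifier(train_x, cohort.labels[tr], spec)
    return predict_prob_patient(model, test_x), model


def selection_overlap(
    mask_a: SelectionMask | np.ndarray, mask_b: SelectionMask | np.ndarray, n_voxels: int
) -> tuple[float, float]:
    """(joint_fraction, containment) of two voxel selections.

    joint_fraction = |A & B| / n_voxels; containment = |A & B| / min(|A|, |B|).
    """
    a = mask_a.indices if isinstance(mask_a, SelectionMask) else np.asarray(mask_a)
    b = mask_b.indices if isinstance(mask_b, SelectionMask) else np.asarray(mask_b)
    if a.size == 0 or b.size == 0:
        raise UndefinedStatisticError("containment undefined for an empty selection")
    inter = np.intersect1d(a, b).size
    return inter / n_voxels, inter / min(a.size, b.size)


def twostep_cv(
    cohort: MultimodalCohort,
    unimodal: dict[str, UnimodalCVResult],
    spec: ClassifierSpec,
    plan: FoldPlan,
    rule: SelectionRule | None = None,
) -> tuple[pd.DataFrame, list[dict[str, SelectionMask]], pd.DataFrame]:
    """Full two-step run over the shared fold plan.

    Returns (PredictionTable with source 'twostep', per-fold selection masks,
    per-fold overlap table with both normalizations for every modality pair).
    """
    rule = rule or SelectionRule.default_for(spec.family)
    modalities = list(unimodal.keys())
    frames = []
    fold_masks: list[dict[str, SelectionMask]] = []
    overlap_rows = []
    for fold in range(plan.n_folds):
        te = plan.test_indices(fold)
        masks = {
            m: select_voxels(unimodal[m].folds[fold].model, rule, modality=m, fold=fold)
            for m in modalities
        }
        fold_masks.append(masks)
        probs, _ = merge_and_refit(cohort, masks, spec, plan, fold)
        frames.append(
            prediction_rows(
                cohort.subject_ids,
                te,
                np.full(len(te), fold),
                "twostep",
                spec.family,
                probs,
                cohort.labels[te],
            )
        )
        for i, a in enumerate(modalities):
            for b in modalities[i + 1:]:
                if masks[a].size == 0 or masks[b].size == 0:
                    continue
                joint, contain = selection_overlap(masks[a], masks[b], cohort.n_voxels)
                overlap_rows.append(
                    {
                        "fold": fold,
                        "modality_a": a,
                        "modality_b": b,
                        "size_a": masks[a].size,
                        "size_b": masks[b].size,
                        "joint_fraction": joint,
                        "containment": contain,
                    }
                )
    table = pd.concat(frames, ignore_index=True)
    return table, fold_masks, pd.DataFrame(overlap_rows)


def mean_overlap(overlap_table: pd.DataFrame) -> pd.DataFrame:
    """Average per-fold overlap statistics for each modality pair."""
    return (
        overlap_table.groupby(["modality_a", "modality_b"])[["joint_fraction", "containment"]]
        .mean()
        .reset_index()
    )
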