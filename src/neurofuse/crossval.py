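"""Fixed K-fold cross-validation of voxel-map classifiers.

One FoldPlan is built per experiment and reused verbatim by every unimodal
and multimodal analysis, so per-subject correctness indicators are directly
comparable across map types and fusion strategies.  Inside each fold the
order of operations is: fit confound model on training rows, residualize
train and test, standardize by training mean/SD, fit the classifier, score
the held-out rows.  Test labels are never read before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from neurofuse.cohort import MultimodalCohort
from neurofuse.confounds import ConfoundModel, fit_confounds, remove_confounds
from neurofuse.errors import ConfigurationError, IncompatibleDataError

FAMILIES = ("ridge", "lasso", "random_forest", "gradient_boosting")

#: PredictionTable column schema (CSV round-trip uses exactly these columns).
PREDICTION_COLUMNS = (
    "subject", "fold", "source", "algorithm", "prob_patient", "predicted", "correct"
)


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of every subject to exactly one test fold."""

    n_folds: int
    assignment: np.ndarray
    stratified: bool
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


def make_folds(
    labels: np.ndarray, n_folds: int = 10, seed: int = 0, stratified: bool = True
) -> FoldPlan:
    """Deterministic (seeded) K-fold partition, stratified by label by default."""
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ConfigurationError("n_folds must be >= 2")
    if n_folds > len(labels):
        raise ConfigurationError("n_folds cannot exceed the number of subjects")
    assignment = np.full(len(labels), -1, dtype=np.int64)
    if stratified:
        classes, counts = np.unique(labels, return_counts=True)
        if counts.min() < n_folds:
            raise ConfigurationError(
                f"smallest class has {counts.min()} subjects; cannot stratify into {n_folds} folds"
            )
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(labels)), labels)):
            assignment[test_idx] = fold
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(labels))
        for fold, chunk in enumerate(np.array_split(perm, n_folds)):
            assignment[chunk] = fold
    return FoldPlan(n_folds=n_folds, assignment=assignment, stratified=stratified, seed=seed)


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the four classifier families plus its tuning settings.

    Penalized families (ridge/lasso) pick their penalty by internal
    stratified 5-fold CV minimizing classification deviance over a path of
    ``n_penalties`` values (or the explicit ``penalties`` list when given).
    Gradient boosting tunes depth, shrinkage and tree count by the same kind
    of internal CV over ``gb_depths`` x ``gb_shrinkages`` x [1..gb_max_trees].
    Random forests use ``n_trees`` trees with sqrt(n_voxels) candidate
    variables per split; the patient probability is the fraction of trees
    voting patient.
    """

    family: str
    seed: int = 0
    internal_cv: int = 5
    n_penalties: int = 10
    penalties: tuple[float, ...] | None = None
    n_trees: int = 1000
    gb_depths: tuple[int, ...] = (1, 2, 3)
    gb_shrinkages: tuple[float, ...] = (0.1, 0.01)
    gb_max_trees: int = 500

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}; choose from {FAMILIES}")


@dataclass
class FittedFold:
    """Everything derived from one fold's training rows.

    Kept so later fusion stages can reuse training-side quantities (in-sample
    probabilities for stacking, coefficient/importance scores for voxel
    selection) without refitting or touching test rows.
    """

    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    confound: ConfoundModel
    center: np.ndarray
    scale: np.ndarray
    model: object
    train_probs: np.ndarray
    test_probs: np.ndarray

    def scores(self) -> np.ndarray:
        """Per-voxel relevance scores of the fitted model."""
        return model_scores(self.model)


@dataclass
class UnimodalCVResult:
    """PredictionTable plus the per-fold fitted artifacts behind it."""

    table: pd.DataFrame
    folds: list[FittedFold] = field(default_factory=list)
    source: str = ""
    algorithm: str = ""


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _fit_gradient_boosting(x: np.ndarray, y: np.ndarray, spec: ClassifierSpec):
    """Internal-CV selection of (depth, shrinkage, n_trees) for boosting.

    For each (depth, shrinkage) a full-length model is fitted on each internal
    training split and ``staged_predict_proba`` gives the validation deviance
    at every intermediate tree count in a single pass.
    """
    splitter = StratifiedKFold(
        n_splits=spec.internal_cv, shuffle=True, random_state=spec.seed
    )
    splits = list(splitter.split(x, y))
    best = None
    for depth in spec.gb_depths:
        for lr in spec.gb_shrinkages:
            dev = np.zeros(spec.gb_max_trees)
            for tr, va in splits:
                gb = GradientBoostingClassifier(
                    max_depth=depth,
                    learning_rate=lr,
                    n_estimators=spec.gb_max_trees,
                    random_state=spec.seed,
                )
                gb.fit(x[tr], y[tr])
                for t, proba in enumerate(gb.staged_predict_proba(x[va])):
                    dev[t] += _deviance(y[va], proba[:, 1])
            t_best = int(np.argmin(dev))
            if best is None or dev[t_best] < best[0]:
                best = (dev[t_best], depth, lr, t_best + 1)
    _, depth, lr, n_trees = best
    final = GradientBoostingClassifier(
        max_depth=depth, learning_rate=lr, n_estimators=n_trees, random_state=spec.seed
    )
    final.fit(x, y)
    return final


def fit_classifier(train_x: np.ndarray, train_y: np.ndarray, spec: ClassifierSpec):
    """Fit one classifier family on (already residualized/standardized) data."""
    train_y = np.asarray(train_y)
    if len(np.unique(train_y)) < 2:
        raise ConfigurationError("training fold contains a single class")
    cv = StratifiedKFold(n_splits=spec.internal_cv, shuffle=True, random_state=spec.seed)
    if spec.family in ("ridge", "lasso"):
        cs = spec.penalties if spec.penalties is not None else spec.n_penalties
        model = LogisticRegressionCV(
            Cs=cs,
            cv=cv,
            l1_ratios=(0.0,) if spec.family == "ridge" else (1.0,),
            solver="lbfgs" if spec.family == "ridge" else "liblinear",
            scoring="neg_log_loss",
            max_iter=2000,
            random_state=spec.seed,
            use_legacy_attributes=False,
        )
        model.fit(train_x, train_y)
        return model
    if spec.family == "random_forest":
        model = RandomForestClassifier(
            n_estimators=spec.n_trees, max_features="sqrt", random_state=spec.seed
        )
        model.fit(train_x, train_y)
        return model
    return _fit_gradient_boosting(train_x, train_y, spec)


def predict_prob_patient(model, x: np.ndarray) -> np.ndarray:
    """Patient-class (label 1) probability per row."""
    proba = model.predict_proba(x)
    col = list(model.classes_).index(1)
    return proba[:, col]


def fit_predict_fold(
    train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray, spec: ClassifierSpec
) -> np.ndarray:
    """Fit on training rows and return patient probabilities for test rows."""
    if train_x.shape[1] != test_x.shape[1]:
        raise IncompatibleDataError("train and test voxel counts differ")
    model = fit_classifier(train_x, train_y, spec)
    return predict_prob_patient(model, test_x)


def model_scores(model) -> np.ndarray:
    """Per-voxel relevance: |coefficient| for linear models, importance for trees."""
    if hasattr(model, "coef_"):
        return np.abs(np.asarray(model.coef_).ravel())
    if hasattr(model, "feature_importances_"):
        return np.asarray(model.feature_importances_)
    raise IncompatibleDataError("model exposes neither coefficients nor importances")


def labels_from_probs(probs: np.ndarray) -> np.ndarray:
    """Threshold at 0.5; exact ties predict control (0)."""
    return (np.asarray(probs) > 0.5).astype(np.int64)


def prediction_rows(
    subject_ids: list[str],
    subject_idx: np.ndarray,
    folds: np.ndarray,
    source: str,
    algorithm: str,
    probs: np.ndarray,
    true_labels: np.ndarray,
) -> pd.DataFrame:
    predicted = labels_from_probs(probs)
    return pd.DataFrame(
        {
            "subject": [subject_ids[i] for i in subject_idx],
            "fold": folds,
            "source": source,
            "algorithm": algorithm,
            "prob_patient": probs,
            "predicted": predicted,
            "correct": (predicted == np.asarray(true_labels)).astype(np.int64),
        }
    )


def standardize_fit(train_x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = train_x.mean(axis=0)
    scale = train_x.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return center, scale


def prepare_fold_features(
    cohort: MultimodalCohort, modality: str, plan: FoldPlan, fold: int
) -> tuple[np.ndarray, np.ndarray, ConfoundModel, np.ndarray, np.ndarray]:
    """Residualize and standardize one modality for one fold.

    Returns (train_z, test_z, confound_model, center, scale); all statistics
    come from training rows only.
    """
    x = cohort.data[modality]
    tr = plan.train_indices(fold)
    te = plan.test_indices(fold)
    confound = fit_confounds(x[tr], cohort.age[tr], cohort.sex[tr])
    train_r = remove_confounds(confound, x[tr], cohort.age[tr], cohort.sex[tr])
    test_r = remove_confounds(confound, x[te], cohort.age[te], cohort.sex[te])
    center, scale = standardize_fit(train_r)
    return (train_r - center) / scale, (test_r - center) / scale, confound, center, scale


def cross_validate_unimodal(
    cohort: MultimodalCohort,
    modality: str,
    spec: ClassifierSpec,
    plan: FoldPlan,
) -> UnimodalCVResult:
    """Run the full fold loop for one modality and one classifier family."""
    if modality not in cohort.data:
        raise ConfigurationError(f"modality {modality!r} not present in cohort")
    if len(plan.assignment) != cohort.n_subjects:
        raise IncompatibleDataError("fold plan does not match cohort size")

    frames = []
    fold_fits: list[FittedFold] = []
    for fold in range(plan.n_folds):
        tr = plan.train_indices(fold)
        te = plan.test_indices(fold)
        train_z, test_z, confound, center, scale = prepare_fold_features(
            cohort, modality, plan, fold
        )
        model = fit_classifier(train_z, cohort.labels[tr], spec)
        test_probs = predict_prob_patient(model, test_z)
        train_probs = predict_prob_patient(model, train_z)
        fold_fits.append(
            FittedFold(
                fold=fold,
                train_idx=tr,
                test_idx=te,
                confound=confound,
                center=center,
                scale=scale,
                model=model,
                train_probs=train_probs,
                test_probs=test_probs,
            )
        )
        frames.append(
            prediction_rows(
                cohort.subject_ids,
                te,
                np.full(len(te), fold),
                modality,
                spec.family,
                test_probs,
                cohort.labels[te],
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return UnimodalCVResult(table=table, folds=fold_fits, source=modality, algorithm=spec.family)


@dataclass(frozen=True)
class AccuracySummary:
    mean: float
    ci_low: float
    ci_high: float
    fold_min: float
    fold_max: float
    n_subjects: int

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "fold_min": self.fold_min,
            "fold_max": self.fold_max,
            "n_subjects": self.n_subjects,
        }


def accuracy_summary(table: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> AccuracySummary:
    """Overall accuracy with subject-level bootstrap CI and per-fold extremes."""
    if len(table) == 0:
        raise ConfigurationError("empty prediction table")
    correct = table["correct"].to_numpy(float)
    n = len(correct)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = correct[idx].mean(axis=1)
    per_fold = table.groupby("fold")["correct"].mean()
    return AccuracySummary(
        mean=float(correct.mean()),
        ci_low=float(np.percentile(boot_means, 2.5)),
        ci_high=float(np.percentile(boot_means, 97.5)),
        fold_min=float(per_fold.min()),
        fold_max=float(per_fold.max()),
        n_subjects=n,
    )


def rerun_with_seed(spec: ClassifierSpec, seed: int) -> ClassifierSpec:
    return replace(spec, seed=seed)
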