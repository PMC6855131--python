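"""Train-only removal of age and sex effects from voxel features.

Per-voxel ordinary least squares of map value on [1, age, sex] is fitted on
training subjects and the fitted linear predictor is subtracted from both
training and test rows.  The diagnosis label never enters the design.
Sex coding is fixed: 1 = male, 0 = female.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from neurofuse.errors import ConfigurationError, IncompatibleDataError


@dataclass
class ConfoundModel:
    intercept: np.ndarray
    age_coef: np.ndarray | None
    sex_coef: np.ndarray | None
    coding: dict = field(default_factory=lambda: {"sex": {"male": 1, "female": 0}})

    @property
    def n_voxels(self) -> int:
        return self.intercept.shape[0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "intercept": self.intercept.tolist(),
            "age_coef": None if self.age_coef is None else self.age_coef.tolist(),
            "sex_coef": None if self.sex_coef is None else self.sex_coef.tolist(),
            "coding": self.coding,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConfoundModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            intercept=np.asarray(payload["intercept"], float),
            age_coef=None if payload["age_coef"] is None else np.asarray(payload["age_coef"], float),
            sex_coef=None if payload["sex_coef"] is None else np.asarray(payload["sex_coef"], float),
            coding=payload["coding"],
        )


def fit_confounds(train_matrix: np.ndarray, age: np.ndarray, sex: np.ndarray) -> ConfoundModel:
    """Fit per-voxel OLS of map values on [1, age, sex] over training rows.

    Constant covariate columns are dropped with a warning (their effect is
    absorbed by the intercept); at least the intercept always remains.
    """
    x = np.asarray(train_matrix, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ConfigurationError("need at least 3 training subjects")
    if age.shape != (n,) or sex.shape != (n,):
        raise IncompatibleDataError("age/sex length must match training rows")

    cols = [np.ones(n)]
    use_age = np.ptp(age) > 0
    use_sex = np.ptp(sex) > 0
    if use_age:
        cols.append(age)
    else:
        warnings.warn("age is constant in the training sample; dropping age term")
    if use_sex:
        cols.append(sex)
    else:
        warnings.warn("sex is constant in the training sample; dropping sex term")
    design = np.column_stack(cols)

    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    idx = 1
    intercept = coef[0]
    age_coef = None
    sex_coef = None
    if use_age:
        age_coef = coef[idx]
        idx += 1
    if use_sex:
        sex_coef = coef[idx]
    return ConfoundModel(intercept=intercept, age_coef=age_coef, sex_coef=sex_coef)


def remove_confounds(
    model: ConfoundModel, matrix: np.ndarray, age: np.ndarray, sex: np.ndarray
) -> np.ndarray:
    """Subtract the fitted age/sex linear predictor from every row."""
    x = np.asarray(matrix, dtype=float)
    if x.shape[1] != model.n_voxels:
        raise IncompatibleDataError(
            f"matrix has {x.shape[1]} voxels but model was fitted on {model.n_voxels}"
        )
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    pred = np.broadcast_to(model.intercept, x.shape).copy()
    if model.age_coef is not None:
        pred += np.outer(age, model.age_coef)
    if model.sex_coef is not None:
        pred += np.outer(sex, model.sex_coef)
    return x - pred
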