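"""Synthetic multimodal cohort generation with known discriminative structure.

Cohorts mimic a two-group (patient/control) imaging study with several
voxel-map modalities on a shared grid.  Each modality carries a
group-difference signal restricted to a known voxel set; the voxel sets of
different modalities can be made to overlap by a controllable pairwise
fraction, which lets downstream redundancy estimates be validated against
ground truth.  Age and sex enter as additive linear effects so confound
removal is exercised end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from neurofuse.errors import ConfigurationError, UnsupportedInputError

DEFAULT_MODALITIES = ("GMVBM", "1back", "2back", "ALFF", "GBC")


@dataclass(kw_only=True)
class CohortSpec:
    """Parameters of a synthetic multimodal cohort.

    Demographics default to the reference study design (115 controls,
    96 patients, 67% male, age ~ truncated normal).  ``effect_size_per_modality``
    is the standardized mean group difference (patients minus controls) in
    units of ``noise_sd`` at signal voxels.  ``pairwise_shared_fraction[a, b]``
    requests ``|mask_a & mask_b| / min(|mask_a|, |mask_b|)``.
    """

    n_voxels: int
    n_controls: int = 115
    n_patients: int = 96
    male_fraction: float = 0.67
    age_mean: float = 36.5
    age_sd: float = 10.6
    age_range: tuple[float, float] = (16.0, 65.0)
    modality_names: tuple[str, ...] = DEFAULT_MODALITIES
    signal_count_per_modality: tuple[int, ...] | int = 100
    effect_size_per_modality: tuple[float, ...] | float = 1.0
    pairwise_shared_fraction: np.ndarray | None = None
    age_slope: float = 0.0
    sex_offset: float = 0.0
    noise_sd: float = 1.0
    shared_signal_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        m = len(self.modality_names)
        if isinstance(self.signal_count_per_modality, (int, np.integer)):
            self.signal_count_per_modality = (int(self.signal_count_per_modality),) * m
        else:
            self.signal_count_per_modality = tuple(int(c) for c in self.signal_count_per_modality)
        if isinstance(self.effect_size_per_modality, (int, float, np.floating)):
            self.effect_size_per_modality = (float(self.effect_size_per_modality),) * m
        else:
            self.effect_size_per_modality = tuple(float(d) for d in self.effect_size_per_modality)
        if self.pairwise_shared_fraction is None:
            self.pairwise_shared_fraction = np.eye(m)
        else:
            self.pairwise_shared_fraction = np.asarray(self.pairwise_shared_fraction, dtype=float)
        self.validate()

    def validate(self) -> None:
        m = len(self.modality_names)
        if self.n_voxels <= 0 or self.n_controls <= 0 or self.n_patients <= 0:
            raise ConfigurationError("counts must be positive")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigurationError("male_fraction must be in [0, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigurationError("age_range must be increasing")
        if len(self.signal_count_per_modality) != m or len(self.effect_size_per_modality) != m:
            raise ConfigurationError("per-modality parameter lengths must match modality_names")
        for c in self.signal_count_per_modality:
            if not 0 < c <= self.n_voxels:
                raise ConfigurationError("signal counts must be in (0, n_voxels]")
        frac = self.pairwise_shared_fraction
        if frac.shape != (m, m):
            raise ConfigurationError("pairwise_shared_fraction must be square of size n_modalities")
        if np.any(frac < 0) or np.any(frac > 1):
            raise ConfigurationError("pairwise_shared_fraction entries must be in [0, 1]")
        if not np.allclose(frac, frac.T):
            raise ConfigurationError("pairwise_shared_fraction must be symmetric")
        if not np.allclose(np.diag(frac), 1.0):
            raise ConfigurationError("pairwise_shared_fraction diagonal must be 1")

    def to_dict(self) -> dict:
        return {
            "n_voxels": self.n_voxels,
            "n_controls": self.n_controls,
            "n_patients": self.n_patients,
            "male_fraction": self.male_fraction,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "age_range": list(self.age_range),
            "modality_names": list(self.modality_names),
            "signal_count_per_modality": list(self.signal_count_per_modality),
            "effect_size_per_modality": list(self.effect_size_per_modality),
            "pairwise_shared_fraction": self.pairwise_shared_fraction.tolist(),
            "age_slope": self.age_slope,
            "sex_offset": self.sex_offset,
            "noise_sd": self.noise_sd,
            "shared_signal_noise": self.shared_signal_noise,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        if "modality_names" in d:
            d["modality_names"] = tuple(d["modality_names"])
        if d.get("pairwise_shared_fraction") is not None:
            d["pairwise_shared_fraction"] = np.asarray(d["pairwise_shared_fraction"], float)
        return cls(**d)


@dataclass
class MultimodalCohort:
    """Per-modality subject-by-voxel matrices plus labels and covariates.

    ``truth_masks`` maps modality name to the set of voxel column indices that
    carry group signal; it is ``None`` for real (non-synthetic) data.
    """

    data: dict[str, np.ndarray]
    labels: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    truth_masks: dict[str, np.ndarray] | None = None
    spec: CohortSpec | None = None
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.labels)
        shapes = {m: x.shape for m, x in self.data.items()}
        n_vox = {s[1] for s in shapes.values()}
        if any(s[0] != n for s in shapes.values()) or len(n_vox) > 1:
            raise ConfigurationError(f"inconsistent modality matrix shapes: {shapes}")
        if len(self.age) != n or len(self.sex) != n:
            raise ConfigurationError("labels, age and sex must have equal length")
        if not self.subject_ids:
            self.subject_ids = [f"s{i:04d}" for i in range(n)]

    @property
    def n_subjects(self) -> int:
        return len(self.labels)

    @property
    def n_voxels(self) -> int:
        return next(iter(self.data.values())).shape[1]

    @property
    def modalities(self) -> list[str]:
        return list(self.data.keys())


def _allocate_truth_masks(spec: CohortSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Build per-modality signal voxel sets with requested pairwise sharing.

    Each unordered modality pair gets a dedicated block of voxels shared by
    exactly those two modalities; the remainder of each modality's quota is
    filled from modality-unique blocks.  Blocks are disjoint, so realized
    pairwise overlaps equal the requested ones (up to integer rounding) and
    no higher-order overlap is introduced.
    """
    names = spec.modality_names
    m = len(names)
    counts = spec.signal_count_per_modality
    frac = spec.pairwise_shared_fraction

    shared = {}
    for a in range(m):
        for b in range(a + 1, m):
            shared[(a, b)] = int(round(frac[a, b] * min(counts[a], counts[b])))

    unique = []
    for a in range(m):
        used = sum(shared[tuple(sorted((a, b)))] for b in range(m) if b != a)
        rest = counts[a] - used
        if rest < 0:
            raise ConfigurationError(
                f"pairwise_shared_fraction infeasible for modality {names[a]!r}: "
                f"shared pools require {used} voxels but signal count is {counts[a]}"
            )
        unique.append(rest)

    total = sum(shared.values()) + sum(unique)
    if total > spec.n_voxels:
        raise ConfigurationError(
            f"signal structure needs {total} distinct voxels but n_voxels = {spec.n_voxels}"
        )

    pool = rng.permutation(spec.n_voxels)
    cursor = 0
    masks = [[] for _ in range(m)]
    for (a, b), size in shared.items():
        block = pool[cursor:cursor + size]
        cursor += size
        masks[a].append(block)
        masks[b].append(block)
    for a in range(m):
        block = pool[cursor:cursor + unique[a]]
        cursor += unique[a]
        masks[a].append(block)

    return {
        names[a]: np.sort(np.concatenate(masks[a]).astype(np.int64)) for a in range(m)
    }


def generate_cohort(spec: CohortSpec) -> MultimodalCohort:
    """Generate a reproducible multimodal cohort from ``spec``.

    Voxel values are ``age_slope * age + sex_offset * sex + signal + noise``
    where signal is ``d * noise_sd`` for patients at in-mask voxels and noise
    is i.i.d. Gaussian with SD ``noise_sd``.

    With ``shared_signal_noise`` (the default) the noise realization at a
    signal voxel is drawn once per (subject, voxel) and reused by every
    modality whose truth mask contains that voxel.  Marginals are unchanged,
    but modalities sharing signal voxels then see identical values there, so
    their classifiers' successes correlate — this is what makes
    ``pairwise_shared_fraction`` an effective redundancy dial.  Setting it to
    False makes all noise independent across modalities.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_controls + spec.n_patients
    labels = np.concatenate(
        [np.zeros(spec.n_controls, dtype=np.int64), np.ones(spec.n_patients, dtype=np.int64)]
    )

    lo, hi = spec.age_range
    a = (lo - spec.age_mean) / spec.age_sd
    b = (hi - spec.age_mean) / spec.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=spec.age_mean, scale=spec.age_sd, size=n, random_state=rng
    )
    sex = (rng.random(n) < spec.male_fraction).astype(np.int64)

    truth_masks = _allocate_truth_masks(spec, rng)

    base = spec.age_slope * age[:, None] + spec.sex_offset * sex[:, None]
    pool_noise = None
    if spec.shared_signal_noise:
        pool_noise = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_voxels))
    data = {}
    for name, d in zip(spec.modality_names, spec.effect_size_per_modality):
        x = base + rng.normal(0.0, spec.noise_sd, size=(n, spec.n_voxels))
        mask = truth_masks[name]
        if pool_noise is not None:
            x[:, mask] = base + pool_noise[:, mask]  # base is (n, 1), broadcasts
        if d != 0.0:
            x[np.ix_(labels == 1, mask)] += d * spec.noise_sd
        data[name] = x

    return MultimodalCohort(
        data=data, labels=labels, age=age, sex=sex, truth_masks=truth_masks, spec=spec
    )


def realized_overlap(cohort: MultimodalCohort, m1: str, m2: str) -> float:
    """Return ``|mask_1 & mask_2| / min(|mask_1|, |mask_2|)`` from truth masks."""
    if cohort.truth_masks is None:
        raise UnsupportedInputError("cohort carries no truth masks (real data?)")
    a = np.asarray(cohort.truth_masks[m1])
    b = np.asarray(cohort.truth_masks[m2])
    inter = np.intersect1d(a, b).size
    return inter / min(a.size, b.size)


def save_cohort(cohort: MultimodalCohort, directory: str | Path) -> None:
    """Write a cohort to ``directory`` as plain-text artifacts.

    Layout: one ``<modality>.csv`` matrix per modality (rows = subjects,
    header = voxel ids), ``subjects.csv`` (id, label, age, sex),
    ``truth_masks.json``, and ``spec.yaml`` when available.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cols = [f"v{j}" for j in range(cohort.n_voxels)]
    for name, x in cohort.data.items():
        pd.DataFrame(x, index=cohort.subject_ids, columns=cols).to_csv(
            directory / f"{name}.csv", index_label="subject"
        )
    pd.DataFrame(
        {
            "subject": cohort.subject_ids,
            "label": cohort.labels,
            "age": cohort.age,
            "sex": cohort.sex,
        }
    ).to_csv(directory / "subjects.csv", index=False)
    if cohort.truth_masks is not None:
        with open(directory / "truth_masks.json", "w") as fh:
            json.dump({k: np.asarray(v).tolist() for k, v in cohort.truth_masks.items()}, fh)
    if cohort.spec is not None:
        with open(directory / "spec.yaml", "w") as fh:
            yaml.safe_dump(cohort.spec.to_dict(), fh)


def load_cohort(directory: str | Path) -> MultimodalCohort:
    """Read a cohort previously written by :func:`save_cohort`."""
    directory = Path(directory)
    subjects = pd.read_csv(directory / "subjects.csv")
    data = {}
    for path in sorted(directory.glob("*.csv")):
        if path.name == "subjects.csv":
            continue
        df = pd.read_csv(path, index_col="subject")
        data[path.stem] = df.to_numpy(dtype=float)
    truth_masks = None
    mask_path = directory / "truth_masks.json"
    if mask_path.exists():
        with open(mask_path) as fh:
            truth_masks = {k: np.asarray(v, dtype=np.int64) for k, v in json.load(fh).items()}
    spec = None
    spec_path = directory / "spec.yaml"
    if spec_path.exists():
        with open(spec_path) as fh:
            spec = CohortSpec.from_dict(yaml.safe_load(fh))
    if spec is not None:
        data = {m: data[m] for m in spec.modality_names if m in data}
    return MultimodalCohort(
        data=data,
        labels=subjects["label"].to_numpy(np.int64),
        age=subjects["age"].to_numpy(float),
        sex=subjects["sex"].to_numpy(np.int64),
        truth_masks=truth_masks,
        spec=spec,
        subject_ids=[str(s) for s in subjects["subject"]],
    )
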