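"""Redundancy of predictive information between map types.

Built from per-subject test-set correctness indicators pooled across all CV
folds.  For an ordered pair (M1, M2) the score is

    rsc = (P(M2 correct | M1 correct) - P(M2 correct)) / (1 - P(M2 correct))

which is 1 when every M1 success is also an M2 success (total redundancy)
and 0 when successes are independent.  Negative finite-sample values are
reported unclipped with an ``anti_redundant`` flag; undefined cases
(no M1 successes, or P(M2) = 1) propagate as explicit missing values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from neurofuse.errors import IncompatibleDataError, UndefinedStatisticError


@dataclass(frozen=True)
class RedundancyResult:
    """Contingency counts and redundancy score for one ordered map pair."""

    m1: str
    m2: str
    n_11: int
    n_10: int
    n_01: int
    n_00: int
    p_m2: float
    p_m2_given_m1: float | None
    rsc: float | None
    anti_redundant: bool = False

    @property
    def n_subjects(self) -> int:
        return self.n_11 + self.n_10 + self.n_01 + self.n_00

    def to_dict(self) -> dict:
        return {
            "m1": self.m1,
            "m2": self.m2,
            "n_11": self.n_11,
            "n_10": self.n_10,
            "n_01": self.n_01,
            "n_00": self.n_00,
            "p_m2": self.p_m2,
            "p_m2_given_m1": self.p_m2_given_m1,
            "rsc": self.rsc,
            "anti_redundant": self.anti_redundant,
        }


def _as_binary(v) -> np.ndarray:
    arr = np.asarray(v).astype(np.int64)
    if not np.isin(arr, (0, 1)).all():
        raise IncompatibleDataError("correctness vectors must be binary")
    return arr


def contingency(correct_1, correct_2) -> tuple[int, int, int, int]:
    """(n_11, n_10, n_01, n_00) counts of joint correctness."""
    c1 = _as_binary(correct_1)
    c2 = _as_binary(correct_2)
    if c1.shape != c2.shape:
        raise IncompatibleDataError("correctness vectors must have equal length")
    n_11 = int(np.sum((c1 == 1) & (c2 == 1)))
    n_10 = int(np.sum((c1 == 1) & (c2 == 0)))
    n_01 = int(np.sum((c1 == 0) & (c2 == 1)))
    n_00 = int(np.sum((c1 == 0) & (c2 == 0)))
    return n_11, n_10, n_01, n_00


def conditional_probability(correct_1, correct_2) -> float:
    """P(map 2 correct | map 1 correct) = n_11 / (n_11 + n_10)."""
    n_11, n_10, _, _ = contingency(correct_1, correct_2)
    if n_11 + n_10 == 0:
        raise UndefinedStatisticError("map 1 has no successes; conditional undefined")
    return n_11 / (n_11 + n_10)


def redundancy_score(correct_1, correct_2) -> float:
    """Normalized excess of conditional over marginal success probability."""
    n_11, n_10, n_01, n_00 = contingency(correct_1, correct_2)
    if n_11 + n_10 == 0:
        raise UndefinedStatisticError("map 1 has no successes; conditional undefined")
    n = n_11 + n_10 + n_01 + n_00
    p_m2 = (n_11 + n_01) / n
    if p_m2 == 1.0:
        raise UndefinedStatisticError("map 2 is always correct; score denominator is zero")
    p_cond = n_11 / (n_11 + n_10)
    return (p_cond - p_m2) / (1.0 - p_m2)


def pair_result(m1: str, m2: str, correct_1, correct_2) -> RedundancyResult:
    """Full RedundancyResult for one ordered pair; undefined values become None."""
    n_11, n_10, n_01, n_00 = contingency(correct_1, correct_2)
    n = n_11 + n_10 + n_01 + n_00
    p_m2 = (n_11 + n_01) / n
    if n_11 + n_10 == 0:
        p_cond, rsc = None, None
    else:
        p_cond = n_11 / (n_11 + n_10)
        rsc = None if p_m2 == 1.0 else (p_cond - p_m2) / (1.0 - p_m2)
    return RedundancyResult(
        m1=m1,
        m2=m2,
        n_11=n_11,
        n_10=n_10,
        n_01=n_01,
        n_00=n_00,
        p_m2=p_m2,
        p_m2_given_m1=p_cond,
        rsc=rsc,
        anti_redundant=bool(rsc is not None and rsc < 0),
    )


def redundancy_matrix(table: pd.DataFrame, algorithm: str) -> list[RedundancyResult]:
    """One RedundancyResult per ordered source pair for a given algorithm.

    ``table`` is a PredictionTable pooling all test individuals across folds.
    Sources keep their order of first appearance; rows condition on M1.
    """
    sub = table[table["algorithm"] == algorithm]
    sources = list(dict.fromkeys(sub["source"]))
    if len(sources) < 2:
        raise IncompatibleDataError("need at least two sources for a redundancy matrix")
    vectors = {}
    subject_order = None
    for src in sources:
        rows = sub[sub["source"] == src].sort_values("subject")
        subjects = tuple(rows["subject"])
        if subject_order is None:
            subject_order = subjects
        elif subjects != subject_order:
            raise IncompatibleDataError(f"source {src!r} covers a different subject set")
        vectors[src] = rows["correct"].to_numpy(np.int64)
    results = []
    for m1 in sources:
        for m2 in sources:
            if m1 == m2:
                continue
            results.append(pair_result(m1, m2, vectors[m1], vectors[m2]))
    return results


def matrix_to_frame(results: list[RedundancyResult]) -> pd.DataFrame:
    """Long-format frame (rows condition on m1; one row per ordered pair)."""
    return pd.DataFrame([r.to_dict() for r in results])


def mean_rsc(results: list[RedundancyResult]) -> float:
    """Mean score over all defined ordered pairs (undefined pairs excluded)."""
    vals = [r.rsc for r in results if r.rsc is not None]
    if not vals:
        raise UndefinedStatisticError("no defined redundancy scores")
    return float(np.mean(vals))
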