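"""EDAS multi-criteria ranking (distance-from-average-solution).

Implements the eight-step procedure exactly as the reference tables this
package reproduces were computed. NOTE the sign convention: with
``convention="as_printed"`` (the default, matching those tables) the
positive-distance matrix for a beneficial criterion is

    PDA = max(0, (mean - x)) / mean

i.e. *below*-average values score positively — the opposite of textbook
EDAS. Pass ``convention="standard"`` for the textbook orientation
(above-average is positive on beneficial criteria). The appraisal score
is the additive average of the two normalized sums, 0.5 * (NSP + NSN).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "DecisionMatrix",
    "EdasResult",
    "DEFAULT_WEIGHTS",
    "column_means",
    "pda_nda",
    "weighted_sums",
    "normalize_scores",
    "appraisal_and_rank",
    "rank",
    "load_benchmark_matrix",
]

#: Exogenous criterion weights (precision, recall, F1) of the packaged
#: benchmark instance.
DEFAULT_WEIGHTS = (0.6125, 0.2737, 0.1139)


@dataclass
class DecisionMatrix:
    """Alternatives x criteria values with weights and beneficial flags."""

    alternatives: list
    criteria: list
    values: np.ndarray
    weights: np.ndarray
    beneficial: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.beneficial = np.asarray(self.beneficial, dtype=bool)
        n_a, n_c = self.values.shape
        if len(self.alternatives) != n_a or len(self.criteria) != n_c:
            raise InvalidParameterError("label/value dimension mismatch")
        if self.weights.shape != (n_c,) or np.any(self.weights < 0):
            raise InvalidParameterError("weights must be non-negative, one per criterion")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("decision matrix must be dense and finite")

    @classmethod
    def from_csv(cls, path, weights=None, beneficial=None) -> "DecisionMatrix":
        """First column = alternative names, header = criterion names.

        An optional row named ``weights`` supplies per-criterion weights.
        """
        df = pd.read_csv(path, index_col=0)
        w = weights
        if "weights" in df.index:
            if w is None:
                w = df.loc["weights"].to_numpy()
            df = df.drop(index="weights")
        if w is None:
            w = np.full(df.shape[1], 1.0 / df.shape[1])
        if beneficial is None:
            beneficial = np.ones(df.shape[1], dtype=bool)
        return cls(
            alternatives=list(df.index),
            criteria=list(df.columns),
            values=df.to_numpy(dtype=np.float64),
            weights=np.asarray(w, dtype=np.float64),
            beneficial=beneficial,
        )


@dataclass
class EdasResult:
    means: np.ndarray
    pda: np.ndarray
    nda: np.ndarray
    sp: np.ndarray
    sn: np.ndarray
    nsp: np.ndarray
    nsn: np.ndarray
    appraisal: np.ndarray
    ranking: np.ndarray  # rank per alternative, 1 = best

    def to_frame(self, matrix: DecisionMatrix) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SP": self.sp,
                "SN": self.sn,
                "NSP": self.nsp,
                "NSN": self.nsn,
                "appraisal": self.appraisal,
                "rank": self.ranking,
            },
            index=matrix.alternatives,
        )


def load_benchmark_matrix() -> DecisionMatrix:
    """The packaged 10-method defocus-segmentation benchmark instance."""
    with resources.as_file(
        resources.files("focusfield") / "data" / "defocus_benchmark.csv"
    ) as path:
        return DecisionMatrix.from_csv(path, weights=np.array(DEFAULT_WEIGHTS))


def column_means(m: DecisionMatrix) -> np.ndarray:
    """Per-criterion arithmetic mean (the average solution)."""
    return m.values.mean(axis=0)


def pda_nda(
    m: DecisionMatrix,
    means: np.ndarray | None = None,
    convention: str = "as_printed",
) -> tuple[np.ndarray, np.ndarray]:
    """Positive/negative distance-from-average matrices.

    ``as_printed``: beneficial criteria score PDA for below-average cells
    (the convention of the reproduced tables); ``standard``: textbook
    EDAS, above-average is positive. Non-beneficial criteria swap the two
    formulas in either convention.
    """
    if convention not in ("as_printed", "standard"):
        raise InvalidParameterError(f"unknown convention {convention!r}")
    if means is None:
        means = column_means(m)
    means = np.asarray(means, dtype=np.float64)
    if np.any(means == 0):
        raise InvalidParameterError("zero criterion mean: distances are undefined")
    below = np.maximum(0.0, means - m.values) / means
    above = np.maximum(0.0, m.values - means) / means
    if convention == "as_printed":
        pda_b, nda_b = below, above
    else:
        pda_b, nda_b = above, below
    ben = m.beneficial[None, :]
    pda = np.where(ben, pda_b, nda_b)
    nda = np.where(ben, nda_b, pda_b)
    return pda, nda


def weighted_sums(pda: np.ndarray, nda: np.ndarray, weights) -> tuple[np.ndarray, np.ndarray]:
    """Weighted row sums SP and SN."""
    w = np.asarray(weights, dtype=np.float64)
    return pda @ w, nda @ w


def normalize_scores(sp: np.ndarray, sn: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """NSP = SP / max(SP); NSN = 1 - SN / max(SN).

    Degenerate maxima: all-zero SP gives NSP = 0 everywhere, all-zero SN
    gives NSN = 1 everywhere, so an all-identical matrix scores a neutral
    0.5 appraisal.
    """
    sp = np.asarray(sp, dtype=np.float64)
    sn = np.asarray(sn, dtype=np.float64)
    nsp = sp / sp.max() if sp.max() > 0 else np.zeros_like(sp)
    nsn = 1.0 - sn / sn.max() if sn.max() > 0 else np.ones_like(sn)
    return nsp, nsn


def appraisal_and_rank(nsp: np.ndarray, nsn: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Appraisal = 0.5 * (NSP + NSN); rank 1 = highest appraisal.

    Ties keep input order (stable sort).
    """
    scores = 0.5 * (np.asarray(nsp) + np.asarray(nsn))
    order = np.argsort(-scores, kind="stable")
    ranking = np.empty(scores.size, dtype=np.int64)
    ranking[order] = np.arange(1, scores.size + 1)
    return scores, ranking


def rank(m: DecisionMatrix, convention: str = "as_printed") -> EdasResult:
    """Run the full eight-step procedure on a decision matrix."""
    means = column_means(m)
    pda, nda = pda_nda(m, means, convention=convention)
    sp, sn = weighted_sums(pda, nda, m.weights)
    nsp, nsn = normalize_scores(sp, sn)
    scores, ranking = appraisal_and_rank(nsp, nsn)
    return EdasResult(means, pda, nda, sp, sn, nsp, nsn, scores, ranking)
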