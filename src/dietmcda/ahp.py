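"""Criterion weighting by the Analytic Hierarchy Process (AHP).

Priorities over a set of criteria are derived from positive-reciprocal
pairwise comparison matrices (PCMs) whose entries live on the Saaty 1-9
scale: ``a_ij`` expresses how much more important criterion *i* is than
criterion *j* (1 equal, 3 moderate, 5 strong, 7 extreme, 9 absolute,
with 2/4/6/8 intermediates and reciprocals for the inverse judgment).

Weights are computed by the arithmetic-mean (column normalization)
method: each column is divided by its sum and the rows of the resulting
normalized matrix are averaged.  Judgment coherence is controlled
through the consistency ratio CR = CI / RI, where
CI = (lambda_max - n) / (n - 1) and RI is the expected CI of random
matrices of the same size; CR below 0.1 is conventionally acceptable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SAATY_MIN",
    "SAATY_MAX",
    "DEFAULT_RI_TABLE",
    "PCMValidationError",
    "ConsistencyError",
    "PairwiseComparisonMatrix",
    "WeightVector",
    "ConsistencyReport",
    "validate_pcm",
    "aggregate_expert_matrices",
    "derive_weights",
    "lambda_max",
    "consistency",
    "ahp_weights",
]

SAATY_MIN = 1.0 / 9.0
SAATY_MAX = 9.0

#: Saaty's classical random-index values by matrix order n (1-based).
#: RI(n) is the mean consistency index of randomly filled reciprocal
#: matrices of order n; several variants circulate for n >= 12, the
#: table is therefore overridable in :func:`consistency`.
DEFAULT_RI_TABLE: dict[int, float] = {
    1: 0.0,
    2: 0.0,
    3: 0.58,
    4: 0.90,
    5: 1.12,
    6: 1.24,
    7: 1.32,
    8: 1.41,
    9: 1.45,
    10: 1.49,
    11: 1.51,
    12: 1.48,
    13: 1.56,
    14: 1.57,
    15: 1.59,
}

_RECIPROCITY_TOL = 1e-9
_SCALE_TOL = 1e-9


class PCMValidationError(ValueError):
    """A pairwise comparison matrix violates its structural invariants."""


class ConsistencyError(RuntimeError):
    """Judgments are too inconsistent for the derived weights to be trusted."""

    def __init__(self, message: str, report: "ConsistencyReport"):
        super().__init__(message)
        self.report = report


@dataclass(frozen=True)
class PairwiseComparisonMatrix:
    """Square positive-reciprocal judgment matrix over named criteria."""

    criteria_ids: tuple[str, ...]
    values: np.ndarray

    def __init__(self, criteria_ids: Sequence[str], values) -> None:
        object.__setattr__(self, "criteria_ids", tuple(str(c) for c in criteria_ids))
        arr = np.asarray(values, dtype=float)
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return len(self.criteria_ids)

    def reordered(self, new_order: Sequence[str]) -> "PairwiseComparisonMatrix":
        """Return the same judgments with criteria permuted into ``new_order``."""
        idx = [self.criteria_ids.index(c) for c in new_order]
        return PairwiseComparisonMatrix(new_order, self.values[np.ix_(idx, idx)])


@dataclass(frozen=True)
class WeightVector:
    """Positive criterion weights summing to one."""

    criteria_ids: tuple[str, ...]
    weights: np.ndarray

    def __init__(self, criteria_ids: Sequence[str], weights) -> None:
        object.__setattr__(self, "criteria_ids", tuple(str(c) for c in criteria_ids))
        arr = np.asarray(weights, dtype=float).copy()
        if arr.ndim != 1 or arr.size != len(self.criteria_ids):
            raise ValueError("weights must be a vector matching criteria_ids")
        if np.any(arr <= 0):
            raise ValueError("all weights must be strictly positive")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {arr.sum():.12f}")
        arr.setflags(write=False)
        object.__setattr__(self, "weights", arr)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.criteria_ids, self.weights.tolist()))

    def reordered(self, new_order: Sequence[str]) -> "WeightVector":
        """Return the same weights permuted into ``new_order``."""
        idx = [self.criteria_ids.index(c) for c in new_order]
        return WeightVector(new_order, self.weights[idx])


@dataclass(frozen=True)
class ConsistencyReport:
    """lambda_max / CI / RI / CR summary with the 0.1-threshold verdict."""

    lambda_max: float
    n: int
    ci: float
    ri: float
    cr: float
    passed: bool
    threshold: float = 0.1

    def as_dict(self) -> dict:
        return {
            "lambda_max": self.lambda_max,
            "n": self.n,
            "ci": self.ci,
            "ri": self.ri,
            "cr": self.cr,
            "passed": self.passed,
            "threshold": self.threshold,
        }


def validate_pcm(matrix: PairwiseComparisonMatrix) -> PairwiseComparisonMatrix:
    """Check diagonal, reciprocity and Saaty-scale range; return the matrix.

    Raises
    ------
    PCMValidationError
        Naming the offending cell ``(i, j)`` (1-based) on the first
        violated invariant.
    """
    a = matrix.values
    n = matrix.n
    if a.ndim != 2 or a.shape != (n, n):
        raise PCMValidationError(
            f"matrix must be {n}x{n} to match its {n} criteria, got shape {a.shape}"
        )
    if len(set(matrix.criteria_ids)) != n:
        raise PCMValidationError("criteria_ids must be unique")
    if np.any(~np.isfinite(a)) or np.any(a <= 0):
        i, j = np.argwhere(~np.isfinite(a) | (a <= 0))[0]
        raise PCMValidationError(f"non-positive or non-finite entry at ({i + 1}, {j + 1})")
    diag = np.diag(a)
    if np.any(diag != 1.0):
        i = int(np.argwhere(diag != 1.0)[0][0])
        raise PCMValidationError(f"diagonal entry at ({i + 1}, {i + 1}) must be exactly 1")
    recip = a * a.T
    bad = np.abs(recip - 1.0) > _RECIPROCITY_TOL
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise PCMValidationError(
            f"reciprocity broken at ({i + 1}, {j + 1}): "
            f"a_ij * a_ji = {recip[i, j]:.12g} != 1"
        )
    off_scale = (a < SAATY_MIN - _SCALE_TOL) | (a > SAATY_MAX + _SCALE_TOL)
    if np.any(off_scale):
        i, j = np.argwhere(off_scale)[0]
        raise PCMValidationError(
            f"entry {a[i, j]:g} at ({i + 1}, {j + 1}) is outside the "
            f"Saaty scale [1/9, 9]"
        )
    return matrix


def aggregate_expert_matrices(
    matrices: Sequence[PairwiseComparisonMatrix],
) -> PairwiseComparisonMatrix:
    """Combine several experts' judgments by the element-wise geometric mean.

    The geometric mean is the standard group-AHP aggregation rule: it is
    the only mean that preserves reciprocity (``gm(a_ij) * gm(a_ji) = 1``).
    Aggregated entries that fall outside the Saaty scale are clipped back
    to ``[1/9, 9]`` with a warning (possible only after clipping-free
    inputs when experts disagree strongly, since the scale is closed
    under geometric means of in-scale reciprocal pairs only up to the
    scale bounds).
    """
    if not matrices:
        raise ValueError("need at least one expert matrix")
    ref = matrices[0].criteria_ids
    for k, m in enumerate(matrices):
        if m.criteria_ids != ref:
            raise ValueError(
                f"expert matrix {k} has criteria {m.criteria_ids}, expected {ref}"
            )
        validate_pcm(m)
    stack = np.stack([m.values for m in matrices])
    gm = np.exp(np.mean(np.log(stack), axis=0))
    clipped = np.clip(gm, SAATY_MIN, SAATY_MAX)
    if not np.allclose(clipped, gm):
        warnings.warn(
            "aggregated judgments clipped back to the Saaty scale [1/9, 9]",
            stacklevel=2,
        )
    # restore exact structural invariants after floating-point averaging
    n = len(ref)
    out = np.ones((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = clipped[iu]
    out[(iu[1], iu[0])] = 1.0 / clipped[iu]
    return PairwiseComparisonMatrix(ref, out)


def derive_weights(matrix: PairwiseComparisonMatrix) -> WeightVector:
    """Arithmetic-mean weights: normalize each column to unit sum, average rows.

    For a perfectly consistent matrix (``a_ij = w_i / w_j``) every
    normalized column equals the underlying weight vector, so the method
    recovers it exactly; for near-consistent matrices it is a standard
    close approximation to the principal eigenvector.
    """
    validate_pcm(matrix)
    a = matrix.values
    a_norm = a / a.sum(axis=0, keepdims=True)
    w = a_norm.mean(axis=1)
    w = w / w.sum()
    return WeightVector(matrix.criteria_ids, w)


def lambda_max(matrix: PairwiseComparisonMatrix, weights: WeightVector) -> float:
    """Approximate principal eigenvalue: mean over i of ``(M w)_i / w_i``.

    Equals the matrix order *n* exactly when judgments are consistent and
    is >= n for every positive-reciprocal matrix.
    """
    if matrix.criteria_ids != weights.criteria_ids:
        raise ValueError("matrix and weights refer to different criteria")
    w = weights.weights
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    mw = matrix.values @ w
    return float(np.mean(mw / w))


def consistency(
    matrix: PairwiseComparisonMatrix,
    weights: WeightVector,
    ri_table: dict[int, float] | None = None,
    threshold: float = 0.1,
) -> ConsistencyReport:
    """Consistency report: CI = (lambda_max - n)/(n - 1), CR = CI/RI(n).

    ``passed`` is strict: CR < threshold passes, CR == threshold fails.
    Orders 1 and 2 are consistent by construction (RI = 0, CR defined as 0).
    """
    table = DEFAULT_RI_TABLE if ri_table is None else ri_table
    n = matrix.n
    if n < 2:
        raise ValueError("consistency is undefined for fewer than 2 criteria")
    if n not in table:
        raise ValueError(
            f"no random index for n={n}; supported sizes: {sorted(table)}"
        )
    lam = lambda_max(matrix, weights)
    ci = (lam - n) / (n - 1)
    ri = table[n]
    if ri == 0.0:
        # n <= 2: CI is 0 up to rounding; anything larger is a logic error
        if abs(ci) > 1e-9:
            raise ValueError(f"nonzero CI {ci:g} at n={n} with RI=0")
        cr = 0.0
    else:
        cr = ci / ri
    return ConsistencyReport(
        lambda_max=lam, n=n, ci=ci, ri=ri, cr=cr,
        passed=bool(cr < threshold), threshold=threshold,
    )


def ahp_weights(
    matrices: Sequence[PairwiseComparisonMatrix],
    enforce_cr: bool = True,
    ri_table: dict[int, float] | None = None,
    threshold: float = 0.1,
) -> tuple[WeightVector, ConsistencyReport]:
    """Full weighting stage: aggregate experts, derive weights, gate on CR.

    Raises :class:`ConsistencyError` (with the report attached) when
    ``enforce_cr`` is set and the aggregated judgments fail the CR gate.
    """
    agg = aggregate_expert_matrices(matrices)
    w = derive_weights(agg)
    report = consistency(agg, w, ri_table=ri_table, threshold=threshold)
    if enforce_cr and not report.passed:
        raise ConsistencyError(
            f"consistency ratio {report.cr:.4f} >= {report.threshold}: "
            "serious inconsistencies may exist in the judgments",
            report,
        )
    return w, report
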