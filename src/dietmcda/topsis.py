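"""TOPSIS ranking of alternatives by closeness to the ideal solution.

The Technique for Order Preference by Similarity to Ideal Solution
scores each alternative by where it sits between two artificial
alternatives in the weighted, vector-normalized criterion space: the
positive ideal A+ (best observed value on every criterion) and the
negative ideal A- (worst observed value).  With Euclidean separations
D+ and D- from those two points, the closeness coefficient

    CC* = D- / (D- + D+)

lies in [0, 1] and alternatives are ranked by decreasing CC*.

Benefit criteria contribute their column maximum to A+ and minimum to
A-; cost criteria the reverse.  Negative matrix entries (percent
*increases* stored with a negative sign) pass through vector
normalization unchanged in sign and need no special handling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ahp import WeightVector
from .evidence import DecisionMatrix, EffectiveObjective

__all__ = [
    "NormalizedMatrix",
    "WeightedMatrix",
    "IdealSolutions",
    "RankingResult",
    "normalize",
    "apply_weights",
    "ideal_solutions",
    "separations",
    "closeness_and_rank",
    "rank_concepts",
]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class NormalizedMatrix:
    """Dimensionless matrix R with unit-Euclidean-norm columns."""

    alternatives: tuple[str, ...]
    criterion_ids: tuple[str, ...]
    values: np.ndarray


@dataclass(frozen=True)
class WeightedMatrix:
    """V = R scaled column-wise by the criterion weights."""

    alternatives: tuple[str, ...]
    criterion_ids: tuple[str, ...]
    values: np.ndarray


@dataclass(frozen=True)
class IdealSolutions:
    """Positive/negative ideal alternatives A+ and A- per criterion."""

    criterion_ids: tuple[str, ...]
    positive_ideal: np.ndarray
    negative_ideal: np.ndarray
    benefit_set: frozenset[str]
    cost_set: frozenset[str]


@dataclass
class RankingResult:
    """Per-alternative separations, closeness scores and 1-based ranks."""

    alternatives: list[str]
    d_plus: np.ndarray
    d_minus: np.ndarray
    closeness: np.ndarray
    rank: np.ndarray
    ties: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Ranking table sorted best-first."""
        df = pd.DataFrame(
            {
                "alternative": self.alternatives,
                "d_plus": self.d_plus,
                "d_minus": self.d_minus,
                "closeness": self.closeness,
                "rank": self.rank,
                "tied": [a in self.ties for a in self.alternatives],
            }
        )
        return df.sort_values("rank", kind="stable").reset_index(drop=True)

    def ordered_alternatives(self) -> list[str]:
        return list(self.to_frame()["alternative"])


def normalize(matrix: DecisionMatrix) -> NormalizedMatrix:
    """Vector normalization: r_ij = x_ij / sqrt(sum_i x_ij^2)."""
    x = matrix.values
    norms = np.sqrt((x**2).sum(axis=0))
    zero = norms == 0
    if np.any(zero):
        bad = [matrix.criterion_ids[j] for j in np.flatnonzero(zero)]
        raise ValueError(f"all-zero column(s) cannot be normalized: {bad}")
    return NormalizedMatrix(
        tuple(matrix.alternatives), tuple(matrix.criterion_ids), x / norms
    )


def apply_weights(r: NormalizedMatrix, w: WeightVector) -> WeightedMatrix:
    """Weighted normalized matrix: v_ij = w_j * r_ij."""
    if tuple(w.criteria_ids) != r.criterion_ids:
        raise ValueError(
            f"weight criteria {w.criteria_ids} do not match matrix "
            f"criteria {r.criterion_ids}"
        )
    return WeightedMatrix(r.alternatives, r.criterion_ids, r.values * w.weights)


def ideal_solutions(
    v: WeightedMatrix, objectives: Mapping[str, EffectiveObjective | str]
) -> IdealSolutions:
    """Build A+ (best per criterion) and A- (worst) from the weighted matrix."""
    benefit, cost = [], []
    for cid in v.criterion_ids:
        if cid not in objectives:
            raise ValueError(f"no benefit/cost orientation for criterion '{cid}'")
        obj = EffectiveObjective(objectives[cid])
        (benefit if obj is EffectiveObjective.BENEFIT else cost).append(cid)
    col_max = v.values.max(axis=0)
    col_min = v.values.min(axis=0)
    is_benefit = np.array([cid in set(benefit) for cid in v.criterion_ids])
    pos = np.where(is_benefit, col_max, col_min)
    neg = np.where(is_benefit, col_min, col_max)
    return IdealSolutions(
        v.criterion_ids, pos, neg, frozenset(benefit), frozenset(cost)
    )


def separations(
    v: WeightedMatrix, ideals: IdealSolutions
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean distances of each alternative to A+ and A-."""
    if ideals.criterion_ids != v.criterion_ids:
        raise ValueError("ideal solutions and matrix refer to different criteria")
    d_plus = np.sqrt(((v.values - ideals.positive_ideal) ** 2).sum(axis=1))
    d_minus = np.sqrt(((v.values - ideals.negative_ideal) ** 2).sum(axis=1))
    return d_plus, d_minus


def closeness_and_rank(
    alternatives: Sequence[str], d_plus: np.ndarray, d_minus: np.ndarray
) -> RankingResult:
    """Closeness coefficients CC* = D-/(D- + D+) and best-first ranks.

    Ties in CC* are broken lexicographically by alternative id and the
    tied alternatives are flagged.  A single alternative (where both
    separations are zero and CC* is 0/0) is assigned CC* = 1 by
    convention, with a warning.
    """
    d_plus = np.asarray(d_plus, dtype=float)
    d_minus = np.asarray(d_minus, dtype=float)
    if np.any(d_plus < 0) or np.any(d_minus < 0):
        raise AssertionError("separations must be nonnegative")
    total = d_plus + d_minus
    closeness = np.empty_like(total)
    degenerate = total == 0
    if np.any(degenerate):
        if len(alternatives) == 1:
            warnings.warn(
                "single alternative: closeness is 0/0, defined as 1 by convention",
                stacklevel=2,
            )
            closeness[:] = 1.0
        else:
            # a row at zero total distance equals both ideals, which forces
            # every column to be constant — all alternatives are then tied
            closeness[:] = 0.5
    else:
        closeness = d_minus / total

    order = sorted(
        range(len(alternatives)), key=lambda i: (-closeness[i], alternatives[i])
    )
    rank = np.empty(len(alternatives), dtype=int)
    for pos, i in enumerate(order):
        rank[i] = pos + 1

    ties: list[str] = []
    cc_sorted = closeness[order]
    for k in range(len(order) - 1):
        if abs(cc_sorted[k] - cc_sorted[k + 1]) <= _TIE_TOL:
            ties.extend(
                [alternatives[order[k]], alternatives[order[k + 1]]]
            )
    ties = sorted(set(ties))

    return RankingResult(
        alternatives=list(alternatives),
        d_plus=d_plus,
        d_minus=d_minus,
        closeness=closeness,
        rank=rank,
        ties=ties,
    )


def rank_concepts(
    matrix: DecisionMatrix,
    weights: WeightVector,
    objectives: Mapping[str, EffectiveObjective | str] | None = None,
) -> RankingResult:
    """Full TOPSIS chain: normalize, weight, ideals, separations, rank.

    When ``objectives`` is omitted the benefit/cost orientation is taken
    from the decision matrix's criteria and value semantics.
    """
    if objectives is None:
        objectives = matrix.effective_objectives()
    r = normalize(matrix)
    v = apply_weights(r, weights)
    ideals = ideal_solutions(v, objectives)
    d_plus, d_minus = separations(v, ideals)
    return closeness_and_rank(matrix.alternatives, d_plus, d_minus)
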