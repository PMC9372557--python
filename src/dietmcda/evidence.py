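"""Evidence aggregation into a diet-concept x criterion decision matrix.

Diet concepts are scored on eleven sustainability indicators spanning
three dimensions: health (risk of diabetes, coronary heart disease,
mortality, obesity, total cancer), environment (greenhouse-gas
emissions, agricultural land use, water consumption, energy
consumption) and socio-economics (daily diet cost, savings to society).
Per-study outcome observations — typically percent reductions relative
to the baseline (current US) diet reported by cohort and life-cycle
assessment studies — are averaged per concept x criterion cell, with
explicit, logged proxy substitution for cells that no direct study
covers.

Sign convention for percent-reduction data: positive values are
reductions relative to the baseline diet, negative values are increases
(a diet that raises energy use by 17% stores -17).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dimension",
    "Objective",
    "ValueSemantics",
    "EffectiveObjective",
    "RiskClass",
    "Criterion",
    "OutcomeObservation",
    "RelativeRiskRecord",
    "DecisionMatrix",
    "MatrixAssemblyError",
    "default_criteria",
    "classify_relative_risk",
    "mean_relative_risk",
    "aggregate_concept_criterion",
    "effective_objective",
    "build_decision_matrix",
]


class Dimension(str, Enum):
    HEALTH = "health"
    ENVIRONMENT = "environment"
    SOCIOECONOMIC = "socioeconomic"


class Objective(str, Enum):
    """Whether the underlying burden/quantity should be small or large."""

    MINIMIZE = "minimize"
    MAXIMIZE = "maximize"


class ValueSemantics(str, Enum):
    """What the numbers in a decision matrix mean."""

    RAW_IMPACT = "raw_impact"
    PERCENT_REDUCTION = "percent_reduction"


class EffectiveObjective(str, Enum):
    """Orientation actually used by the ranking stage."""

    BENEFIT = "benefit"
    COST = "cost"


class RiskClass(str, Enum):
    INCREASED = "increased"
    NEUTRAL = "neutral"
    DECREASED = "decreased"


@dataclass(frozen=True)
class Criterion:
    criterion_id: str
    name: str
    dimension: Dimension
    objective: Objective
    units: str = ""

    def __post_init__(self):
        object.__setattr__(self, "dimension", Dimension(self.dimension))
        object.__setattr__(self, "objective", Objective(self.objective))


@dataclass(frozen=True)
class OutcomeObservation:
    """One study-level value for one concept on one criterion."""

    concept_id: str
    criterion_id: str
    value: float
    source_id: str = ""
    is_proxy: bool = False


@dataclass(frozen=True)
class RelativeRiskRecord:
    """Relative risk per additional daily serving of a food group."""

    food_group: str
    outcome: str
    rr: float

    def __post_init__(self):
        if not self.rr > 0:
            raise ValueError(f"relative risk must be positive, got {self.rr}")


class MatrixAssemblyError(ValueError):
    """The decision matrix could not be fully populated."""


@dataclass
class DecisionMatrix:
    """Alternatives x criteria performance grid with orientation metadata.

    ``values[i, j]`` is the performance of alternative ``alternatives[i]``
    on criterion ``criteria[j]``.  ``provenance`` carries, per cell, the
    number of source observations and how many were proxies.
    """

    alternatives: list[str]
    criteria: list[Criterion]
    values: np.ndarray
    semantics: ValueSemantics = ValueSemantics.PERCENT_REDUCTION
    provenance: dict[tuple[str, str], dict] = field(default_factory=dict)

    def __post_init__(self):
        self.semantics = ValueSemantics(self.semantics)
        self.values = np.asarray(self.values, dtype=float)
        n_a, n_c = len(self.alternatives), len(self.criteria)
        if self.values.shape != (n_a, n_c):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n_a} alternatives x {n_c} criteria"
            )
        if len(set(self.alternatives)) != n_a:
            raise ValueError("alternative ids must be unique")
        ids = [c.criterion_id for c in self.criteria]
        if len(set(ids)) != n_c:
            raise ValueError("criterion ids must be unique")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("decision matrix contains non-finite cells")

    @property
    def criterion_ids(self) -> list[str]:
        return [c.criterion_id for c in self.criteria]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.alternatives, columns=self.criterion_ids
        )

    def effective_objectives(self) -> dict[str, EffectiveObjective]:
        """Per-criterion benefit/cost orientation under this matrix's semantics."""
        return {
            c.criterion_id: effective_objective(c, self.semantics)
            for c in self.criteria
        }


#: The eleven default evaluation criteria (id, name, dimension, objective, units).
_DEFAULT_CRITERIA = [
    ("diabetes", "Risk to diabetes", Dimension.HEALTH, Objective.MINIMIZE, "%"),
    ("chd", "Prevention of coronary heart diseases", Dimension.HEALTH, Objective.MINIMIZE, "%"),
    ("mortality", "Risk to mortality", Dimension.HEALTH, Objective.MINIMIZE, "%"),
    ("obesity", "Risk to obesity", Dimension.HEALTH, Objective.MINIMIZE, "%"),
    ("cancer", "Total cancer", Dimension.HEALTH, Objective.MINIMIZE, "%"),
    ("ghge", "GHGE reduction", Dimension.ENVIRONMENT, Objective.MINIMIZE, "kg CO2eq/capita/year"),
    ("land_use", "Agricultural land use reduction", Dimension.ENVIRONMENT, Objective.MINIMIZE, "m2/capita/year"),
    ("water", "Water consumption", Dimension.ENVIRONMENT, Objective.MINIMIZE, "L/capita/day"),
    ("energy", "Energy consumption", Dimension.ENVIRONMENT, Objective.MINIMIZE, ""),
    ("diet_cost", "Average cost of a healthy diet", Dimension.SOCIOECONOMIC, Objective.MINIMIZE, "EUR/day"),
    ("savings", "Socio-economic savings to society", Dimension.SOCIOECONOMIC, Objective.MAXIMIZE, ""),
]


def default_criteria() -> list[Criterion]:
    """The eleven standard sustainability criteria used to score diets."""
    return [Criterion(*row) for row in _DEFAULT_CRITERIA]


def classify_relative_risk(rr: float) -> RiskClass:
    """Classify a relative risk: >1 increased, <1 decreased, =1 neutral.

    An RR above one means each additional daily serving of the food
    group raises the risk of the outcome (or the environmental burden);
    below one it lowers it.
    """
    if not rr > 0:
        raise ValueError(f"relative risk must be positive, got {rr}")
    if rr > 1:
        return RiskClass.INCREASED
    if rr < 1:
        return RiskClass.DECREASED
    return RiskClass.NEUTRAL


def mean_relative_risk(
    records: Sequence[RelativeRiskRecord],
) -> tuple[float, RiskClass]:
    """Arithmetic mean RR across outcomes for one food group, with its class."""
    if not records:
        raise ValueError("need at least one relative-risk record")
    groups = {r.food_group for r in records}
    if len(groups) > 1:
        raise ValueError(f"records mix food groups: {sorted(groups)}")
    mean = float(np.mean([r.rr for r in records]))
    return mean, classify_relative_risk(mean)


def aggregate_concept_criterion(
    observations: Sequence[OutcomeObservation],
) -> float:
    """Unweighted arithmetic mean of study values for one concept x criterion."""
    if not observations:
        raise MatrixAssemblyError(
            "no observations for this cell; a proxy value is required"
        )
    keys = {(o.concept_id, o.criterion_id) for o in observations}
    if len(keys) > 1:
        raise ValueError(f"observations mix cells: {sorted(keys)}")
    return float(np.mean([o.value for o in observations]))


def effective_objective(
    criterion: Criterion, semantics: ValueSemantics
) -> EffectiveObjective:
    """Orientation of a criterion under the given data semantics.

    Raw impact values inherit the criterion's objective directly.  When
    values are percent *reductions* of the underlying quantity, a
    minimized burden flips to a benefit (a larger reduction is better);
    a maximized quantity expressed as its own reduction is contradictory
    and rejected.
    """
    semantics = ValueSemantics(semantics)
    if semantics is ValueSemantics.RAW_IMPACT:
        return (
            EffectiveObjective.COST
            if criterion.objective is Objective.MINIMIZE
            else EffectiveObjective.BENEFIT
        )
    if criterion.objective is Objective.MAXIMIZE:
        raise ValueError(
            f"criterion '{criterion.criterion_id}' is maximized but its values "
            "are expressed as percent reduction — contradictory configuration"
        )
    return EffectiveObjective.BENEFIT


def build_decision_matrix(
    observations: Iterable[OutcomeObservation],
    criteria: Sequence[Criterion],
    alternatives: Sequence[str],
    semantics: ValueSemantics = ValueSemantics.PERCENT_REDUCTION,
    proxy_policy: str = "error",
) -> DecisionMatrix:
    """Assemble the fully populated alternatives x criteria matrix.

    Each cell is the arithmetic mean of its direct (non-proxy)
    observations together with any proxy observations supplied for it.
    A cell with no observation at all is an assembly error under
    ``proxy_policy="error"``; under ``proxy_policy="proxy_pool"`` such a
    cell may be covered only by proxy-flagged observations, which is
    recorded in the per-cell provenance.  Missing cells are never filled
    silently.
    """
    if proxy_policy not in ("error", "proxy_pool"):
        raise ValueError(f"unknown proxy_policy {proxy_policy!r}")
    alternatives = list(alternatives)
    crit_ids = [c.criterion_id for c in criteria]
    known_alts, known_crits = set(alternatives), set(crit_ids)

    cells: dict[tuple[str, str], list[OutcomeObservation]] = {}
    for obs in observations:
        if obs.concept_id not in known_alts:
            raise MatrixAssemblyError(f"unknown alternative '{obs.concept_id}'")
        if obs.criterion_id not in known_crits:
            raise MatrixAssemblyError(f"unknown criterion '{obs.criterion_id}'")
        cells.setdefault((obs.concept_id, obs.criterion_id), []).append(obs)

    values = np.empty((len(alternatives), len(crit_ids)))
    provenance: dict[tuple[str, str], dict] = {}
    missing: list[tuple[str, str]] = []
    for i, alt in enumerate(alternatives):
        for j, cid in enumerate(crit_ids):
            obs_list = cells.get((alt, cid), [])
            direct = [o for o in obs_list if not o.is_proxy]
            proxies = [o for o in obs_list if o.is_proxy]
            if not direct and (proxy_policy == "error" or not proxies):
                missing.append((alt, cid))
                continue
            used = obs_list if proxy_policy == "proxy_pool" else direct + proxies
            values[i, j] = aggregate_concept_criterion(used)
            provenance[(alt, cid)] = {
                "n_sources": len(used),
                "n_proxy": len(proxies),
                "proxy_only": not direct,
            }
    if missing:
        raise MatrixAssemblyError(
            "empty decision-matrix cells (alternative, criterion): "
            + ", ".join(f"({a}, {c})" for a, c in missing)
        )
    return DecisionMatrix(
        alternatives=alternatives,
        criteria=list(criteria),
        values=values,
        semantics=semantics,
        provenance=provenance,
    )
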