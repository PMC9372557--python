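"""Seeded synthetic inputs for every pipeline stage.

The package evaluates diet concepts from two kinds of empirical input
that cannot be redistributed: expert pairwise-comparison surveys and a
literature evidence base of cohort / life-cycle-assessment outcomes.
This module generates statistically controlled stand-ins for both —
expert judgment matrices with tunable inconsistency, percent-reduction
performance matrices with an optionally planted dominant alternative,
and study dossiers engineered to fail a declared screening step — so
that the full screening -> weighting -> ranking chain is testable
offline and reproducibly (every generator is a pure function of its
arguments and seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .ahp import (
    SAATY_MAX,
    SAATY_MIN,
    PairwiseComparisonMatrix,
    WeightVector,
    consistency,
    derive_weights,
    validate_pcm,
)
from .evidence import Criterion, DecisionMatrix, Dimension, Objective, ValueSemantics
from .screening import ConceptDossier, ScreeningConfig, StudyRecord

__all__ = [
    "SyntheticSpec",
    "NoisyPCMInfo",
    "gen_consistent_pcm",
    "gen_noisy_pcm",
    "gen_performance_matrix",
    "gen_study_dossiers",
    "TABLE4_PROFILE",
    "table4_dossiers",
    "expected_flags",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic study-condition draw."""

    seed: int = 0
    n_criteria: int = 11
    n_alternatives: int = 9
    target_cr_band: tuple[float, float] = (0.0, 0.1)
    planted_best_index: Optional[int] = None
    noise_scale: float = 0.1
    n_experts: int = 1

    def __post_init__(self):
        if self.n_criteria < 2:
            raise ValueError("need at least 2 criteria")
        if self.n_alternatives < 1:
            raise ValueError("need at least 1 alternative")
        low, high = self.target_cr_band
        if not (0 <= low <= high < 0.3):
            raise ValueError("target_cr_band must satisfy 0 <= low <= high < 0.3")
        if self.planted_best_index is not None and not (
            0 <= self.planted_best_index < self.n_alternatives
        ):
            raise ValueError("planted_best_index out of range")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")
        if self.n_experts < 1:
            raise ValueError("need at least 1 expert")


@dataclass(frozen=True)
class NoisyPCMInfo:
    """Achieved consistency and sampling effort of a noisy matrix draw."""

    achieved_cr: float
    attempts: int


def gen_consistent_pcm(weights: WeightVector) -> PairwiseComparisonMatrix:
    """Perfectly consistent matrix ``a_ij = w_i / w_j`` (CR = 0).

    The weight spread must fit the Saaty scale: max(w)/min(w) <= 9.
    """
    w = weights.weights
    spread = float(w.max() / w.min())
    if spread > SAATY_MAX + 1e-12:
        raise ValueError(
            f"weight ratio spread {spread:.3f} exceeds the Saaty scale cap of 9"
        )
    a = np.outer(w, 1.0 / w)
    np.fill_diagonal(a, 1.0)
    return validate_pcm(PairwiseComparisonMatrix(weights.criteria_ids, a))


def gen_noisy_pcm(
    weights: WeightVector,
    noise_scale: float,
    target_cr_band: tuple[float, float] = (0.0, 0.1),
    seed: int = 0,
    max_tries: int = 1000,
) -> tuple[PairwiseComparisonMatrix, NoisyPCMInfo]:
    """Near-consistent matrix with CR rejection-sampled into a target band.

    Upper-triangle entries of the consistent matrix are multiplied by
    log-normal noise (sigma = ``noise_scale``), clipped to the Saaty
    scale and mirrored as reciprocals; draws are repeated until the
    consistency ratio (verified through the AHP machinery, not assumed)
    lands in ``[low, high)``.  CR has no closed-form inverse in the
    noise scale, hence rejection sampling.
    """
    low, high = target_cr_band
    rng = np.random.default_rng(seed)
    base = gen_consistent_pcm(weights).values
    n = len(weights.criteria_ids)
    iu = np.triu_indices(n, k=1)
    last_cr = float("nan")
    for attempt in range(1, max_tries + 1):
        noise = rng.lognormal(mean=0.0, sigma=noise_scale, size=len(iu[0]))
        upper = np.clip(base[iu] * noise, SAATY_MIN, SAATY_MAX)
        a = np.ones((n, n))
        a[iu] = upper
        a[(iu[1], iu[0])] = 1.0 / upper
        pcm = PairwiseComparisonMatrix(weights.criteria_ids, a)
        report = consistency(pcm, derive_weights(pcm))
        last_cr = report.cr
        if low <= last_cr < high:
            return pcm, NoisyPCMInfo(achieved_cr=last_cr, attempts=attempt)
    raise RuntimeError(
        f"could not reach CR band [{low}, {high}) in {max_tries} tries; "
        f"last achieved CR = {last_cr:.4f}"
    )


def gen_performance_matrix(
    spec: SyntheticSpec,
) -> tuple[DecisionMatrix, Optional[str]]:
    """Percent-reduction performance matrix with an optional planted winner.

    Values are drawn uniformly in [-20, 90] percent (negative values are
    increases relative to the baseline diet), emulating the spread of
    reported health and environmental reductions across diet concepts.
    All generated criteria are minimized burdens, so under
    percent-reduction semantics every criterion is benefit-oriented and
    the planted row — the column-wise maximum of all other rows plus a
    margin of at least ``noise_scale`` — dominates on every criterion.

    Returns the matrix and the planted alternative's id (or None).
    """
    rng = np.random.default_rng(spec.seed)
    criteria = [
        Criterion(f"C{j + 1}", f"criterion {j + 1}", Dimension.ENVIRONMENT,
                  Objective.MINIMIZE, "%")
        for j in range(spec.n_criteria)
    ]
    alternatives = [f"diet_{i + 1}" for i in range(spec.n_alternatives)]
    values = rng.uniform(-20.0, 90.0, size=(spec.n_alternatives, spec.n_criteria))
    planted_id = None
    if spec.planted_best_index is not None and spec.n_alternatives > 1:
        k = spec.planted_best_index
        margin = max(spec.noise_scale, 1.0)
        others = np.delete(values, k, axis=0)
        values[k] = others.max(axis=0) + margin
        planted_id = alternatives[k]
    elif spec.planted_best_index is not None:
        planted_id = alternatives[spec.planted_best_index]
    dm = DecisionMatrix(
        alternatives=alternatives,
        criteria=criteria,
        values=values,
        semantics=ValueSemantics.PERCENT_REDUCTION,
    )
    return dm, planted_id


_VALID_PROFILES = {None, "pass", "step1", "step2", "step3", "step4"}


def _passing_study(
    concept_id: str, k: int, rng: np.random.Generator, config: ScreeningConfig,
    health: bool = True, env: bool = True,
) -> StudyRecord:
    return StudyRecord(
        study_id=f"{concept_id}_s{k}",
        concept_id=concept_id,
        country="USA",
        year=int(rng.integers(2000, 2021)),
        n_participants=int(rng.integers(config.min_participants,
                                        config.min_participants * 4)),
        includes_women_and_children=True,
        duration_years=float(config.min_duration_years + rng.uniform(0, 6)),
        has_health_outcomes=health,
        has_environmental_outcomes=env,
    )


def gen_study_dossiers(
    pass_profile: Mapping[str, Optional[str]],
    config: ScreeningConfig = ScreeningConfig(),
    seed: int = 0,
    concept_names: Optional[Mapping[str, str]] = None,
) -> list[ConceptDossier]:
    """Dossiers whose first failing screening step is exactly as declared.

    ``pass_profile`` maps each concept id to the step it should fail
    ("step1" .. "step4") or to None/"pass" for a fully selected concept.
    The generated evidence realizes the declared outcome under the given
    screening thresholds: e.g. a "step2" concept gets one study fewer
    than the minimum, a "step3" concept gets ten studies of which only
    half meet the duration sub-criterion, a "step4" concept's studies
    all lack environmental outcomes.
    """
    rng = np.random.default_rng(seed)
    dossiers: list[ConceptDossier] = []
    for concept_id, fail in pass_profile.items():
        if fail not in _VALID_PROFILES:
            raise ValueError(
                f"contradictory profile {fail!r} for '{concept_id}'; "
                f"expected one of {sorted(p for p in _VALID_PROFILES if p)}"
                " or None"
            )
        name = (concept_names or {}).get(concept_id, concept_id)
        region = fail != "step1"
        n_pass = max(config.min_studies, 6)
        if fail == "step1":
            studies = [_passing_study(concept_id, k, rng, config) for k in range(3)]
        elif fail == "step2":
            studies = [
                _passing_study(concept_id, k, rng, config)
                for k in range(config.min_studies - 1)
            ]
        elif fail == "step3":
            n = 10
            n_short = n - int(np.ceil(config.subcriterion_pass_fraction * n)) + 1
            studies = []
            for k in range(n):
                s = _passing_study(concept_id, k, rng, config)
                if k < n_short:  # too short to meet the duration sub-criterion
                    s = replace(s, duration_years=float(config.min_duration_years / 2))
                studies.append(s)
        elif fail == "step4":
            studies = [
                _passing_study(concept_id, k, rng, config, env=False)
                for k in range(n_pass)
            ]
        else:  # pass
            studies = [
                _passing_study(
                    concept_id, k, rng, config,
                    # vary outcome coverage while keeping both types present
                    health=(k != 1), env=(k != 0),
                )
                for k in range(n_pass)
            ]
        dossiers.append(
            ConceptDossier(
                concept_id=concept_id,
                concept_name=name,
                region_applicable=region,
                studies=tuple(studies),
            )
        )
    return dossiers


#: Published screening outcome of the 17 candidate diet concepts: the
#: step at which each concept was excluded, or None if it was selected.
#: Nine concepts survive all four steps.
TABLE4_PROFILE: tuple[tuple[str, Optional[str]], ...] = (
    ("mediterranean", None),
    ("eat_lancet", "step1"),
    ("vegetarian", None),
    ("atlantic", "step4"),
    ("dash", None),
    ("pesco_vegetarian", None),
    ("healthy_nordic", "step4"),
    ("paleolithic", "step4"),
    ("traditional_persian", "step2"),
    ("vegan", None),
    ("healthy_us_style", None),
    ("chinese", "step4"),
    ("western", "step4"),
    ("spanish", "step4"),
    ("provegetarian", None),
    ("pescatarian", None),
    ("flexitarian", None),
)

TABLE4_NAMES: dict[str, str] = {
    "mediterranean": "The Mediterranean diet pattern",
    "eat_lancet": "Healthy planetary diet (EAT-Lancet pattern)",
    "vegetarian": "Healthy vegetarian diet pattern",
    "atlantic": "Atlantic diet pattern",
    "dash": "Diet approach to stop hypertension (DASH diet)",
    "pesco_vegetarian": "Pesco-vegetarian",
    "healthy_nordic": "The healthy Nordic diet pattern",
    "paleolithic": "Paleolithic diet",
    "traditional_persian": "Traditional Persian medicine diet",
    "vegan": "Vegan diet",
    "healthy_us_style": "The healthy U.S. style diet pattern",
    "chinese": "Chinese diet pattern",
    "western": "Western diet concept",
    "spanish": "Spanish diet pattern",
    "provegetarian": "Provegetarian food pattern",
    "pescatarian": "Pescatarian diet",
    "flexitarian": "Flexitarian diet",
}


def table4_dossiers(
    config: ScreeningConfig = ScreeningConfig(), seed: int = 0
) -> list[ConceptDossier]:
    """Synthetic dossiers reproducing the published 17-concept screening."""
    return gen_study_dossiers(
        dict(TABLE4_PROFILE), config=config, seed=seed, concept_names=TABLE4_NAMES
    )


def expected_flags(
    fail: Optional[str],
) -> tuple[Optional[bool], Optional[bool], Optional[bool], Optional[bool]]:
    """Step flags implied by a declared first failing step (None = selected)."""
    if fail in (None, "pass"):
        return (True, True, True, True)
    k = int(fail[-1])
    flags: list[Optional[bool]] = [True] * (k - 1) + [False] + [None] * (4 - k)
    return tuple(flags)
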