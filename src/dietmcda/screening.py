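"""Four-step eligibility screening of candidate diet concepts.

A diet concept enters the evaluation only if the body of implementation
studies behind it survives four sequential inclusion/exclusion steps:

1. the concept and its studies apply to the focus region;
2. at least ``min_studies`` implementation studies exist (default 5);
3. a sufficient fraction (default 60%) of those studies satisfies each
   of three quality sub-criteria — sample size (>= 5,000 participants),
   demography (women and children included), and duration (>= 4 years);
4. both environmental-impact and health-outcome data are available.

Evaluation short-circuits at the first failing step: later steps are
reported as not-evaluated (``None``), mirroring the blank cells of a
screening summary table, and a concept is selected only when all four
steps pass.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "StudyRecord",
    "ConceptDossier",
    "ScreeningConfig",
    "ScreeningResult",
    "evaluate_steps",
    "screen_concepts",
    "selection_table",
]

_YEAR_MIN = 1900


@dataclass(frozen=True)
class StudyRecord:
    """One implementation study of a diet concept."""

    study_id: str
    concept_id: str
    country: str
    year: int
    n_participants: int
    includes_women_and_children: bool
    duration_years: float
    has_health_outcomes: bool
    has_environmental_outcomes: bool

    def __post_init__(self):
        if self.n_participants < 0:
            raise ValueError(f"n_participants must be >= 0, got {self.n_participants}")
        if self.duration_years < 0:
            raise ValueError(f"duration_years must be >= 0, got {self.duration_years}")
        current = datetime.date.today().year
        if not (_YEAR_MIN <= self.year <= current):
            raise ValueError(
                f"year {self.year} outside plausible range [{_YEAR_MIN}, {current}]"
            )


@dataclass(frozen=True)
class ConceptDossier:
    """A candidate diet concept with its evidence base."""

    concept_id: str
    concept_name: str
    region_applicable: bool
    studies: tuple[StudyRecord, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "studies", tuple(self.studies))


@dataclass(frozen=True)
class ScreeningConfig:
    """Thresholds of the four screening steps."""

    min_studies: int = 5
    min_participants: int = 5000
    min_duration_years: float = 4.0
    subcriterion_pass_fraction: float = 0.60
    require_env_and_health_data: bool = True

    def __post_init__(self):
        if self.min_studies <= 0 or self.min_participants <= 0:
            raise ValueError("study and participant thresholds must be positive")
        if self.min_duration_years <= 0:
            raise ValueError("duration threshold must be positive")
        if not (0 < self.subcriterion_pass_fraction <= 1):
            raise ValueError("subcriterion_pass_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ScreeningResult:
    """Outcome of the four steps for one concept.

    ``step1..step4`` are True/False where evaluated and ``None`` where a
    prior failure stopped evaluation.  ``selected`` requires all four
    steps to be True.
    """

    concept_id: str
    step1: Optional[bool]
    step2: Optional[bool]
    step3: Optional[bool]
    step4: Optional[bool]

    @property
    def steps(self) -> tuple[Optional[bool], ...]:
        return (self.step1, self.step2, self.step3, self.step4)

    @property
    def selected(self) -> bool:
        return all(s is True for s in self.steps)

    @property
    def first_failed_step(self) -> Optional[int]:
        """1-based index of the failing step, or None if selected."""
        for k, s in enumerate(self.steps, start=1):
            if s is False:
                return k
        return None


def _subcriterion_fractions(
    studies: Sequence[StudyRecord], config: ScreeningConfig
) -> dict[str, float]:
    n = len(studies)
    if n == 0:
        return {"sample_size": 0.0, "demography": 0.0, "duration": 0.0}
    return {
        "sample_size": sum(s.n_participants >= config.min_participants for s in studies) / n,
        "demography": sum(s.includes_women_and_children for s in studies) / n,
        "duration": sum(s.duration_years >= config.min_duration_years for s in studies) / n,
    }


def evaluate_steps(
    dossier: ConceptDossier, config: ScreeningConfig = ScreeningConfig()
) -> ScreeningResult:
    """Apply the four inclusion/exclusion steps to one concept dossier.

    Step 3 requires each of the three quality sub-criteria (sample size,
    demography, duration) to be met by at least
    ``subcriterion_pass_fraction`` of the concept's studies, compared
    with >= so that exactly 60% of the studies passing counts as a pass.
    """
    flags: list[Optional[bool]] = [None, None, None, None]

    flags[0] = bool(dossier.region_applicable)
    if flags[0]:
        flags[1] = len(dossier.studies) >= config.min_studies
    if flags[1]:
        fractions = _subcriterion_fractions(dossier.studies, config)
        flags[2] = all(
            f >= config.subcriterion_pass_fraction for f in fractions.values()
        )
    if flags[2]:
        if config.require_env_and_health_data:
            flags[3] = any(
                s.has_environmental_outcomes for s in dossier.studies
            ) and any(s.has_health_outcomes for s in dossier.studies)
        else:
            flags[3] = True
    return ScreeningResult(dossier.concept_id, *flags)


def screen_concepts(
    dossiers: Sequence[ConceptDossier],
    config: ScreeningConfig = ScreeningConfig(),
) -> list[ScreeningResult]:
    """Screen every dossier, preserving order; concept ids must be unique."""
    seen: set[str] = set()
    for d in dossiers:
        if d.concept_id in seen:
            raise ValueError(f"duplicate concept_id '{d.concept_id}'")
        seen.add(d.concept_id)
    return [evaluate_steps(d, config) for d in dossiers]


def selection_table(
    results: Sequence[ScreeningResult],
    names: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Human-readable selection report with check/cross marks.

    Evaluated steps render as a check mark or cross; steps skipped after
    a failure render blank.  Status is ``*`` for selected concepts and
    ``-`` for excluded ones.
    """

    def mark(flag: Optional[bool]) -> str:
        if flag is None:
            return ""
        return "√" if flag else "×"

    rows = []
    for k, r in enumerate(results, start=1):
        rows.append(
            {
                "s_n": k,
                "concept": (names or {}).get(r.concept_id, r.concept_id),
                "step1": mark(r.step1),
                "step2": mark(r.step2),
                "step3": mark(r.step3),
                "step4": mark(r.step4),
                "status": "*" if r.selected else "-",
            }
        )
    return pd.DataFrame(rows)
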