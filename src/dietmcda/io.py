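"""File dialects, run configuration and the machine-readable run report.

All tabular inputs are header-row CSV (UTF-8, "." decimal separator);
criteria configuration is YAML; reports are JSON with deterministic
field ordering.  Fraction strings like "1/3" are accepted only in
pairwise-comparison-matrix files, where they are the natural notation
for reciprocal Saaty judgments.  Every file write is atomic
(write-to-temporary, then rename) so partial outputs never masquerade
as results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ahp import ConsistencyReport, PairwiseComparisonMatrix, WeightVector, validate_pcm
from .evidence import (
    Criterion,
    DecisionMatrix,
    OutcomeObservation,
    RelativeRiskRecord,
    ValueSemantics,
)
from .screening import ConceptDossier, ScreeningConfig, ScreeningResult, StudyRecord
from .topsis import RankingResult

__all__ = [
    "RunConfig",
    "RunReport",
    "atomic_write_text",
    "read_pcm",
    "write_pcm",
    "read_criteria",
    "write_criteria",
    "read_studies",
    "read_concepts",
    "read_dossiers",
    "read_observations",
    "read_relative_risks",
    "read_decision_matrix",
    "write_decision_matrix",
    "write_report",
]

_BOOL_TRUE = {"true", "1", "yes", "y"}
_BOOL_FALSE = {"false", "0", "no", "n"}


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in _BOOL_TRUE:
        return True
    if s in _BOOL_FALSE:
        return False
    raise ValueError(f"cannot parse boolean from {x!r}")


def atomic_write_text(path: str | Path, text: str) -> Path:
    """Write ``text`` to ``path`` via a temporary file and atomic rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# pairwise comparison matrices

def _parse_judgment(cell, row: int, col: int) -> float:
    s = str(cell).strip()
    try:
        if "/" in s:
            return float(Fraction(s))
        return float(s)
    except (ValueError, ZeroDivisionError) as exc:
        raise ValueError(
            f"cannot parse judgment {cell!r} at row {row + 1}, column {col + 1}"
        ) from exc


def read_pcm(path: str | Path) -> PairwiseComparisonMatrix:
    """Read a PCM from CSV with matching header row/column of criterion ids."""
    df = pd.read_csv(path, index_col=0, dtype=str)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: PCM file must be square, got {df.shape}")
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if rows != cols:
        raise ValueError(f"{path}: row labels {rows} != column labels {cols}")
    n = len(rows)
    values = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            values[i, j] = _parse_judgment(df.iat[i, j], i, j)
    return validate_pcm(PairwiseComparisonMatrix(rows, values))


def write_pcm(pcm: PairwiseComparisonMatrix, path: str | Path) -> Path:
    ids = list(pcm.criteria_ids)
    lines = ["," + ",".join(ids)]
    for i, cid in enumerate(ids):
        lines.append(cid + "," + ",".join(repr(float(v)) for v in pcm.values[i]))
    return atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# criteria configuration

def read_criteria(path: str | Path) -> list[Criterion]:
    """Read the criteria set from YAML (list of id/name/dimension/objective/units)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, dict):
        raw = raw.get("criteria", raw)
    return [
        Criterion(
            criterion_id=str(d["id"]),
            name=str(d.get("name", d["id"])),
            dimension=d["dimension"],
            objective=d["objective"],
            units=str(d.get("units", "")),
        )
        for d in raw
    ]


def write_criteria(criteria: Sequence[Criterion], path: str | Path) -> Path:
    payload = {
        "criteria": [
            {
                "id": c.criterion_id,
                "name": c.name,
                "dimension": c.dimension.value,
                "objective": c.objective.value,
                "units": c.units,
            }
            for c in criteria
        ]
    }
    return atomic_write_text(path, yaml.safe_dump(payload, sort_keys=False))


# ---------------------------------------------------------------------------
# screening inputs

def read_studies(path: str | Path) -> list[StudyRecord]:
    df = pd.read_csv(path)
    return [
        StudyRecord(
            study_id=str(r.study_id),
            concept_id=str(r.concept_id),
            country=str(r.country),
            year=int(r.year),
            n_participants=int(r.n_participants),
            includes_women_and_children=_parse_bool(r.includes_women_and_children),
            duration_years=float(r.duration_years),
            has_health_outcomes=_parse_bool(r.has_health_outcomes),
            has_environmental_outcomes=_parse_bool(r.has_environmental_outcomes),
        )
        for r in df.itertuples(index=False)
    ]


def read_concepts(path: str | Path) -> list[tuple[str, str, bool]]:
    """Concept roster rows: (concept_id, name, region_applicable)."""
    df = pd.read_csv(path)
    return [
        (str(r.concept_id), str(r.concept_name), _parse_bool(r.region_applicable))
        for r in df.itertuples(index=False)
    ]


def read_dossiers(studies_path: str | Path, concepts_path: str | Path) -> list[ConceptDossier]:
    """Join the concept roster with its studies into screening dossiers."""
    studies = read_studies(studies_path)
    by_concept: dict[str, list[StudyRecord]] = {}
    for s in studies:
        by_concept.setdefault(s.concept_id, []).append(s)
    return [
        ConceptDossier(
            concept_id=cid,
            concept_name=name,
            region_applicable=region,
            studies=tuple(by_concept.get(cid, [])),
        )
        for cid, name, region in read_concepts(concepts_path)
    ]


# ---------------------------------------------------------------------------
# evidence inputs

def read_observations(path: str | Path) -> list[OutcomeObservation]:
    df = pd.read_csv(path)
    has_proxy = "is_proxy" in df.columns
    has_source = "source_id" in df.columns
    return [
        OutcomeObservation(
            concept_id=str(r.concept_id),
            criterion_id=str(r.criterion_id),
            value=float(r.value),
            source_id=str(r.source_id) if has_source else "",
            is_proxy=_parse_bool(r.is_proxy) if has_proxy else False,
        )
        for r in df.itertuples(index=False)
    ]


def read_relative_risks(path: str | Path) -> list[RelativeRiskRecord]:
    df = pd.read_csv(path)
    return [
        RelativeRiskRecord(
            food_group=str(r.food_group), outcome=str(r.outcome), rr=float(r.rr)
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# decision matrix

def write_decision_matrix(dm: DecisionMatrix, path: str | Path) -> Path:
    """Write the matrix as CSV plus a JSON sidecar with semantics/provenance."""
    path = Path(path)
    csv_text = dm.to_frame().to_csv(index_label="alternative", lineterminator="\n")
    atomic_write_text(path, csv_text)
    sidecar = {
        "semantics": dm.semantics.value,
        "criteria": [
            {
                "id": c.criterion_id,
                "name": c.name,
                "dimension": c.dimension.value,
                "objective": c.objective.value,
                "units": c.units,
            }
            for c in dm.criteria
        ],
        "provenance": {
            f"{a}|{c}": info for (a, c), info in sorted(dm.provenance.items())
        },
    }
    atomic_write_text(
        path.with_suffix(path.suffix + ".json"),
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n",
    )
    return path


def read_decision_matrix(
    path: str | Path, criteria: Optional[Sequence[Criterion]] = None
) -> DecisionMatrix:
    """Read a matrix CSV; criteria metadata from the sidecar unless given."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    semantics = ValueSemantics.PERCENT_REDUCTION
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if criteria is None:
        if not sidecar_path.exists():
            raise FileNotFoundError(
                f"no criteria given and no sidecar {sidecar_path} found"
            )
        with open(sidecar_path, encoding="utf-8") as fh:
            sidecar = json.load(fh)
        semantics = ValueSemantics(sidecar["semantics"])
        criteria = [
            Criterion(
                criterion_id=d["id"],
                name=d.get("name", d["id"]),
                dimension=d["dimension"],
                objective=d["objective"],
                units=d.get("units", ""),
            )
            for d in sidecar["criteria"]
        ]
    elif sidecar_path.exists():
        with open(sidecar_path, encoding="utf-8") as fh:
            semantics = ValueSemantics(json.load(fh)["semantics"])
    order = [c.criterion_id for c in criteria]
    if sorted(order) != sorted(map(str, df.columns)):
        raise ValueError(
            f"matrix columns {list(df.columns)} do not match criteria {order}"
        )
    return DecisionMatrix(
        alternatives=[str(a) for a in df.index],
        criteria=list(criteria),
        values=df[order].to_numpy(dtype=float),
        semantics=semantics,
    )


# ---------------------------------------------------------------------------
# run configuration and report

@dataclass
class RunConfig:
    """Everything needed to reproduce a full pipeline run."""

    studies: str
    concepts: str
    pcm: list[str]
    observations: str
    criteria: Optional[str] = None
    out_dir: str = "out"
    seed: int = 0
    enforce_cr: bool = True
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    ri_table: Optional[dict[int, float]] = None
    semantics: ValueSemantics = ValueSemantics.PERCENT_REDUCTION
    proxy_policy: str = "proxy_pool"

    def input_paths(self) -> dict[str, str]:
        paths = {"studies": self.studies, "concepts": self.concepts,
                 "observations": self.observations}
        for k, p in enumerate(self.pcm):
            paths[f"pcm_{k}"] = p
        if self.criteria:
            paths["criteria"] = self.criteria
        return paths


def _to_jsonable(x: Any) -> Any:
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return [_to_jsonable(v) for v in x.tolist()]
    if isinstance(x, dict):
        return {str(k): _to_jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_to_jsonable(v) for v in x]
    return x


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run (JSON round-trippable)."""

    version: str = __version__
    seed: int = 0
    input_digests: dict[str, str] = field(default_factory=dict)
    screening: list[dict] = field(default_factory=list)
    weights: dict[str, float] = field(default_factory=dict)
    consistency: dict = field(default_factory=dict)
    ranking: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @staticmethod
    def screening_rows(results: Sequence[ScreeningResult]) -> list[dict]:
        return [
            {
                "concept_id": r.concept_id,
                "step1": r.step1,
                "step2": r.step2,
                "step3": r.step3,
                "step4": r.step4,
                "selected": r.selected,
            }
            for r in results
        ]

    @staticmethod
    def ranking_rows(ranking: RankingResult) -> list[dict]:
        df = ranking.to_frame()
        return [
            {
                "alternative": row.alternative,
                "d_plus": float(row.d_plus),
                "d_minus": float(row.d_minus),
                "closeness": float(row.closeness),
                "rank": int(row.rank),
                "tied": bool(row.tied),
            }
            for row in df.itertuples(index=False)
        ]

    def to_json(self) -> str:
        payload = _to_jsonable(dataclasses.asdict(self))
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        d = json.loads(text)
        return cls(**d)


def digest_inputs(config: RunConfig) -> dict[str, str]:
    return {name: _digest(p) for name, p in sorted(config.input_paths().items())}


def write_report(report: RunReport, out_dir: str | Path) -> dict[str, Path]:
    """Emit report.json, ranking.csv, weights.json, screening.csv, summary.txt."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files["report"] = atomic_write_text(out / "report.json", report.to_json())
    files["weights"] = atomic_write_text(
        out / "weights.json",
        json.dumps(_to_jsonable(report.weights), indent=2, sort_keys=True) + "\n",
    )
    rank_df = pd.DataFrame(report.ranking)
    files["ranking"] = atomic_write_text(
        out / "ranking.csv", rank_df.to_csv(index=False, lineterminator="\n")
    )
    screen_df = pd.DataFrame(report.screening)
    files["screening"] = atomic_write_text(
        out / "screening.csv", screen_df.to_csv(index=False, lineterminator="\n")
    )

    lines = [
        f"dietmcda run report (version {report.version}, seed {report.seed})",
        "",
        "Screening: "
        + f"{sum(r['selected'] for r in report.screening)} of "
        + f"{len(report.screening)} concepts selected",
        "",
        "Criterion weights:",
    ]
    for cid, w in sorted(report.weights.items(), key=lambda kv: -kv[1]):
        lines.append(f"  {cid:<24s} {w:.4f}")
    if report.consistency:
        c = report.consistency
        lines += [
            "",
            f"Consistency: lambda_max={c['lambda_max']:.4f} CI={c['ci']:.4f} "
            f"RI={c['ri']:.2f} CR={c['cr']:.4f} "
            f"({'PASS' if c['passed'] else 'FAIL'} at CR<{c['threshold']})",
        ]
    if report.ranking:
        lines += ["", "Ranking (best first):"]
        for row in sorted(report.ranking, key=lambda r: r["rank"]):
            tie = "  [tie]" if row.get("tied") else ""
            lines.append(
                f"  {row['rank']:>2d}. {row['alternative']:<24s} "
                f"CC*={row['closeness']:.3f}{tie}"
            )
    if report.warnings:
        lines += ["", "Warnings:"] + [f"  - {w}" for w in report.warnings]
    files["summary"] = atomic_write_text(out / "summary.txt", "\n".join(lines) + "\n")
    return files
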