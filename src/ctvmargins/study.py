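"""Multi-case margin studies: per-case evaluation and cross-case summaries.

A *case* is one patient: a GTV, an ensemble of expert CTVs, a consensus CTV
(given, or computed here by STAPLE), optional barrier mask, and a set of
clinician-chosen probe directions, each tagged with a route-of-spread class
(e.g. intraosseous / extraosseous). Per direction the case yields the
consensus margin M(d) (GTV vs consensus CTV) and the margin deviation CV(d)
(GTV vs each expert CTV). A *study* pools the per-direction results of many
cases by route class — each direction is one datum, so a case can contribute
to several classes — and reports the median and range per class.

A failed direction (e.g. every ray blocked by the barrier) never aborts its
case: the failure reason is recorded and the direction is excluded from, but
counted alongside, the summaries.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .errors import CtvMarginsError, StudyConfigError
from .geometry import BinaryVolume, DirectionSpec, require_compatible
from .io import read_mask, write_mask
from .margins import CastParams, directional_margin, margin_deviation
from .staple import staple_consensus

__all__ = [
    "CaseConfig",
    "DirectionOutcome",
    "CaseResult",
    "ClassSummary",
    "ConsensusSummary",
    "evaluate_case",
    "run_case",
    "summarize_study",
    "load_study_config",
    "run_study",
    "write_study_reports",
]

logger = logging.getLogger(__name__)

#: Reporting precision of the human-readable table (mm, dimensionless).
MARGIN_DECIMALS = 1
CV_DECIMALS = 2


@dataclass(frozen=True)
class CaseConfig:
    """File-based description of one case."""

    case_id: str
    gtv_path: Path
    expert_ctv_paths: tuple[Path, ...]
    directions: tuple[DirectionSpec, ...]
    consensus_ctv_path: Optional[Path] = None
    barrier_path: Optional[Path] = None

    def __post_init__(self) -> None:
        if not self.case_id:
            raise StudyConfigError("case_id must be non-empty")
        if not self.directions:
            raise StudyConfigError(f"case {self.case_id!r} has no directions")
        labels = [d.label for d in self.directions]
        if len(set(labels)) != len(labels):
            raise StudyConfigError(
                f"case {self.case_id!r} has duplicate direction labels: {labels}"
            )
        if not self.expert_ctv_paths and self.consensus_ctv_path is None:
            raise StudyConfigError(
                f"case {self.case_id!r} needs expert CTVs or a consensus CTV"
            )


@dataclass(frozen=True)
class DirectionOutcome:
    """Per-direction results (or recorded failure) within one case."""

    direction: DirectionSpec
    consensus_margin_mm: Optional[float] = None
    margin_cv: Optional[float] = None
    per_expert_margins_mm: Optional[tuple[float, ...]] = None
    counters: Mapping[str, int] = field(default_factory=dict)
    error: Optional[str] = None

    @property
    def failed(self) -> bool:
        return self.error is not None


@dataclass(frozen=True)
class CaseResult:
    case_id: str
    per_direction: tuple[DirectionOutcome, ...]


@dataclass(frozen=True)
class ClassSummary:
    """Pooled per-route-class statistics across a study."""

    route_class: str
    median_margin_mm: float
    margin_range_mm: tuple[float, float]
    median_cv: Optional[float]
    cv_range: Optional[tuple[float, float]]
    n_directions: int
    n_cases: int
    n_failed: int


@dataclass(frozen=True)
class ConsensusSummary:
    per_class: tuple[ClassSummary, ...]

    def __getitem__(self, route_class: str) -> ClassSummary:
        for c in self.per_class:
            if c.route_class == route_class:
                return c
        raise KeyError(route_class)


def evaluate_case(
    case_id: str,
    gtv: BinaryVolume,
    directions: Sequence[DirectionSpec],
    expert_ctvs: Sequence[BinaryVolume] = (),
    consensus_ctv: Optional[BinaryVolume] = None,
    barrier: Optional[BinaryVolume] = None,
    params: CastParams = CastParams(),
    staple_threshold: float = 0.5,
) -> CaseResult:
    """Evaluate every direction of one case from in-memory volumes.

    When ``consensus_ctv`` is None it is computed from the experts by
    STAPLE. The margin deviation is computed only when >= 2 experts are
    given. A single direction's failure is recorded, not raised.
    """
    volumes = [gtv, *expert_ctvs]
    names = ["gtv"] + [f"expert[{j}]" for j in range(len(expert_ctvs))]
    if consensus_ctv is not None:
        volumes.append(consensus_ctv)
        names.append("consensus")
    if barrier is not None:
        volumes.append(barrier)
        names.append("barrier")
    require_compatible(*volumes, names=names)
    if consensus_ctv is None:
        logger.info("case %s: computing STAPLE consensus of %d experts", case_id, len(expert_ctvs))
        consensus_ctv = staple_consensus(
            expert_ctvs, threshold=staple_threshold
        ).consensus_mask
    outcomes = []
    for direction in directions:
        logger.info("case %s: direction %s", case_id, direction.label)
        try:
            margin = directional_margin(gtv, consensus_ctv, direction, barrier, params)
            cv_value = None
            per_expert = None
            if len(expert_ctvs) >= 2:
                deviation = margin_deviation(gtv, expert_ctvs, direction, barrier, params)
                cv_value = deviation.cv
                per_expert = tuple(float(m) for m in deviation.per_expert_margins_mm)
            outcomes.append(
                DirectionOutcome(
                    direction=direction,
                    consensus_margin_mm=margin.margin_mm,
                    margin_cv=cv_value,
                    per_expert_margins_mm=per_expert,
                    counters=margin.vector_set.counters(),
                )
            )
        except CtvMarginsError as exc:
            logger.warning("case %s: direction %s failed: %s", case_id, direction.label, exc)
            outcomes.append(DirectionOutcome(direction=direction, error=str(exc)))
    return CaseResult(case_id=case_id, per_direction=tuple(outcomes))


def run_case(config: CaseConfig, params: CastParams = CastParams()) -> CaseResult:
    """Load a case's volumes from disk and evaluate it."""
    gtv = read_mask(config.gtv_path)
    experts = [read_mask(p) for p in config.expert_ctv_paths]
    consensus = (
        read_mask(config.consensus_ctv_path)
        if config.consensus_ctv_path is not None
        else None
    )
    barrier = read_mask(config.barrier_path) if config.barrier_path is not None else None
    return evaluate_case(
        case_id=config.case_id,
        gtv=gtv,
        directions=config.directions,
        expert_ctvs=experts,
        consensus_ctv=consensus,
        barrier=barrier,
        params=params,
    )


def summarize_study(
    results: Sequence[CaseResult],
    route_classes: Optional[Mapping[str, str]] = None,
) -> ConsensusSummary:
    """Pool per-direction margins and CVs by route class across cases.

    Each successful direction contributes one margin (and one CV when
    available) to its route class; the class of a direction is taken from
    ``route_classes[label]`` when the mapping is given, else from the
    direction's own ``route_class``. Failed directions are excluded from the
    statistics but counted in ``n_failed``.
    """
    margins: dict[str, list[float]] = {}
    cvs: dict[str, list[float]] = {}
    case_ids: dict[str, set[str]] = {}
    failed: dict[str, int] = {}
    for result in results:
        for outcome in result.per_direction:
            label = outcome.direction.label
            cls = (
                route_classes[label]
                if route_classes is not None and label in route_classes
                else outcome.direction.route_class
            )
            if outcome.failed:
                failed[cls] = failed.get(cls, 0) + 1
                continue
            margins.setdefault(cls, []).append(float(outcome.consensus_margin_mm))
            case_ids.setdefault(cls, set()).add(result.case_id)
            if outcome.margin_cv is not None:
                cvs.setdefault(cls, []).append(float(outcome.margin_cv))
    if not margins:
        raise CtvMarginsError("nothing to summarize: no direction succeeded")
    summaries = []
    for cls in sorted(set(margins) | set(failed)):
        values = margins.get(cls)
        if values is None:
            continue
        arr = np.asarray(values)
        cls_cvs = cvs.get(cls)
        summaries.append(
            ClassSummary(
                route_class=cls,
                median_margin_mm=float(np.median(arr)),
                margin_range_mm=(float(arr.min()), float(arr.max())),
                median_cv=float(np.median(cls_cvs)) if cls_cvs else None,
                cv_range=(
                    (float(min(cls_cvs)), float(max(cls_cvs))) if cls_cvs else None
                ),
                n_directions=len(values),
                n_cases=len(case_ids.get(cls, set())),
                n_failed=failed.get(cls, 0),
            )
        )
    return ConsensusSummary(per_class=tuple(summaries))


# -- configuration ----------------------------------------------------------


def _parse_direction(entry: Mapping) -> DirectionSpec:
    route = str(entry.get("route_class", "unspecified"))
    if "vector" in entry:
        label = str(entry.get("label", "custom"))
        return DirectionSpec.from_vector(entry["vector"], label=label, route_class=route)
    if "label" in entry:
        return DirectionSpec.from_label(str(entry["label"]), route_class=route)
    raise StudyConfigError(f"direction entry needs 'label' or 'vector': {entry!r}")


def load_study_config(path: str | Path) -> list[CaseConfig]:
    """Read a study description (YAML or JSON) into :class:`CaseConfig` list.

    Relative mask paths are resolved against the config file's directory.
    Expected layout::

        cases:
          - case_id: case01
            gtv: masks/case01_gtv.nii.gz
            experts: [masks/e1.nii.gz, masks/e2.nii.gz]
            consensus_ctv: masks/consensus.nii.gz   # optional
            barrier: masks/cortex.nii.gz            # optional
            directions:
              - {label: SA, route_class: intraosseous}
              - {label: ext1, vector: [0, 1, 0], route_class: extraosseous}
    """
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping) or "cases" not in data:
        raise StudyConfigError(f"{path}: expected a mapping with a 'cases' list")
    base = path.parent
    configs = []
    for entry in data["cases"]:
        try:
            directions = tuple(_parse_direction(d) for d in entry["directions"])
            configs.append(
                CaseConfig(
                    case_id=str(entry["case_id"]),
                    gtv_path=base / entry["gtv"],
                    expert_ctv_paths=tuple(base / p for p in entry.get("experts", [])),
                    directions=directions,
                    consensus_ctv_path=(
                        base / entry["consensus_ctv"] if "consensus_ctv" in entry else None
                    ),
                    barrier_path=base / entry["barrier"] if "barrier" in entry else None,
                )
            )
        except KeyError as exc:
            raise StudyConfigError(f"{path}: case entry missing key {exc}") from exc
    ids = [c.case_id for c in configs]
    if len(set(ids)) != len(ids):
        raise StudyConfigError(f"{path}: duplicate case ids {ids}")
    return configs


# -- reports ----------------------------------------------------------------

_CSV_COLUMNS = [
    "case_id",
    "direction_label",
    "route_class",
    "consensus_margin_mm",
    "margin_cv",
    "n_vectors",
    "n_rejected_interior",
    "n_rejected_barrier",
    "n_clamped",
    "error",
]


def _outcome_record(case_id: str, outcome: DirectionOutcome) -> dict:
    counters = dict(outcome.counters)
    return {
        "case_id": case_id,
        "direction_label": outcome.direction.label,
        "route_class": outcome.direction.route_class,
        "consensus_margin_mm": outcome.consensus_margin_mm,
        "margin_cv": outcome.margin_cv,
        "n_vectors": counters.get("n_vectors"),
        "n_rejected_interior": counters.get("n_rejected_interior"),
        "n_rejected_barrier": counters.get("n_rejected_barrier"),
        "n_clamped": counters.get("n_clamped"),
        "error": outcome.error,
    }


def _case_json(result: CaseResult) -> dict:
    return {
        "case_id": result.case_id,
        "directions": [
            {
                "label": o.direction.label,
                "vector": [float(v) for v in o.direction.vector],
                "route_class": o.direction.route_class,
                "consensus_margin_mm": o.consensus_margin_mm,
                "margin_cv": o.margin_cv,
                "per_expert_margins_mm": (
                    list(o.per_expert_margins_mm)
                    if o.per_expert_margins_mm is not None
                    else None
                ),
                "counters": dict(o.counters),
                "error": o.error,
            }
            for o in result.per_direction
        ],
    }


def _summary_json(summary: ConsensusSummary) -> dict:
    return {
        "per_class": [
            {
                "route_class": c.route_class,
                "median_margin_mm": c.median_margin_mm,
                "margin_range_mm": list(c.margin_range_mm),
                "median_cv": c.median_cv,
                "cv_range": list(c.cv_range) if c.cv_range is not None else None,
                "n_directions": c.n_directions,
                "n_cases": c.n_cases,
                "n_failed": c.n_failed,
                # rounded view at the reporting precision of the tables
                "median_margin_mm_rounded": round(c.median_margin_mm, MARGIN_DECIMALS),
                "median_cv_rounded": (
                    round(c.median_cv, CV_DECIMALS) if c.median_cv is not None else None
                ),
            }
            for c in summary.per_class
        ]
    }


def write_study_reports(
    results: Sequence[CaseResult],
    summary: ConsensusSummary,
    out_dir: str | Path,
) -> None:
    """Write per-case JSON, the tidy study CSV and the summary JSON.

    Output is deterministic: identical inputs produce bit-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for result in results:
        with open(out / f"case_{result.case_id}.json", "w") as fh:
            json.dump(_case_json(result), fh, indent=1, sort_keys=True)
            fh.write("\n")
    with open(out / "study.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for result in results:
            for outcome in result.per_direction:
                writer.writerow(_outcome_record(result.case_id, outcome))
    with open(out / "summary.json", "w") as fh:
        json.dump(_summary_json(summary), fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_study(
    configs: Sequence[CaseConfig],
    out_dir: Optional[str | Path] = None,
    params: CastParams = CastParams(),
) -> tuple[list[CaseResult], ConsensusSummary]:
    """Run every case, summarize by route class, optionally write reports."""
    results = [run_case(cfg, params) for cfg in configs]
    summary = summarize_study(results)
    if out_dir is not None:
        write_study_reports(results, summary, out_dir)
    return results, summary
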