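"""Pipeline orchestration: validated YAML configs and the full stability
workflow (per-experiment geNorm -> cross-experiment rank aggregation) with a
machine-readable, schema-versioned JSON report."""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .data_model import collapse_replicates, read_cq_table, to_relative_quantities
from .genorm import StabilityConfig, StabilityResult, analyze_stability
from .rankagg import (
    CeConfig,
    ConsensusRanking,
    EXHAUSTIVE_LIMIT,
    RankedList,
    aggregate_ce,
    aggregate_exhaustive,
)

__all__ = [
    "ConfigError",
    "PipelineConfig",
    "ExperimentSpec",
    "Thresholds",
    "AggregationSettings",
    "validate_config",
    "run_stability_suite",
    "ranked_list_from_stability",
    "validate_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = "1.0"


class ConfigError(ValueError):
    """Carries every violation found during validation, not just the first."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("invalid pipeline config:\n  - " + "\n  - ".join(self.errors))


@dataclass(frozen=True)
class Thresholds:
    m_high: float = 0.5
    m_very_high: float = 0.2
    v_cutoff: float = 0.15
    efficiency_low: float = 90.0
    efficiency_high: float = 110.0
    r2_min: float = 0.98
    conservation_min: float = 97.0
    min_hits: int = 30


@dataclass(frozen=True)
class ExperimentSpec:
    experiment_id: str
    cq_table: Path
    layout: str = "long"
    drop_samples: tuple[str, ...] = ()
    drop_targets: tuple[str, ...] = ()
    max_spread: float = 0.5


@dataclass(frozen=True)
class AggregationSettings:
    distance: str = "weighted_footrule"
    seed: int = 0
    sample_size: int | None = None
    elite_fraction: float = 0.1
    smoothing: float = 0.25
    max_iterations: int = 100
    convergence_patience: int = 15
    force_monte_carlo: bool = False

    def ce_config(self) -> CeConfig:
        return CeConfig(
            sample_size=self.sample_size,
            elite_fraction=self.elite_fraction,
            smoothing=self.smoothing,
            max_iterations=self.max_iterations,
            convergence_patience=self.convergence_patience,
        )


@dataclass(frozen=True)
class PipelineConfig:
    experiments: tuple[ExperimentSpec, ...]
    thresholds: Thresholds = field(default_factory=Thresholds)
    aggregation: AggregationSettings = field(default_factory=AggregationSettings)
    output_dir: Path = Path("erenorm_out")


_TOP_KEYS = {"experiments", "thresholds", "aggregation", "output_dir"}
_EXPERIMENT_KEYS = {"id", "cq_table", "layout", "drop_samples", "drop_targets", "max_spread"}
_THRESHOLD_KEYS = {f.name for f in Thresholds.__dataclass_fields__.values()}
_AGG_KEYS = {f.name for f in AggregationSettings.__dataclass_fields__.values()}


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config, injecting all defaults.

    Unknown keys are rejected (typo guard) and every violation is reported at
    once in the raised :class:`ConfigError`.
    """
    raw = yaml.safe_load(Path(path).read_text())
    errors: list[str] = []
    if not isinstance(raw, Mapping):
        raise ConfigError(["config root must be a mapping"])
    for key in set(raw) - _TOP_KEYS:
        errors.append(f"unknown key {key!r}")

    base = Path(path).parent
    experiments: list[ExperimentSpec] = []
    raw_exps = raw.get("experiments", [])
    if not isinstance(raw_exps, list) or not raw_exps:
        errors.append("'experiments' must be a non-empty list")
        raw_exps = []
    for i, exp in enumerate(raw_exps):
        if not isinstance(exp, Mapping):
            errors.append(f"experiment #{i + 1} must be a mapping")
            continue
        for key in set(exp) - _EXPERIMENT_KEYS:
            errors.append(f"experiment #{i + 1}: unknown key {key!r}")
        if "id" not in exp or "cq_table" not in exp:
            errors.append(f"experiment #{i + 1}: 'id' and 'cq_table' are required")
            continue
        table = Path(exp["cq_table"])
        if not table.is_absolute():
            table = base / table
        if not table.exists():
            errors.append(f"experiment {exp['id']!r}: no such Cq table {table}")
        layout = exp.get("layout", "long")
        if layout not in ("long", "wide"):
            errors.append(f"experiment {exp['id']!r}: layout must be long or wide")
        max_spread = float(exp.get("max_spread", 0.5))
        if max_spread <= 0:
            errors.append(f"experiment {exp['id']!r}: max_spread must be positive")
        experiments.append(
            ExperimentSpec(
                str(exp["id"]),
                table,
                layout,
                tuple(exp.get("drop_samples", ())),
                tuple(exp.get("drop_targets", ())),
                max_spread,
            )
        )
    ids = [e.experiment_id for e in experiments]
    if len(set(ids)) != len(ids):
        errors.append("duplicate experiment ids")

    thr_raw = raw.get("thresholds", {}) or {}
    for key in set(thr_raw) - _THRESHOLD_KEYS:
        errors.append(f"thresholds: unknown key {key!r}")
    thr_kwargs = {k: v for k, v in thr_raw.items() if k in _THRESHOLD_KEYS}
    thresholds = Thresholds(**{**{}, **thr_kwargs})
    if not 0 < thresholds.m_very_high < thresholds.m_high:
        errors.append("thresholds: need 0 < m_very_high < m_high")
    if thresholds.v_cutoff <= 0:
        errors.append("thresholds: v_cutoff must be positive")
    if not thresholds.efficiency_low < thresholds.efficiency_high:
        errors.append("thresholds: efficiency_low must be below efficiency_high")
    if not 0 < thresholds.r2_min < 1:
        errors.append("thresholds: r2_min must be in (0, 1)")
    if not 0 < thresholds.conservation_min <= 100:
        errors.append("thresholds: conservation_min must be in (0, 100]")
    if thresholds.min_hits < 1:
        errors.append("thresholds: min_hits must be >= 1")

    agg_raw = raw.get("aggregation", {}) or {}
    for key in set(agg_raw) - _AGG_KEYS:
        errors.append(f"aggregation: unknown key {key!r}")
    agg_kwargs = {k: v for k, v in agg_raw.items() if k in _AGG_KEYS}
    aggregation = AggregationSettings(**agg_kwargs)
    if aggregation.distance not in ("footrule", "weighted_footrule"):
        errors.append("aggregation: distance must be footrule or weighted_footrule")
    try:
        aggregation.ce_config()
    except ValueError as exc:
        errors.append(f"aggregation: {exc}")

    if errors:
        raise ConfigError(errors)
    out_dir = Path(raw.get("output_dir", "erenorm_out"))
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    return PipelineConfig(tuple(experiments), thresholds, aggregation, out_dir)


def ranked_list_from_stability(
    experiment_id: str, result: StabilityResult
) -> RankedList:
    """Build an aggregation input from one experiment's stability result:
    targets ordered by first-pass M (ascending, ties lexicographic)."""
    ordering = tuple(sorted(result.m_values, key=lambda t: (result.m_values[t], t)))
    return RankedList(experiment_id, ordering, dict(result.m_values))


def _stability_payload(result: StabilityResult) -> dict[str, Any]:
    elim_m = dict(result.elimination_order)
    return {
        "m_values": result.m_values,
        "m_at_elimination": elim_m,
        "ranked_targets": result.ranked_targets,
        "v_series": {str(n): v for n, v in result.v_series.items()},
        "optimal_n": result.optimal_n,
        "optimal_n_flag": result.optimal_n_flag,
        "classes": result.classes,
    }


def run_stability_suite(config: PipelineConfig) -> dict[str, Any]:
    """Run the stability workflow for every configured experiment, then
    aggregate the per-experiment rankings into a consensus order.

    With a single experiment, aggregation is skipped with an explicit notice.
    The JSON report is written atomically (temp file + rename) so a failed
    run leaves no partial report behind.
    """
    stab_config = StabilityConfig(
        m_high=config.thresholds.m_high,
        m_very_high=config.thresholds.m_very_high,
        v_cutoff=config.thresholds.v_cutoff,
    )
    per_experiment: dict[str, Any] = {}
    ranked_lists: list[RankedList] = []
    for spec in config.experiments:
        try:
            table = read_cq_table(spec.cq_table, layout=spec.layout)
            matrix = collapse_replicates(table, max_spread=spec.max_spread)
            matrix = matrix.drop(samples=spec.drop_samples, targets=spec.drop_targets)
            quantities = to_relative_quantities(matrix)
            result = analyze_stability(quantities, stab_config)
        except ValueError as exc:
            raise RuntimeError(
                f"stability stage failed for experiment {spec.experiment_id!r} "
                f"({spec.cq_table}): {exc}"
            ) from exc
        per_experiment[spec.experiment_id] = _stability_payload(result)
        ranked_lists.append(ranked_list_from_stability(spec.experiment_id, result))

    consensus: ConsensusRanking | None = None
    notice = None
    if len(ranked_lists) >= 2:
        agg = config.aggregation
        k = len(ranked_lists[0].ordering)
        if k <= EXHAUSTIVE_LIMIT and not agg.force_monte_carlo:
            consensus = aggregate_exhaustive(ranked_lists, agg.distance)
        else:
            consensus = aggregate_ce(
                ranked_lists, agg.distance, agg.ce_config(), agg.seed
            )
    else:
        notice = "single experiment: aggregation skipped"

    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "thresholds": {f: getattr(config.thresholds, f) for f in sorted(_THRESHOLD_KEYS)},
        "experiments": per_experiment,
        "aggregation": None
        if consensus is None
        else {
            "ordering": list(consensus.ordering),
            "objective": consensus.objective,
            "method": consensus.method,
            "distance": consensus.distance,
            "seed": consensus.seed,
            "mean_rank": consensus.mean_rank,
        },
        "notices": [notice] if notice else [],
    }
    validate_report(report)

    config.output_dir.mkdir(parents=True, exist_ok=True)
    out_path = config.output_dir / "report.json"
    fd, tmp = tempfile.mkstemp(dir=config.output_dir, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        os.replace(tmp, out_path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return report


_REPORT_REQUIRED: dict[str, type | tuple[type, ...]] = {
    "schema_version": str,
    "thresholds": dict,
    "experiments": dict,
    "notices": list,
}


def validate_report(report: Mapping[str, Any]) -> None:
    """Structural check of a run report against the shipped schema version."""
    problems = []
    for key, typ in _REPORT_REQUIRED.items():
        if key not in report:
            problems.append(f"missing key {key!r}")
        elif not isinstance(report[key], typ):
            problems.append(f"key {key!r} has wrong type")
    if report.get("schema_version") != REPORT_SCHEMA_VERSION:
        problems.append(
            f"schema_version {report.get('schema_version')!r} != {REPORT_SCHEMA_VERSION!r}"
        )
    for exp_id, payload in report.get("experiments", {}).items():
        for key in ("m_values", "ranked_targets", "v_series", "optimal_n", "classes"):
            if key not in payload:
                problems.append(f"experiment {exp_id!r} missing {key!r}")
    agg = report.get("aggregation")
    if agg is not None:
        for key in ("ordering", "objective", "method"):
            if key not in agg:
                problems.append(f"aggregation missing {key!r}")
    if problems:
        raise ConfigError(problems)
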