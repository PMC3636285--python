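"""End-to-end analysis orchestration and report serialisation.

:func:`run_full_analysis` binds the stages together — load or synthesise
inputs, price both strategies, compare them, sweep and scale the unit
costs, test the 2x2 tables exactly, and find the break-even patient
count — and returns a single report mapping.  The report holds unrounded
machine-readable numbers (except where rounding is part of the incremental
arithmetic itself); :func:`write_report` renders it as stable JSON or as
a text report mirroring the layout of published cost-effectiveness tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import yaml

from . import cea_engine, cost_model, effectiveness_stats, sensitivity, synthetic_cohort
from .cea_engine import Dominance, PrecisionSpec, REPORTING
from .synthetic_cohort import CohortConfig, HORIZON_1MO, HORIZONS

logger = logging.getLogger("neocea")

#: Published per-patient strategy costs of the bundled reference
#: evaluation (internet-based, hospital-based), euros; their internal
#: aggregation is external to the cost model, so they enter as an anchor.
REFERENCE_STRATEGY_COSTS = (86.1, 182.1)

#: Development cost of the reference web tool (1.5 person-months of a
#: programmer's salary, euros).
REFERENCE_DEVELOPMENT_COST = 7500.0

REPORT_REQUIRED_KEYS = (
    "seed",
    "inputs",
    "cost_breakdowns",
    "cea",
    "exact_tests",
    "one_way",
    "tornado",
    "scenarios",
    "break_even",
)


class PipelineError(RuntimeError):
    """A stage rejected its input; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything :func:`run_full_analysis` needs.

    Exactly one of ``outcomes_path`` (observed per-arm counts) and
    ``cohort`` (synthetic cohort configuration) must be supplied.  File
    paths left as ``None`` fall back to the bundled reference scenario.
    ``strategy_costs`` optionally supplies published per-patient totals
    (intervention, comparator) used as the incremental-analysis anchor in
    place of the modelled totals.
    """

    cost_parameters_path: Optional[str] = None
    intervention_profile_path: Optional[str] = None
    control_profile_path: Optional[str] = None
    outcomes_path: Optional[str] = None
    cohort: Optional[CohortConfig] = None
    cohort_mode: str = "fixture"
    scenario_factors: tuple[float, ...] = (1.75, 0.4375)
    precision: PrecisionSpec = REPORTING
    strategy_costs: Optional[tuple[float, float]] = None
    development_cost: float = REFERENCE_DEVELOPMENT_COST
    horizon: str = HORIZON_1MO

    def __post_init__(self) -> None:
        if (self.outcomes_path is None) == (self.cohort is None):
            raise ValueError(
                "exactly one of outcomes_path and cohort must be supplied"
            )
        if any(f <= 0 for f in self.scenario_factors):
            raise ValueError("scenario factors must all be > 0")
        if self.cohort_mode not in ("fixture", "sampling"):
            raise ValueError(f"unknown cohort mode {self.cohort_mode!r}")
        if self.horizon not in HORIZONS:
            raise ValueError(f"unknown horizon {self.horizon!r}")
        if self.development_cost < 0:
            raise ValueError("development cost must be >= 0")


def reference_analysis_config(seed: int = 0) -> AnalysisConfig:
    """The bundled reference scenario: fixture-mode cohort at the study
    sample sizes, published strategy costs as anchor, scenario factors
    1.75 and 0.4375."""
    return AnalysisConfig(
        cohort=CohortConfig(seed=seed),
        cohort_mode="fixture",
        strategy_costs=REFERENCE_STRATEGY_COSTS,
    )


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML or JSON document whose
    keys are the config field names (``cohort`` as a nested mapping of
    :class:`CohortConfig` fields, ``precision`` likewise)."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)  # JSON is a YAML subset
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping")
    if "cohort" in data and data["cohort"] is not None:
        data["cohort"] = CohortConfig(**data["cohort"])
    if "precision" in data and data["precision"] is not None:
        data["precision"] = PrecisionSpec(**data["precision"])
    if "scenario_factors" in data:
        data["scenario_factors"] = tuple(data["scenario_factors"])
    if "strategy_costs" in data and data["strategy_costs"] is not None:
        data["strategy_costs"] = tuple(data["strategy_costs"])
    try:
        return AnalysisConfig(**data)
    except TypeError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, exc) from exc


def _breakdown_dict(breakdown: cost_model.CostBreakdown) -> dict[str, Any]:
    return {
        "strategy_name": breakdown.strategy_name,
        "components": [
            {"name": c.name, "category": c.category, "amount": c.amount}
            for c in breakdown.components
        ],
        "total": breakdown.total,
    }


def _cea_dict(result: cea_engine.CEAResult) -> dict[str, Any]:
    data = dataclasses.asdict(result)
    data["dominance"] = result.dominance.value
    return data


def run_full_analysis(config: AnalysisConfig) -> dict[str, Any]:
    """Run every stage and return the complete report mapping.

    Any stage failure propagates as :class:`PipelineError` naming the
    stage; no partial report is ever returned.
    """
    inputs: dict[str, Any] = {}

    # --- unit costs
    if config.cost_parameters_path is not None:
        params = _stage(
            "cost_parameters", cost_model.load_cost_parameters, config.cost_parameters_path
        )
        inputs["cost_parameters"] = _digest(config.cost_parameters_path)
    else:
        params = cost_model.default_cost_parameters()
        inputs["cost_parameters"] = "default"
    logger.info("stage cost_parameters: %d parameters (%s)", len(params),
                inputs["cost_parameters"])

    # --- resource profiles
    if config.intervention_profile_path is not None:
        profile_if = _stage(
            "intervention_profile",
            cost_model.load_resource_profile,
            config.intervention_profile_path,
        )
        inputs["intervention_profile"] = _digest(config.intervention_profile_path)
    else:
        profile_if = cost_model.default_intervention_profile()
        inputs["intervention_profile"] = "default"
    if config.control_profile_path is not None:
        profile_hf = _stage(
            "control_profile",
            cost_model.load_resource_profile,
            config.control_profile_path,
        )
        inputs["control_profile"] = _digest(config.control_profile_path)
    else:
        profile_hf = cost_model.default_control_profile()
        inputs["control_profile"] = "default"

    # --- outcomes
    seed = None
    if config.outcomes_path is not None:
        tables = _stage("outcomes", effectiveness_stats.load_outcomes, config.outcomes_path)
        inputs["outcomes"] = _digest(config.outcomes_path)
    else:
        assert config.cohort is not None
        seed = config.cohort.seed
        cohort = _stage(
            "synthetic_cohort",
            synthetic_cohort.generate_cohort,
            config.cohort,
            config.cohort_mode,
        )
        tables = {
            horizon: _stage(
                "aggregate_outcomes", synthetic_cohort.aggregate_outcomes, cohort, horizon
            )
            for horizon in HORIZONS
        }
        inputs["outcomes"] = f"synthetic/{config.cohort_mode}/seed={seed}"
    logger.info("stage outcomes: %s (seed=%s)", inputs["outcomes"], seed)
    if config.horizon not in tables:
        raise PipelineError(
            "outcomes", ValueError(f"horizon {config.horizon!r} absent from outcomes")
        )
    main_table = tables[config.horizon]

    # --- per-strategy expected costs
    breakdown_if = _stage(
        "cost_model", cost_model.expected_cost_per_patient, profile_if, params
    )
    breakdown_hf = _stage(
        "cost_model", cost_model.expected_cost_per_patient, profile_hf, params
    )

    # --- incremental analysis
    if config.strategy_costs is not None:
        c_if, c_hf = config.strategy_costs
        anchor = config.strategy_costs
        cost_source = "supplied"
    else:
        c_if, c_hf = breakdown_if.total, breakdown_hf.total
        anchor = None
        cost_source = "model"
    e_if = effectiveness_stats.effectiveness(main_table.c, main_table.n_intervention)
    e_hf = effectiveness_stats.effectiveness(main_table.a, main_table.n_control)
    cea = _stage(
        "cea_engine", cea_engine.compute_icer, c_if, c_hf, e_if, e_hf, config.precision
    )
    logger.info("stage cea_engine: dC=%.4g dE=%.4g icer=%s dominance=%s",
                cea.delta_cost, cea.delta_effect, cea.icer, cea.dominance.value)

    # --- deterministic sensitivity
    one_way = _stage(
        "one_way_sweep",
        sensitivity.one_way_sweep,
        params, profile_if, profile_hf, main_table, config.precision, anchor,
    )
    tornado = sensitivity.tornado_order(one_way)
    scenarios = [
        _stage(
            "scenario_analysis",
            sensitivity.scenario_analysis,
            params, factor, profile_if, profile_hf, main_table,
            config.precision, anchor,
        )
        for factor in config.scenario_factors
    ]

    # --- exact tests
    exact_tests = {
        horizon: {
            "table": [t.a, t.b, t.c, t.d],
            "control_rate": effectiveness_stats.ed_visit_rate(t.a, t.n_control),
            "intervention_rate": effectiveness_stats.ed_visit_rate(t.c, t.n_intervention),
            "risk_difference": effectiveness_stats.risk_difference(t),
            "p_value": _stage("fisher_exact", effectiveness_stats.fisher_exact_two_sided, t),
        }
        for horizon, t in tables.items()
    }

    # --- break-even
    savings = -cea.delta_cost
    if savings > 0:
        break_even: Optional[dict[str, Any]] = {
            "development_cost": config.development_cost,
            "savings_per_patient": savings,
            "patients": _stage(
                "break_even",
                cea_engine.break_even_patients,
                config.development_cost,
                savings,
            ),
        }
    else:
        break_even = None

    return {
        "seed": seed,
        "inputs": inputs,
        "horizon": config.horizon,
        "cost_breakdowns": {
            "intervention": _breakdown_dict(breakdown_if),
            "control": _breakdown_dict(breakdown_hf),
        },
        "cea": {**_cea_dict(cea), "cost_source": cost_source},
        "exact_tests": exact_tests,
        "one_way": [dataclasses.asdict(r) for r in one_way],
        "tornado": [r.parameter_name for r in tornado],
        "scenarios": [
            {
                "scale_factor": s.scale_factor,
                "scaled_parameters": {name: cost for name, cost in s.scaled_parameters},
                "cost_if": s.cost_if,
                "cost_hf": s.cost_hf,
                "icer": s.icer,
                "cea": _cea_dict(s.cea),
            }
            for s in scenarios
        ],
        "break_even": break_even,
    }


# ---------------------------------------------------------------------------
# Serialisation


def _validate_report(report: dict[str, Any]) -> None:
    missing = [key for key in REPORT_REQUIRED_KEYS if key not in report]
    if missing:
        raise ValueError(f"incomplete report: missing block(s) {missing}")


def _text_report(report: dict[str, Any]) -> str:
    cea = report["cea"]
    lines = []
    lines.append("Cost-effectiveness analysis")
    lines.append("=" * 60)
    lines.append(
        f"{'Strategy':<24}{'Cost':>8}{'Incr.cost':>11}{'Eff.':>8}{'Incr.eff.':>11}{'ICER':>10}"
    )
    icer = "" if cea["icer"] is None else f"{cea['icer']:.1f}"
    lines.append(
        f"{'Internet-based':<24}{cea['c_if']:>7.1f}€{-cea['delta_cost']:>10.1f}€"
        f"{cea['e_if']:>8.3f}{-cea['delta_effect']:>11.3f}{icer:>9}€"
    )
    lines.append(f"{'Hospital-based':<24}{cea['c_hf']:>7.1f}€{'':>11}{cea['e_hf']:>8.3f}")
    verdict = cea["dominance"].replace("_", " ")
    if cea["dominance"] == Dominance.INTERVENTION_DOMINANT.value:
        verdict = "intervention dominant (less costly, more effective)"
    lines.append(f"Verdict: {verdict}")
    lines.append("")
    lines.append("Exact tests (ED visits)")
    for horizon, test in report["exact_tests"].items():
        lines.append(
            f"  {horizon}: {100 * test['control_rate']:.1f}% vs "
            f"{100 * test['intervention_rate']:.1f}%  P={test['p_value']:.3f}"
        )
    lines.append("")
    lines.append("Scenario analysis (uniform cost scaling)")
    lines.append(f"{'factor':>8}{'cost_if':>10}{'cost_hf':>10}{'ICER':>11}")
    for s in report["scenarios"]:
        icer = "" if s["icer"] is None else f"{s['icer']:.1f}"
        lines.append(
            f"{s['scale_factor']:>8.4g}{s['cost_if']:>9.1f}€{s['cost_hf']:>9.1f}€{icer:>10}€"
        )
    lines.append("")
    lines.append("Tornado order (widest ICER span first)")
    widths = {r["parameter_name"]: r["width"] for r in report["one_way"]}
    for name in report["tornado"]:
        lines.append(f"  {name:<24} width {widths[name]:.1f}€")
    if report["break_even"] is not None:
        be = report["break_even"]
        lines.append("")
        lines.append(
            f"Break-even: {be['patients']} patients "
            f"({be['development_cost']:.0f}€ development / "
            f"{be['savings_per_patient']:.1f}€ saved per patient)"
        )
    return "\n".join(lines) + "\n"


def write_report(report: dict[str, Any], format: str = "json") -> str:
    """Serialise a complete report as stable JSON (lossless, sorted keys)
    or as a text table with reporting-precision rounding."""
    _validate_report(report)
    if format == "json":
        return json.dumps(report, indent=2, sort_keys=True) + "\n"
    if format == "text":
        return _text_report(report)
    raise ValueError(f"unknown report format {format!r}")


def read_report(text: str) -> dict[str, Any]:
    """Parse a JSON report back into the report mapping."""
    report = json.loads(text)
    _validate_report(report)
    return report
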