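"""Deterministic sensitivity analysis: one-way sweeps, tornado ordering,
and uniform-scaling cost scenarios.

One-way analysis moves a single unit cost to the ends of its plausible
range (base x (1 - f) .. base x (1 + f), f the parameter's range
fraction) while holding everything else at base, recomputes both
strategies' per-patient costs and the ICER, and records the induced ICER
span.  Scenario analysis rescales *all* unit costs by one factor.

Both operations can be anchored at published per-patient strategy totals
whose internal aggregation is not part of the cost model.  Because every
modelled cost is linear in the unit costs, a one-way perturbation shifts
an anchored total by exactly the modelled component delta, and a uniform
scaling multiplies any total (modelled or published) by the factor; the
anchored results are therefore exact, not approximations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .cea_engine import CEAResult, PrecisionSpec, REPORTING, compute_icer
from .cost_model import (
    CostParameter,
    ResourceProfile,
    expected_cost_per_patient,
    scale_parameters,
)
from .effectiveness_stats import TwoByTwoTable, effectiveness


@dataclass(frozen=True)
class OneWayResult:
    """ICER at the low and high end of one parameter's plausible range."""

    parameter_name: str
    low_value: float
    high_value: float
    icer_at_low: float
    icer_at_high: float
    width: float
    clamped_low: bool = False  # True when base x (1 - f) fell below 0

    def __post_init__(self) -> None:
        if self.width < 0:
            raise ValueError("width must be non-negative")


@dataclass(frozen=True)
class ScenarioResult:
    """Costs and ICER after scaling every unit cost by one factor."""

    scale_factor: float
    scaled_parameters: tuple[tuple[str, float], ...]
    cost_if: float
    cost_hf: float
    icer: Optional[float]
    cea: CEAResult


def _arm_effectiveness(outcomes: TwoByTwoTable) -> tuple[float, float]:
    e_if = effectiveness(outcomes.c, outcomes.n_intervention)
    e_hf = effectiveness(outcomes.a, outcomes.n_control)
    return e_if, e_hf


def one_way_sweep(
    params: Sequence[CostParameter],
    intervention_profile: ResourceProfile,
    control_profile: ResourceProfile,
    outcomes: TwoByTwoTable,
    precision: PrecisionSpec = REPORTING,
    anchor_costs: Optional[tuple[float, float]] = None,
) -> tuple[OneWayResult, ...]:
    """One :class:`OneWayResult` per parameter, others held at base.

    ``anchor_costs`` optionally supplies published per-patient totals
    ``(cost_if, cost_hf)`` to perturb instead of the modelled totals;
    each end's cost is then anchor + (modelled component delta), which is
    exact because the cost model is linear in every unit cost.  A low end
    that would fall below zero is clamped at 0 and flagged.
    """
    e_if, e_hf = _arm_effectiveness(outcomes)
    base_if = expected_cost_per_patient(intervention_profile, params).total
    base_hf = expected_cost_per_patient(control_profile, params).total

    def costs_with(modified: Sequence[CostParameter]) -> tuple[float, float]:
        c_if = expected_cost_per_patient(intervention_profile, modified).total
        c_hf = expected_cost_per_patient(control_profile, modified).total
        if anchor_costs is not None:
            c_if = anchor_costs[0] + (c_if - base_if)
            c_hf = anchor_costs[1] + (c_hf - base_hf)
        return c_if, c_hf

    results = []
    for i, param in enumerate(params):
        low = param.unit_cost * (1.0 - param.range_fraction)
        clamped = low < 0
        if clamped:
            low = 0.0
        high = param.unit_cost * (1.0 + param.range_fraction)
        icers = []
        for value in (low, high):
            modified = list(params)
            modified[i] = replace(param, unit_cost=value)
            c_if, c_hf = costs_with(modified)
            result = compute_icer(c_if, c_hf, e_if, e_hf, precision)
            if result.icer is None:
                raise ValueError(
                    "one-way sweep needs a non-zero effectiveness difference"
                )
            icers.append(result.icer)
        results.append(
            OneWayResult(
                parameter_name=param.name,
                low_value=low,
                high_value=high,
                icer_at_low=icers[0],
                icer_at_high=icers[1],
                width=abs(icers[1] - icers[0]),
                clamped_low=clamped,
            )
        )
    return tuple(results)


def tornado_order(results: Iterable[OneWayResult]) -> tuple[OneWayResult, ...]:
    """Sort one-way results by decreasing ICER span (ties broken by
    parameter name ascending), the ordering of a tornado diagram."""
    return tuple(
        sorted(results, key=lambda r: (-r.width, r.parameter_name))
    )


def scenario_analysis(
    params: Sequence[CostParameter],
    scale_factor: float,
    intervention_profile: ResourceProfile,
    control_profile: ResourceProfile,
    outcomes: TwoByTwoTable,
    precision: PrecisionSpec = REPORTING,
    anchor_costs: Optional[tuple[float, float]] = None,
) -> ScenarioResult:
    """Rescale every unit cost by ``scale_factor`` and recompute the
    comparison.  Under an anchor the per-patient totals scale by the
    factor directly (every cost is degree-1 homogeneous in unit costs)."""
    if not (math.isfinite(scale_factor) and scale_factor > 0):
        raise ValueError(f"scale factor must be > 0, got {scale_factor!r}")
    scaled = scale_parameters(params, scale_factor)
    if anchor_costs is not None:
        c_if = anchor_costs[0] * scale_factor
        c_hf = anchor_costs[1] * scale_factor
    else:
        c_if = expected_cost_per_patient(intervention_profile, scaled).total
        c_hf = expected_cost_per_patient(control_profile, scaled).total
    e_if, e_hf = _arm_effectiveness(outcomes)
    cea = compute_icer(c_if, c_hf, e_if, e_hf, precision)
    return ScenarioResult(
        scale_factor=scale_factor,
        scaled_parameters=tuple((p.name, p.unit_cost) for p in scaled),
        cost_if=cea.c_if,
        cost_hf=cea.c_hf,
        icer=cea.icer,
        cea=cea,
    )


def write_one_way_csv(results: Sequence[OneWayResult], path: str | Path) -> None:
    """Write one-way results with header
    ``parameter,low,high,icer_low,icer_high,width``."""
    pd.DataFrame(
        [
            (r.parameter_name, r.low_value, r.high_value, r.icer_at_low,
             r.icer_at_high, r.width)
            for r in results
        ],
        columns=["parameter", "low", "high", "icer_low", "icer_high", "width"],
    ).to_csv(path, index=False)


def write_scenario_csv(results: Sequence[ScenarioResult], path: str | Path) -> None:
    """Write scenario results with header ``factor,cost_if,cost_hf,icer``."""
    pd.DataFrame(
        [(r.scale_factor, r.cost_if, r.cost_hf, r.icer) for r in results],
        columns=["factor", "cost_if", "cost_hf", "icer"],
    ).to_csv(path, index=False)
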