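"""Unit costs and expected per-patient cost of a follow-up strategy.

A follow-up strategy is priced from a small table of unit costs (what one
emergency-department visit, one scheduled hospital visit, one nurse-hour,
one round trip to the hospital, or one missed work hour costs) combined
with a resource-use profile saying how much of each resource an average
patient in that strategy consumes.  Costs are taken from a societal
perspective: direct health costs (visits, nursing time), direct non-health
costs (family transport) and indirect costs (parents' missed work time).

The expected per-patient cost is linear in every unit cost, and the
breakdown is reported per unit-cost parameter so that one-way sensitivity
analysis can perturb a single price and read off the exact change.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

#: Allowed cost categories (societal perspective).
CATEGORIES = ("direct_health", "direct_nonhealth", "indirect")

# Canonical parameter names referenced by the default component formulas.
ED_VISIT = "ed_visit"
HOSPITAL_VISIT = "hospital_visit"
NURSE_HOURLY_SALARY = "nurse_hourly_salary"
TRANSPORT = "transport"
MISSED_WORK_HOUR = "missed_work_hour"

#: Names that :func:`expected_cost_per_patient` requires to be present.
REQUIRED_PARAMETERS = (
    ED_VISIT,
    HOSPITAL_VISIT,
    NURSE_HOURLY_SALARY,
    TRANSPORT,
    MISSED_WORK_HOUR,
)

#: Columns of the cost-parameter CSV interchange format.
COST_CSV_COLUMNS = ("name", "category", "unit_cost", "unit", "range_fraction", "source")


@dataclass(frozen=True)
class CostParameter:
    """One unit cost with its category and deterministic sensitivity range.

    ``range_fraction`` is the half-width of the plausible range as a
    fraction of the base value (0.75 means the one-way sweep explores
    base x 0.25 .. base x 1.75).
    """

    name: str
    category: str
    unit_cost: float
    unit: str = ""
    range_fraction: float = 0.75
    source: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("cost parameter needs a non-empty name")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"parameter {self.name!r}: category {self.category!r} "
                f"not one of {CATEGORIES}"
            )
        if not (math.isfinite(self.unit_cost) and self.unit_cost >= 0):
            raise ValueError(
                f"parameter {self.name!r}: unit_cost must be >= 0, "
                f"got {self.unit_cost!r}"
            )
        if not (math.isfinite(self.range_fraction) and self.range_fraction >= 0):
            raise ValueError(
                f"parameter {self.name!r}: range_fraction must be >= 0, "
                f"got {self.range_fraction!r}"
            )


@dataclass(frozen=True)
class ResourceProfile:
    """Expected resource quantities per patient for one follow-up strategy.

    Probabilities are per-patient probabilities of consuming the resource
    at least once; times are in minutes (nursing) or hours (missed work).
    """

    strategy_name: str
    hospital_visit_prob: float
    ed_visit_prob: float
    nurse_training_minutes: float = 0.0
    nurse_monitoring_minutes_per_day: float = 0.0
    monitoring_days: float = 0.0
    transport_trips_per_hospital_visit: float = 1.0
    transport_trips_per_ed_visit: float = 1.0
    missed_hours_per_ambulatory_visit: float = 3.0
    missed_hours_per_ed_visit: float = 5.0

    def __post_init__(self) -> None:
        for prob_field in ("hospital_visit_prob", "ed_visit_prob"):
            value = getattr(self, prob_field)
            if not (0.0 <= value <= 1.0):
                raise ValueError(
                    f"profile {self.strategy_name!r}: {prob_field} must be a "
                    f"probability in [0, 1], got {value!r}"
                )
        for qty_field in (
            "nurse_training_minutes",
            "nurse_monitoring_minutes_per_day",
            "monitoring_days",
            "transport_trips_per_hospital_visit",
            "transport_trips_per_ed_visit",
            "missed_hours_per_ambulatory_visit",
            "missed_hours_per_ed_visit",
        ):
            value = getattr(self, qty_field)
            if not (math.isfinite(value) and value >= 0):
                raise ValueError(
                    f"profile {self.strategy_name!r}: {qty_field} must be >= 0, "
                    f"got {value!r}"
                )

    @property
    def nurse_hours(self) -> float:
        """Total expected nursing time per patient, in hours."""
        return (
            self.nurse_training_minutes
            + self.nurse_monitoring_minutes_per_day * self.monitoring_days
        ) / 60.0


class CostComponent(NamedTuple):
    """Expected cost attributable to one unit-cost parameter."""

    name: str
    category: str
    amount: float


@dataclass(frozen=True)
class CostBreakdown:
    """Per-patient expected cost of one strategy, itemised per unit cost."""

    strategy_name: str
    components: tuple[CostComponent, ...]
    total: float

    def __post_init__(self) -> None:
        if abs(self.total - math.fsum(c.amount for c in self.components)) > 1e-9:
            raise ValueError(
                f"breakdown for {self.strategy_name!r}: total does not equal "
                "the sum of its components"
            )

    def component(self, name: str) -> CostComponent:
        for comp in self.components:
            if comp.name == name:
                return comp
        raise KeyError(name)


def default_cost_parameters() -> tuple[CostParameter, ...]:
    """Unit costs of the bundled reference scenario (a public hospital in
    Barcelona; euros, 2011 price level; plausible range +/-75%)."""
    return (
        CostParameter(ED_VISIT, "direct_health", 127.2, "per visit", 0.75, "hospital"),
        CostParameter(HOSPITAL_VISIT, "direct_health", 85.4, "per visit", 0.75, "hospital"),
        CostParameter(NURSE_HOURLY_SALARY, "direct_health", 33.0, "per hour", 0.75, "hospital"),
        CostParameter(TRANSPORT, "direct_nonhealth", 30.0, "per round trip", 0.75, "assumption"),
        CostParameter(MISSED_WORK_HOUR, "indirect", 15.0, "per hour", 0.75, "assumption"),
    )


def default_control_profile() -> ResourceProfile:
    """Hospital-based follow-up: every family attends one scheduled visit
    (one accompanying parent, 3 missed work hours, one transport trip);
    emergency-department use at the reference control-arm rate."""
    return ResourceProfile(
        strategy_name="hospital_based",
        hospital_visit_prob=1.0,
        ed_visit_prob=18 / 114,
    )


def default_intervention_profile(monitoring_days: float = 30.0) -> ResourceProfile:
    """Internet-based follow-up: 10 minutes of family training plus 5
    minutes of nurse web-monitoring per baby per day; a scheduled hospital
    visit only when clinically required; reference intervention-arm rates.

    ``monitoring_days`` defaults to 30 (one-month horizon); the monitoring
    period in practice ends when the baby reaches an appropriate weight.
    """
    return ResourceProfile(
        strategy_name="internet_based",
        hospital_visit_prob=32 / 90,
        ed_visit_prob=5 / 90,
        nurse_training_minutes=10.0,
        nurse_monitoring_minutes_per_day=5.0,
        monitoring_days=monitoring_days,
    )


def expected_cost_per_patient(
    profile: ResourceProfile, params: Iterable[CostParameter]
) -> CostBreakdown:
    """Expected societal cost per patient under ``profile``.

    The breakdown is itemised per unit-cost parameter:

    * ``ed_visit``              = P(ED visit) x ED unit cost
    * ``hospital_visit``        = P(hospital visit) x visit unit cost
    * ``nurse_hourly_salary``   = nursing hours x hourly salary
    * ``transport``             = expected round trips x trip cost
    * ``missed_work_hour``      = expected missed hours x hourly wage

    so the total is linear in every unit cost, with the component amount
    as the exact coefficient-times-price contribution.
    """
    by_name: dict[str, CostParameter] = {}
    for param in params:
        if param.name in by_name:
            raise ValueError(f"duplicate cost parameter {param.name!r}")
        by_name[param.name] = param
    for required in REQUIRED_PARAMETERS:
        if required not in by_name:
            raise ValueError(
                f"cost parameter {required!r} is required by the cost model "
                "but missing from the parameter collection"
            )

    trips = (
        profile.hospital_visit_prob * profile.transport_trips_per_hospital_visit
        + profile.ed_visit_prob * profile.transport_trips_per_ed_visit
    )
    missed_hours = (
        profile.hospital_visit_prob * profile.missed_hours_per_ambulatory_visit
        + profile.ed_visit_prob * profile.missed_hours_per_ed_visit
    )
    quantities = {
        ED_VISIT: profile.ed_visit_prob,
        HOSPITAL_VISIT: profile.hospital_visit_prob,
        NURSE_HOURLY_SALARY: profile.nurse_hours,
        TRANSPORT: trips,
        MISSED_WORK_HOUR: missed_hours,
    }
    components = tuple(
        CostComponent(name, by_name[name].category, qty * by_name[name].unit_cost)
        for name, qty in quantities.items()
    )
    return CostBreakdown(
        strategy_name=profile.strategy_name,
        components=components,
        total=math.fsum(c.amount for c in components),
    )


def scale_parameters(
    params: Iterable[CostParameter], factor: float
) -> tuple[CostParameter, ...]:
    """Multiply every unit cost by ``factor`` (> 0), leaving all other
    fields untouched.  Used by uniform-scaling scenario analysis."""
    if not (math.isfinite(factor) and factor > 0):
        raise ValueError(f"scale factor must be > 0, got {factor!r}")
    return tuple(replace(p, unit_cost=p.unit_cost * factor) for p in params)


# ---------------------------------------------------------------------------
# Interchange formats


def load_cost_parameters(path: str | Path) -> tuple[CostParameter, ...]:
    """Read unit costs from a CSV file with header
    ``name,category,unit_cost,unit,range_fraction,source``.

    Rejects files with missing columns, duplicate names or invalid values,
    naming the offending row.
    """
    df = pd.read_csv(path)
    missing = [col for col in COST_CSV_COLUMNS if col not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    params: list[CostParameter] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        name = str(row["name"])
        if name in seen:
            raise ValueError(f"{path}: duplicate parameter name {name!r} (row {i})")
        seen.add(name)
        try:
            params.append(
                CostParameter(
                    name=name,
                    category=str(row["category"]),
                    unit_cost=float(row["unit_cost"]),
                    unit="" if pd.isna(row["unit"]) else str(row["unit"]),
                    range_fraction=float(row["range_fraction"]),
                    source="" if pd.isna(row["source"]) else str(row["source"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i} ({name!r}): {exc}") from exc
    return tuple(params)


def dump_cost_parameters(params: Sequence[CostParameter], path: str | Path) -> None:
    """Write unit costs to the CSV interchange format."""
    pd.DataFrame([p.__dict__ for p in params], columns=COST_CSV_COLUMNS).to_csv(
        path, index=False
    )


def load_resource_profile(path: str | Path) -> ResourceProfile:
    """Read a resource profile from a JSON object whose keys are the
    :class:`ResourceProfile` field names."""
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a JSON object")
    try:
        return ResourceProfile(**data)
    except TypeError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def dump_resource_profile(profile: ResourceProfile, path: str | Path) -> None:
    """Write a resource profile as a JSON object."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(profile.__dict__, fh, indent=2, sort_keys=True)
        fh.write("\n")
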