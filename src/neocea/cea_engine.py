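"""Incremental cost-effectiveness: ICER, dominance, break-even.

Two strategies are compared through the incremental cost-effectiveness
ratio ICER = (C_int - C_comp) / (E_int - E_comp), euros per additional
patient free of emergency-department visits.  A strategy is *dominant*
when it is strictly cheaper and strictly more effective; then the ICER is
negative and reads as the saving per additional visit-free patient.

Published cost-effectiveness tables round costs to 0.1 and proportions to
3 decimals before forming the ratio; :data:`REPORTING` reproduces that
arithmetic, :data:`EXACT` forms the ratio on unrounded inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Optional


class Dominance(str, Enum):
    """Quadrant of the cost-effectiveness plane occupied by (dC, dE)."""

    INTERVENTION_DOMINANT = "intervention_dominant"  # cheaper and better
    COMPARATOR_DOMINANT = "comparator_dominant"      # dearer and worse
    TRADEOFF_NE = "tradeoff_ne"                      # dearer, better
    TRADEOFF_SW = "tradeoff_sw"                      # cheaper, worse
    EQUIVALENT = "equivalent"


def round_half_away(value: float, decimals: int) -> float:
    """Round half away from zero (the convention of printed cost tables;
    Python's built-in round is banker's rounding)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PrecisionSpec:
    """How inputs are rounded before the incremental arithmetic.

    ``None`` in any slot means "do not round".  The default reproduces
    the arithmetic of published tables: costs to 0.1, effectiveness and
    its increment to 3 decimals, the ICER reported to 0.1.
    """

    cost_decimals: Optional[int] = 1
    effect_decimals: Optional[int] = 3
    delta_effect_decimals: Optional[int] = 3
    icer_decimals: Optional[int] = 1

    @classmethod
    def exact(cls) -> "PrecisionSpec":
        return cls(None, None, None, None)

    @staticmethod
    def apply(value: float, decimals: Optional[int]) -> float:
        return value if decimals is None else round_half_away(value, decimals)


REPORTING = PrecisionSpec()
EXACT = PrecisionSpec.exact()


@dataclass(frozen=True)
class CEAResult:
    """Per-arm costs and effectiveness with their increments.

    Increments follow the formula convention dC = c_if - c_hf,
    dE = e_if - e_hf (intervention minus comparator); ``icer`` is absent
    when dE = 0.
    """

    c_if: float
    c_hf: float
    e_if: float
    e_hf: float
    delta_cost: float
    delta_effect: float
    icer: Optional[float]
    dominance: Dominance

    def __post_init__(self) -> None:
        if abs(self.delta_cost - (self.c_if - self.c_hf)) > 1e-9:
            raise ValueError("delta_cost must equal c_if - c_hf")
        if abs(self.delta_effect - (self.e_if - self.e_hf)) > 1e-9:
            raise ValueError("delta_effect must equal e_if - e_hf")
        if (self.icer is None) != (self.delta_effect == 0):
            raise ValueError("icer must be present exactly when delta_effect != 0")


def classify_dominance(delta_cost: float, delta_effect: float) -> Dominance:
    """Quadrant classification with strict inequalities for dominance;
    boundary cases (one increment exactly zero) fall into the adjacent
    trade-off quadrant, and the origin is ``EQUIVALENT``."""
    if not (math.isfinite(delta_cost) and math.isfinite(delta_effect)):
        raise ValueError("increments must be finite")
    if delta_cost == 0 and delta_effect == 0:
        return Dominance.EQUIVALENT
    if delta_cost < 0 and delta_effect > 0:
        return Dominance.INTERVENTION_DOMINANT
    if delta_cost > 0 and delta_effect < 0:
        return Dominance.COMPARATOR_DOMINANT
    if delta_cost >= 0 and delta_effect >= 0:
        return Dominance.TRADEOFF_NE
    return Dominance.TRADEOFF_SW


def compute_icer(
    c_if: float,
    c_hf: float,
    e_if: float,
    e_hf: float,
    precision: PrecisionSpec = REPORTING,
) -> CEAResult:
    """Incremental comparison of the intervention (``_if``) against the
    comparator (``_hf``).

    Inputs are rounded per ``precision`` before the increments and the
    ratio are formed, so the default spec reproduces the arithmetic of a
    printed table exactly.  When the (rounded) effectiveness difference
    is zero the result carries no ICER and dominance is decided by the
    cost difference alone.
    """
    for label, cost in (("c_if", c_if), ("c_hf", c_hf)):
        if not (math.isfinite(cost) and cost >= 0):
            raise ValueError(f"{label} must be a finite cost >= 0, got {cost!r}")
    for label, eff in (("e_if", e_if), ("e_hf", e_hf)):
        if not (0.0 <= eff <= 1.0):
            raise ValueError(f"{label} must be a proportion in [0, 1], got {eff!r}")

    rc_if = PrecisionSpec.apply(c_if, precision.cost_decimals)
    rc_hf = PrecisionSpec.apply(c_hf, precision.cost_decimals)
    re_if = PrecisionSpec.apply(e_if, precision.effect_decimals)
    re_hf = PrecisionSpec.apply(e_hf, precision.effect_decimals)

    delta_cost = rc_if - rc_hf
    if precision.cost_decimals is not None:
        # re-quantise to kill float dust from the subtraction
        delta_cost = round_half_away(delta_cost, precision.cost_decimals)
    delta_effect = PrecisionSpec.apply(re_if - re_hf, precision.delta_effect_decimals)

    if delta_effect == 0:
        icer: Optional[float] = None
    else:
        icer = PrecisionSpec.apply(delta_cost / delta_effect, precision.icer_decimals)

    return CEAResult(
        c_if=rc_if,
        c_hf=rc_hf,
        e_if=re_if,
        e_hf=re_hf,
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=icer,
        dominance=classify_dominance(delta_cost, delta_effect),
    )


def break_even_patients(development_cost: float, savings_per_patient: float) -> int:
    """Smallest number of patients whose cumulative per-patient savings
    cover a fixed upfront development cost: ceil(cost / savings)."""
    if not (math.isfinite(development_cost) and development_cost >= 0):
        raise ValueError(f"development cost must be >= 0, got {development_cost!r}")
    if not (math.isfinite(savings_per_patient) and savings_per_patient > 0):
        raise ValueError(
            f"savings per patient must be > 0 (cost is never recovered "
            f"otherwise), got {savings_per_patient!r}"
        )
    n = math.ceil(development_cost / savings_per_patient)
    # guard against float dust pushing an exact ratio up one patient
    if n > 0 and (n - 1) * savings_per_patient >= development_cost:
        n -= 1
    return n
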