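"""Emergency-department visit rates and exact two-arm comparison.

Effectiveness of a follow-up strategy is the proportion of newborns in
that arm with no emergency-department (ED) visit within the time horizon.
Two arms are compared on a 2x2 table (visit / no visit by arm) with
Fisher's exact test, computed from first principles by enumerating the
hypergeometric distribution conditional on the table margins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Relative tolerance used when deciding whether an enumerated table is
#: "at most as probable" as the observed one (absorbs floating-point ties).
TIE_RELATIVE_TOL = 1e-7

#: Columns of the cohort-outcome CSV interchange format.
OUTCOME_CSV_COLUMNS = ("arm", "horizon", "events", "size")

ARMS = ("control", "intervention")


@dataclass(frozen=True)
class TwoByTwoTable:
    """ED-visit counts for two arms at one time horizon.

    ``a``/``b`` are control-arm patients with / without at least one ED
    visit; ``c``/``d`` the same for the intervention arm.  Row totals
    ``a + b`` and ``c + d`` are the arm sizes.
    """

    label: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in ("a", "b", "c", "d"):
            value = getattr(self, cell)
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise ValueError(f"cell {cell} must be an integer, got {value!r}")
            if value < 0:
                raise ValueError(f"cell {cell} must be non-negative, got {value}")

    @property
    def n_control(self) -> int:
        return self.a + self.b

    @property
    def n_intervention(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.n_control + self.n_intervention

    def swapped_arms(self) -> "TwoByTwoTable":
        return TwoByTwoTable(self.label, self.c, self.d, self.a, self.b)

    def swapped_outcomes(self) -> "TwoByTwoTable":
        return TwoByTwoTable(self.label, self.b, self.a, self.d, self.c)


def ed_visit_rate(arm_events: int, arm_size: int) -> float:
    """Proportion of an arm with at least one ED visit.

    The value is returned unrounded; the reporting layer rounds to one
    decimal of percent.
    """
    if arm_size <= 0:
        raise ValueError(f"arm size must be > 0, got {arm_size}")
    if not 0 <= arm_events <= arm_size:
        raise ValueError(
            f"events must lie in [0, arm size], got {arm_events}/{arm_size}"
        )
    return arm_events / arm_size


def effectiveness(arm_events: int, arm_size: int) -> float:
    """Proportion of an arm with *no* ED visit: 1 - ed_visit_rate."""
    return 1.0 - ed_visit_rate(arm_events, arm_size)


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_probabilities(table: TwoByTwoTable) -> tuple[int, np.ndarray]:
    """Conditional probabilities of every table sharing ``table``'s margins.

    Returns ``(lo, probs)`` where ``probs[k - lo]`` is the hypergeometric
    probability of the table with control-events cell equal to ``k``; the
    support runs over all feasible values of that cell.  Computed through
    log-factorials so large cohorts cannot overflow.
    """
    r1, r2 = table.n_control, table.n_intervention
    c1 = table.a + table.c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    log_probs = np.array(
        [
            _log_comb(r1, k) + _log_comb(r2, c1 - k) - _log_comb(n, c1)
            for k in range(lo, hi + 1)
        ]
    )
    return lo, np.exp(log_probs)


def fisher_exact_two_sided(table: TwoByTwoTable) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table.

    Conditional on the margins, the p-value is the total probability of
    every table whose hypergeometric probability is at most that of the
    observed table (up to relative tolerance :data:`TIE_RELATIVE_TOL`,
    which absorbs floating-point ties).  Degenerate margins (an empty row
    or column) admit a single table and give p = 1.
    """
    lo, probs = hypergeom_probabilities(table)
    p_observed = probs[table.a - lo]
    p_value = float(probs[probs <= p_observed * (1.0 + TIE_RELATIVE_TOL)].sum())
    return min(p_value, 1.0)


def risk_difference(table: TwoByTwoTable) -> float:
    """Incremental effectiveness: intervention minus control proportion
    with no ED visit.  Positive when the intervention arm avoids more
    visits."""
    if table.n_control == 0 or table.n_intervention == 0:
        raise ValueError("both arms must be non-empty")
    return effectiveness(table.c, table.n_intervention) - effectiveness(
        table.a, table.n_control
    )


def load_outcomes(path: str | Path) -> dict[str, TwoByTwoTable]:
    """Read per-arm outcome counts from a CSV file with header
    ``arm,horizon,events,size`` (one row per arm per horizon) and return
    one :class:`TwoByTwoTable` per horizon label."""
    df = pd.read_csv(path)
    missing = [col for col in OUTCOME_CSV_COLUMNS if col not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    tables: dict[str, TwoByTwoTable] = {}
    for horizon, group in df.groupby("horizon", sort=False):
        rows = {str(r["arm"]): r for _, r in group.iterrows()}
        unknown = set(rows) - set(ARMS)
        if unknown:
            raise ValueError(f"{path}: unknown arm label(s) {sorted(unknown)}")
        if set(rows) != set(ARMS):
            raise ValueError(
                f"{path}: horizon {horizon!r} needs one row per arm "
                f"{ARMS}, got {sorted(rows)}"
            )
        ctrl, itv = rows["control"], rows["intervention"]
        tables[str(horizon)] = TwoByTwoTable(
            label=str(horizon),
            a=int(ctrl["events"]),
            b=int(ctrl["size"]) - int(ctrl["events"]),
            c=int(itv["events"]),
            d=int(itv["size"]) - int(itv["events"]),
        )
    if not tables:
        raise ValueError(f"{path}: no outcome rows")
    return tables


def dump_outcomes(tables: dict[str, TwoByTwoTable], path: str | Path) -> None:
    """Write per-arm outcome counts to the CSV interchange format."""
    records = []
    for horizon, t in tables.items():
        records.append(("control", horizon, t.a, t.n_control))
        records.append(("intervention", horizon, t.c, t.n_intervention))
    pd.DataFrame(records, columns=OUTCOME_CSV_COLUMNS).to_csv(path, index=False)
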