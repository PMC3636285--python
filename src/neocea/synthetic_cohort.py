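"""Synthetic two-arm newborn cohorts with the study's statistical structure.

Each synthetic newborn carries an arm label, emergency-department visit
flags at two nested horizons (a visit in the first month implies one by
two months), an indicator for a scheduled hospital visit, web-service
usage counters (questionnaires answered, emails sent — intervention arm
only) and an optional 0-5 Likert satisfaction score from the subset of
parents who answer the final survey.

Two generation modes are provided:

* ``"sampling"`` — per-patient Bernoulli draws for the visit flags (the
  two-month flag adds the conditional increment (p2 - p1) / (1 - p1) on
  top of the one-month flag), Poisson usage counts, and satisfaction from
  a discretised normal on {0..5} moment-matched to the configured mean
  and spread.  Deterministic given the seed: one seed sequence feeds
  per-component substreams.
* ``"fixture"`` — event counts set deterministically to round(p x n), so
  a cohort at the reference sample sizes reproduces the reference counts
  exactly; usage counters and satisfaction scores are likewise laid out
  deterministically to match the configured totals.  Used to replay a
  published analysis end-to-end without sampling noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import norm

from .effectiveness_stats import TwoByTwoTable

HORIZON_1MO = "1 month"
HORIZON_2MO = "2 months"
HORIZONS = (HORIZON_1MO, HORIZON_2MO)

COHORT_CSV_COLUMNS = (
    "patient_id",
    "arm",
    "ed_visit_1mo",
    "ed_visit_2mo",
    "hospital_visit",
    "questionnaires_answered",
    "emails_sent",
    "satisfaction",
)

LIKERT_MAX = 5


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters of a two-arm cohort.

    Defaults reproduce the reference evaluation: 114 control newborns
    against 90 active intervention participants (of 116 enrolled), ED
    visit probabilities 18/114 vs 5/90 at one month and 29/114 vs 7/90 at
    two months, a 32/90 chance of a clinically required hospital visit in
    the intervention arm, 382/90 questionnaires and 1 email per monitored
    baby, and a 48% survey response rate with scores at 4.3 +/- 0.9.
    """

    n_control: int = 114
    n_intervention: int = 90
    n_enrolled_intervention: int = 116
    p_ed_1mo_control: float = 18 / 114
    p_ed_1mo_intervention: float = 5 / 90
    p_ed_2mo_control: float = 29 / 114
    p_ed_2mo_intervention: float = 7 / 90
    p_hospital_visit_intervention: float = 32 / 90
    mean_questionnaires: float = 382 / 90
    mean_emails: float = 1.0
    likert_mean: float = 4.3
    likert_sd: float = 0.9
    response_rate: float = 0.48
    seed: int = 0

    def __post_init__(self) -> None:
        for count_field in ("n_control", "n_intervention", "n_enrolled_intervention"):
            value = getattr(self, count_field)
            if not isinstance(value, (int, np.integer)) or value <= 0:
                raise ValueError(f"{count_field} must be a positive integer, got {value!r}")
        if self.n_enrolled_intervention < self.n_intervention:
            raise ValueError("n_enrolled_intervention must be >= n_intervention")
        for prob_field in (
            "p_ed_1mo_control",
            "p_ed_1mo_intervention",
            "p_ed_2mo_control",
            "p_ed_2mo_intervention",
            "p_hospital_visit_intervention",
            "response_rate",
        ):
            value = getattr(self, prob_field)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{prob_field} must lie in [0, 1], got {value!r}")
        if self.p_ed_2mo_control < self.p_ed_1mo_control:
            raise ValueError("control 2-month ED probability must be >= 1-month")
        if self.p_ed_2mo_intervention < self.p_ed_1mo_intervention:
            raise ValueError("intervention 2-month ED probability must be >= 1-month")
        for rate_field in ("mean_questionnaires", "mean_emails"):
            value = getattr(self, rate_field)
            if not (math.isfinite(value) and value >= 0):
                raise ValueError(f"{rate_field} must be >= 0, got {value!r}")
        if not (0.0 <= self.likert_mean <= LIKERT_MAX):
            raise ValueError(f"likert_mean must lie in [0, {LIKERT_MAX}]")
        if not (math.isfinite(self.likert_sd) and self.likert_sd >= 0):
            raise ValueError("likert_sd must be >= 0")

    @property
    def participation_rate(self) -> float:
        """Fraction of enrolled intervention families who participated
        actively to the end of monitoring."""
        return self.n_intervention / self.n_enrolled_intervention


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic newborn."""

    patient_id: str
    arm: str
    ed_visit_1mo: bool
    ed_visit_2mo: bool
    hospital_visit: bool
    questionnaires_answered: int
    emails_sent: int
    satisfaction: Optional[int] = None

    def __post_init__(self) -> None:
        if self.arm not in ("control", "intervention"):
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.ed_visit_1mo and not self.ed_visit_2mo:
            raise ValueError("an ED visit by 1 month implies one by 2 months")
        if self.arm == "control":
            if not self.hospital_visit:
                raise ValueError("control-arm patients always have the hospital visit")
            if self.questionnaires_answered or self.emails_sent:
                raise ValueError("web usage counters must be 0 in the control arm")
            if self.satisfaction is not None:
                raise ValueError("the satisfaction survey covers the intervention arm only")
        if self.questionnaires_answered < 0 or self.emails_sent < 0:
            raise ValueError("usage counters must be non-negative")
        if self.satisfaction is not None and not (0 <= self.satisfaction <= LIKERT_MAX):
            raise ValueError(f"satisfaction must lie in 0..{LIKERT_MAX}")


# ---------------------------------------------------------------------------
# Satisfaction score distribution


@lru_cache(maxsize=64)
def fit_likert_distribution(mean: float, sd: float) -> tuple[float, ...]:
    """Probabilities over scores {0..5} from a discretised normal whose
    latent (mu, sigma) are moment-matched so the discrete distribution
    hits the target mean and standard deviation.

    A latent normal is binned at half-integer cut points (tails clamped
    to 0 and 5) and (mu, log sigma) are fitted by least squares on the
    two moment residuals.  ``sd = 0`` degenerates to a point mass at the
    nearest score.
    """
    if not (0.0 <= mean <= LIKERT_MAX):
        raise ValueError(f"mean must lie in [0, {LIKERT_MAX}]")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    scores = np.arange(LIKERT_MAX + 1)
    if sd == 0:
        probs = np.zeros(LIKERT_MAX + 1)
        probs[int(round(mean))] = 1.0
        return tuple(probs)

    edges = scores[:-1] + 0.5  # internal cut points 0.5 .. 4.5

    def discretise(mu: float, sigma: float) -> np.ndarray:
        cdf = norm.cdf(edges, loc=mu, scale=sigma)
        return np.diff(np.concatenate(([0.0], cdf, [1.0])))

    def residuals(theta: np.ndarray) -> list[float]:
        probs = discretise(theta[0], math.exp(theta[1]))
        m = float(probs @ scores)
        v = float(probs @ (scores - m) ** 2)
        return [m - mean, math.sqrt(v) - sd]

    fit = least_squares(residuals, x0=[mean, math.log(max(sd, 0.1))], xtol=1e-14)
    return tuple(discretise(fit.x[0], math.exp(fit.x[1])))


def _likert_quantile_scores(probs: Sequence[float], n: int) -> np.ndarray:
    """Deterministic score layout: inverse CDF of ``probs`` evaluated at
    the n mid-quantiles (i + 0.5) / n.  Used by fixture mode."""
    cdf = np.cumsum(probs)
    quantiles = (np.arange(n) + 0.5) / n
    return np.searchsorted(cdf, quantiles, side="left").clip(0, LIKERT_MAX)


# ---------------------------------------------------------------------------
# Generation


def _even_split(total: int, n: int) -> np.ndarray:
    """Distribute ``total`` units over ``n`` patients as evenly as possible."""
    base, extra = divmod(total, n)
    counts = np.full(n, base, dtype=int)
    counts[:extra] += 1
    return counts


def _fixture_cohort(config: CohortConfig) -> tuple[PatientRecord, ...]:
    records: list[PatientRecord] = []
    # control arm: first k2 patients have the 2-month flag, the first k1
    # of those also the 1-month flag, so the nesting invariant holds.
    k1 = round(config.p_ed_1mo_control * config.n_control)
    k2 = round(config.p_ed_2mo_control * config.n_control)
    for i in range(config.n_control):
        records.append(
            PatientRecord(
                patient_id=f"C{i + 1:04d}",
                arm="control",
                ed_visit_1mo=i < k1,
                ed_visit_2mo=i < k2,
                hospital_visit=True,
                questionnaires_answered=0,
                emails_sent=0,
            )
        )
    n = config.n_intervention
    k1 = round(config.p_ed_1mo_intervention * n)
    k2 = round(config.p_ed_2mo_intervention * n)
    kh = round(config.p_hospital_visit_intervention * n)
    questionnaires = _even_split(round(config.mean_questionnaires * n), n)
    emails = _even_split(round(config.mean_emails * n), n)
    n_responders = round(config.response_rate * n)
    scores = _likert_quantile_scores(
        fit_likert_distribution(config.likert_mean, config.likert_sd), n_responders
    ) if n_responders else np.empty(0, dtype=int)
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"I{i + 1:04d}",
                arm="intervention",
                ed_visit_1mo=i < k1,
                ed_visit_2mo=i < k2,
                hospital_visit=i < kh,
                questionnaires_answered=int(questionnaires[i]),
                emails_sent=int(emails[i]),
                satisfaction=int(scores[i]) if i < n_responders else None,
            )
        )
    return tuple(records)


def _nested_flags(
    rng: np.random.Generator, n: int, p1: float, p2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli 1-month flags plus nested 2-month flags via the
    conditional increment (p2 - p1) / (1 - p1)."""
    flag1 = rng.random(n) < p1
    p_inc = 0.0 if p1 >= 1.0 else (p2 - p1) / (1.0 - p1)
    flag2 = flag1 | (rng.random(n) < p_inc)
    return flag1, flag2


def _sampled_cohort(config: CohortConfig) -> tuple[PatientRecord, ...]:
    streams = [
        np.random.default_rng(child)
        for child in np.random.SeedSequence(config.seed).spawn(4)
    ]
    rng_control, rng_intervention, rng_usage, rng_survey = streams

    records: list[PatientRecord] = []
    flag1, flag2 = _nested_flags(
        rng_control, config.n_control, config.p_ed_1mo_control, config.p_ed_2mo_control
    )
    for i in range(config.n_control):
        records.append(
            PatientRecord(
                patient_id=f"C{i + 1:04d}",
                arm="control",
                ed_visit_1mo=bool(flag1[i]),
                ed_visit_2mo=bool(flag2[i]),
                hospital_visit=True,
                questionnaires_answered=0,
                emails_sent=0,
            )
        )

    n = config.n_intervention
    flag1, flag2 = _nested_flags(
        rng_intervention, n, config.p_ed_1mo_intervention, config.p_ed_2mo_intervention
    )
    hospital = rng_intervention.random(n) < config.p_hospital_visit_intervention
    questionnaires = rng_usage.poisson(config.mean_questionnaires, n)
    emails = rng_usage.poisson(config.mean_emails, n)
    responders = rng_survey.random(n) < config.response_rate
    probs = fit_likert_distribution(config.likert_mean, config.likert_sd)
    scores = rng_survey.choice(LIKERT_MAX + 1, size=n, p=probs)
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"I{i + 1:04d}",
                arm="intervention",
                ed_visit_1mo=bool(flag1[i]),
                ed_visit_2mo=bool(flag2[i]),
                hospital_visit=bool(hospital[i]),
                questionnaires_answered=int(questionnaires[i]),
                emails_sent=int(emails[i]),
                satisfaction=int(scores[i]) if responders[i] else None,
            )
        )
    return tuple(records)


def generate_cohort(
    config: CohortConfig, mode: str = "sampling"
) -> tuple[PatientRecord, ...]:
    """Generate a synthetic cohort (deterministic given ``config.seed``).

    ``mode`` is ``"sampling"`` (seeded draws) or ``"fixture"`` (event
    counts fixed to round(p x n); replays a published analysis exactly).
    """
    if mode == "sampling":
        return _sampled_cohort(config)
    if mode == "fixture":
        return _fixture_cohort(config)
    raise ValueError(f"unknown generation mode {mode!r}")


# ---------------------------------------------------------------------------
# Aggregation


def aggregate_outcomes(
    cohort: Iterable[PatientRecord], horizon: str
) -> TwoByTwoTable:
    """Tally the cohort's ED-visit flags at ``horizon`` into a 2x2 table
    (control events / non-events, intervention events / non-events)."""
    if horizon not in HORIZONS:
        raise ValueError(f"unknown horizon {horizon!r}; expected one of {HORIZONS}")
    attr = "ed_visit_1mo" if horizon == HORIZON_1MO else "ed_visit_2mo"
    counts = {"control": [0, 0], "intervention": [0, 0]}
    for record in cohort:
        counts[record.arm][0 if getattr(record, attr) else 1] += 1
    (a, b), (c, d) = counts["control"], counts["intervention"]
    if a + b == 0 or c + d == 0:
        raise ValueError("both arms must be non-empty")
    return TwoByTwoTable(label=horizon, a=a, b=b, c=c, d=d)


def summarize_satisfaction(
    cohort: Iterable[PatientRecord],
) -> tuple[float, float, int]:
    """Mean, sample standard deviation (ddof=1) and count of the Likert
    scores over survey responders only."""
    scores = np.array(
        [r.satisfaction for r in cohort if r.satisfaction is not None], dtype=float
    )
    if scores.size == 0:
        raise ValueError("no survey responders in the cohort")
    sd = float(scores.std(ddof=1)) if scores.size > 1 else 0.0
    return float(scores.mean()), sd, int(scores.size)


# ---------------------------------------------------------------------------
# Interchange format


def write_cohort_csv(cohort: Sequence[PatientRecord], path: str | Path) -> None:
    """Write patient records to CSV (flags as 0/1, missing satisfaction
    as an empty field)."""
    frame = pd.DataFrame(
        [
            (
                r.patient_id,
                r.arm,
                int(r.ed_visit_1mo),
                int(r.ed_visit_2mo),
                int(r.hospital_visit),
                r.questionnaires_answered,
                r.emails_sent,
                r.satisfaction,
            )
            for r in cohort
        ],
        columns=COHORT_CSV_COLUMNS,
    )
    frame.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> tuple[PatientRecord, ...]:
    """Read patient records written by :func:`write_cohort_csv`."""
    df = pd.read_csv(path)
    missing = [col for col in COHORT_CSV_COLUMNS if col not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    records = []
    for _, row in df.iterrows():
        satisfaction = row["satisfaction"]
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                arm=str(row["arm"]),
                ed_visit_1mo=bool(row["ed_visit_1mo"]),
                ed_visit_2mo=bool(row["ed_visit_2mo"]),
                hospital_visit=bool(row["hospital_visit"]),
                questionnaires_answered=int(row["questionnaires_answered"]),
                emails_sent=int(row["emails_sent"]),
                satisfaction=None if pd.isna(satisfaction) else int(satisfaction),
            )
        )
    return tuple(records)
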