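# Methods

This note documents the models, conventions and design choices behind
`neocea`, in the order the pipeline runs.

## Cost model

A strategy's expected per-patient cost is assembled from five unit
costs — ED visit, hospital visit, nurse-hour, transport round trip,
missed work hour — and a resource-use profile. The breakdown is
itemised *per unit cost*:

| component | expected quantity × price |
|---|---|
| `ed_visit` | P(ED visit) × ED visit cost |
| `hospital_visit` | P(hospital visit) × visit cost |
| `nurse_hourly_salary` | (training min + monitoring min/day × days)/60 × hourly salary |
| `transport` | (P(hosp) × trips/hosp + P(ED) × trips/ED) × trip cost |
| `missed_work_hour` | (P(hosp) × 3 h + P(ED) × 5 h) × hourly wage |

so the total is exactly linear in every unit cost and the component
amount is the coefficient-times-price contribution — the property the
one-way sensitivity analysis relies on. Defaults: one accompanying
parent per visit, 3 missed hours for an ambulatory visit and 5 for an
ED visit, one transport round trip per visit, 10 minutes of family
training and 5 minutes of web monitoring per baby per day over a
30-day monitoring period (the real monitoring period ends when the baby
reaches an appropriate weight; its length is configurable). Currency is
euros throughout; the one-month horizon makes discounting moot; money
is kept at full float precision and rounded only when reported.

### Published totals as an anchor

The reference evaluation reports per-patient strategy totals of 86.1 €
(Internet-based) and 182.1 € (hospital-based) whose internal aggregation
is not fully specified by its published inputs; no configuration of this
cost model reproduces them exactly, and the package makes no attempt to
reverse-engineer them. Instead `run_full_analysis` accepts published
totals as a `strategy_costs` anchor:

* **one-way sweep** — a perturbed strategy cost is the anchor plus the
  modelled component delta. Because the model is linear in unit costs,
  this delta is exact, whatever the unobserved remainder of the anchor
  is, provided that remainder does not itself depend on the swept price.
* **scenario scaling** — every cost is degree-1 homogeneous in the unit
  costs, so scaling all of them by *f* multiplies any total (modelled or
  published) by *f* exactly; anchored scenario costs are *f* × anchor.

With the anchor in place the reference scenario's qualitative result is
reproduced exactly: dominance (negative ICER, positive effectiveness
gain) survives all ten one-way endpoints and both scenarios. Without an
anchor the sweep uses the modelled totals directly.

## Effectiveness and the exact test

Effectiveness is the proportion of an arm with no ED visit in the
horizon; incremental effectiveness is intervention minus control. Arms
are compared with a two-sided Fisher exact test computed from first
principles: conditional on the 2×2 margins, the probability of each
feasible table is hypergeometric, evaluated through log-factorials
(`lgamma`) so large cohorts cannot overflow; the p-value sums the
probabilities of all tables at most as probable as the observed one.
That "sum of smaller-or-equal probabilities" rule is the most common
two-sided convention (also scipy's); a relative tolerance of 1e-7 on
the ≤ comparison absorbs floating-point ties, and the implementation is
checked against an exact integer-arithmetic enumeration on every table
with grand total ≤ 40 and against scipy on random larger tables.
Degenerate margins (an empty row or column) admit one table and give
p = 1.

## Incremental analysis

Increments follow the formula convention ΔC = C_IF − C_HF,
ΔE = E_IF − E_HF (some published tables print these with flipped
signs; the text renderer mirrors that presentation, the engine does
not). Dominance uses strict inequalities: intervention-dominant iff
ΔC < 0 and ΔE > 0; boundary cases fall into the adjacent trade-off
quadrant and the origin is "equivalent". When ΔE = 0 no ICER is
reported.

**Rounding-before-ratio.** Published cost-effectiveness tables compute
the ICER from already-rounded columns. The default precision spec
reproduces that arithmetic — costs rounded to 0.1 €, effectiveness and
its increment to 3 decimals, ICER reported to 0.1 € — with half-away-
from-zero rounding (the convention of printed tables; Python's builtin
is banker's). On the reference inputs this yields −96.0/0.102 = −941.2 €.
An exact mode (no pre-rounding) is also provided; on unrounded cohort
proportions it gives −938.1 €. The difference is pure rounding
propagation, worth keeping visible.

**Break-even.** The development cost is recovered at the smallest *n*
with *n* × saving ≥ cost, i.e. the ceiling of the ratio (7,500/96.0 →
79), with a guard against float dust on exact ratios.

## Sensitivity analysis

One-way sweeps move a single unit cost to base × (1 ± range fraction)
— ±75% for every reference parameter — holding the rest at base, and
record the ICER at both ends; a low end below zero is clamped at 0 and
flagged. Tornado ordering sorts by descending ICER span with
alphabetical tie-breaks, so output order is deterministic. Scenario
analysis rescales all unit costs by one explicit factor; the reference
configuration runs 1.75 and 0.4375, the two factors consistent with the
published scenario columns (the "−75% scenario" column of the reference
evaluation equals base × 0.4375, not × 0.25; the factor is therefore
always explicit, never inferred). Resource quantities are never swept —
only prices, as in the reference analysis. Probabilistic sensitivity
analysis is out of scope.

## Synthetic cohorts

The generator emulates the reference study's per-patient structure: arm
label; ED-visit flags at one and two months with the one-month flag
nested in the two-month flag (sampling draws the 1-month flag at p₁ and
adds the conditional increment (p₂ − p₁)/(1 − p₁)); an intervention-arm
hospital-visit indicator; Poisson questionnaire/email counts
(intervention only — defaults 382/90 ≈ 4.24 questionnaires and 1 email
per baby; the source narrative also quotes "4.7 answers per patient",
inconsistent with its own totals, and the config default follows the
totals); and a 0–5 Likert satisfaction score for a 48% responder
subset, drawn from a discretised normal on {0..5} whose latent mean and
spread are moment-matched (least squares on the two moment residuals)
to the configured 4.3 ± 0.9 — the source gives no distributional form,
and the discretised normal is the simplest shape matching both moments
on a bounded support. All draws flow from one seed through spawned
per-component substreams, so cohorts are bit-reproducible.

Two modes:

* **sampling** — seeded Bernoulli/Poisson/categorical draws as above;
  used for parameter-recovery properties (at 10,000 per arm every
  configured rate is recovered within 2 percentage points).
* **fixture** — event counts are set deterministically to round(p × n)
  and laid out to respect the nesting invariant; usage totals and the
  responder count likewise, with satisfaction scores placed at the
  fitted distribution's mid-quantiles. At the reference sample sizes
  this replays the published counts (18/114, 5/90, 29/114, 7/90, 32/90,
  382, 90, 43) exactly, which is what the acceptance script and the
  reference analysis configuration use.

What the generator does **not** model: gestational age, birth weight or
the eligibility strata (they never enter the computation); seasonality
of ED visits; correlation between ED use and satisfaction or usage
intensity; attrition dynamics (participation enters only as the 90/116
ratio). Passing tests therefore demonstrate the pipeline's arithmetic
and its statistical calibration under idealised independence, not the
epidemiology of real cohorts.

## Orchestration and reporting

`run_full_analysis` wires the stages together; any stage failure
surfaces as a `PipelineError` naming the stage, and no partial report
is emitted. The JSON report is lossless and key-sorted (byte-identical
across runs at a fixed seed); rounding beyond what the incremental
arithmetic itself prescribes happens only in the text renderer, which
mirrors the layout of published cost-effectiveness tables. Input files
are logged with SHA-256 digests alongside the seed. Tornado/scenario
tables are data; plotting is deliberately left to the caller.

## Problem sizes

The test suite and acceptance script run at the reference cohort sizes
(114 + 90), with calibration properties at 10,000–20,000 patients per
arm and the exact-test oracle sweep over all 2×2 tables with total ≤ 40
(~136,000 tables); the whole suite completes in a few seconds on one
CPU.
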