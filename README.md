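# neocea

A two-arm decision-analytic cost-effectiveness pipeline for neonatal
post-discharge follow-up strategies, written for health economists and
clinical researchers evaluating telehealth alternatives to conventional
hospital-based care.

## The problem and the model

After a newborn leaves the maternity ward, some form of follow-up catches
feeding problems, jaundice and excessive weight loss before they become
emergency-department (ED) visits. The pipeline compares two strategies
for low-risk newborns over the first month of life:

* **Hospital-based follow-up** — every family attends a scheduled
  hospital visit within 48 hours of discharge.
* **Internet-based follow-up** — nurses monitor the baby remotely
  through periodic web questionnaires and email, with a hospital visit
  only when clinically required.

Costs are societal: direct health costs (ED and hospital visits, nursing
time), direct non-health costs (family transport) and indirect costs
(parents' missed work hours). Effectiveness is the proportion of
newborns with **no** ED visit within the horizon. The strategies are
compared through the incremental cost-effectiveness ratio

```
ICER = (C_IF − C_HF) / (E_IF − E_HF)
```

where `C`/`E` are per-patient cost and effectiveness of the
Internet-based (`IF`) and hospital-based (`HF`) strategies. A negative
ICER with a positive effectiveness gain means the Internet-based
strategy *dominates*: it is cheaper **and** better, and |ICER| is the
saving per additional visit-free newborn. Around this core the package
provides:

* a unit-cost table and per-patient expected-cost model, linear in every
  unit cost (`cost_model`);
* exact two-sided Fisher tests of the two arms' ED-visit rates,
  enumerated from first principles (`effectiveness_stats`);
* ICER, dominance classification and break-even patient count
  (`cea_engine`);
* one-way (tornado) and uniform-scaling scenario sensitivity analyses
  (`sensitivity`);
* a seeded synthetic-cohort generator with the study's statistical
  structure, so the whole pipeline is testable without any external data
  (`synthetic_cohort`);
* an orchestrated runner, JSON/text reports and a CLI (`io_reporting`,
  `neocea` command).

The bundled reference scenario describes an evaluation of an
Internet-based monitoring service at a public university hospital:
114 control newborns against 90 actively participating intervention
newborns (of 116 enrolled), unit costs in 2011 euros (ED visit 127.2,
hospital visit 85.4, nurse-hour 33.0, transport 30.0, missed work hour
15.0, each with a ±75% plausible range) and a 7,500 € one-off tool
development cost.

## Worked example

```
$ neocea cea --seed 0
Cost-effectiveness analysis
============================================================
Strategy                    Cost  Incr.cost    Eff.  Incr.eff.      ICER
Internet-based             86.1€      96.0€   0.944     -0.102   -941.2€
Hospital-based            182.1€              0.842
Verdict: intervention dominant (less costly, more effective)

Exact tests (ED visits)
  1 month: 15.8% vs 5.6%  P=0.026
  2 months: 25.4% vs 7.8%  P=0.001

Scenario analysis (uniform cost scaling)
  factor   cost_if   cost_hf       ICER
    1.75    150.7€    318.7€   -1647.1€
  0.4375     37.7€     79.7€    -411.8€

Tornado order (widest ICER span first)
  nurse_hourly_salary      width 1294.1€
  hospital_visit           width 808.8€
  missed_work_hour         width 539.2€
  transport                width 330.4€
  ed_visit                 width 192.2€

Break-even: 79 patients (7500€ development / 96.0€ saved per patient)
```

Reading the numbers: the Internet-based strategy costs 86.1 € per
patient against 182.1 € (a 96.0 € saving) and leaves 94.4% of newborns
ED-visit-free against 84.2%, so it dominates; society saves 941.2 € per
additional visit-free newborn. The 15.8% vs 5.6% one-month ED-visit
rates differ significantly (two-sided exact P = .026). Dominance
survives every ±75% one-way cost sweep (all tornado ICERs stay negative)
and uniform cost rescaling to 175% or 43.75% of base. The 7,500 €
development cost is recovered after 79 patients.

The same analysis is available programmatically:

```python
from neocea import reference_analysis_config, run_full_analysis

report = run_full_analysis(reference_analysis_config(seed=0))
print(report["cea"]["icer"])            # -941.2
print(report["break_even"]["patients"]) # 79
```

Other subcommands: `neocea rates 18 96 5 85` (2×2 rates + exact test),
`neocea simulate` (synthetic cohort CSV), `neocea tornado`,
`neocea scenario --factor 1.75`. Custom analyses take a YAML/JSON config
(`--config`) pointing at a cost-parameter CSV, two resource-profile JSON
files and an outcomes CSV — or an inline synthetic-cohort configuration.

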