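# preterm-cascade

A deterministic decision-tree cohort model of neonatal mortality among
preterm births in sub-Saharan Africa, for health-systems researchers and
modellers who want to rank intervention scale-up strategies by lives saved.

A single-year cohort of 3,988,000 preterm births is split across three
levels of care (home 50%, clinic 35%, hospital 15%) and six mutually
exclusive causes of death — respiratory distress syndrome (RDS),
intraventricular hemorrhage (IVH), necrotizing enterocolitis (NEC), sepsis,
birth asphyxia, and low birth weight alone. Care reaches each stratum
through a coverage cascade

```
diagnosis  = penetration × utilization × diagnostic accuracy
coverage_i = diagnosis × penetration_i × utilization_i      (gated treatment)
CFR_eff    = CFR_untreated × Π_i (1 − coverage_i × efficacy_i)
deaths     = Σ_strata  n_cases × CFR_eff
```

where *penetration* is availability at a setting, *utilization* is
appropriate use, and *efficacy* the relative mortality reduction when
received. Scenarios boost selected interventions and diagnostic gates to
**incremental** (+20 percentage points, capped at 98%) or **universal**
(98%) coverage, can enable transfer of diagnosed cases to hospital, and can
relocate deliveries altogether. A seeded individual-level microsimulation
re-expresses the same tree stochastically and serves as an independent
correctness oracle for the expected-value arithmetic.

The bundled parameter set (`src/preterm_cascade/data/baseline_ssa_2015.yaml`)
carries the published 2015 sub-Saharan-Africa estimates for every
prevalence, case-fatality rate and coverage value; the 30-entry scenario
library (`scenarios_ssa_2015.yaml`) maps the published scale-up scenarios
onto engine levers. See `docs/methods.md` for the model assumptions and for
which published figures do and do not reproduce from the printed tables.

## Worked example

```python
from preterm_cascade import (
    baseline_parameter_set, run_cohort, run_scenario,
    deaths_prevented, round_nearest_100,
)
from preterm_cascade.scenario_engine import scenario_by_id

p = baseline_parameter_set()
spec = scenario_by_id("t3s12")          # hospital delivery for all preterm births,
                                        # with ANCS and full RDS diagnosis/treatment
baseline = run_cohort(p, subconditions=spec.subcondition_filter)
result = run_scenario(spec, p)

saved, pct = deaths_prevented(baseline, result.universal)
print("baseline RDS+IVH+NEC deaths:", round_nearest_100(baseline.total_deaths))
print("universal-coverage deaths:  ", round_nearest_100(result.universal.total_deaths))
print(f"lives saved: {round_nearest_100(saved)} ({pct:.1f}%)")
```

prints

```
baseline RDS+IVH+NEC deaths: 302200
universal-coverage deaths:   113300
lives saved: 188900 (62.5%)
```

i.e. under current care the model attributes ≈302,200 deaths to the three
direct complications of prematurity; relocating all deliveries to hospital
with near-universal antenatal corticosteroids, RDS diagnosis, surfactant and
CPAP would avert ≈188,900 of them (62.5%).

The same run from the shell, including the full scenario tables and a
per-stratum audit trace:

```bash
preterm-cascade run --scenario t3s12 --trace --out results/
preterm-cascade run --all --out results/          # tables 3 and 4 as CSV/JSON
preterm-cascade oracle --scenario t3s12 -n 2000000 --seed 17
```

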