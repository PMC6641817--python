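# Methods

## The model

`preterm-cascade` is a nonstochastic decision-tree cohort model of neonatal
mortality among preterm births in sub-Saharan Africa in 2015. A cohort of
N = 3,988,000 preterm births is partitioned by setting of birth (home 50%,
clinic 35%, hospital 15%) and by exactly one of six mutually exclusive
subconditions whose prevalences sum to 100%:

| subcondition | prevalence | untreated CFR |
|---|---|---|
| respiratory distress syndrome (RDS) | 20% | 35% |
| intraventricular hemorrhage (IVH) | 7% | 7.5% |
| necrotizing enterocolitis (NEC) | 1% | 25% |
| sepsis | 9% | 40% |
| birth asphyxia | 20% | 20% |
| low birth weight only (LBW) | 43% | 2.1% |

Absent any care the model therefore predicts
Σ N × prevalence × CFR = 649,166.64 expected deaths; current-care coverage
reduces this through the cascade below. All case counts are expected values
(real numbers); the model contains no sampling and is bit-reproducible.

## Coverage cascade

Each diagnostic and intervention carries per-setting **penetration**
(availability) and **utilization** (appropriate use given availability);
interventions additionally carry per-target **efficacy** (relative reduction
in mortality when received, setting-independent), and diagnostics carry a
per-setting accuracy (symptom recognition at home performs worse than
clinical or technology-based diagnosis in facilities).

* diagnosis probability at a setting: `pen × util × accuracy`;
* receipt of a gated treatment: `diagnosed × pen × util`;
* receipt of universal newborn care (drying and stimulation, cord care,
  breastfeeding, kangaroo mother care): `pen × util`, no gate;
* effective CFR of a stratum:
  `CFR_untreated × Π_i (1 − coverage_i × efficacy_i)`.

The multiplicative-residual combination rule treats intervention receipts as
conditionally independent given the stratum, each marginally gated by its
diagnostic probability. This is the standard cohort-model convention, keeps
the CFR in [0, 1], and is deliberately mirrored by the stochastic
microsimulation (below), so engine/oracle agreement tests the arithmetic,
not the shared assumption. The per-stratum `--trace` output logs every
coverage so alternative rules can be diffed.

Gating map: antenatal corticosteroids (ANCS) are gated by recognition of
imminent preterm labor; surfactant, oxygen and CPAP by RDS diagnosis (for
their RDS efficacy); PPV, oxygen and CPAP by asphyxia recognition (for their
asphyxia efficacy); empirical antibiotics by sepsis diagnosis; warmers by
LBW identification. KMC applies only to the LBW-only stratum (it is
modelled as efficacious only in stable neonates without a critical
subcondition), as does the LBW efficacy of breastfeeding.

No published row exists for the asphyxia-recognition gate; the fixture
copies the RDS clinical-diagnosis row and flags this as an assumption.

## Antenatal timing

ANCS is received before delivery: its population coverage is the
antenatal-care location mix (home 30%, clinic 65%, hospital 5%) weighted
over `diagnosis × pen × util` per setting, applied uniformly to every birth
stratum. A switch (`antenatal_weighting`) allows weighting by the delivery
mix instead. When a scenario overrides the location mix ("hospital delivery
for all preterm birth"), both the delivery and antenatal mixes move: this
choice is forced by the published scenario-12 result, which is only
reproducible if the relocated births also receive hospital-level ANCS.

## Transfer

Baseline care includes no transfer: the source tables print no baseline
transfer probabilities, so diagnosed cases are assumed treated where they
present (documented in the fixture). Scenarios enable transfer per gate:
the diagnosed fraction `diag × rate` of a non-hospital stratum moves to the
destination (hospital), where the triggering gate counts as confirmed
(receipt of its treatments no longer re-rolls diagnosis) and all subsequent
care uses destination penetration/utilization. The remainder keeps the
conditional probability `diag(1−rate)/(1−diag×rate)` of having been
diagnosed. Interventions delivered at birth (drying and stimulation, cord
care) always use the setting of birth. Preterm-labor transfer acts
antenatally and re-settles the delivery itself — every subcondition of the
moved births — and the transferred mothers, being recognised in preterm
labor, receive ANCS at destination `pen × util`; non-transferred strata
keep the population-average antenatal coverage (a second-order
simplification). Transfer rates are not published, so transfer-enabled
scenarios use the same improvement level as coverage: 0.20 incremental,
0.98 universal.

## Scenario transforms

* **Incremental change**: penetration and utilization of each boosted
  profile/gate rise by +20 percentage points, capped at the 98% maximum
  attainable coverage. The additive reading is forced by the cord-care
  scenario, whose baseline coverage is zero yet whose incremental impact is
  nonzero in the published table; a `mode="relative"` switch preserves the
  ×1.2 alternative for sensitivity analysis.
* **Universal coverage**: penetration and utilization set to 98%.

Neither transform reduces coverage (baseline breastfeeding penetration is
99%, above the cap; transforms take the maximum of baseline and boosted
value), which preserves the invariant universal ≤ incremental ≤ baseline.
Transforms are pure functions; inapplicable settings (e.g. oxygen at home)
stay at zero. Scenario definitions are data
(`data/scenarios_ssa_2015.yaml`, schema in `data/scenario_library.schema.json`):
each of the 30 entries records which profiles, gates, transfers and location
overrides its published description implies. Two mapping choices warrant
note: treatment-only scenarios (surfactant, oxygen/CPAP, and the Table-4
single interventions) do not boost their diagnostic gates, because the
scenario ladder introduces "increased diagnosis" as a separate lever; the
ANCS scenario is the exception — corticosteroids cannot be scaled up without
recognising preterm labor, and the published lives-saved figure is only
approached when its gate rises with it.

## Reporting

Death counts are rounded to the nearest 100 (ties half-up) only at the
reporting layer; percent reductions are computed from unrounded totals and
printed to one decimal. The two scenario tables score disjoint cause
groups: RDS+IVH+NEC, and sepsis+asphyxia+LBW.

## Synthetic parameters and the microsimulation oracle

`random_parameter_set` draws valid parameter sets over the fixed model
structure: Dirichlet location mixes and prevalences (so strata always
partition the cohort), uniform coverage and efficacy values within
configurable sub-intervals of [0, 1] (defaults: penetration/utilization/
efficacy over the full interval, diagnostic accuracy over [0.2, 1], CFR over
[0.01, 0.6] — wide enough to exercise the arithmetic, bounded away from
degenerate corners). Inapplicable settings keep zero coverage.

`microsim_oracle` simulates individual neonates: categorical draws for birth
setting and subcondition, Bernoulli draws for diagnosis, transfer, each
intervention's receipt, and death at the product-residual CFR. It shares no
arithmetic with the deterministic engine and is the package's primary
correctness check: the engine's expected deaths must fall within 3
Monte-Carlo standard errors of the simulated count (tested at n = 2,000,000
for 10 random parameter sets × 3 scenarios, including transfer and
location-override paths). Because draws are seeded, common random numbers
across parameter variants give coupled, monotone comparisons at modest n.
The simulator emulates the model's own assumptions — one subcondition per
neonate, conditionally independent receipts — not the additional structure
of real data (co-morbidity, gestational-age heterogeneity, facility-level
clustering), so passing tests certify the cohort arithmetic, not clinical
realism.

## Reproduction of the published numbers, and known gaps

`scripts/acceptance.py` recomputes the headline published quantities from
the bundled tables. On the RDS/IVH/NEC side the cascade reproduces the
published figures closely: baseline 302,200 vs 303,400 printed (−0.4%), and
the all-hospital-delivery package saves 188,900 vs 190,600 printed (−0.9%).
The ANCS and oxygen/CPAP universal scenarios land within ~6–7% (5,300 vs
5,000; 45,400 vs 42,300).

The sepsis/asphyxia/LBW group is not recoverable from the printed
parameters. The printed current-care baseline (198,400) implies ~141,000
deaths averted from the untreated 339,100, but the printed coverage values
support only ~64,000 (this package computes 275,200). Birth asphyxia makes
the gap structural: even with perfect recognition in every setting, the
printed PPV/oxygen/CPAP penetration × utilization leaves ≥ ~137,000
asphyxia deaths, whereas the printed baseline implies ~95,000 — so the
published model must embed current-care parameters that its tables do not
print (most plausibly baseline transfer rates, whose footnote points to a
table without transfer numbers, and/or different asphyxia-recognition
coverage). The cord-care incremental result is similarly diagnostic: the
published universal/incremental savings ratio (~4.9) matches a transform of
a single coverage quantity, not the documented +20-points-each on
penetration and utilization (which yields 0.2² = 0.04 coverage from zero).
These comparisons are kept red in `tests/test_acceptance.py` rather than
tuned away; the per-stratum trace output localizes each gap.

## Limitations

No gestational-age stratification, no interaction between co-occurring
subconditions, no harm from over-treatment, and no uncertainty intervals:
the cohort model is a point-estimate decision tree, and uncertainty
exploration lives in the property-test randomization only. Results are a
single sub-Saharan-Africa aggregate; regional heterogeneity is out of
scope.
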