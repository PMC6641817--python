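# Baseline current-care parameterization, sub-Saharan Africa, 2015.
# All probability-valued entries are percentages (units: percent), matching
# the published parameter tables; the loader rescales them to proportions.
#
# Assumptions embedded here (see docs/methods.md for rationale):
#   * birth_asphyxia diagnostic gate: no published row exists; it copies the
#     RDS clinical-diagnosis row (asphyxia recognition is treated as the same
#     class of clinical assessment).
#   * transfer.rates is empty: no baseline transfer numbers are published, so
#     current care assumes diagnosed cases stay where they present; scenarios
#     enable transfer as an explicit lever.
#   * cord_care is a single profile covering chlorhexidine at home and dry
#     cord care in clinics; it is not applicable in hospitals.
schema_version: 1
units: percent
name: baseline_ssa_2015

population:
  n_preterm_births: 3988000
  delivery_mix: {home: 50, clinic: 35, hospital: 15}
  anc_mix: {home: 30, clinic: 65, hospital: 5}

subconditions:
  RDS:            {prevalence: 20, untreated_cfr: 35}
  IVH:            {prevalence: 7,  untreated_cfr: 7.5}
  NEC:            {prevalence: 1,  untreated_cfr: 25}
  sepsis:         {prevalence: 9,  untreated_cfr: 40}
  birth_asphyxia: {prevalence: 20, untreated_cfr: 20}
  LBW_only:       {prevalence: 43, untreated_cfr: 2.1}

diagnostics:
  preterm_labor:
    penetration: {home: 50, clinic: 85, hospital: 90}
    utilization: {home: 5, clinic: 20, hospital: 35}
    efficacy: {home: 25, clinic: 80, hospital: 80}
    target: null   # detects imminent preterm birth in the mother
  rds:
    penetration: {home: 50, clinic: 85, hospital: 90}
    utilization: {home: 40, clinic: 60, hospital: 95}
    efficacy: {home: 75, clinic: 95, hospital: 95}
    target: RDS
  ivh:
    penetration: {home: 50, clinic: 85, hospital: 90}
    utilization: {home: 5, clinic: 40, hospital: 70}
    efficacy: {home: 25, clinic: 45, hospital: 45}
    target: IVH
  nec:
    penetration: {home: 50, clinic: 85, hospital: 90}
    utilization: {home: 5, clinic: 40, hospital: 70}
    efficacy: {home: 25, clinic: 85, hospital: 85}
    target: NEC
  sepsis:
    penetration: {home: 95, clinic: 85, hospital: 90}
    utilization: {home: 75, clinic: 80, hospital: 90}
    efficacy: {home: 75, clinic: 95, hospital: 95}
    target: sepsis
  lbw:
    penetration: {home: 50, clinic: 85, hospital: 90}
    utilization: {home: 5, clinic: 75, hospital: 90}
    efficacy: {home: 25, clinic: 95, hospital: 95}
    target: LBW_only
  birth_asphyxia:   # assumed equal to the rds row; no published values
    penetration: {home: 50, clinic: 85, hospital: 90}
    utilization: {home: 40, clinic: 60, hospital: 95}
    efficacy: {home: 75, clinic: 95, hospital: 95}
    target: birth_asphyxia

interventions:
  ancs:   # antenatal corticosteroids for women in imminent preterm labor
    role: preventive
    timing: antenatal
    applicable_settings: [clinic, hospital]
    penetration: {home: 0, clinic: 10, hospital: 50}
    utilization: {home: 0, clinic: 5, hospital: 25}
    efficacy: {RDS: 50, IVH: 42, NEC: 54}
    gates: {RDS: preterm_labor, IVH: preterm_labor, NEC: preterm_labor}
  cord_care:   # chlorhexidine (home) / dry cord care (clinic)
    role: preventive
    timing: delivery
    at_birth: true
    applicable_settings: [home, clinic]
    penetration: {home: 0, clinic: 0, hospital: 0}
    utilization: {home: 0, clinic: 0, hospital: 0}
    efficacy: {sepsis: 55}
    gates: {sepsis: null}
  kmc:   # kangaroo mother care, stable LBW neonates only
    role: treatment
    timing: postnatal
    applicable_settings: [home, clinic, hospital]
    penetration: {home: 95, clinic: 95, hospital: 95}
    utilization: {home: 0, clinic: 0, hospital: 2}
    efficacy: {LBW_only: 51}
    gates: {LBW_only: null}
  warmers:   # radiant warmers / incubators, facilities only
    role: treatment
    timing: postnatal
    applicable_settings: [hospital]
    penetration: {home: 0, clinic: 0, hospital: 50}
    utilization: {home: 0, clinic: 0, hospital: 30}
    efficacy: {LBW_only: 60}
    gates: {LBW_only: lbw}
  breastfeeding:
    role: preventive
    timing: postnatal
    applicable_settings: [home, clinic, hospital]
    penetration: {home: 99, clinic: 99, hospital: 99}
    utilization: {home: 20, clinic: 40, hospital: 55}
    efficacy: {sepsis: 55, LBW_only: 18}
    gates: {sepsis: null, LBW_only: null}
  drying_stimulation:   # immediate drying and additional stimulation
    role: treatment
    timing: delivery
    at_birth: true
    applicable_settings: [home, clinic, hospital]
    penetration: {home: 50, clinic: 85, hospital: 90}
    utilization: {home: 50, clinic: 70, hospital: 85}
    efficacy: {birth_asphyxia: 15}
    gates: {birth_asphyxia: null}
  ppv:   # positive pressure ventilation
    role: treatment
    timing: delivery
    applicable_settings: [home, clinic, hospital]
    penetration: {home: 5, clinic: 50, hospital: 95}
    utilization: {home: 20, clinic: 40, hospital: 60}
    efficacy: {birth_asphyxia: 40}
    gates: {birth_asphyxia: birth_asphyxia}
  oxygen:
    role: treatment
    timing: postnatal
    applicable_settings: [clinic, hospital]
    penetration: {home: 0, clinic: 15, hospital: 60}
    utilization: {home: 0, clinic: 50, hospital: 75}
    efficacy: {RDS: 25, birth_asphyxia: 25}
    gates: {RDS: rds, birth_asphyxia: birth_asphyxia}
  cpap:
    role: treatment
    timing: postnatal
    applicable_settings: [clinic, hospital]
    penetration: {home: 0, clinic: 2, hospital: 20}
    utilization: {home: 0, clinic: 50, hospital: 70}
    efficacy: {RDS: 50, birth_asphyxia: 50}
    gates: {RDS: rds, birth_asphyxia: birth_asphyxia}
  surfactant:
    role: treatment
    timing: postnatal
    applicable_settings: [clinic, hospital]
    penetration: {home: 0, clinic: 1, hospital: 5}
    utilization: {home: 0, clinic: 50, hospital: 75}
    efficacy: {RDS: 35}
    gates: {RDS: rds}
  sepsis_antibiotics:   # empirical antibiotics for suspected neonatal sepsis
    role: treatment
    timing: postnatal
    applicable_settings: [home, clinic, hospital]
    penetration: {home: 10, clinic: 85, hospital: 95}
    utilization: {home: 20, clinic: 65, hospital: 75}
    efficacy: {sepsis: 72}
    gates: {sepsis: sepsis}

transfer:
  destination: hospital
  rates: {}

coverage_cap: 98
antenatal_weighting: anc_mix
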