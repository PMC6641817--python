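"""Decision-tree arithmetic: allocation, gating, transfer, combined risk."""

import numpy as np
import pytest

from preterm_cascade.cohort_cascade import (
    allocate_cohort,
    apply_transfer,
    combined_residual_cfr,
    diagnosis_probability,
    run_cohort,
    treatment_probability,
)
from preterm_cascade.model_params import (
    SETTINGS,
    Setting,
    Subcondition,
    SubconditionSpec,
)
from preterm_cascade.synthetic_params import SyntheticConfig, random_parameter_set

H, C, HO = Setting.HOME, Setting.CLINIC, Setting.HOSPITAL

# Closed-form no-intervention total: Σ births × prevalence × untreated CFR
# over the six published rows (hand-verified component by component).
UNTREATED_COMPONENTS = {
    Subcondition.RDS: 279_160.0,
    Subcondition.IVH: 20_937.0,
    Subcondition.NEC: 9_970.0,
    Subcondition.SEPSIS: 143_568.0,
    Subcondition.BIRTH_ASPHYXIA: 159_520.0,
    Subcondition.LBW_ONLY: 36_011.64,
}
UNTREATED_TOTAL = 649_166.64


def zero_coverage(p):
    """All penetrations and utilizations forced to zero."""
    zeros = {s: 0.0 for s in SETTINGS}
    return p.model_copy(
        update={
            "interventions": {
                k: iv.model_copy(update={"penetration": zeros, "utilization": zeros})
                for k, iv in p.interventions.items()
            }
        }
    )


class TestAllocation:
    def test_home_rds_stratum(self, baseline):
        strata = allocate_cohort(baseline)
        (st,) = [
            s
            for s in strata
            if s.subcondition == Subcondition.RDS and s.origin_setting == H
        ]
        assert st.n_cases == pytest.approx(3_988_000 * 0.50 * 0.20)  # 398,800

    def test_cases_partition_the_cohort(self, baseline):
        strata = allocate_cohort(baseline)
        assert sum(s.n_cases for s in strata) == pytest.approx(3_988_000)
        assert len(strata) == 6 * 3

    def test_degenerate_prevalence_all_lbw(self, baseline):
        subs = {
            k: SubconditionSpec(
                prevalence=1.0 if k == Subcondition.LBW_ONLY else 0.0,
                untreated_cfr=v.untreated_cfr,
            )
            for k, v in baseline.subconditions.items()
        }
        strata = allocate_cohort(baseline.model_copy(update={"subconditions": subs}))
        nonzero = [s for s in strata if s.n_cases > 0]
        assert {s.subcondition for s in nonzero} == {Subcondition.LBW_ONLY}
        assert sum(s.n_cases for s in nonzero) == pytest.approx(3_988_000)


class TestCoverageChain:
    def test_sepsis_gate_at_home(self, baseline):
        # 0.95 × 0.75 × 0.75
        assert diagnosis_probability(baseline.diagnostics["sepsis"], H) == pytest.approx(
            0.534375
        )

    def test_rds_gate_at_hospital(self, baseline):
        # 0.90 × 0.95 × 0.95
        assert diagnosis_probability(baseline.diagnostics["rds"], HO) == pytest.approx(
            0.81225
        )

    def test_zero_utilization_gate(self, baseline):
        g = baseline.diagnostics["rds"].model_copy(
            update={"utilization": {s: 0.0 for s in SETTINGS}}
        )
        assert diagnosis_probability(g, C) == 0.0

    def test_diagnosis_rejects_intervention_profile(self, baseline):
        with pytest.raises(ValueError, match="not a diagnostic"):
            diagnosis_probability(baseline.interventions["ancs"], H)

    def test_sepsis_antibiotics_chain_at_hospital(self, baseline):
        diagnosed = diagnosis_probability(baseline.diagnostics["sepsis"], HO)
        assert diagnosed == pytest.approx(0.90 * 0.90 * 0.95)
        cov = treatment_probability(
            baseline.interventions["sepsis_antibiotics"], HO, diagnosed,
            target=Subcondition.SEPSIS,
        )
        assert cov == pytest.approx(0.7695 * 0.95 * 0.75)

    def test_zero_diagnosis_blocks_gated_treatment(self, baseline):
        assert (
            treatment_probability(
                baseline.interventions["sepsis_antibiotics"], C, 0.0,
                target=Subcondition.SEPSIS,
            )
            == 0.0
        )

    def test_ungated_care_ignores_diagnosis(self, baseline):
        bf = baseline.interventions["breastfeeding"]
        cov = treatment_probability(bf, H, 0.0, target=Subcondition.SEPSIS)
        assert cov == pytest.approx(0.99 * 0.20)

    def test_cord_care_baseline_coverage_is_zero(self, baseline):
        assert (
            treatment_probability(
                baseline.interventions["cord_care"], H, 1.0, target=Subcondition.SEPSIS
            )
            == 0.0
        )

    def test_treatment_rejects_diagnostic_profile(self, baseline):
        with pytest.raises(ValueError, match="not an intervention"):
            treatment_probability(baseline.diagnostics["rds"], H, 1.0)


class TestCombinedResidualCFR:
    def test_empty_product_leaves_cfr(self):
        sub = SubconditionSpec(prevalence=0.1, untreated_cfr=0.4)
        assert combined_residual_cfr(sub, []) == 0.4

    def test_perfect_intervention_zeroes_cfr(self):
        sub = SubconditionSpec(prevalence=0.1, untreated_cfr=0.4)
        assert combined_residual_cfr(sub, [(1.0, 1.0)]) == 0.0

    def test_half_coverage_half_efficacy(self):
        sub = SubconditionSpec(prevalence=0.2, untreated_cfr=0.35)
        assert combined_residual_cfr(sub, [(0.5, 0.5)]) == pytest.approx(0.2625)

    def test_rejects_out_of_range(self):
        sub = SubconditionSpec(prevalence=0.2, untreated_cfr=0.35)
        with pytest.raises(ValueError):
            combined_residual_cfr(sub, [(1.5, 0.5)])


class TestTransfer:
    def test_no_rates_is_identity(self, baseline):
        strata = allocate_cohort(baseline)
        assert apply_transfer(strata, baseline) == strata

    def test_certain_transfer_moves_all_diagnosed(self, baseline):
        g = baseline.diagnostics["sepsis"].model_copy(
            update={
                "penetration": {s: 1.0 for s in SETTINGS},
                "utilization": {s: 1.0 for s in SETTINGS},
                "efficacy": {s: 1.0 for s in SETTINGS},
            }
        )
        p = baseline.model_copy(
            update={
                "diagnostics": {**baseline.diagnostics, "sepsis": g},
                "transfer": baseline.transfer.model_copy(
                    update={"rates": {"sepsis": {H: 0.0, C: 1.0, HO: 0.0}}}
                ),
            }
        )
        out = apply_transfer(allocate_cohort(p), p)
        clinic_sepsis = [
            s
            for s in out
            if s.subcondition == Subcondition.SEPSIS and s.origin_setting == C
        ]
        assert len(clinic_sepsis) == 1
        assert clinic_sepsis[0].setting == HO
        assert "sepsis" in clinic_sepsis[0].gate_confirmed

    @pytest.mark.parametrize("seed", range(10))
    def test_transfer_conserves_cases(self, seed):
        rng = np.random.default_rng(seed)
        p = random_parameter_set(SyntheticConfig(seed=seed))
        rates = {
            gate: {H: float(rng.uniform()), C: float(rng.uniform()), HO: 0.0}
            for gate in ("preterm_labor", "rds", "sepsis", "birth_asphyxia")
        }
        p = p.model_copy(update={"transfer": p.transfer.model_copy(update={"rates": rates})})
        strata = allocate_cohort(p)
        out = apply_transfer(strata, p)
        assert sum(s.n_cases for s in out) == pytest.approx(
            sum(s.n_cases for s in strata), rel=1e-12
        )

    def test_stratum_rejects_downward_transfer(self):
        from preterm_cascade.cohort_cascade import Stratum

        with pytest.raises(ValueError):
            Stratum(
                subcondition=Subcondition.RDS,
                origin_setting=HO,
                setting=H,
                n_cases=1.0,
            )


class TestRunCohort:
    def test_zero_coverage_matches_closed_form(self, baseline):
        res = run_cohort(zero_coverage(baseline))
        by_sub = res.deaths_by_subcondition()
        for sub, expected in UNTREATED_COMPONENTS.items():
            assert by_sub[sub] == pytest.approx(expected)
        assert res.total_deaths == pytest.approx(UNTREATED_TOTAL)

    def test_zero_efficacy_ignores_coverage(self, baseline):
        p = baseline.model_copy(
            update={
                "interventions": {
                    k: iv.model_copy(update={"efficacy": {t: 0.0 for t in iv.efficacy}})
                    for k, iv in baseline.interventions.items()
                }
            }
        )
        assert run_cohort(p).total_deaths == pytest.approx(UNTREATED_TOTAL)

    def test_deterministic_bitwise(self, baseline):
        a = run_cohort(baseline)
        b = run_cohort(baseline)
        assert a.deaths == b.deaths
        assert a.total_deaths == b.total_deaths

    def test_total_is_sum_of_cells(self, baseline):
        res = run_cohort(baseline)
        assert res.total_deaths == pytest.approx(sum(res.deaths.values()), rel=1e-9)

    def test_subcondition_filter_partitions_total(self, baseline, library):
        full = run_cohort(baseline).total_deaths
        parts = [
            run_cohort(baseline, subconditions=s.subcondition_filter).total_deaths
            for s in library
            if s.boost_mode == "none"
        ]
        assert sum(parts) == pytest.approx(full, rel=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_deaths_bounded_by_untreated(self, seed):
        p = random_parameter_set(SyntheticConfig(seed=seed))
        res = run_cohort(p)
        untreated = run_cohort(zero_coverage(p))
        assert 0.0 <= res.total_deaths <= untreated.total_deaths + 1e-9
        by_sub = res.deaths_by_subcondition()
        untreated_by_sub = untreated.deaths_by_subcondition()
        for sub, d in by_sub.items():
            assert d <= untreated_by_sub[sub] + 1e-9

    def test_trace_reports_stratum_probabilities(self, baseline):
        res = run_cohort(baseline, trace=True)
        assert res.trace is not None
        assert res.trace["deaths"].sum() == pytest.approx(res.total_deaths)
        assert {"effective_cfr", "coverages", "n_cases"} <= set(res.trace.columns)


def _perturb(p, rng):
    """Raise one random penetration/utilization/efficacy value."""
    kind = rng.choice(["iv_cov", "iv_eff", "diag"])
    if kind == "iv_cov":
        name = rng.choice(sorted(p.interventions))
        iv = p.interventions[name]
        field = rng.choice(["penetration", "utilization"])
        s = SETTINGS[rng.integers(3)]
        vals = dict(getattr(iv, field))
        vals[s] = float(rng.uniform(vals[s], 1.0))
        new = iv.model_copy(update={field: vals})
        return p.model_copy(update={"interventions": {**p.interventions, name: new}})
    if kind == "iv_eff":
        name = rng.choice(sorted(p.interventions))
        iv = p.interventions[name]
        tgt = sorted(iv.efficacy)[rng.integers(len(iv.efficacy))]
        eff = dict(iv.efficacy)
        eff[tgt] = float(rng.uniform(eff[tgt], 1.0))
        new = iv.model_copy(update={"efficacy": eff})
        return p.model_copy(update={"interventions": {**p.interventions, name: new}})
    gate = rng.choice(sorted(p.diagnostics))
    g = p.diagnostics[gate]
    field = rng.choice(["penetration", "utilization", "efficacy"])
    s = SETTINGS[rng.integers(3)]
    vals = dict(getattr(g, field))
    vals[s] = float(rng.uniform(vals[s], 1.0))
    new = g.model_copy(update={field: vals})
    return p.model_copy(update={"diagnostics": {**p.diagnostics, gate: new}})


@pytest.mark.parametrize("seed", range(40))
def test_raising_any_coverage_never_increases_deaths(seed):
    """More availability, use, accuracy or efficacy can only avert deaths."""
    rng = np.random.default_rng(seed)
    p = random_parameter_set(SyntheticConfig(seed=seed))
    base = run_cohort(p).total_deaths
    for _ in range(3):
        assert run_cohort(_perturb(p, rng)).total_deaths <= base + 1e-6


def test_transfer_to_dominant_hospital_never_increases_deaths(baseline):
    """With hospital coverage at least origin coverage, transfer only helps."""
    for gate in ("rds", "sepsis", "birth_asphyxia", "lbw"):
        rates = {gate: {H: 0.5, C: 0.5, HO: 0.0}}
        p = baseline.model_copy(
            update={"transfer": baseline.transfer.model_copy(update={"rates": rates})}
        )
        assert run_cohort(p).total_deaths <= run_cohort(baseline).total_deaths + 1e-6
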