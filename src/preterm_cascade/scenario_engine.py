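"""Scenario transforms and the published 30-scenario library.

Every scenario is evaluated at two levels of improvement:

* incremental change — penetration and utilization of each boosted profile
  rise by 20 percentage points, capped at the 98% maximum attainable
  coverage;
* universal coverage — penetration and utilization are set to 98%.

Neither transform ever lowers coverage below its current-care value (one
baseline penetration, breastfeeding, sits above the cap at 99%). Diagnostic
gates boosted alongside keep their accuracy (efficacy) unchanged. Scenarios
may also enable transfer of diagnosed cases to the destination setting —
with the transfer probability at the same improvement level as coverage
(0.20 incremental, 0.98 universal), since no separate numbers are published
— and may override the location mix (e.g. all deliveries in hospital).
Transforms are pure: the input parameter set is never mutated.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Literal, Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .cohort_cascade import MortalityResult, run_cohort
from .model_params import (
    SETTINGS,
    ParameterSet,
    Setting,
    Subcondition,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "apply_incremental",
    "apply_universal",
    "run_scenario",
    "deaths_prevented",
    "load_scenario_library",
]

INCREMENT = 0.20
UNIVERSAL = 0.98


class Boost(BaseModel):
    """One profile (or gate) boosted by a scenario, optionally per-setting."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    name: str
    settings: Optional[list[Setting]] = None


class ScenarioSpec(BaseModel):
    """A named transformation of the current-care parameter set."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    id: str
    table: Literal[3, 4]
    number: int = Field(ge=1)
    description: str
    boost_mode: Literal["none", "incremental", "universal", "both"] = "both"
    boosted_profiles: list[Boost] = Field(default_factory=list)
    boosted_gates: list[Boost] = Field(default_factory=list)
    transfer_gates: list[str] = Field(default_factory=list)
    transfer_destination: Setting = Setting.HOSPITAL
    location_override: Optional[dict[Setting, float]] = None
    subcondition_filter: list[Subcondition]

    @model_validator(mode="after")
    def _check(self) -> "ScenarioSpec":
        if self.boost_mode == "none" and (
            self.boosted_profiles or self.boosted_gates or self.transfer_gates
        ):
            raise ValueError(f"{self.id}: baseline scenarios must not boost anything")
        if self.location_override is not None:
            total = sum(self.location_override.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{self.id}: location_override sums to {total}")
        return self


@dataclasses.dataclass(frozen=True)
class ScenarioResult:
    """The two improvement levels of one scenario."""

    spec: ScenarioSpec
    incremental: MortalityResult
    universal: MortalityResult


def _boost_value(base: float, level: str, cap: float, mode: str = "additive") -> float:
    if level == "incremental":
        boosted = base + INCREMENT if mode == "additive" else base * (1.0 + INCREMENT)
        return max(base, min(boosted, cap))
    return max(base, cap)


def _transform(p: ParameterSet, spec: ScenarioSpec, level: str, mode: str = "additive") -> ParameterSet:
    if spec.boost_mode == "none":
        return p
    cap = p.coverage_cap
    update: dict = {}

    interventions = dict(p.interventions)
    for boost in spec.boosted_profiles:
        if boost.name not in interventions:
            raise KeyError(f"scenario {spec.id}: unknown profile '{boost.name}'")
        iv = interventions[boost.name]
        settings = set(boost.settings or SETTINGS) & set(iv.applicable_settings)
        pen = dict(iv.penetration)
        util = dict(iv.utilization)
        for s in settings:
            pen[s] = _boost_value(pen[s], level, cap, mode)
            util[s] = _boost_value(util[s], level, cap, mode)
        interventions[boost.name] = iv.model_copy(
            update={"penetration": pen, "utilization": util}
        )
    update["interventions"] = interventions

    diagnostics = dict(p.diagnostics)
    for boost in spec.boosted_gates:
        if boost.name not in diagnostics:
            raise KeyError(f"scenario {spec.id}: unknown gate '{boost.name}'")
        g = diagnostics[boost.name]
        pen = dict(g.penetration)
        util = dict(g.utilization)
        for s in boost.settings or SETTINGS:
            pen[s] = _boost_value(pen[s], level, cap, mode)
            util[s] = _boost_value(util[s], level, cap, mode)
        diagnostics[boost.name] = g.model_copy(
            update={"penetration": pen, "utilization": util}
        )
    update["diagnostics"] = diagnostics

    if spec.transfer_gates:
        rate = min(INCREMENT if level == "incremental" else UNIVERSAL, cap)
        rates = dict(p.transfer.rates)
        for gate in spec.transfer_gates:
            if gate not in diagnostics:
                raise KeyError(f"scenario {spec.id}: unknown transfer gate '{gate}'")
            base = p.transfer.rates.get(gate, {})
            rates[gate] = {
                s: (
                    0.0
                    if s >= spec.transfer_destination
                    else max(base.get(s, 0.0), min(base.get(s, 0.0) + rate, cap))
                )
                for s in SETTINGS
            }
        update["transfer"] = p.transfer.model_copy(
            update={"rates": rates, "destination": spec.transfer_destination}
        )

    if spec.location_override is not None:
        # all deliveries re-located: antenatal contact follows the same mix
        update["population"] = p.population.model_copy(
            update={
                "delivery_mix": dict(spec.location_override),
                "anc_mix": dict(spec.location_override),
            }
        )

    return p.model_copy(update=update)


def apply_incremental(p: ParameterSet, spec: ScenarioSpec, mode: str = "additive") -> ParameterSet:
    """+20-percentage-point coverage boost, capped at 98%.

    ``mode="relative"`` keeps the alternative ×1.2 reading available for
    sensitivity checks; the additive reading is the default because scenarios
    that start from zero coverage (cord care) report nonzero incremental
    impact in the source tables.
    """
    if spec.boost_mode not in ("incremental", "both", "none"):
        raise ValueError(f"{spec.id}: not an incremental scenario")
    if mode not in ("additive", "relative"):
        raise ValueError(f"unknown incremental mode {mode!r}")
    return _transform(p, spec, "incremental", mode)


def apply_universal(p: ParameterSet, spec: ScenarioSpec) -> ParameterSet:
    """Set penetration and utilization of boosted profiles to 98%."""
    if spec.boost_mode not in ("universal", "both", "none"):
        raise ValueError(f"{spec.id}: not a universal scenario")
    return _transform(p, spec, "universal")


def run_scenario(
    spec: ScenarioSpec,
    p: ParameterSet,
    trace: bool = False,
) -> ScenarioResult:
    """Evaluate both improvement levels of a scenario against ``p``."""
    filt = spec.subcondition_filter
    inc = run_cohort(
        apply_incremental(p, spec), subconditions=filt, trace=trace,
        provenance=f"{p.name}:{spec.id}:incremental",
    )
    uni = run_cohort(
        apply_universal(p, spec), subconditions=filt, trace=trace,
        provenance=f"{p.name}:{spec.id}:universal",
    )
    return ScenarioResult(spec=spec, incremental=inc, universal=uni)


def deaths_prevented(
    baseline: MortalityResult, scenario: MortalityResult
) -> tuple[float, float]:
    """(absolute deaths prevented, percent of baseline)."""
    base_subs = {sub for sub, _s in baseline.deaths}
    scen_subs = {sub for sub, _s in scenario.deaths}
    if base_subs != scen_subs:
        raise ValueError(
            f"subcondition sets differ: {sorted(s.value for s in base_subs)} vs "
            f"{sorted(s.value for s in scen_subs)}"
        )
    if baseline.total_deaths == 0:
        raise ZeroDivisionError("baseline total deaths is 0; percent undefined")
    absolute = baseline.total_deaths - scenario.total_deaths
    return absolute, 100.0 * absolute / baseline.total_deaths


def load_scenario_library(source: Optional[str] = None) -> list[ScenarioSpec]:
    """The published 12 + 18 scenario definitions (bundled YAML)."""
    if source is None:
        source = (
            resources.files("preterm_cascade.data")
            .joinpath("scenarios_ssa_2015.yaml")
            .read_text()
        )
    raw = yaml.safe_load(source)
    specs = [ScenarioSpec.model_validate(entry) for entry in raw["scenarios"]]
    ids = [s.id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate scenario ids in library")
    return specs


def scenario_by_id(scenario_id: str, library: Optional[Sequence[ScenarioSpec]] = None) -> ScenarioSpec:
    lib = library if library is not None else load_scenario_library()
    for s in lib:
        if s.id == scenario_id:
            return s
    raise KeyError(f"unknown scenario id '{scenario_id}'")
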