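"""Parameter space of the preterm-mortality cohort model.

The model describes a single-year cohort of preterm births in sub-Saharan
Africa distributed over three levels of care (home, clinic, hospital) and six
mutually exclusive causes of death ("subconditions"): respiratory distress
syndrome (RDS), intraventricular hemorrhage (IVH), necrotizing enterocolitis
(NEC), sepsis, birth asphyxia, and low birth weight with no other condition.
Care is parameterized by coverage profiles: *penetration* (availability of an
intervention at a setting), *utilization* (appropriate use where available)
and *efficacy* (relative reduction of the target outcome when received).
Treatments are gated by diagnostics, which carry their own
penetration/utilization and a setting-dependent accuracy ("diagnostic
efficacy").

This module defines the validated, immutable parameter types, loads and dumps
them from YAML/JSON configs (percent or proportion units), and ships the
baseline sub-Saharan-Africa 2015 parameterization as a bundled fixture.
"""

from __future__ import annotations

import enum
import functools
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "Setting",
    "Subcondition",
    "PopulationSpec",
    "SubconditionSpec",
    "CoverageProfile",
    "DiagnosticProfile",
    "InterventionProfile",
    "TransferSpec",
    "ParameterSet",
    "Violation",
    "load_parameter_set",
    "dump_parameter_set",
    "validate_parameter_set",
    "baseline_parameter_set",
    "ParameterConfigError",
]

_MIX_TOL = 1e-9


class ParameterConfigError(ValueError):
    """Raised when a parameter config fails schema or range validation."""


@functools.total_ordering
class Setting(str, enum.Enum):
    """Level of care; totally ordered home < clinic < hospital."""

    HOME = "home"
    CLINIC = "clinic"
    HOSPITAL = "hospital"

    @property
    def level(self) -> int:
        return _SETTING_LEVEL[self]

    def __lt__(self, other: object) -> bool:
        if not isinstance(other, Setting):
            return NotImplemented
        return self.level < other.level


_SETTING_LEVEL = {Setting.HOME: 0, Setting.CLINIC: 1, Setting.HOSPITAL: 2}
SETTINGS: tuple[Setting, ...] = (Setting.HOME, Setting.CLINIC, Setting.HOSPITAL)


class Subcondition(str, enum.Enum):
    """Cause-of-death channel for a preterm neonate."""

    RDS = "RDS"
    IVH = "IVH"
    NEC = "NEC"
    SEPSIS = "sepsis"
    BIRTH_ASPHYXIA = "birth_asphyxia"
    LBW_ONLY = "LBW_only"


SUBCONDITIONS: tuple[Subcondition, ...] = tuple(Subcondition)

#: The two publication groupings of subconditions (direct respiratory/gut
#: complications vs sepsis/asphyxia/LBW), used as scenario filters.
RDS_GROUP = (Subcondition.RDS, Subcondition.IVH, Subcondition.NEC)
SEPSIS_GROUP = (Subcondition.SEPSIS, Subcondition.BIRTH_ASPHYXIA, Subcondition.LBW_ONLY)

Proportion = Field(ge=0.0, le=1.0)


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid", use_enum_values=False)


PerSetting = dict[Setting, float]


def _check_per_setting(name: str, values: PerSetting) -> None:
    missing = [s for s in SETTINGS if s not in values]
    if missing:
        raise ValueError(f"{name} missing settings: {[s.value for s in missing]}")
    for s, v in values.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}[{s.value}]={v} outside [0, 1]")


class PopulationSpec(_Frozen):
    """Cohort size and where births / antenatal contacts take place."""

    n_preterm_births: int = Field(gt=0)
    delivery_mix: PerSetting
    anc_mix: PerSetting

    @model_validator(mode="after")
    def _check(self) -> "PopulationSpec":
        for name, mix in (("delivery_mix", self.delivery_mix), ("anc_mix", self.anc_mix)):
            _check_per_setting(name, mix)
            total = sum(mix.values())
            if abs(total - 1.0) > _MIX_TOL:
                raise ValueError(f"{name} sums to {total}, expected 1.0")
        return self


class SubconditionSpec(_Frozen):
    """Prevalence among preterm births and case-fatality rate absent care."""

    prevalence: float = Proportion
    untreated_cfr: float = Proportion


class CoverageProfile(_Frozen):
    """Per-setting penetration/utilization shared by diagnostics and interventions."""

    name: str
    penetration: PerSetting
    utilization: PerSetting

    @model_validator(mode="after")
    def _check_cov(self) -> "CoverageProfile":
        _check_per_setting(f"{self.name}.penetration", self.penetration)
        _check_per_setting(f"{self.name}.utilization", self.utilization)
        return self


class DiagnosticProfile(CoverageProfile):
    """A diagnostic gate.

    ``efficacy`` is the setting-dependent accuracy of the diagnostic (symptom
    recognition at home vs clinical/technological diagnosis in facilities).
    ``target`` is the subcondition the gate detects; the preterm-labor gate
    detects imminent preterm birth in the mother and has ``target=None``.
    """

    role: Literal["diagnostic"] = "diagnostic"
    efficacy: PerSetting
    target: Optional[Subcondition] = None

    @model_validator(mode="after")
    def _check_diag(self) -> "DiagnosticProfile":
        _check_per_setting(f"{self.name}.efficacy", self.efficacy)
        return self


class InterventionProfile(CoverageProfile):
    """A preventive or treatment intervention.

    ``efficacy`` maps each target subcondition to the relative mortality
    reduction when the intervention is received; ``gates`` maps each target to
    the diagnostic gate that conditions receipt (``None`` for universal
    newborn care that requires no diagnosis). ``at_birth`` interventions
    (drying and stimulation, cord care) are delivered where the birth happens,
    before any postnatal transfer.
    """

    role: Literal["preventive", "treatment"]
    timing: Literal["antenatal", "delivery", "postnatal"]
    at_birth: bool = False
    applicable_settings: list[Setting]
    efficacy: dict[Subcondition, float]
    gates: dict[Subcondition, Optional[str]]

    @model_validator(mode="after")
    def _check_iv(self) -> "InterventionProfile":
        if not self.efficacy:
            raise ValueError(f"{self.name}: at least one target subcondition required")
        for tgt, e in self.efficacy.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"{self.name}.efficacy[{tgt.value}]={e} outside [0, 1]")
        if set(self.gates) != set(self.efficacy):
            raise ValueError(f"{self.name}: gates and efficacy must cover the same targets")
        if not self.applicable_settings:
            raise ValueError(f"{self.name}: applicable_settings must not be empty")
        return self


class TransferSpec(_Frozen):
    """Probability that a gate-diagnosed case moves to the destination setting.

    ``rates[gate][origin]`` applies to cases diagnosed by ``gate`` at
    ``origin``. At the current-care baseline no rates are set (the published
    tables print none); scenarios enable transfer as a lever.
    """

    destination: Setting = Setting.HOSPITAL
    rates: dict[str, PerSetting] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_rates(self) -> "TransferSpec":
        for gate, per in self.rates.items():
            for s, v in per.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"transfer[{gate}][{s.value}]={v} outside [0, 1]")
            if per.get(Setting.HOSPITAL, 0.0) != 0.0:
                raise ValueError(f"transfer[{gate}]: transfer out of hospital must be 0")
        return self

    def rate(self, gate: str, origin: Setting) -> float:
        return self.rates.get(gate, {}).get(origin, 0.0)


#: Gate name used for maternal recognition of imminent preterm birth.
PRETERM_LABOR_GATE = "preterm_labor"


class ParameterSet(_Frozen):
    """Complete parameterization of the cohort model."""

    name: str = "unnamed"
    population: PopulationSpec
    subconditions: dict[Subcondition, SubconditionSpec]
    diagnostics: dict[str, DiagnosticProfile]
    interventions: dict[str, InterventionProfile]
    transfer: TransferSpec = Field(default_factory=TransferSpec)
    coverage_cap: float = Field(default=0.98, ge=0.0, le=1.0)
    antenatal_weighting: Literal["anc_mix", "delivery_mix"] = "anc_mix"

    @model_validator(mode="after")
    def _check_complete(self) -> "ParameterSet":
        missing = [c.value for c in SUBCONDITIONS if c not in self.subconditions]
        if missing:
            raise ValueError(f"subconditions missing: {missing}")
        for iv in self.interventions.values():
            for tgt, gate in iv.gates.items():
                if gate is not None and gate not in self.diagnostics:
                    raise ValueError(
                        f"intervention {iv.name}: gate '{gate}' for target "
                        f"{tgt.value} has no diagnostic profile"
                    )
        for gate in self.transfer.rates:
            if gate not in self.diagnostics:
                raise ValueError(f"transfer references unknown gate '{gate}'")
        return self

    def gate_for(self, intervention: str, target: Subcondition) -> Optional[str]:
        return self.interventions[intervention].gates.get(target)


class Violation(_Frozen):
    """One invariant violation, reported as data rather than an exception."""

    type_name: str
    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.type_name}.{self.field}: {self.rule}"


# --------------------------------------------------------------------------
# config I/O

_PROB_KEYS = {
    "penetration",
    "utilization",
    "efficacy",
    "prevalence",
    "untreated_cfr",
    "delivery_mix",
    "anc_mix",
    "rates",
    "coverage_cap",
}


def _scale(node: object, active: bool, factor: float) -> object:
    """Recursively divide probability-valued leaves by ``factor``."""
    if isinstance(node, dict):
        return {k: _scale(v, active or k in _PROB_KEYS, factor) for k, v in node.items()}
    if isinstance(node, list):
        return [_scale(v, active, factor) for v in node]
    if active and isinstance(node, (int, float)) and not isinstance(node, bool):
        return node / factor
    return node


def load_parameter_set(source: str | Path) -> ParameterSet:
    """Load and validate a parameter set from YAML/JSON text or a file path.

    The config declares ``units: percent`` (as printed in the source tables)
    or ``units: proportion``; percent values are rescaled to proportions.
    Unknown keys and out-of-range proportions are rejected.
    """
    if isinstance(source, Path):
        text = source.read_text()
    else:
        text = str(source)
        p = Path(text)
        # allow short path-like strings
        if "\n" not in text and len(text) < 4096 and p.suffix in {".yaml", ".yml", ".json"} and p.exists():
            text = p.read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - malformed input
        raise ParameterConfigError(f"config is not valid YAML/JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ParameterConfigError("config root must be a mapping")
    raw = dict(raw)
    raw.pop("schema_version", None)
    units = raw.pop("units", "proportion")
    if units not in ("percent", "proportion"):
        raise ParameterConfigError(f"units must be 'percent' or 'proportion', got {units!r}")
    if units == "percent":
        raw = _scale(raw, False, 100.0)
    # profile names live on the mapping keys; inject them
    for section in ("diagnostics", "interventions"):
        block = raw.get(section)
        if isinstance(block, dict):
            for key, profile in block.items():
                if isinstance(profile, dict):
                    profile.setdefault("name", key)
    try:
        return ParameterSet.model_validate(raw)
    except ValidationError as exc:
        raise ParameterConfigError(str(exc)) from exc


def _plain(obj: object) -> object:
    if isinstance(obj, dict):
        return {(k.value if isinstance(k, enum.Enum) else k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_plain(v) for v in obj]
    if isinstance(obj, enum.Enum):
        return obj.value
    return obj


def dump_parameter_set(p: ParameterSet) -> str:
    """Serialize to YAML in proportion units; round-trips through load."""
    raw = _plain(p.model_dump(mode="json"))
    for section in ("diagnostics", "interventions"):
        for key, profile in raw[section].items():
            profile.pop("name", None)
    doc = {"schema_version": 1, "units": "proportion", **raw}
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)


def validate_parameter_set(p: ParameterSet) -> list[Violation]:
    """Re-check every type invariant on an already-constructed parameter set.

    Returns an empty list iff all invariants hold; violations are data so the
    caller can report them all at once. Useful for parameter sets built by
    hand or mutated through ``model_construct`` paths that bypass validation.
    """
    out: list[Violation] = []

    def _rng(type_name: str, field: str, value: float) -> None:
        if not 0.0 <= value <= 1.0:
            out.append(Violation(type_name=type_name, field=field, rule=f"value {value} outside [0, 1]"))

    pop = p.population
    if pop.n_preterm_births <= 0:
        out.append(Violation(type_name="PopulationSpec", field="n_preterm_births", rule="must be > 0"))
    for mix_name, mix in (("delivery_mix", pop.delivery_mix), ("anc_mix", pop.anc_mix)):
        for s in SETTINGS:
            if s not in mix:
                out.append(Violation(type_name="PopulationSpec", field=f"{mix_name}[{s.value}]", rule="missing"))
            else:
                _rng("PopulationSpec", f"{mix_name}[{s.value}]", mix[s])
        total = sum(mix.values())
        if abs(total - 1.0) > _MIX_TOL:
            out.append(Violation(type_name="PopulationSpec", field=mix_name, rule=f"sums to {total}, expected 1.0"))

    for c in SUBCONDITIONS:
        if c not in p.subconditions:
            out.append(Violation(type_name="ParameterSet", field=f"subconditions[{c.value}]", rule="missing"))
            continue
        spec = p.subconditions[c]
        _rng("SubconditionSpec", f"{c.value}.prevalence", spec.prevalence)
        _rng("SubconditionSpec", f"{c.value}.untreated_cfr", spec.untreated_cfr)

    for gate, d in p.diagnostics.items():
        for s in SETTINGS:
            _rng("DiagnosticProfile", f"{gate}.penetration[{s.value}]", d.penetration.get(s, 0.0))
            _rng("DiagnosticProfile", f"{gate}.utilization[{s.value}]", d.utilization.get(s, 0.0))
            _rng("DiagnosticProfile", f"{gate}.efficacy[{s.value}]", d.efficacy.get(s, 0.0))

    for name, iv in p.interventions.items():
        for s in SETTINGS:
            _rng("InterventionProfile", f"{name}.penetration[{s.value}]", iv.penetration.get(s, 0.0))
            _rng("InterventionProfile", f"{name}.utilization[{s.value}]", iv.utilization.get(s, 0.0))
        if not iv.efficacy:
            out.append(Violation(type_name="InterventionProfile", field=f"{name}.efficacy", rule="no target subcondition"))
        for tgt, e in iv.efficacy.items():
            _rng("InterventionProfile", f"{name}.efficacy[{tgt.value}]", e)
        for tgt, gate in iv.gates.items():
            if gate is not None and gate not in p.diagnostics:
                out.append(
                    Violation(
                        type_name="ParameterSet",
                        field=f"interventions[{name}].gates[{tgt.value}]",
                        rule=f"references missing diagnostic '{gate}'",
                    )
                )

    for gate, per in p.transfer.rates.items():
        for s, v in per.items():
            _rng("TransferSpec", f"rates[{gate}][{s.value}]", v)
        if per.get(Setting.HOSPITAL, 0.0) != 0.0:
            out.append(Violation(type_name="TransferSpec", field=f"rates[{gate}][hospital]", rule="transfer out of hospital must be 0"))
        if gate not in p.diagnostics:
            out.append(Violation(type_name="TransferSpec", field=f"rates[{gate}]", rule="references missing diagnostic"))

    _rng("ParameterSet", "coverage_cap", p.coverage_cap)
    return out


def _data_path(filename: str):
    return resources.files("preterm_cascade.data").joinpath(filename)


@functools.lru_cache(maxsize=1)
def baseline_parameter_set() -> ParameterSet:
    """The bundled sub-Saharan-Africa 2015 current-care parameter set."""
    return load_parameter_set(_data_path("baseline_ssa_2015.yaml").read_text())
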