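"""Deterministic decision-tree cohort arithmetic.

The cohort of preterm births is partitioned into strata by (subcondition ×
setting of birth). Each stratum flows through the care cascade:

1. diagnosis — a gate's probability at a setting is penetration ×
   utilization × diagnostic accuracy;
2. transfer (when enabled) — the diagnosed fraction moves to the destination
   setting and subsequently uses destination coverage, with the triggering
   gate counted as confirmed; the remainder keeps the conditional probability
   of having been diagnosed but not moved;
3. treatment — each intervention reaches a stratum with coverage
   diagnosis × penetration × utilization (diagnosis forced to 1 for
   universal newborn care), and the interventions combine as independent
   multiplicative reductions of the untreated case-fatality rate:
   CFR_eff = CFR_untreated × Π_i (1 − coverage_i × efficacy_i).

Antenatal prophylaxis (corticosteroids) is received before delivery: its
coverage is the antenatal-care location mix weighted over settings of the
gate × penetration × utilization chain, identical for every newborn stratum.

Everything is an expected-value computation on real-valued case counts; the
model is nonstochastic and bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model_params import (
    PRETERM_LABOR_GATE,
    SETTINGS,
    CoverageProfile,
    InterventionProfile,
    ParameterSet,
    Setting,
    Subcondition,
    SubconditionSpec,
)

__all__ = [
    "Stratum",
    "MortalityResult",
    "allocate_cohort",
    "diagnosis_probability",
    "treatment_probability",
    "combined_residual_cfr",
    "apply_transfer",
    "run_cohort",
]


@dataclasses.dataclass(frozen=True)
class Stratum:
    """A homogeneous slice of the cohort.

    ``origin_setting`` is where the birth takes place (after any antenatal
    re-settlement of the delivery itself); ``setting`` is where postnatal care
    happens after transfer. ``gate_confirmed`` lists gates whose diagnosis is
    certain for this stratum (it triggered the move); ``gate_conditional``
    stores P(diagnosed | not moved) for gates whose transfer split the parent
    stratum.
    """

    subcondition: Subcondition
    origin_setting: Setting
    setting: Setting
    n_cases: float
    gate_confirmed: frozenset[str] = frozenset()
    gate_conditional: Mapping[str, float] = dataclasses.field(default_factory=dict)
    pl_transferred: bool = False

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be non-negative")
        if self.setting < self.origin_setting:
            raise ValueError("care setting cannot be below the setting of birth")


@dataclasses.dataclass(frozen=True)
class MortalityResult:
    """Expected deaths by subcondition × care setting."""

    deaths: Mapping[tuple[Subcondition, Setting], float]
    provenance: str = ""
    trace: Optional[pd.DataFrame] = None

    @property
    def total_deaths(self) -> float:
        return float(sum(self.deaths.values()))

    def deaths_by_subcondition(self) -> dict[Subcondition, float]:
        out: dict[Subcondition, float] = {}
        for (sub, _s), v in self.deaths.items():
            out[sub] = out.get(sub, 0.0) + v
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subcondition": sub.value, "setting": s.value, "deaths": v}
            for (sub, s), v in sorted(
                self.deaths.items(), key=lambda kv: (kv[0][0].value, kv[0][1].level)
            )
        ]
        return pd.DataFrame(rows, columns=["subcondition", "setting", "deaths"])


def allocate_cohort(p: ParameterSet) -> list[Stratum]:
    """Split the cohort into (subcondition × birth-setting) strata.

    Prevalences partition the cohort (the published table sums to 100%), so
    total cases equal the number of preterm births whenever they sum to 1.
    """
    strata = []
    n = p.population.n_preterm_births
    for sub, spec in p.subconditions.items():
        for s in SETTINGS:
            strata.append(
                Stratum(
                    subcondition=sub,
                    origin_setting=s,
                    setting=s,
                    n_cases=n * p.population.delivery_mix[s] * spec.prevalence,
                )
            )
    return strata


def diagnosis_probability(gate: CoverageProfile, setting: Setting) -> float:
    """P(case diagnosed) = penetration × utilization × diagnostic accuracy."""
    if getattr(gate, "role", None) != "diagnostic":
        raise ValueError(f"{gate.name} is not a diagnostic profile")
    return gate.penetration[setting] * gate.utilization[setting] * gate.efficacy[setting]


def treatment_probability(
    tx: CoverageProfile,
    setting: Setting,
    diagnosed: float,
    target: Optional[Subcondition] = None,
) -> float:
    """P(intervention received) = diagnosed × penetration × utilization.

    For targets whose receipt requires no prior diagnosis (universal newborn
    care such as drying and stimulation, cord care, breastfeeding, KMC) the
    diagnosed probability is forced to 1.
    """
    role = getattr(tx, "role", None)
    if role not in ("preventive", "treatment"):
        raise ValueError(f"{tx.name} is not an intervention profile")
    if target is not None and isinstance(tx, InterventionProfile):
        if tx.gates.get(target) is None:
            diagnosed = 1.0
    return diagnosed * tx.penetration[setting] * tx.utilization[setting]


def combined_residual_cfr(
    sub: SubconditionSpec, received: Iterable[tuple[float, float]]
) -> float:
    """Effective CFR after independent multiplicative risk reductions.

    ``received`` yields (efficacy, coverage) pairs; each intervention removes
    a fraction coverage × efficacy of the remaining risk.
    """
    cfr = sub.untreated_cfr
    for efficacy, coverage in received:
        if not 0.0 <= efficacy <= 1.0 or not 0.0 <= coverage <= 1.0:
            raise ValueError("efficacy and coverage must be in [0, 1]")
        cfr *= 1.0 - coverage * efficacy
    return cfr


def _split(st: Stratum, frac_moved: float, dest: Setting, gate: str, pl: bool) -> list[Stratum]:
    """Split a stratum into moved/stayed pieces, conserving cases."""
    pieces: list[Stratum] = []
    if frac_moved > 0:
        pieces.append(
            dataclasses.replace(
                st,
                n_cases=st.n_cases * frac_moved,
                # an antenatal move re-settles the birth itself
                origin_setting=dest if pl else st.origin_setting,
                setting=dest,
                gate_confirmed=st.gate_confirmed | ({gate} if not pl else frozenset()),
                pl_transferred=pl or st.pl_transferred,
            )
        )
    if frac_moved < 1:
        pieces.append(dataclasses.replace(st, n_cases=st.n_cases * (1.0 - frac_moved)))
    return pieces


def apply_transfer(
    strata: Sequence[Stratum], p: ParameterSet, gates: Optional[Iterable[str]] = None
) -> list[Stratum]:
    """Move the diagnosed fraction of each stratum per the enabled transfers.

    The preterm-labor gate acts antenatally and moves the delivery itself
    (every subcondition); condition gates move only their target subcondition
    postnatally. Case counts are conserved exactly.
    """
    enabled = set(p.transfer.rates if gates is None else gates)
    dest = p.transfer.destination
    out: list[Stratum] = list(strata)

    if PRETERM_LABOR_GATE in enabled:
        gate = p.diagnostics[PRETERM_LABOR_GATE]
        moved: list[Stratum] = []
        for st in out:
            rate = p.transfer.rate(PRETERM_LABOR_GATE, st.setting)
            if st.setting >= dest or rate == 0.0:
                moved.append(st)
                continue
            d = diagnosis_probability(gate, st.setting)
            moved.extend(_split(st, d * rate, dest, PRETERM_LABOR_GATE, pl=True))
        out = moved

    for gate_name in sorted(enabled - {PRETERM_LABOR_GATE}):
        gate = p.diagnostics[gate_name]
        target = gate.target
        moved = []
        for st in out:
            rate = p.transfer.rate(gate_name, st.setting)
            if st.subcondition != target or st.setting >= dest or rate == 0.0:
                moved.append(st)
                continue
            d = diagnosis_probability(gate, st.setting)
            f = d * rate
            pieces = _split(st, f, dest, gate_name, pl=False)
            for piece in pieces:
                if piece.setting != dest or gate_name not in piece.gate_confirmed:
                    # staying piece: conditional P(diagnosed | not moved)
                    cond = d * (1.0 - rate) / (1.0 - f) if f < 1.0 else 0.0
                    piece = dataclasses.replace(
                        piece, gate_conditional={**piece.gate_conditional, gate_name: cond}
                    )
                moved.append(piece)
        out = moved
    return out


def _antenatal_coverage(p: ParameterSet, iv: InterventionProfile, target: Subcondition) -> float:
    """Population-average receipt of an antenatal profile (gate at ANC setting)."""
    gate_name = iv.gates.get(target)
    weights = (
        p.population.anc_mix
        if p.antenatal_weighting == "anc_mix"
        else p.population.delivery_mix
    )
    cov = 0.0
    for s in SETTINGS:
        d = 1.0 if gate_name is None else diagnosis_probability(p.diagnostics[gate_name], s)
        cov += weights[s] * d * iv.penetration[s] * iv.utilization[s]
    return cov


def _stratum_interventions(
    p: ParameterSet, st: Stratum
) -> list[tuple[str, float, float]]:
    """(name, efficacy, coverage) for every intervention acting on the stratum."""
    rows = []
    for name, iv in p.interventions.items():
        if st.subcondition not in iv.efficacy:
            continue
        e = iv.efficacy[st.subcondition]
        if iv.timing == "antenatal":
            if st.pl_transferred:
                # the mother was recognised in preterm labor and moved; the
                # gate is satisfied, receipt depends on destination coverage
                s = st.setting
                c = iv.penetration[s] * iv.utilization[s]
            else:
                c = _antenatal_coverage(p, iv, st.subcondition)
        else:
            s = st.origin_setting if iv.at_birth else st.setting
            gate_name = iv.gates.get(st.subcondition)
            if gate_name is None:
                d = 1.0
            elif gate_name in st.gate_confirmed:
                d = 1.0
            elif gate_name in st.gate_conditional:
                d = st.gate_conditional[gate_name]
            else:
                d = diagnosis_probability(p.diagnostics[gate_name], s)
            c = treatment_probability(iv, s, d, target=st.subcondition)
        rows.append((name, e, c))
    return rows


def run_cohort(
    p: ParameterSet,
    subconditions: Optional[Sequence[Subcondition]] = None,
    trace: bool = False,
    provenance: str = "",
) -> MortalityResult:
    """Full deterministic pipeline: allocate → transfer → treat → count deaths.

    ``subconditions`` restricts the reported deaths to a cause group (the
    publication scores its two scenario tables on disjoint groups); the
    cascade itself is always run on the full cohort.
    """
    keep = set(subconditions) if subconditions is not None else set(p.subconditions)
    strata = apply_transfer(allocate_cohort(p), p)
    deaths: dict[tuple[Subcondition, Setting], float] = {}
    trace_rows: list[dict] = []
    for st in strata:
        if st.subcondition not in keep:
            continue
        received = _stratum_interventions(p, st)
        cfr = combined_residual_cfr(
            p.subconditions[st.subcondition], [(e, c) for _n, e, c in received]
        )
        d = st.n_cases * cfr
        key = (st.subcondition, st.setting)
        deaths[key] = deaths.get(key, 0.0) + d
        if trace:
            trace_rows.append(
                {
                    "subcondition": st.subcondition.value,
                    "origin_setting": st.origin_setting.value,
                    "setting": st.setting.value,
                    "n_cases": st.n_cases,
                    "untreated_cfr": p.subconditions[st.subcondition].untreated_cfr,
                    "effective_cfr": cfr,
                    "deaths": d,
                    "coverages": {n: c for n, _e, c in received},
                }
            )
    return MortalityResult(
        deaths=deaths,
        provenance=provenance or p.name,
        trace=pd.DataFrame(trace_rows) if trace else None,
    )
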