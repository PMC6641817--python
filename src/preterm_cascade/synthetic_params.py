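"""Random valid parameter sets and a stochastic microsimulation oracle.

The generator draws random coverage, efficacy, prevalence and case-fatality
values over the model's fixed structure (three settings, six subconditions,
the published diagnostic gates and intervention roster), so every cascade
property is testable without external data.

The microsimulation re-expresses the decision tree stochastically: each
simulated neonate draws a birth setting, a subcondition, diagnosis/transfer
outcomes and the receipt of each intervention as Bernoulli events, then dies
with probability untreated CFR × Π (1 − efficacy) over received
interventions. It shares no arithmetic with the deterministic engine and
serves as its independent oracle: the engine's expected deaths must sit
within Monte-Carlo error of the simulated count.

Both the engine and the simulator treat intervention receipts as
conditionally independent given the stratum (each gated marginally by its
diagnostic probability); this is a shared modelling assumption, not an
artifact of either implementation.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model_params import (
    PRETERM_LABOR_GATE,
    SETTINGS,
    SUBCONDITIONS,
    ParameterSet,
    Setting,
    Subcondition,
    SubconditionSpec,
    baseline_parameter_set,
)
from .scenario_engine import ScenarioSpec, apply_incremental, apply_universal

__all__ = ["SyntheticConfig", "random_parameter_set", "microsim_oracle"]

Interval = tuple[float, float]


class SyntheticConfig(BaseModel):
    """Sampling intervals for random parameter sets and microsim size."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    seed: int = 0
    n_subconditions: int = Field(default=6, ge=1, le=6)
    n_individuals: int = Field(default=2_000_000, ge=1)
    penetration_range: Interval = (0.0, 1.0)
    utilization_range: Interval = (0.0, 1.0)
    efficacy_range: Interval = (0.0, 1.0)
    diagnostic_efficacy_range: Interval = (0.2, 1.0)
    cfr_range: Interval = (0.01, 0.6)

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        for name in (
            "penetration_range",
            "utilization_range",
            "efficacy_range",
            "diagnostic_efficacy_range",
            "cfr_range",
        ):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name}={lo, hi} must be a sub-interval of [0, 1]")
        return self


def _unif(rng: np.random.Generator, interval: Interval, size=None):
    return rng.uniform(interval[0], interval[1], size=size)


def random_parameter_set(cfg: SyntheticConfig) -> ParameterSet:
    """Draw a valid random parameter set; deterministic given ``cfg.seed``.

    The structure (settings, subconditions, gates, intervention roster and
    applicability) follows the bundled baseline; all probabilities are
    resampled. Prevalences are Dirichlet-distributed over the active
    subconditions so they partition the cohort exactly.
    """
    template = baseline_parameter_set()
    rng = np.random.default_rng(cfg.seed)

    mixes = rng.dirichlet(np.ones(3), size=2)
    population = template.population.model_copy(
        update={
            "delivery_mix": dict(zip(SETTINGS, mixes[0])),
            "anc_mix": dict(zip(SETTINGS, mixes[1])),
        }
    )

    active = list(rng.choice(len(SUBCONDITIONS), size=cfg.n_subconditions, replace=False))
    prev = np.zeros(len(SUBCONDITIONS))
    prev[active] = rng.dirichlet(np.ones(cfg.n_subconditions))
    subconditions = {
        sub: SubconditionSpec(
            prevalence=float(prev[i]),
            untreated_cfr=float(_unif(rng, cfg.cfr_range)),
        )
        for i, sub in enumerate(SUBCONDITIONS)
    }

    diagnostics = {
        name: g.model_copy(
            update={
                "penetration": {s: float(_unif(rng, cfg.penetration_range)) for s in SETTINGS},
                "utilization": {s: float(_unif(rng, cfg.utilization_range)) for s in SETTINGS},
                "efficacy": {
                    s: float(_unif(rng, cfg.diagnostic_efficacy_range)) for s in SETTINGS
                },
            }
        )
        for name, g in template.diagnostics.items()
    }

    interventions = {}
    for name, iv in template.interventions.items():
        applicable = set(iv.applicable_settings)
        interventions[name] = iv.model_copy(
            update={
                "penetration": {
                    s: float(_unif(rng, cfg.penetration_range)) if s in applicable else 0.0
                    for s in SETTINGS
                },
                "utilization": {
                    s: float(_unif(rng, cfg.utilization_range)) if s in applicable else 0.0
                    for s in SETTINGS
                },
                "efficacy": {
                    tgt: float(_unif(rng, cfg.efficacy_range)) for tgt in iv.efficacy
                },
            }
        )

    return template.model_copy(
        update={
            "name": f"synthetic-{cfg.seed}",
            "population": population,
            "subconditions": subconditions,
            "diagnostics": diagnostics,
            "interventions": interventions,
        }
    )


def _diag_vec(p: ParameterSet, gate: str) -> np.ndarray:
    g = p.diagnostics[gate]
    return np.array([g.penetration[s] * g.utilization[s] * g.efficacy[s] for s in SETTINGS])


def microsim_oracle(
    p: ParameterSet,
    n_individuals: int,
    seed: int,
    scenario: Optional[ScenarioSpec] = None,
    level: str = "universal",
    subconditions: Optional[Sequence[Subcondition]] = None,
) -> tuple[float, float]:
    """Simulate individual neonates; return (death estimate, standard error).

    The estimate is scaled to the cohort size (expected deaths among all
    preterm births, restricted to ``subconditions`` if given) with its
    binomial Monte-Carlo standard error on the same scale.
    """
    if scenario is not None:
        p = (
            apply_incremental(p, scenario)
            if level == "incremental"
            else apply_universal(p, scenario)
        )
    rng = np.random.default_rng(seed)
    n = int(n_individuals)
    n_births = p.population.n_preterm_births
    subs = list(SUBCONDITIONS)
    dest = p.transfer.destination
    dest_i = SETTINGS.index(dest)

    mix = np.array([p.population.delivery_mix[s] for s in SETTINGS])
    anc_mix = np.array([p.population.anc_mix[s] for s in SETTINGS])
    prev = np.array([p.subconditions[c].prevalence for c in subs])
    prev_total = prev.sum()
    if prev_total <= 0:
        return 0.0, 0.0

    birth = rng.choice(len(SETTINGS), size=n, p=mix / mix.sum())
    sub = rng.choice(len(subs), size=n, p=prev / prev_total)
    care = birth.copy()
    pl_trans = np.zeros(n, dtype=bool)
    residual = np.ones(n)

    # --- antenatal re-settlement of the delivery (preterm-labor transfer)
    if PRETERM_LABOR_GATE in p.transfer.rates:
        d_pl = _diag_vec(p, PRETERM_LABOR_GATE)
        for si, s in enumerate(SETTINGS):
            rate = p.transfer.rate(PRETERM_LABOR_GATE, s)
            if rate > 0 and si < dest_i:
                m = (birth == si) & (rng.random(n) < d_pl[si] * rate)
                birth[m] = dest_i
                care[m] = dest_i
                pl_trans[m] = True

    # --- postnatal transfer of diagnosed cases, per condition gate
    confirmed: dict[str, np.ndarray] = {}
    stay_cond: dict[str, np.ndarray] = {}
    for gate in sorted(set(p.transfer.rates) - {PRETERM_LABOR_GATE}):
        target = p.diagnostics[gate].target
        if target is None:
            continue
        t_i = subs.index(target)
        d_g = _diag_vec(p, gate)
        conf = np.zeros(n, dtype=bool)
        cond = d_g.copy()  # P(diagnosed | stayed), per origin setting
        for si in range(len(SETTINGS)):
            rate = p.transfer.rate(gate, SETTINGS[si])
            if rate > 0 and si < dest_i:
                f = d_g[si] * rate
                m = (sub == t_i) & (care == si) & (rng.random(n) < f)
                care[m] = dest_i
                conf[m] = True
                cond[si] = d_g[si] * (1.0 - rate) / (1.0 - f) if f < 1.0 else 0.0
        confirmed[gate] = conf
        stay_cond[gate] = cond

    # --- intervention receipts and survival
    for name, iv in p.interventions.items():
        pen = np.array([iv.penetration[s] for s in SETTINGS])
        util = np.array([iv.utilization[s] for s in SETTINGS])
        pu = pen * util
        for target, eff in iv.efficacy.items():
            t_i = subs.index(target)
            m = sub == t_i
            if iv.timing == "antenatal":
                rec = np.zeros(n, dtype=bool)
                m1 = m & pl_trans
                rec[m1] = rng.random(int(m1.sum())) < pu[dest_i]
                m0 = m & ~pl_trans
                k = int(m0.sum())
                if k:
                    w = anc_mix if p.antenatal_weighting == "anc_mix" else mix
                    anc = rng.choice(len(SETTINGS), size=k, p=w / w.sum())
                    gate = iv.gates[target]
                    d = np.ones(k) if gate is None else _diag_vec(p, gate)[anc]
                    rec[m0] = (rng.random(k) < d) & (rng.random(k) < pu[anc])
            else:
                where = birth if iv.at_birth else care
                gate = iv.gates[target]
                if gate is None:
                    d = np.ones(n)
                else:
                    d = _diag_vec(p, gate)[where]
                    if gate in stay_cond:
                        d = stay_cond[gate][where]
                        d[confirmed[gate]] = 1.0
                rec = m & (rng.random(n) < d * pu[where])
            residual[rec] *= 1.0 - eff
    cfr = np.array([p.subconditions[c].untreated_cfr for c in subs])[sub]
    dead = rng.random(n) < cfr * residual

    if subconditions is not None:
        keep = np.isin(sub, [subs.index(c) for c in subconditions])
        dead = dead & keep
    p_hat = dead.sum() / n
    scale = n_births * prev_total
    estimate = scale * p_hat
    se = scale * float(np.sqrt(p_hat * (1.0 - p_hat) / n))
    return float(estimate), se
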