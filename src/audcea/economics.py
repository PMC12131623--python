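"""Cost and QALY accounting, discounting, and incremental analysis.

Quality-adjusted life years accrue as cycle-end occupancy times the
state's utility times the cycle length, discounted to present value at
the cycle end. Short-term cycles use the trial utilities matched to the
measurement occasion (12, 26, 52 weeks); medium-term cycles carry the
52-week values forward. Complication states use literature utilities.

Intervention costs are charged in full at model start (treatment spans
the first 12 weeks) and are not discounted; complication costs (direct
medical and productivity) are charged once on entry into the event state,
discounted at that cycle's end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .markov import CohortTrace
from .params import ModelConfig, ParameterSet
from .states import (
    DEAD_INDEX,
    N_STATES,
    STATE_SPACE,
    Drl,
    Sex,
    StateKind,
)


def discount_factor(t_years: float, rate: float) -> float:
    """Present-value factor (1 + rate)^(-t)."""
    if t_years < 0 or not math.isfinite(t_years):
        raise ValueError(f"t_years must be finite and non-negative, got {t_years}")
    if rate < 0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    return (1.0 + rate) ** (-t_years)


@dataclass
class ArmResult:
    """Discounted per-person costs (2024 USD) and QALYs for one arm."""

    arm: str
    intervention_cost: float
    direct_medical_cost: float
    productivity_cost: float
    qalys: float

    @property
    def total_healthcare_cost(self) -> float:
        return self.intervention_cost + self.direct_medical_cost

    @property
    def total_societal_cost(self) -> float:
        return self.total_healthcare_cost + self.productivity_cost


@dataclass
class IncrementalResult:
    """Intervention minus comparator, with dominance classification."""

    delta_intervention_cost: float
    delta_direct_medical_cost: float
    delta_productivity_cost: float
    delta_healthcare_cost: float
    delta_societal_cost: float
    delta_qalys: float
    icer_healthcare: float | str
    icer_societal: float | str


def _state_utilities(params: ParameterSet, sex: Sex, timepoint: str) -> np.ndarray:
    u = np.zeros(N_STATES)
    for i, s in enumerate(STATE_SPACE):
        if s.kind is StateKind.DRL:
            u[i] = params.drl_utility(s.drl, sex, timepoint)
        elif s.kind in (StateKind.PERMANENT_EVENT, StateKind.TUNNEL_EVENT):
            u[i] = params.event_utility(s.event)
        # dead stays 0
    return u


def _state_costs(params: ParameterSet, cost_type: str) -> np.ndarray:
    c = np.zeros(N_STATES)
    for i, s in enumerate(STATE_SPACE):
        if s.kind in (StateKind.PERMANENT_EVENT, StateKind.TUNNEL_EVENT):
            c[i] = params.event_cost(s.event, cost_type)
    return c


@dataclass
class StratumAccrual:
    """Discounted accruals for one arm x sex stratum (no intervention cost)."""

    direct_medical_cost: float
    productivity_cost: float
    qalys: float


def accumulate(
    trace: CohortTrace, params: ParameterSet, config: ModelConfig
) -> StratumAccrual:
    """Attach utilities and complication costs to a trace and discount them."""
    rate = config.discount_rate
    sex = Sex(trace.sex)
    direct_c = _state_costs(params, "direct")
    prod_c = _state_costs(params, "productivity")

    qalys = 0.0
    direct = 0.0
    productivity = 0.0
    for c in range(trace.n_cycles):
        df = discount_factor(trace.t_end[c], rate)
        u = _state_utilities(params, sex, trace.utility_timepoint[c])
        occ_end = trace.occupancy[c + 1]
        qalys += float(occ_end @ u) * trace.cycle_years[c] * df
        if config.event_cost_timing == "once_on_entry":
            cost_weights = trace.entries[c]
        else:  # per_cycle: every cycle of residence in an event state is charged
            cost_weights = np.where(
                [s.kind in (StateKind.PERMANENT_EVENT, StateKind.TUNNEL_EVENT) for s in STATE_SPACE],
                occ_end, 0.0,
            )
        direct += float(cost_weights @ direct_c) * df
        productivity += float(cost_weights @ prod_c) * df
    return StratumAccrual(direct_medical_cost=direct, productivity_cost=productivity, qalys=qalys)


def incremental(intervention: ArmResult, comparator: ArmResult) -> IncrementalResult:
    """Paired incremental analysis with dominance flags instead of sign-flipped ICERs."""
    dq = intervention.qalys - comparator.qalys

    def icer(dc: float) -> float | str:
        if dq > 0 and dc < 0:
            return "dominant"
        if dq < 0 and dc > 0:
            return "dominated"
        if dq == 0:
            return "cost-minimization" if dc != 0 else "equivalent"
        return dc / dq

    dc_h = intervention.total_healthcare_cost - comparator.total_healthcare_cost
    dc_s = intervention.total_societal_cost - comparator.total_societal_cost
    return IncrementalResult(
        delta_intervention_cost=intervention.intervention_cost - comparator.intervention_cost,
        delta_direct_medical_cost=intervention.direct_medical_cost - comparator.direct_medical_cost,
        delta_productivity_cost=intervention.productivity_cost - comparator.productivity_cost,
        delta_healthcare_cost=dc_h,
        delta_societal_cost=dc_s,
        delta_qalys=dq,
        icer_healthcare=icer(dc_h),
        icer_societal=icer(dc_s),
    )
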