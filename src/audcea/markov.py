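"""Transition-matrix construction and the two-phase cohort simulation.

The model runs one year of three-month cycles (the trial follow-up
period, during which the arms differ through their observed DRL
transitions) followed by four annual cycles (the extrapolation period,
during which a literature-informed relapse probability and the
alcohol-attributable event risks apply).

Competing risks within a cycle are resolved in a fixed order that
guarantees row-stochasticity: death first (all-cause plus fatal events),
then non-fatal event exits, then DRL movement applied to the event-free
remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelConfig, ParameterSet, TIMEPOINTS
from .risk import (
    StateEventProbs,
    annual_to_cycle_probability,
    event_probabilities_for_state,
)
from .states import (
    DEAD_INDEX,
    DRL_INDICES,
    EVENT_STATE_INDICES,
    N_STATES,
    PERMANENT_EVENTS,
    TEMPORARY_EVENTS,
    Drl,
    Sex,
    permanent_state_index,
    tunnel_state_index,
)

_ROW_TOL = 1e-10


@dataclass
class TransitionMatrix:
    """A 22-state per-cycle transition matrix."""

    p: np.ndarray
    cycle_years: float
    phase: str  # "short" or "medium"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.p.shape != (N_STATES, N_STATES):
            raise ValueError(f"transition matrix must be {N_STATES}x{N_STATES}")
        if (self.p < -1e-15).any():
            raise ValueError("negative transition probability")
        sums = self.p.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > _ROW_TOL)[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(f"row {i} sums to {sums[i]:.12f}, expected 1")


def _event_state_rows(
    p: np.ndarray, sex: Sex, age: float, mortality, cycle_years: float,
    background_mortality: bool,
) -> None:
    """Fill tunnel, permanent and dead rows (shared by both phases)."""
    if background_mortality:
        p_death = annual_to_cycle_probability(
            mortality.annual_probability(age, sex), min(cycle_years, 1.0)
        )
    else:
        p_death = 0.0
    for event in PERMANENT_EVENTS:
        i = permanent_state_index(event)
        p[i, i] = 1.0 - p_death
        p[i, DEAD_INDEX] = p_death
    for event in TEMPORARY_EVENTS:
        for origin in Drl:
            i = tunnel_state_index(event, origin)
            p[i, int(origin)] = 1.0 - p_death  # forced exit back to origin DRL
            p[i, DEAD_INDEX] = p_death
    p[DEAD_INDEX, DEAD_INDEX] = 1.0


def _allocate_drl_row(
    row: np.ndarray, drl: Drl, ep: StateEventProbs | None,
    relapse_p: float, improvement_p: float, drl_block_row: np.ndarray | None,
    p_death_allcause: float,
) -> None:
    """Fill one DRL row following the fixed competing-risk order."""
    p_dead = p_death_allcause
    if ep is not None:
        p_dead = ep.p_death_allcause + sum(ep.p_fatal.values())
        for event in PERMANENT_EVENTS:
            row[permanent_state_index(event)] = ep.p_nonfatal.get(event, 0.0)
        for event in TEMPORARY_EVENTS:
            row[tunnel_state_index(event, drl)] = ep.p_nonfatal.get(event, 0.0)
    row[DEAD_INDEX] = p_dead
    remaining = 1.0 - row.sum()
    if remaining < -1e-12:
        raise ValueError(f"exit mass exceeds 1 in DRL row {drl.name}")
    remaining = max(remaining, 0.0)
    if drl_block_row is not None:
        row[DRL_INDICES[0]: DRL_INDICES[-1] + 1] += remaining * drl_block_row
        return
    # medium-term phase: one-step worsening (relapse) and optional improvement
    stay = remaining
    if drl in (Drl.LOW, Drl.MEDIUM) and relapse_p > 0:
        row[int(drl) + 1] += remaining * relapse_p
        stay -= remaining * relapse_p
    if drl in (Drl.MEDIUM, Drl.HIGH, Drl.VERY_HIGH) and improvement_p > 0:
        row[int(drl) - 1] += remaining * improvement_p
        stay -= remaining * improvement_p
    row[int(drl)] += stay


def build_short_term_matrix(
    drl_block: np.ndarray,
    sex: Sex,
    age: float,
    mortality,
    cycle_years: float = 0.25,
    event_probs: dict[Drl, StateEventProbs] | None = None,
    background_mortality_in_event_states: bool = True,
) -> TransitionMatrix:
    """Quarterly matrix: trial-observed DRL movement plus all-cause death.

    By default no complication risks act in this phase; `event_probs`
    enables them for exploration.
    """
    drl_block = np.asarray(drl_block, dtype=float)
    if drl_block.shape != (4, 4):
        raise ValueError("drl_block must be 4x4")
    sums = drl_block.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > 1e-8)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(f"DRL block row {Drl(i).name} sums to {sums[i]:.6f}, expected 1")

    p_death = annual_to_cycle_probability(
        mortality.annual_probability(age, sex), min(cycle_years, 1.0)
    )
    p = np.zeros((N_STATES, N_STATES))
    for drl in Drl:
        _allocate_drl_row(
            p[int(drl)], drl,
            event_probs.get(drl) if event_probs else None,
            relapse_p=0.0, improvement_p=0.0,
            drl_block_row=drl_block[int(drl)],
            p_death_allcause=p_death,
        )
    _event_state_rows(p, sex, age, mortality, cycle_years, background_mortality_in_event_states)
    return TransitionMatrix(p, cycle_years, "short")


def build_medium_term_matrix(
    relapse_p: float,
    sex: Sex,
    age: float,
    risks,
    mortality,
    cycle_years: float = 1.0,
    improvement_p: float = 0.0,
    background_mortality_in_event_states: bool = True,
) -> TransitionMatrix:
    """Annual matrix: event risks, relapse/improvement, background death."""
    p = np.zeros((N_STATES, N_STATES))
    for drl in Drl:
        ep = event_probabilities_for_state(drl, sex, age, risks, mortality, cycle_years)
        _allocate_drl_row(
            p[int(drl)], drl, ep, relapse_p, improvement_p,
            drl_block_row=None, p_death_allcause=ep.p_death_allcause,
        )
    _event_state_rows(p, sex, age, mortality, cycle_years, background_mortality_in_event_states)
    return TransitionMatrix(p, cycle_years, "medium")


def split_interval_matrix(m: np.ndarray) -> np.ndarray:
    """Approximate one-quarter step of a two-quarter transition block.

    Each row's total off-diagonal mass p becomes 1 - (1-p)^0.5, spread
    proportionally over the original destinations. Used because the trial's
    26-to-52-week interval spans two model cycles.
    """
    m = np.asarray(m, dtype=float)
    out = np.zeros_like(m)
    for i in range(m.shape[0]):
        off = 1.0 - m[i, i]
        if off <= 0:
            out[i, i] = 1.0
            continue
        q = 1.0 - np.sqrt(max(1.0 - off, 0.0))
        out[i] = m[i] * (q / off)
        out[i, i] = 1.0 - q
    return out


@dataclass
class CohortTrace:
    """Occupancy and accrual history of one arm x sex stratum."""

    arm: str
    sex: str
    occupancy: np.ndarray  # (n_cycles + 1, 22); row 0 = baseline
    entries: np.ndarray  # (n_cycles, 22); inflow into event states per cycle
    t_end: np.ndarray  # (n_cycles,) years at each cycle end
    cycle_years: np.ndarray  # (n_cycles,)
    phase: list[str] = field(default_factory=list)
    utility_timepoint: list[str] = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return self.entries.shape[0]

    def validate(self) -> None:
        sums = self.occupancy.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            raise ValueError("occupancy does not sum to 1 at every cycle")
        if (self.occupancy < -1e-12).any():
            raise ValueError("negative occupancy")
        dead = self.occupancy[:, DEAD_INDEX]
        if (np.diff(dead) < -1e-12).any():
            raise ValueError("dead occupancy decreased")


def _short_term_blocks(params: ParameterSet, arm: str, config: ModelConfig) -> list[np.ndarray]:
    """Quarterly DRL blocks for the 4 short cycles from the 3 trial intervals."""
    m1, m2, m3 = params.short_term_transitions[arm]
    m3q = split_interval_matrix(m3)
    return [m1, m2, m3q, m3q]


#: Utility timepoint matched to each short cycle (cycle 3 and 4 share 52 wk).
_SHORT_CYCLE_TIMEPOINTS = ("12wk", "26wk", "52wk", "52wk")


def run_cohort(
    initial_distribution: np.ndarray,
    arm: str,
    sex: Sex,
    config: ModelConfig,
    params: ParameterSet,
) -> CohortTrace:
    """Run the two-phase simulation for one arm and sex stratum."""
    init = np.asarray(initial_distribution, dtype=float)
    if init.shape != (4,):
        raise ValueError("initial distribution must cover the 4 DRL states")
    if (init < 0).any() or abs(init.sum() - 1.0) > 1e-9:
        raise ValueError(f"initial distribution must be non-negative and sum to 1, got {init}")

    sex = Sex(sex)
    age0 = params.baseline_age[arm]
    n_short, n_long = config.n_short_cycles, config.n_long_cycles
    n_cycles = n_short + n_long

    occupancy = np.zeros((n_cycles + 1, N_STATES))
    occupancy[0, :4] = init
    entries = np.zeros((n_cycles, N_STATES))
    t_end = np.zeros(n_cycles)
    cycle_years = np.zeros(n_cycles)
    phases: list[str] = []
    timepoints: list[str] = []

    blocks = _short_term_blocks(params, arm, config)
    t = 0.0
    for c in range(n_cycles):
        short = c < n_short
        dt = config.short_cycle_years if short else config.long_cycle_years
        age = age0 + t
        if short:
            eps = None
            if config.events_in_short_phase:
                eps = {
                    d: event_probabilities_for_state(
                        d, sex, age, params.risks, params.mortality, dt
                    )
                    for d in Drl
                }
            tm = build_short_term_matrix(
                blocks[c], sex, age, params.mortality, dt,
                event_probs=eps,
                background_mortality_in_event_states=config.background_mortality_in_event_states,
            )
            timepoints.append(_SHORT_CYCLE_TIMEPOINTS[c])
        else:
            tm = build_medium_term_matrix(
                config.relapse_probability, sex, age, params.risks, params.mortality, dt,
                improvement_p=config.improvement_probability,
                background_mortality_in_event_states=config.background_mortality_in_event_states,
            )
            timepoints.append(TIMEPOINTS[-1])  # latest trial utilities carry forward
        prev = occupancy[c]
        occupancy[c + 1] = prev @ tm.p
        # entries into event states: inflow from other states only
        inflow = prev @ tm.p - prev * np.diag(tm.p)
        mask = np.zeros(N_STATES, dtype=bool)
        mask[list(EVENT_STATE_INDICES)] = True
        entries[c, mask] = inflow[mask]
        t += dt
        t_end[c] = t
        cycle_years[c] = dt
        phases.append(tm.phase)

    trace = CohortTrace(
        arm=arm, sex=sex.value, occupancy=occupancy, entries=entries,
        t_end=t_end, cycle_years=cycle_years, phase=phases, utility_timepoint=timepoints,
    )
    trace.validate()
    return trace
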