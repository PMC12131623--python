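"""Independent individual-level microsimulation oracle.

Steps a large number of simulated persons through the same per-cycle
transition matrices the cohort engine builds, with its own bookkeeping
for undiscounted QALYs and event costs. Used to validate the cohort
(expected-value) engine: occupancies should agree within Monte-Carlo
error and expected costs/QALYs within a small relative tolerance.
"""

from __future__ import annotations

import numpy as np

from audcea.economics import _state_costs, _state_utilities
from audcea.markov import (
    _short_term_blocks,
    build_medium_term_matrix,
    build_short_term_matrix,
)
from audcea.params import ModelConfig, ParameterSet
from audcea.states import N_STATES, Sex


def microsimulate(
    initial_distribution: np.ndarray,
    arm: str,
    sex: Sex,
    config: ModelConfig,
    params: ParameterSet,
    n_persons: int,
    seed: int,
) -> dict:
    """Simulate n_persons individually; return occupancy fractions and
    mean undiscounted QALYs / direct / productivity costs per person."""
    rng = np.random.default_rng(seed)
    sex = Sex(sex)
    age0 = params.baseline_age[arm]
    n_short, n_long = config.n_short_cycles, config.n_long_cycles
    n_cycles = n_short + n_long
    blocks = _short_term_blocks(params, arm, config)

    states = rng.choice(4, size=n_persons, p=np.asarray(initial_distribution))
    occ = np.zeros((n_cycles + 1, N_STATES))
    occ[0] = np.bincount(states, minlength=N_STATES) / n_persons

    direct_c = _state_costs(params, "direct")
    prod_c = _state_costs(params, "productivity")
    qalys = np.zeros(n_persons)
    direct = np.zeros(n_persons)
    productivity = np.zeros(n_persons)

    t = 0.0
    timepoints = ("12wk", "26wk", "52wk", "52wk")
    for c in range(n_cycles):
        short = c < n_short
        dt = config.short_cycle_years if short else config.long_cycle_years
        age = age0 + t
        if short:
            tm = build_short_term_matrix(blocks[c], sex, age, params.mortality, dt)
            tp = timepoints[c]
        else:
            tm = build_medium_term_matrix(
                config.relapse_probability, sex, age, params.risks, params.mortality, dt,
                improvement_p=config.improvement_probability,
            )
            tp = "52wk"
        cum = np.cumsum(tm.p, axis=1)
        u = rng.random(n_persons)
        new_states = (u[:, None] > cum[states]).sum(axis=1)
        entered = new_states != states
        # one-off event costs on entry into an event state
        direct += np.where(entered, direct_c[new_states], 0.0)
        productivity += np.where(entered, prod_c[new_states], 0.0)
        util = _state_utilities(params, sex, tp)
        qalys += util[new_states] * dt
        states = new_states
        occ[c + 1] = np.bincount(states, minlength=N_STATES) / n_persons
        t += dt

    return {
        "occupancy": occ,
        "qalys": qalys.mean(),
        "direct": direct.mean(),
        "productivity": productivity.mean(),
    }
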