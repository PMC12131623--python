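"""End-to-end deterministic evaluation: parameters in, arm results out.

Each arm is simulated separately for the male and female strata (all risk
and utility inputs are sex-specific) and the strata are aggregated with
the arm's trial sex mix as weights.
"""

from __future__ import annotations

from .economics import ArmResult, IncrementalResult, accumulate, incremental
from .markov import CohortTrace, run_cohort
from .params import ARMS, COMPARATOR_ARM, INTERVENTION_ARM, ModelConfig, ParameterSet
from .states import Sex


def evaluate_arm(
    arm: str,
    params: ParameterSet,
    config: ModelConfig,
    include_supervision_cost: bool = True,
) -> ArmResult:
    """Deterministic per-person costs and QALYs for one treatment arm."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    p_female = params.female_proportion[arm]
    weights = {Sex.FEMALE: p_female, Sex.MALE: 1.0 - p_female}

    direct = productivity = qalys = 0.0
    for sex, w in weights.items():
        if w == 0.0:
            continue
        trace = run_cohort(params.baseline_drl[(arm, sex.value)], arm, sex, config, params)
        acc = accumulate(trace, params, config)
        direct += w * acc.direct_medical_cost
        productivity += w * acc.productivity_cost
        qalys += w * acc.qalys

    return ArmResult(
        arm=arm,
        intervention_cost=params.intervention_cost_total(arm, include_supervision_cost),
        direct_medical_cost=direct,
        productivity_cost=productivity,
        qalys=qalys,
    )


def run_base_case(
    params: ParameterSet,
    config: ModelConfig,
    include_supervision_cost: bool = True,
) -> dict:
    """Both arms plus the paired incremental comparison (BSCT vs MET)."""
    results = {
        arm: evaluate_arm(arm, params, config, include_supervision_cost) for arm in ARMS
    }
    inc = incremental(results[INTERVENTION_ARM], results[COMPARATOR_ARM])
    return {"arms": results, "incremental": inc}


def cohort_traces(
    arm: str, params: ParameterSet, config: ModelConfig
) -> dict[str, CohortTrace]:
    """Per-sex traces for one arm (for inspection and export)."""
    return {
        sex.value: run_cohort(params.baseline_drl[(arm, sex.value)], arm, sex, config, params)
        for sex in Sex
    }
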