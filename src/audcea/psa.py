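"""Probabilistic sensitivity analysis.

Each Monte-Carlo iteration draws one joint parameter set (independent
across parameters), evaluates *both* arms on that same draw (common
random parameters, so incrementals are paired), and stores per-arm and
incremental results. Uncertainty is summarised by 2.5th/97.5th percentile
intervals, the cost-effectiveness plane, and the cost-effectiveness
acceptability curve CEAC(lambda) = Pr(lambda * dQALY - dCost > 0).

Iteration i uses an independent substream spawned from the run seed, so
results do not depend on evaluation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import (  # noqa: F401  (re-exported: canonical home of the PSA families)
    DistributionSpec,
    beta_from_moments,
    gamma_from_moments,
    sample_triangular,
)
from .economics import ArmResult, IncrementalResult, incremental
from .params import ARMS, COMPARATOR_ARM, INTERVENTION_ARM, ModelConfig, ParameterSet, UtilityItem
from .pipeline import evaluate_arm


def sample_parameter_set(base: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One joint draw of every uncertain parameter; fixed items untouched.

    Sampling order is the sorted key order of each table, so a given
    substream always maps to the same draw regardless of caller.
    """
    sampled = dataclasses.replace(
        base,
        utilities_drl=dict(base.utilities_drl),
        utilities_events=dict(base.utilities_events),
        event_costs=dict(base.event_costs),
    )
    # sampled items carry se=0: they are realised values, not distributions
    for key in sorted(sampled.utilities_drl):
        item = sampled.utilities_drl[key]
        sampled.utilities_drl[key] = dataclasses.replace(
            item, utility=item.spec.sample(rng), se=0.0
        )
    for key in sorted(sampled.utilities_events):
        item = sampled.utilities_events[key]
        sampled.utilities_events[key] = dataclasses.replace(
            item, utility=item.spec.sample(rng), se=0.0
        )
    for key in sorted(sampled.event_costs):
        item = sampled.event_costs[key]
        sampled.event_costs[key] = dataclasses.replace(item, mean=item.spec.sample(rng))
    return sampled


@dataclass
class PsaDraws:
    """Paired per-iteration results of a probabilistic sensitivity analysis."""

    arm_results: dict[str, list[ArmResult]] = field(default_factory=lambda: {a: [] for a in ARMS})
    incrementals: list[IncrementalResult] = field(default_factory=list)
    seed: int | None = None

    @property
    def n_iterations(self) -> int:
        return len(self.incrementals)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, inc in enumerate(self.incrementals):
            row = {"iteration": i}
            for arm in ARMS:
                r = self.arm_results[arm][i]
                row |= {
                    f"{arm}_total_healthcare_cost": r.total_healthcare_cost,
                    f"{arm}_total_societal_cost": r.total_societal_cost,
                    f"{arm}_qalys": r.qalys,
                }
            row |= {
                "delta_qaly": inc.delta_qalys,
                "delta_cost_healthcare": inc.delta_healthcare_cost,
                "delta_cost_societal": inc.delta_societal_cost,
            }
            rows.append(row)
        return pd.DataFrame(rows)


def run_psa(
    base_params: ParameterSet,
    config: ModelConfig,
    seed: int | None = None,
    n_iterations: int | None = None,
) -> PsaDraws:
    """Paired Monte-Carlo PSA; reproducible under a fixed seed."""
    n = n_iterations if n_iterations is not None else config.psa_iterations
    if n < 1:
        raise ValueError("n_iterations must be >= 1")
    run_seed = config.seed if seed is None else seed
    streams = np.random.SeedSequence(run_seed).spawn(n)

    draws = PsaDraws(seed=run_seed)
    for i in range(n):
        rng = np.random.default_rng(streams[i])
        sampled = sample_parameter_set(base_params, rng)
        results = {arm: evaluate_arm(arm, sampled, config) for arm in ARMS}
        for arm in ARMS:
            draws.arm_results[arm].append(results[arm])
        draws.incrementals.append(
            incremental(results[INTERVENTION_ARM], results[COMPARATOR_ARM])
        )
    return draws


def uncertainty_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Central percentile interval (numpy linear-interpolation convention)."""
    arr = np.asarray(samples, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 samples for an uncertainty interval")
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(arr, [tail, 100.0 - tail], method="linear")
    return float(lo), float(hi)


def ce_plane_and_ceac(
    draws: PsaDraws,
    wtp_grid,
    perspective: str = "societal",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CE-plane points and the acceptability curve over a WTP grid."""
    if draws.n_iterations == 0:
        raise ValueError("PSA draws are empty")
    if perspective not in ("societal", "healthcare"):
        raise ValueError(f"unknown perspective {perspective!r}")
    dq = np.array([inc.delta_qalys for inc in draws.incrementals])
    dc = np.array(
        [
            inc.delta_societal_cost if perspective == "societal" else inc.delta_healthcare_cost
            for inc in draws.incrementals
        ]
    )
    plane = pd.DataFrame(
        {"iteration": np.arange(draws.n_iterations), "delta_qaly": dq, "delta_cost": dc}
    )
    wtp = np.asarray(wtp_grid, dtype=float)
    if (wtp < 0).any():
        raise ValueError("willingness-to-pay values must be non-negative")
    prob = [(lam * dq - dc > 0).mean() for lam in wtp]
    ceac = pd.DataFrame({"wtp": wtp, "probability": prob})
    return plane, ceac


def summarize(draws: PsaDraws) -> pd.DataFrame:
    """Mean and 95% UI of every headline output, per arm and incremental."""
    rows = []

    def add(label: str, values) -> None:
        lo, hi = uncertainty_interval(values)
        rows.append({"quantity": label, "mean": float(np.mean(values)), "ui_lo": lo, "ui_hi": hi})

    for arm in ARMS:
        res = draws.arm_results[arm]
        add(f"{arm}_healthcare_cost", [r.direct_medical_cost for r in res])
        add(f"{arm}_productivity_cost", [r.productivity_cost for r in res])
        add(f"{arm}_total_healthcare_cost", [r.total_healthcare_cost for r in res])
        add(f"{arm}_total_societal_cost", [r.total_societal_cost for r in res])
        add(f"{arm}_qalys", [r.qalys for r in res])
    incs = draws.incrementals
    add("delta_healthcare_cost", [i.delta_healthcare_cost for i in incs])
    add("delta_productivity_cost", [i.delta_productivity_cost for i in incs])
    add("delta_societal_cost", [i.delta_societal_cost for i in incs])
    add("delta_qalys", [i.delta_qalys for i in incs])
    return pd.DataFrame(rows)
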