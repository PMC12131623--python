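"""Univariate scenario analysis.

Each scenario overrides a single base-case assumption — discount rate,
relapse probability, removal of supervision/coding costs, or an
alternative DRL utility table — and reruns the deterministic model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .params import ARMS, ModelConfig, ParameterSet, _load_utilities_drl
from .pipeline import run_base_case

_CONFIG_KEYS = {"discount_rate", "relapse_probability", "improvement_probability"}
_PARAM_KEYS = {"drop_supervision_costs", "utilities_drl_table"}


@dataclass
class ScenarioSpec:
    """One named deviation from the base case."""

    name: str
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.overrides) - _CONFIG_KEYS - _PARAM_KEYS
        if unknown:
            raise ValueError(f"scenario {self.name!r}: unknown override keys {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        d = dict(d)
        name = d.pop("name")
        overrides = d.pop("overrides", d)
        return cls(name=name, overrides=overrides)


def apply_scenario(
    params: ParameterSet, config: ModelConfig, spec: ScenarioSpec
) -> tuple[ParameterSet, ModelConfig, bool]:
    """Return (params, config, include_supervision) with only the overridden
    fields differing from base."""
    cfg_over = {k: v for k, v in spec.overrides.items() if k in _CONFIG_KEYS}
    config2 = dataclasses.replace(config, **cfg_over) if cfg_over else config

    params2 = params
    include_supervision = not bool(spec.overrides.get("drop_supervision_costs", False))
    if "utilities_drl_table" in spec.overrides:
        table = Path(spec.overrides["utilities_drl_table"])
        if not table.is_absolute():
            cfg_dir = Path(params.source_files.get("config", ".")).parent
            table = cfg_dir / table
        params2 = dataclasses.replace(params, utilities_drl=_load_utilities_drl(table))
    return params2, config2, include_supervision


def run_scenarios(
    params: ParameterSet,
    config: ModelConfig,
    scenarios: list[ScenarioSpec] | None = None,
) -> pd.DataFrame:
    """Base case plus each scenario; one output row per arm per scenario."""
    if scenarios is None:
        scenarios = [ScenarioSpec.from_dict(d) for d in params.scenarios]
    specs = [ScenarioSpec(name="base_case")] + list(scenarios)

    rows = []
    for spec in specs:
        p, c, include_sup = apply_scenario(params, config, spec)
        out = run_base_case(p, c, include_supervision_cost=include_sup)
        inc = out["incremental"]
        for arm in ARMS:
            r = out["arms"][arm]
            rows.append(
                {
                    "scenario": spec.name,
                    "arm": arm,
                    "intervention_cost": r.intervention_cost,
                    "direct_medical_cost": r.direct_medical_cost,
                    "productivity_cost": r.productivity_cost,
                    "total_healthcare_cost": r.total_healthcare_cost,
                    "total_societal_cost": r.total_societal_cost,
                    "qalys": r.qalys,
                }
            )
        rows.append(
            {
                "scenario": spec.name,
                "arm": "incremental",
                "intervention_cost": inc.delta_intervention_cost,
                "direct_medical_cost": inc.delta_direct_medical_cost,
                "productivity_cost": inc.delta_productivity_cost,
                "total_healthcare_cost": inc.delta_healthcare_cost,
                "total_societal_cost": inc.delta_societal_cost,
                "qalys": inc.delta_qalys,
                "icer_healthcare": inc.icer_healthcare,
                "icer_societal": inc.icer_societal,
            }
        )
    return pd.DataFrame(rows)
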