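"""Model configuration and parameter loading.

All inputs enter as plain delimited-text tables referenced from a single
YAML configuration file; every invariant (row-stochastic matrices,
probabilities in range, feasible distribution moments) is checked eagerly
at load time so an invalid input can never surface mid-simulation.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .distributions import DistributionSpec
from .drl import DrlThresholdTable
from .risk import MortalityTable, RiskTable
from .states import Drl, Sex

log = logging.getLogger(__name__)

ARMS: tuple[str, str] = ("BSCT", "MET")
INTERVENTION_ARM = "BSCT"
COMPARATOR_ARM = "MET"

#: Trial measurement occasions the short-term utilities are matched to.
TIMEPOINTS: tuple[str, ...] = ("12wk", "26wk", "52wk")
INTERVALS: tuple[str, ...] = ("baseline-12wk", "12wk-26wk", "26wk-52wk")

_ROW_TOL = 1e-8


@dataclass
class ModelConfig:
    """Run-level settings of the cohort model."""

    horizon_years: float = 5.0
    short_cycle_years: float = 0.25
    short_phase_years: float = 1.0
    long_cycle_years: float = 1.0
    discount_rate: float = 0.03
    relapse_probability: float = 0.14  # annual LOW->MEDIUM and MEDIUM->HIGH worsening
    improvement_probability: float = 0.0
    cohort_size: int = 250
    psa_iterations: int = 1000
    grams_per_drink: float = 12.0
    seed: int = 0
    events_in_short_phase: bool = False
    background_mortality_in_event_states: bool = True
    event_cost_timing: str = "once_on_entry"  # or "per_cycle"

    def __post_init__(self) -> None:
        for name in ("discount_rate", "relapse_probability", "improvement_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        n_long = (self.horizon_years - self.short_phase_years) / self.long_cycle_years
        if abs(n_long - round(n_long)) > 1e-9 or n_long < 0:
            raise ValueError("horizon must equal short phase plus whole long cycles")
        if self.event_cost_timing not in ("once_on_entry", "per_cycle"):
            raise ValueError(f"unknown event_cost_timing {self.event_cost_timing!r}")

    @property
    def n_short_cycles(self) -> int:
        return int(round(self.short_phase_years / self.short_cycle_years))

    @property
    def n_long_cycles(self) -> int:
        return int(round((self.horizon_years - self.short_phase_years) / self.long_cycle_years))


@dataclass(frozen=True)
class UtilityItem:
    """A health-state preference weight with its sampling uncertainty."""

    state_id: str
    utility: float
    se: float = 0.0
    family: str = "beta"

    def __post_init__(self) -> None:
        if self.utility > 1.0:
            raise ValueError(f"utility {self.utility} > 1 for {self.state_id}")
        if self.se < 0:
            raise ValueError(f"negative se for {self.state_id}")
        try:
            _ = self.spec  # eager feasibility check of the sampling distribution
        except ValueError as err:
            raise ValueError(f"{self.state_id}: {err}") from None

    @property
    def spec(self) -> DistributionSpec:
        if self.family == "fixed" or self.se == 0.0:
            return DistributionSpec("fixed", self.utility)
        return DistributionSpec("beta", self.utility, se=self.se)


@dataclass(frozen=True)
class CostItem:
    """A cost input (2024 USD) with its uncertainty distribution."""

    item_id: str
    category: str  # intervention_fixed/_variable/_supervision, direct_medical, productivity
    mean: float
    spec: DistributionSpec
    timing: str = "once_on_entry"

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError(f"negative mean cost for {self.item_id}")


@dataclass
class ParameterSet:
    """Every model input; the unit of PSA sampling."""

    thresholds: DrlThresholdTable
    short_term_transitions: dict[str, list[np.ndarray]]  # arm -> 3 interval 4x4 blocks
    baseline_drl: dict[tuple[str, str], np.ndarray]  # (arm, sex) -> 4-vector
    female_proportion: dict[str, float]  # per arm
    baseline_age: dict[str, float]  # per arm, years
    risks: RiskTable
    mortality: MortalityTable
    utilities_drl: dict[tuple[int, str, str], UtilityItem]  # (drl, sex, timepoint); NA cells absent
    utilities_events: dict[str, UtilityItem]
    intervention_costs: dict[str, dict[str, float]]  # arm -> component -> USD
    event_costs: dict[tuple[str, str], CostItem]  # (event, "direct"|"productivity")
    scenarios: list[dict] = field(default_factory=list)
    source_files: dict[str, str] = field(default_factory=dict)

    _warned_vh: set = field(default_factory=set, repr=False)

    def drl_utility(self, drl: Drl | int, sex: Sex, timepoint: str) -> float:
        """Utility for a DRL state; VERY_HIGH falls back to HIGH where the
        trial had no occupants (mirrors the 'NA' cells), with a warning."""
        sexv = Sex(sex).value
        key = (int(drl), sexv, timepoint)
        if key in self.utilities_drl:
            return self.utilities_drl[key].utility
        if int(drl) == int(Drl.VERY_HIGH):
            fb = (int(Drl.HIGH), sexv, timepoint)
            if fb in self.utilities_drl:
                if key not in self._warned_vh:
                    log.warning(
                        "no VERY_HIGH utility for %s/%s; inheriting HIGH", sexv, timepoint
                    )
                    self._warned_vh.add(key)
                return self.utilities_drl[fb].utility
        raise KeyError(f"no utility for DRL={int(drl)}, sex={sexv}, timepoint={timepoint}")

    def event_utility(self, event: str) -> float:
        try:
            return self.utilities_events[event].utility
        except KeyError:
            raise KeyError(f"no utility for event {event!r}") from None

    def event_cost(self, event: str, cost_type: str) -> float:
        try:
            return self.event_costs[(event, cost_type)].mean
        except KeyError:
            raise KeyError(f"no {cost_type} cost for event {event!r}") from None

    def intervention_cost_total(self, arm: str, include_supervision: bool = True) -> float:
        comps = self.intervention_costs[arm]
        total = sum(comps.values())
        if not include_supervision:
            total -= comps.get("supervision", 0.0)
        return total

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


def _check_row_stochastic(m: np.ndarray, context: str) -> None:
    if m.shape != (4, 4):
        raise ValueError(f"{context}: expected a 4x4 block, got {m.shape}")
    if (m < -1e-12).any() or (m > 1 + 1e-12).any():
        raise ValueError(f"{context}: entries outside [0, 1]")
    sums = m.sum(axis=1)
    for i, s in enumerate(sums):
        if abs(s - 1.0) > _ROW_TOL:
            raise ValueError(f"{context}: row {Drl(i).name} sums to {s:.6f}, expected 1")


def _load_transitions(path: Path) -> dict[str, list[np.ndarray]]:
    df = pd.read_csv(path, comment="#")
    drl_order = [d.name.lower() for d in Drl]
    out: dict[str, list[np.ndarray]] = {}
    for arm in ARMS:
        blocks = []
        for interval in INTERVALS:
            sub = df[(df["arm"] == arm) & (df["interval"] == interval)]
            if len(sub) == 0:
                raise ValueError(f"{path}: no transitions for arm={arm}, interval={interval}")
            m = np.zeros((4, 4))
            for r in sub.itertuples():
                m[drl_order.index(r.from_drl), drl_order.index(r.to_drl)] = float(r.probability)
            _check_row_stochastic(m, f"{path}: {arm} {interval}")
            blocks.append(m)
        out[arm] = blocks
    return out


def _load_baseline(path: Path) -> dict[tuple[str, str], np.ndarray]:
    df = pd.read_csv(path, comment="#")
    drl_order = [d.name.lower() for d in Drl]
    out: dict[tuple[str, str], np.ndarray] = {}
    for (arm, sex), grp in df.groupby(["arm", "sex"]):
        v = np.zeros(4)
        for r in grp.itertuples():
            v[drl_order.index(r.drl)] = float(r.probability)
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{path}: baseline distribution for {arm}/{sex} sums to {v.sum():.6f}")
        out[(arm, Sex(sex).value)] = v / v.sum()
    for arm in ARMS:
        for sex in Sex:
            if (arm, sex.value) not in out:
                raise ValueError(f"{path}: missing baseline distribution for {arm}/{sex.value}")
    return out


def _load_utilities_drl(path: Path) -> dict[tuple[int, str, str], UtilityItem]:
    df = pd.read_csv(path, comment="#")
    drl_order = [d.name.lower() for d in Drl]
    out: dict[tuple[int, str, str], UtilityItem] = {}
    for r in df.itertuples():
        if pd.isna(r.utility):
            continue  # NA cell: no trial occupants at that timepoint
        key = (drl_order.index(r.drl), Sex(r.sex).value, r.timepoint)
        se = 0.0 if pd.isna(r.se) else float(r.se)
        out[key] = UtilityItem(
            state_id=f"drl_{r.drl}_{r.sex}_{r.timepoint}", utility=float(r.utility), se=se
        )
    return out


def _load_utilities_events(path: Path) -> dict[str, UtilityItem]:
    df = pd.read_csv(path, comment="#")
    return {
        r.event: UtilityItem(
            state_id=r.event,
            utility=float(r.utility),
            se=0.0 if pd.isna(r.se) else float(r.se),
            family=r.family if isinstance(r.family, str) else "beta",
        )
        for r in df.itertuples()
    }


def _load_event_costs(path: Path) -> dict[tuple[str, str], CostItem]:
    df = pd.read_csv(path, comment="#")
    out: dict[tuple[str, str], CostItem] = {}
    for r in df.itertuples():
        mean = float(r.mean)
        fam = r.family
        if fam == "triangular":
            spec = DistributionSpec.triangular_clamped(mean, float(r.lo), float(r.hi))
            mean = spec.mean  # clamped mode is the point estimate used deterministically
        elif fam == "gamma":
            spec = DistributionSpec("gamma", mean, sd=float(r.sd))
        elif fam == "fixed":
            spec = DistributionSpec("fixed", mean)
        else:
            raise ValueError(f"{path}: unknown family {fam!r} for {r.event}/{r.cost_type}")
        out[(r.event, r.cost_type)] = CostItem(
            item_id=f"{r.event}_{r.cost_type}",
            category="direct_medical" if r.cost_type == "direct" else "productivity",
            mean=mean,
            spec=spec,
        )
    return out


def default_config_path() -> Path:
    return Path(resources.files("audcea").joinpath("data/config.yaml"))


def load_parameters(config_path: str | Path | None = None) -> tuple[ParameterSet, ModelConfig]:
    """Load and eagerly validate the full parameter set from a YAML config."""
    path = Path(config_path) if config_path is not None else default_config_path()
    if not path.exists():
        raise FileNotFoundError(f"config file {path} does not exist")
    with open(path) as fh:
        raw = yaml.safe_load(fh)

    base = path.parent
    tables = {k: base / v for k, v in raw.get("tables", {}).items()}
    required_tables = {
        "thresholds", "mortality", "risks", "utilities_drl",
        "utilities_events", "event_costs", "transitions", "baseline_distribution",
    }
    missing = required_tables - set(tables)
    if missing:
        raise ValueError(f"{path}: missing table entries {sorted(missing)}")

    model_raw = dict(raw.get("model", {}))
    if "discount_rate" not in model_raw:
        log.info("discount_rate not set; using default 0.03")
    config = ModelConfig(**model_raw)

    arms_raw = raw.get("arms", {})
    female_proportion: dict[str, float] = {}
    baseline_age: dict[str, float] = {}
    intervention_costs: dict[str, dict[str, float]] = {}
    for arm in ARMS:
        if arm not in arms_raw:
            raise ValueError(f"{path}: missing arm block {arm!r}")
        a = arms_raw[arm]
        p = float(a["female_proportion"])
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{path}: female_proportion for {arm} outside [0, 1]")
        female_proportion[arm] = p
        baseline_age[arm] = float(a["baseline_age"])
        comps = {k: float(v) for k, v in a["intervention_costs"].items()}
        if any(v < 0 for v in comps.values()):
            raise ValueError(f"{path}: negative intervention cost component for {arm}")
        intervention_costs[arm] = comps

    params = ParameterSet(
        thresholds=DrlThresholdTable.from_csv(tables["thresholds"]),
        short_term_transitions=_load_transitions(tables["transitions"]),
        baseline_drl=_load_baseline(tables["baseline_distribution"]),
        female_proportion=female_proportion,
        baseline_age=baseline_age,
        risks=RiskTable.from_csv(tables["risks"]),
        mortality=MortalityTable.from_csv(tables["mortality"]),
        utilities_drl=_load_utilities_drl(tables["utilities_drl"]),
        utilities_events=_load_utilities_events(tables["utilities_events"]),
        intervention_costs=intervention_costs,
        event_costs=_load_event_costs(tables["event_costs"]),
        scenarios=list(raw.get("scenarios", [])),
        source_files={k: str(v) for k, v in tables.items()} | {"config": str(path)},
    )
    if "utilities_drl_alt" in tables:
        params.source_files["utilities_drl_alt"] = str(tables["utilities_drl_alt"])
    log.info(
        "loaded parameters: %d risk items, %d DRL utility cells, %d event cost items",
        len(params.risks.items()), len(params.utilities_drl), len(params.event_costs),
    )
    return params, config


def load_default_parameters() -> tuple[ParameterSet, ModelConfig]:
    return load_parameters(default_config_path())
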