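"""Alcohol-attributable event risks and rate/probability conversions.

Per-person ("personal") risk of each alcohol-attributable event is the
product of the general-population annual incidence and the consumption-
level-specific relative risk:

    personal_risk(i, x) = population_risk(i) * relative_risk(i, x)

where i is the event and x the drinking-risk category. Register rates are
converted to per-cycle probabilities with the standard exponential
transform 1 - exp(-rate * t); inputs flagged as probabilities bypass the
exponential and are rescaled to the cycle length instead. Each event's
per-cycle probability is split into fatal and non-fatal parts by a case
fatality fraction, so event incidence is never double-counted between the
morbidity and mortality inputs. All-cause background mortality enters
separately from an age x sex life table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .drl import drl_to_medium_term_category
from .states import Drl, MediumTermRisk, PERMANENT_EVENTS, TEMPORARY_EVENTS, Sex


@dataclass(frozen=True)
class RiskItem:
    """Risk inputs for one (event, sex, risk-category) cell."""

    event: str
    sex: Sex
    risk_category: str  # "low"/"medium"/"high" (+"very_high" for temporary events)
    population_risk: float  # annual incidence: a rate >=0, or a probability if flagged
    relative_risk: float
    case_fatality: float = 0.0
    risk_is_probability: bool = False

    def __post_init__(self) -> None:
        if self.population_risk < 0 or not math.isfinite(self.population_risk):
            raise ValueError(f"{self.event}: population_risk must be finite and >= 0")
        if self.relative_risk <= 0 or not math.isfinite(self.relative_risk):
            raise ValueError(f"{self.event}: relative_risk must be finite and > 0")
        if not 0.0 <= self.case_fatality <= 1.0:
            raise ValueError(f"{self.event}: case_fatality must lie in [0, 1]")


class RiskTable:
    """Lookup of RiskItems keyed by (event, sex, risk_category)."""

    def __init__(self, items: list[RiskItem]):
        self._items: dict[tuple[str, str, str], RiskItem] = {}
        for it in items:
            key = (it.event, Sex(it.sex).value, it.risk_category)
            if key in self._items:
                raise ValueError(f"duplicate risk entry {key}")
            self._items[key] = it

    def lookup(self, event: str, sex: Sex, risk_category: str) -> RiskItem:
        key = (event, Sex(sex).value, risk_category)
        try:
            return self._items[key]
        except KeyError:
            raise KeyError(
                f"no risk entry for event={event!r}, sex={Sex(sex).value!r}, "
                f"risk_category={risk_category!r}"
            ) from None

    def items(self) -> list[RiskItem]:
        return list(self._items.values())

    @classmethod
    def from_csv(cls, path: str | Path) -> "RiskTable":
        df = pd.read_csv(path, comment="#")
        items = [
            RiskItem(
                event=r.event,
                sex=Sex(r.sex),
                risk_category=r.risk_category,
                population_risk=float(r.population_risk),
                relative_risk=float(r.relative_risk),
                case_fatality=float(r.case_fatality),
                risk_is_probability=bool(int(r.risk_is_probability)),
            )
            for r in df.itertuples()
        ]
        return cls(items)


class MortalityTable:
    """Annual all-cause death probability by integer age and sex."""

    def __init__(self, df: pd.DataFrame):
        required = {"age", "sex", "annual_death_probability"}
        if not required.issubset(df.columns):
            raise ValueError(f"mortality table must have columns {sorted(required)}")
        p = df["annual_death_probability"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("mortality probabilities must lie in [0, 1]")
        self._lookup = {
            (int(r.age), Sex(r.sex).value): float(r.annual_death_probability)
            for r in df.itertuples()
        }

    def annual_probability(self, age: float, sex: Sex) -> float:
        key = (int(math.floor(age)), Sex(sex).value)
        try:
            return self._lookup[key]
        except KeyError:
            raise KeyError(f"mortality table has no entry for age {key[0]}, sex {key[1]}") from None

    @classmethod
    def from_csv(cls, path: str | Path) -> "MortalityTable":
        return cls(pd.read_csv(path, comment="#"))


def personal_risk(population_risk: float, relative_risk: float) -> float:
    """Population incidence scaled by the consumption-specific relative risk."""
    if not math.isfinite(population_risk) or population_risk < 0:
        raise ValueError("population_risk must be finite and non-negative")
    if not math.isfinite(relative_risk) or relative_risk <= 0:
        raise ValueError("relative_risk must be finite and positive")
    return population_risk * relative_risk


def rate_to_probability(rate: float, t: float = 1.0) -> float:
    """Constant-hazard conversion of an annual rate to a t-year probability."""
    if rate < 0 or not math.isfinite(rate):
        raise ValueError("rate must be finite and non-negative")
    if t <= 0 or not math.isfinite(t):
        raise ValueError("t must be finite and positive")
    return -math.expm1(-rate * t)


def annual_to_cycle_probability(p_annual: float, cycle_years: float) -> float:
    """Rescale an annual probability to a shorter cycle assuming a constant hazard."""
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError("p_annual must lie in [0, 1]")
    if not 0.0 < cycle_years <= 1.0:
        raise ValueError("cycle_years must lie in (0, 1]")
    return 1.0 - (1.0 - p_annual) ** cycle_years


@dataclass
class StateEventProbs:
    """Per-cycle exit probabilities out of one DRL state."""

    p_nonfatal: dict[str, float] = field(default_factory=dict)
    p_fatal: dict[str, float] = field(default_factory=dict)
    p_death_allcause: float = 0.0

    @property
    def total_exit(self) -> float:
        return (
            self.p_death_allcause
            + sum(self.p_fatal.values())
            + sum(self.p_nonfatal.values())
        )


def event_probabilities_for_state(
    drl: Drl,
    sex: Sex,
    age: float,
    risks: RiskTable,
    mortality: MortalityTable,
    cycle_years: float,
) -> StateEventProbs:
    """Per-cycle event and death probabilities for one DRL state.

    Chronic (permanent-state) events are looked up under the three-tier
    medium-term category for this DRL; acute (tunnel) events under the
    four-tier DRL itself.
    """
    out = StateEventProbs()
    p_ann = mortality.annual_probability(age, sex)
    out.p_death_allcause = annual_to_cycle_probability(p_ann, min(cycle_years, 1.0))

    mt_cat = MediumTermRisk(drl_to_medium_term_category(drl)).name.lower()
    drl_cat = drl.name.lower()
    for event in PERMANENT_EVENTS + TEMPORARY_EVENTS:
        cat = mt_cat if event in PERMANENT_EVENTS else drl_cat
        item = risks.lookup(event, sex, cat)
        pr = personal_risk(item.population_risk, item.relative_risk)
        if item.risk_is_probability:
            if pr > 1.0:
                raise ValueError(
                    f"personal risk {pr:.4f} > 1 for probability-flagged event "
                    f"{event}/{Sex(sex).value}/{cat}"
                )
            p = annual_to_cycle_probability(pr, min(cycle_years, 1.0))
        else:
            p = rate_to_probability(pr, cycle_years)
        out.p_fatal[event] = p * item.case_fatality
        out.p_nonfatal[event] = p * (1.0 - item.case_fatality)

    if out.total_exit >= 1.0:
        raise ValueError(
            f"total exit probability {out.total_exit:.4f} >= 1 for "
            f"drl={drl.name}, sex={Sex(sex).value}, age={age}"
        )
    return out
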