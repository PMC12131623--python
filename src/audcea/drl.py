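"""WHO drinking-risk-level (DRL) classification.

Consumption enters the model as mean weekly standard drinks (Swedish
standard drink = 12 g pure alcohol) averaged over the 90 days preceding
the measurement; it is converted to grams of pure alcohol per day and
classified, sex-specifically, into the WHO risk tiers for temporary
complications (four tiers) and medium-term complications (three tiers).

Printed tier boundaries are integer-anchored (e.g. women 0–20 / 21–40 g);
because the daily average is continuous, tiers are realised as half-open
intervals on the real line — women temporary [0,20], (20,40], (40,60],
(60,∞); men [0,40], (40,60], (60,100], (100,∞) — preserving the printed
anchors while leaving no gram value unassigned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .states import Drl, MediumTermRisk, Sex

#: Grams of pure alcohol in one Swedish standard drink.
GRAMS_PER_DRINK_DEFAULT: float = 12.0

_TEMPORARY_TIERS = ("low", "medium", "high", "very_high")
_MEDIUM_TERM_TIERS = ("low", "medium", "high")


@dataclass(frozen=True)
class ConsumptionRecord:
    """One consumption measurement, in both native and classified units."""

    weekly_standard_drinks: float
    grams_per_day: float
    sex: Sex

    @classmethod
    def from_weekly_drinks(
        cls, weekly_drinks: float, sex: Sex, grams_per_drink: float = GRAMS_PER_DRINK_DEFAULT
    ) -> "ConsumptionRecord":
        return cls(
            weekly_standard_drinks=weekly_drinks,
            grams_per_day=grams_per_day_from_weekly_drinks(weekly_drinks, grams_per_drink),
            sex=sex,
        )


class DrlThresholdTable:
    """Sex-specific gram/day bounds for the temporary and medium-term tiers.

    Internally stores, per (sex, horizon), the ordered upper bounds of all
    tiers but the last; classification is a bisect over those cut points
    with the half-open convention (lower, upper] for every tier above the
    first, [0, upper] for the first.
    """

    def __init__(self, cuts: dict[tuple[str, str], list[float]]):
        for key, c in cuts.items():
            if any(b <= a for a, b in zip(c, c[1:])):
                raise ValueError(f"thresholds not strictly increasing for {key}: {c}")
        expected = {
            (sex.value, "temporary"): len(_TEMPORARY_TIERS) - 1 for sex in Sex
        } | {(sex.value, "medium_term"): len(_MEDIUM_TERM_TIERS) - 1 for sex in Sex}
        for key, n in expected.items():
            if key not in cuts or len(cuts[key]) != n:
                raise ValueError(f"threshold table missing or malformed for {key}")
        self._cuts = {k: tuple(v) for k, v in cuts.items()}

    def cut_points(self, sex: Sex, horizon: str) -> tuple[float, ...]:
        return self._cuts[(sex.value, horizon)]

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrlThresholdTable":
        df = pd.read_csv(path, comment="#")
        required = {"sex", "horizon", "tier", "lower_g", "upper_g"}
        if not required.issubset(df.columns):
            raise ValueError(f"threshold table {path} must have columns {sorted(required)}")
        cuts: dict[tuple[str, str], list[float]] = {}
        for (sex, horizon), grp in df.groupby(["sex", "horizon"]):
            grp = grp.sort_values("lower_g")
            uppers = grp["upper_g"].tolist()
            if not pd.isna(uppers[-1]) and not math.isinf(uppers[-1]):
                raise ValueError(f"top tier for ({sex}, {horizon}) must be unbounded (empty upper_g)")
            cuts[(sex, horizon)] = [float(u) for u in uppers[:-1]]
        return cls(cuts)

    @classmethod
    def default(cls) -> "DrlThresholdTable":
        """WHO tier bounds: women 20/40/60 g, men 40/60/100 g (temporary);
        women 20/40 g, men 40/60 g (medium-term)."""
        return cls(
            {
                ("female", "temporary"): [20.0, 40.0, 60.0],
                ("male", "temporary"): [40.0, 60.0, 100.0],
                ("female", "medium_term"): [20.0, 40.0],
                ("male", "medium_term"): [40.0, 60.0],
            }
        )


def grams_per_day_from_weekly_drinks(
    weekly_drinks: float, grams_per_drink: float = GRAMS_PER_DRINK_DEFAULT
) -> float:
    """Mean daily grams of pure alcohol from weekly standard drinks."""
    if not math.isfinite(weekly_drinks) or weekly_drinks < 0:
        raise ValueError(f"weekly_drinks must be finite and non-negative, got {weekly_drinks}")
    if not math.isfinite(grams_per_drink) or grams_per_drink <= 0:
        raise ValueError(f"grams_per_drink must be finite and positive, got {grams_per_drink}")
    return weekly_drinks * grams_per_drink / 7.0


def _classify(grams_per_day: float, cuts: tuple[float, ...]) -> int:
    if not math.isfinite(grams_per_day) or grams_per_day < 0:
        raise ValueError(f"grams_per_day must be finite and non-negative, got {grams_per_day}")
    tier = 0
    for cut in cuts:
        if grams_per_day > cut:
            tier += 1
        else:
            break
    return tier


def classify_temporary(
    grams_per_day: float, sex: Sex, thresholds: DrlThresholdTable | None = None
) -> Drl:
    """Four-tier DRL for temporary-complication risk."""
    thresholds = thresholds or DrlThresholdTable.default()
    return Drl(_classify(grams_per_day, thresholds.cut_points(Sex(sex), "temporary")))


def classify_medium_term(
    grams_per_day: float, sex: Sex, thresholds: DrlThresholdTable | None = None
) -> MediumTermRisk:
    """Three-tier risk category for medium-term (chronic) complications."""
    thresholds = thresholds or DrlThresholdTable.default()
    return MediumTermRisk(_classify(grams_per_day, thresholds.cut_points(Sex(sex), "medium_term")))


def drl_to_medium_term_category(drl: Drl) -> MediumTermRisk:
    """Collapse the 4-level model state onto the 3-level medium-term table.

    VERY_HIGH maps to HIGH — the only order-preserving surjection.
    """
    return MediumTermRisk(min(int(drl), int(MediumTermRisk.HIGH)))
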