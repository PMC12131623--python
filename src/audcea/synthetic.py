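"""Synthetic trial-data generator and input estimators.

The generator emulates the structure of the underlying two-arm RCT
(125 participants per arm; sex mix, age, and baseline weekly consumption
per arm matching the published baseline table): DRL trajectories at
12/26/52 weeks are sampled from known ground-truth transition matrices,
follow-up consumption is decorated within the occupied DRL's gram band,
EQ-5D-style utilities are anchored per DRL x sex x timepoint, and
missing-at-random dropout is applied at the published attrition rates
(which may depend on baseline DRL so imputation is non-trivial).

From such records the model's trial-derived inputs are estimated: the
three short-term transition matrices per arm, the baseline DRL
distribution, and the DRL x sex x timepoint utility table, after a
simplified chained-equation multiple imputation of the missing follow-ups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drl import DrlThresholdTable, classify_temporary, grams_per_day_from_weekly_drinks
from .params import ARMS, INTERVALS, TIMEPOINTS
from .states import Drl, Sex

log = logging.getLogger(__name__)

_ALL_TIMEPOINTS = ("baseline",) + TIMEPOINTS
#: Gram/day width drawn beyond the lower bound in the unbounded top band.
_TOP_BAND_SCALE = 15.0


def _default_utility_anchors() -> dict[tuple[int, str, str], float]:
    """Trial utility means per DRL x sex x timepoint (NA cells inherit HIGH)."""
    male = {
        "12wk": [0.850, 0.840, 0.842, 0.842],
        "26wk": [0.866, 0.867, 0.815, 0.815],
        "52wk": [0.890, 0.881, 0.833, 0.833],
    }
    female = {
        "12wk": [0.834, 0.857, 0.872, 0.795],
        "26wk": [0.836, 0.882, 0.815, 0.718],
        "52wk": [0.862, 0.897, 0.868, 0.868],
    }
    anchors: dict[tuple[int, str, str], float] = {}
    for tp in TIMEPOINTS:
        for d in range(4):
            anchors[(d, "male", tp)] = male[tp][d]
            anchors[(d, "female", tp)] = female[tp][d]
    return anchors


def _default_transitions() -> dict[str, list[np.ndarray]]:
    b = [
        np.array([[.92, .06, .02, 0], [.45, .45, .08, .02], [.25, .40, .30, .05], [.10, .30, .35, .25]]),
        np.array([[.90, .08, .02, 0], [.30, .55, .12, .03], [.15, .35, .40, .10], [.08, .22, .35, .35]]),
        np.array([[.90, .08, .02, 0], [.25, .60, .12, .03], [.12, .33, .45, .10], [.05, .20, .35, .40]]),
    ]
    m = [
        np.array([[.90, .08, .02, 0], [.40, .47, .10, .03], [.20, .40, .33, .07], [.08, .27, .37, .28]]),
        np.array([[.88, .09, .03, 0], [.27, .55, .14, .04], [.12, .35, .42, .11], [.06, .20, .36, .38]]),
        np.array([[.88, .09, .03, 0], [.22, .60, .14, .04], [.10, .33, .46, .11], [.04, .18, .36, .42]]),
    ]
    return {"BSCT": b, "MET": m}


@dataclass
class GeneratorConfig:
    """Study conditions the synthetic trial reproduces."""

    n_per_arm: int = 125
    female_proportion: dict[str, float] = field(
        default_factory=lambda: {"BSCT": 0.42, "MET": 0.54}
    )
    baseline_drinks: dict[str, tuple[float, float]] = field(  # mean, sd weekly drinks
        default_factory=lambda: {"BSCT": (23.65, 12.44), "MET": (24.34, 12.75)}
    )
    age: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"BSCT": (52.2, 11.4), "MET": (51.4, 10.7)}
    )
    sessions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"BSCT": (3.8, 1.4), "MET": (3.6, 1.3)}
    )
    transitions: dict[str, list[np.ndarray]] = field(default_factory=_default_transitions)
    utility_anchors: dict[tuple[int, str, str], float] = field(
        default_factory=_default_utility_anchors
    )
    utility_noise_sd: float = 0.05
    missingness: dict[str, tuple[float, float, float]] = field(  # per follow-up
        default_factory=lambda: {"BSCT": (0.15, 0.30, 0.40), "MET": (0.1667, 0.2778, 0.3889)}
    )
    mar_slope: float = 0.05  # missingness tilt per baseline-DRL step (mean-centred)
    grams_per_drink: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 0:
            raise ValueError("n_per_arm must be >= 0")
        for arm, p in self.female_proportion.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"female_proportion[{arm}] outside [0, 1]")
        for arm, rates in self.missingness.items():
            if any(not 0.0 <= r <= 1.0 for r in rates):
                raise ValueError(f"missingness[{arm}] outside [0, 1]")
        for arm, blocks in self.transitions.items():
            for k, m in enumerate(blocks):
                if np.abs(np.asarray(m).sum(axis=1) - 1.0).max() > 1e-8:
                    raise ValueError(f"transitions[{arm}][{k}] not row-stochastic")


def _band_bounds(sex: Sex, thresholds: DrlThresholdTable) -> list[tuple[float, float]]:
    cuts = thresholds.cut_points(sex, "temporary")
    bounds = [(0.0, cuts[0])]
    bounds += [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]
    bounds.append((cuts[-1], np.inf))
    return bounds


def _grams_in_band(drl: int, sex: Sex, thresholds: DrlThresholdTable, rng) -> float:
    lo, hi = _band_bounds(sex, thresholds)[drl]
    if np.isinf(hi):
        # open-ended top band: shifted exponential just above the bound
        return lo + 1e-9 + rng.exponential(_TOP_BAND_SCALE)
    # strictly inside (lo, hi] under the half-open convention
    return lo + (hi - lo) * rng.uniform(1e-9, 1.0)


def generate_trial(
    gc: GeneratorConfig, thresholds: DrlThresholdTable | None = None
) -> pd.DataFrame:
    """Simulate one synthetic trial; one row per participant."""
    thresholds = thresholds or DrlThresholdTable.default()
    rng = np.random.default_rng(gc.seed)
    rows = []
    pid = 0
    for arm in ARMS:
        n = gc.n_per_arm
        m_dr, s_dr = gc.baseline_drinks[arm]
        m_age, s_age = gc.age[arm]
        m_ses, s_ses = gc.sessions[arm]
        blocks = [np.asarray(b, dtype=float) for b in gc.transitions[arm]]
        for _ in range(n):
            sex = Sex.FEMALE if rng.random() < gc.female_proportion[arm] else Sex.MALE
            age = float(np.clip(rng.normal(m_age, s_age), 20.0, 80.0))
            drinks0 = max(rng.normal(m_dr, s_dr), 0.0)
            g0 = grams_per_day_from_weekly_drinks(drinks0, gc.grams_per_drink)
            drl = int(classify_temporary(g0, sex, thresholds))

            drinks = {"baseline": drinks0}
            noise0 = rng.normal(0.0, gc.utility_noise_sd) if gc.utility_noise_sd > 0 else 0.0
            # baseline utilities are generated (imputation covariate) but the
            # model itself starts at the 12-week utility block
            utils = {"baseline": min(gc.utility_anchors[(drl, sex.value, "12wk")] + noise0, 1.0)}
            for k, tp in enumerate(TIMEPOINTS):
                drl = int(rng.choice(4, p=blocks[k][drl]))
                g = _grams_in_band(drl, sex, thresholds, rng)
                drinks[tp] = g * 7.0 / gc.grams_per_drink
                noise = rng.normal(0.0, gc.utility_noise_sd) if gc.utility_noise_sd > 0 else 0.0
                utils[tp] = min(gc.utility_anchors[(drl, sex.value, tp)] + noise, 1.0)

            rows.append(
                {
                    "pid": pid,
                    "arm": arm,
                    "sex": sex.value,
                    "age": age,
                    "sessions_attended": int(np.clip(round(rng.normal(m_ses, s_ses)), 0, 12)),
                    **{f"drinks_{tp}": drinks[tp] for tp in _ALL_TIMEPOINTS},
                    **{f"util_{tp}": utils[tp] for tp in _ALL_TIMEPOINTS},
                }
            )
            pid += 1

    df = pd.DataFrame(rows)
    if df.empty:
        return df

    # MAR dropout: probability depends only on always-observed baseline DRL,
    # mean-centred within arm so the marginal rate matches the target.
    for arm in ARMS:
        sel = df["arm"] == arm
        if not sel.any():
            continue
        base_drl = np.array(
            [
                int(classify_temporary(
                    grams_per_day_from_weekly_drinks(d, gc.grams_per_drink), Sex(s), thresholds
                ))
                for d, s in zip(df.loc[sel, "drinks_baseline"], df.loc[sel, "sex"])
            ]
        )
        centred = base_drl - base_drl.mean()
        for k, tp in enumerate(TIMEPOINTS):
            rate = gc.missingness[arm][k]
            if rate == 0.0:
                p_miss = np.zeros(sel.sum())  # no dropout, no tilt
            else:
                p_miss = np.clip(rate + gc.mar_slope * centred, 0.0, 1.0)
            miss = rng.random(sel.sum()) < p_miss
            df.loc[sel, f"miss_{tp}"] = miss
            df.loc[df.index[sel][miss], [f"drinks_{tp}", f"util_{tp}"]] = np.nan
    for tp in TIMEPOINTS:
        df[f"miss_{tp}"] = df.get(f"miss_{tp}", False).astype(bool)
    return df


def _classified_drls(
    df: pd.DataFrame, thresholds: DrlThresholdTable, grams_per_drink: float = 12.0
) -> pd.DataFrame:
    """DRL (int, NaN where unobserved) per participant per timepoint."""
    out = pd.DataFrame(index=df.index)
    for tp in _ALL_TIMEPOINTS:
        vals = []
        for d, s in zip(df[f"drinks_{tp}"], df["sex"]):
            if pd.isna(d):
                vals.append(np.nan)
            else:
                vals.append(
                    int(classify_temporary(
                        grams_per_day_from_weekly_drinks(float(d), grams_per_drink),
                        Sex(s), thresholds,
                    ))
                )
        out[tp] = vals
    return out


def estimate_transitions(
    records: pd.DataFrame,
    thresholds: DrlThresholdTable | None = None,
    grams_per_drink: float = 12.0,
) -> dict[str, dict]:
    """Per-arm interval transition matrices from observed consecutive pairs.

    Rows with no observed pair fall back to identity with a warning;
    raw counts are returned for optional Dirichlet resampling.
    """
    thresholds = thresholds or DrlThresholdTable.default()
    out: dict[str, dict] = {}
    for arm in ARMS:
        sub = records[records["arm"] == arm]
        drls = _classified_drls(sub, thresholds, grams_per_drink)
        matrices, counts = [], []
        for k, interval in enumerate(INTERVALS):
            frm, to = _ALL_TIMEPOINTS[k], _ALL_TIMEPOINTS[k + 1]
            c = np.zeros((4, 4))
            ok = drls[frm].notna() & drls[to].notna()
            for i, j in zip(drls.loc[ok, frm].astype(int), drls.loc[ok, to].astype(int)):
                c[i, j] += 1
            m = np.zeros((4, 4))
            for i in range(4):
                tot = c[i].sum()
                if tot == 0:
                    log.warning("%s %s: no observed pairs from %s; identity fallback",
                                arm, interval, Drl(i).name)
                    m[i, i] = 1.0
                else:
                    m[i] = c[i] / tot
            matrices.append(m)
            counts.append(c)
        out[arm] = {"matrices": matrices, "counts": counts}
    return out


def estimate_baseline_distribution(
    records: pd.DataFrame,
    thresholds: DrlThresholdTable | None = None,
    grams_per_drink: float = 12.0,
) -> dict[tuple[str, str], np.ndarray]:
    """Baseline DRL occupancy per arm and sex (model entry distribution)."""
    thresholds = thresholds or DrlThresholdTable.default()
    out: dict[tuple[str, str], np.ndarray] = {}
    for arm in ARMS:
        for sex in Sex:
            sub = records[(records["arm"] == arm) & (records["sex"] == sex.value)]
            v = np.zeros(4)
            for d in sub["drinks_baseline"]:
                v[int(classify_temporary(
                    grams_per_day_from_weekly_drinks(float(d), grams_per_drink), sex, thresholds
                ))] += 1
            if v.sum() == 0:
                raise ValueError(f"no participants for {arm}/{sex.value}")
            out[(arm, sex.value)] = v / v.sum()
    return out


_IMPUTABLE = [f"drinks_{tp}" for tp in TIMEPOINTS] + [f"util_{tp}" for tp in TIMEPOINTS]


def impute_missing(
    records: pd.DataFrame, m: int = 5, seed: int = 0, n_sweeps: int = 10
) -> list[pd.DataFrame]:
    """Simplified chained-equation multiple imputation.

    Each variable with missing values is regressed linearly on all other
    covariates (arm and sex indicators, age, baseline consumption and
    utility, and the other follow-up variables at their current fill) over
    its originally observed rows; missing cells are replaced by draws from
    the predictive distribution. Sweeps cycle a fixed number of times; the
    whole procedure repeats m times with independent seeds.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    base_cov = ["age", "drinks_baseline", "util_baseline"]
    df0 = records.copy()
    df0["_arm_num"] = (df0["arm"] == "BSCT").astype(float)
    df0["_sex_num"] = (df0["sex"] == "female").astype(float)
    covariates = base_cov + ["_arm_num", "_sex_num"]

    targets = [v for v in _IMPUTABLE if v in df0.columns and df0[v].isna().any()]
    for v in targets:
        if df0[v].isna().all():
            raise ValueError(f"variable {v!r} has no observed values to impute from")

    streams = np.random.SeedSequence(seed).spawn(m)
    completed: list[pd.DataFrame] = []
    for rep in range(m):
        rng = np.random.default_rng(streams[rep])
        df = df0.copy()
        observed_mask = {v: records[v].notna().to_numpy() for v in targets}
        for v in targets:  # initial fill: observed mean
            df[v] = df[v].fillna(df[v].mean())
        for _ in range(n_sweeps if targets else 0):
            for v in targets:
                preds = covariates + [w for w in _IMPUTABLE if w in df.columns and w != v]
                X = df[preds].to_numpy(dtype=float)
                X = np.column_stack([np.ones(len(X)), X])
                y = df[v].to_numpy(dtype=float)
                obs = observed_mask[v]
                beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
                resid = y[obs] - X[obs] @ beta
                dof = max(obs.sum() - X.shape[1], 1)
                sigma = float(np.sqrt((resid @ resid) / dof))
                mis = ~obs
                draw = X[mis] @ beta + rng.normal(0.0, sigma, mis.sum())
                if v.startswith("drinks_"):
                    draw = np.maximum(draw, 0.0)
                else:
                    draw = np.minimum(draw, 1.0)
                y[mis] = draw
                df[v] = y
        completed.append(df.drop(columns=["_arm_num", "_sex_num"]))
    return completed


def estimate_utilities(
    completed_sets: list[pd.DataFrame],
    thresholds: DrlThresholdTable | None = None,
    grams_per_drink: float = 12.0,
) -> pd.DataFrame:
    """DRL x sex x timepoint utility means pooled over imputed sets.

    Cells never occupied in any set are returned as NaN (the trial's 'NA').
    """
    thresholds = thresholds or DrlThresholdTable.default()
    acc: dict[tuple[int, str, str], list[float]] = {}
    ns: dict[tuple[int, str, str], list[int]] = {}
    for df in completed_sets:
        drls = _classified_drls(df, thresholds, grams_per_drink)
        for tp in TIMEPOINTS:
            for sex in Sex:
                sel = (df["sex"] == sex.value) & drls[tp].notna()
                for d in range(4):
                    cell = sel & (drls[tp] == d)
                    key = (d, sex.value, tp)
                    if cell.any():
                        acc.setdefault(key, []).append(float(df.loc[cell, f"util_{tp}"].mean()))
                        ns.setdefault(key, []).append(int(cell.sum()))
    rows = []
    for tp in TIMEPOINTS:
        for sex in Sex:
            for d in range(4):
                key = (d, sex.value, tp)
                rows.append(
                    {
                        "drl": Drl(d).name.lower(),
                        "sex": sex.value,
                        "timepoint": tp,
                        "utility": float(np.mean(acc[key])) if key in acc else np.nan,
                        "n": int(np.mean(ns[key])) if key in ns else 0,
                    }
                )
    return pd.DataFrame(rows)
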