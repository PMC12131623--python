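"""Synthetic trial generation, input estimation, and imputation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from audcea import (
    GeneratorConfig,
    Sex,
    classify_temporary,
    estimate_baseline_distribution,
    estimate_transitions,
    estimate_utilities,
    generate_trial,
    grams_per_day_from_weekly_drinks,
    impute_missing,
)
from audcea.params import TIMEPOINTS


@pytest.fixture(scope="module")
def default_trial():
    return generate_trial(GeneratorConfig(seed=42))


@pytest.fixture(scope="module")
def clean_trial():
    """Noise-free, fully observed trial."""
    gc = GeneratorConfig(
        seed=7, utility_noise_sd=0.0,
        missingness={"BSCT": (0, 0, 0), "MET": (0, 0, 0)},
    )
    return gc, generate_trial(gc)


class TestGenerateTrial:
    def test_empty_for_zero_participants(self):
        assert generate_trial(GeneratorConfig(n_per_arm=0, seed=1)).empty

    def test_default_size_and_schema(self, default_trial):
        df = default_trial
        assert len(df) == 250
        assert set(df["arm"]) == {"BSCT", "MET"}
        for tp in ("baseline",) + TIMEPOINTS:
            assert f"drinks_{tp}" in df and f"util_{tp}" in df
        assert df["drinks_baseline"].notna().all()
        assert df["util_baseline"].notna().all()
        assert (df["drinks_baseline"] >= 0).all()
        assert (df[[f"util_{tp}" for tp in TIMEPOINTS]].max() <= 1.0).all()

    def test_missingness_fractions_near_targets(self):
        gc = GeneratorConfig(seed=5, n_per_arm=2000)
        df = generate_trial(gc)
        for arm in ("BSCT", "MET"):
            sub = df[df["arm"] == arm]
            for k, tp in enumerate(TIMEPOINTS):
                frac = sub[f"drinks_{tp}"].isna().mean()
                assert frac == pytest.approx(gc.missingness[arm][k], abs=0.03)

    def test_reproducible_under_seed(self):
        a = generate_trial(GeneratorConfig(seed=11))
        b = generate_trial(GeneratorConfig(seed=11))
        pd.testing.assert_frame_equal(a, b)

    def test_followup_consumption_consistent_with_sampled_drl(self, clean_trial):
        """Decorated gram values classify back into the trajectory's DRL band,
        so estimator round-trips are exact."""
        gc, df = clean_trial
        anchors = gc.utility_anchors
        for _, row in df.head(50).iterrows():
            for tp in TIMEPOINTS:
                g = grams_per_day_from_weekly_drinks(row[f"drinks_{tp}"])
                d = int(classify_temporary(g, Sex(row["sex"])))
                # noise-free utilities identify the generating DRL exactly
                assert row[f"util_{tp}"] == pytest.approx(anchors[(d, row["sex"], tp)])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_per_arm=-1)
        with pytest.raises(ValueError):
            GeneratorConfig(missingness={"BSCT": (0.5, 0.5, 1.5), "MET": (0, 0, 0)})


class TestEstimateTransitions:
    def test_counting_on_handcrafted_records(self, thresholds):
        # two participants stay low; two move low -> medium (male bands: low<=40g/d)
        rows = []
        for pid, dest in enumerate([10.0, 10.0, 30.0, 30.0]):
            rows.append(
                {
                    "pid": pid, "arm": "BSCT", "sex": "male", "age": 50,
                    "drinks_baseline": 10.0,
                    "drinks_12wk": dest * 7 / 12, "drinks_26wk": np.nan, "drinks_52wk": np.nan,
                    "util_baseline": 0.9, "util_12wk": 0.9,
                    "util_26wk": np.nan, "util_52wk": np.nan,
                }
            )
        # destination 10 g/d stays LOW; 30 g/d would still be LOW for males...
        rows[2]["drinks_12wk"] = 45.0 * 7 / 12  # MEDIUM (40 < g <= 60)
        rows[3]["drinks_12wk"] = 45.0 * 7 / 12
        df = pd.DataFrame(rows)
        est = estimate_transitions(df, thresholds)
        m = est["BSCT"]["matrices"][0]
        assert m[0, 0] == pytest.approx(0.5)
        assert m[0, 1] == pytest.approx(0.5)
        assert est["BSCT"]["counts"][0][0].sum() == 4

    def test_sparse_rows_fall_back_to_identity(self, thresholds, caplog):
        df = pd.DataFrame(
            [
                {
                    "pid": 0, "arm": "BSCT", "sex": "male", "age": 50,
                    "drinks_baseline": 5.0, "drinks_12wk": 5.0,
                    "drinks_26wk": 5.0, "drinks_52wk": 5.0,
                    "util_baseline": 0.9, "util_12wk": 0.9, "util_26wk": 0.9, "util_52wk": 0.9,
                },
                {
                    "pid": 1, "arm": "MET", "sex": "male", "age": 50,
                    "drinks_baseline": 5.0, "drinks_12wk": 5.0,
                    "drinks_26wk": 5.0, "drinks_52wk": 5.0,
                    "util_baseline": 0.9, "util_12wk": 0.9, "util_26wk": 0.9, "util_52wk": 0.9,
                },
            ]
        )
        est = estimate_transitions(df, thresholds)
        for arm in ("BSCT", "MET"):
            for m in est[arm]["matrices"]:
                assert np.allclose(m.sum(axis=1), 1.0)
                assert m[3, 3] == 1.0  # never-observed row is identity

    def test_recovery_of_ground_truth_at_large_n(self, thresholds):
        gc = GeneratorConfig(
            seed=3, n_per_arm=4000, utility_noise_sd=0.0,
            missingness={"BSCT": (0, 0, 0), "MET": (0, 0, 0)},
        )
        df = generate_trial(gc)
        est = estimate_transitions(df, thresholds)
        for arm in ("BSCT", "MET"):
            for k in range(3):
                truth = gc.transitions[arm][k]
                m = est[arm]["matrices"][k]
                counts = est[arm]["counts"][k]
                for i in range(4):
                    n = counts[i].sum()
                    if n < 30:
                        continue
                    for j in range(4):
                        se = np.sqrt(max(truth[i, j] * (1 - truth[i, j]), 1e-12) / n)
                        assert abs(m[i, j] - truth[i, j]) <= 3 * se + 1e-9


class TestImputation:
    def test_no_missing_is_identity(self, clean_trial):
        _, df = clean_trial
        for completed in impute_missing(df, m=3, seed=1):
            pd.testing.assert_frame_equal(
                completed.reset_index(drop=True), df.reset_index(drop=True)
            )

    def test_observed_values_preserved(self, default_trial):
        completed = impute_missing(default_trial, m=2, seed=9)
        for c in completed:
            for tp in TIMEPOINTS:
                col = f"util_{tp}"
                obs = default_trial[col].notna()
                assert np.allclose(c.loc[obs, col], default_trial.loc[obs, col])
                assert c[col].notna().all()

    def test_requested_number_of_sets(self, default_trial):
        assert len(impute_missing(default_trial, m=5, seed=2)) == 5

    def test_all_missing_variable_rejected(self, default_trial):
        df = default_trial.copy()
        df["util_52wk"] = np.nan
        with pytest.raises(ValueError, match="util_52wk"):
            impute_missing(df, m=1, seed=0)

    def test_imputation_less_biased_than_complete_case(self):
        """Under DRL-dependent dropout, pooled imputed utility means sit closer
        to the complete-data truth than complete-case means (averaged over reps)."""
        gains = []
        for rep in range(20):
            gc_full = GeneratorConfig(
                seed=1000 + rep, n_per_arm=250, mar_slope=0.12,
                missingness={"BSCT": (0, 0, 0), "MET": (0, 0, 0)},
            )
            full = generate_trial(gc_full)
            gc_miss = GeneratorConfig(seed=1000 + rep, n_per_arm=250, mar_slope=0.12)
            miss = generate_trial(gc_miss)
            truth = full["util_52wk"].mean()
            cc = miss["util_52wk"].mean()  # complete-case
            pooled = np.mean([c["util_52wk"].mean() for c in impute_missing(miss, 3, rep)])
            gains.append(abs(cc - truth) - abs(pooled - truth))
        assert np.mean(gains) > 0


class TestEstimateUtilities:
    def test_single_participant_cell(self, thresholds):
        df = pd.DataFrame(
            [
                {
                    "pid": 0, "arm": "BSCT", "sex": "male", "age": 50,
                    "drinks_baseline": 5.0, "drinks_12wk": 5.0,
                    "drinks_26wk": 5.0, "drinks_52wk": 5.0,
                    "util_baseline": 0.9, "util_12wk": 0.9, "util_26wk": 0.9, "util_52wk": 0.9,
                }
            ]
        )
        table = estimate_utilities([df], thresholds)
        cell = table[(table.drl == "low") & (table.sex == "male") & (table.timepoint == "52wk")]
        assert cell["utility"].iloc[0] == pytest.approx(0.9)
        # unoccupied cells are NA, mirroring the trial's empty tiers
        vh = table[(table.drl == "very_high") & (table.sex == "male")]
        assert vh["utility"].isna().all()

    def test_noise_free_recovery_of_anchors(self, clean_trial):
        gc, df = clean_trial
        table = estimate_utilities([df])
        for _, row in table.iterrows():
            if np.isnan(row["utility"]):
                continue
            d = ["low", "medium", "high", "very_high"].index(row["drl"])
            assert row["utility"] == pytest.approx(
                gc.utility_anchors[(d, row["sex"], row["timepoint"])], abs=1e-12
            )


class TestBaselineDistribution:
    def test_probabilities_sum_to_one(self, default_trial):
        dist = estimate_baseline_distribution(default_trial)
        for v in dist.values():
            assert v.sum() == pytest.approx(1.0)
            assert (v >= 0).all()
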