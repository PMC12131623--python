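"""Uncertainty distributions and the paired probabilistic sensitivity analysis."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from audcea import (
    ArmResult,
    DistributionSpec,
    beta_from_moments,
    ce_plane_and_ceac,
    gamma_from_moments,
    run_psa,
    sample_parameter_set,
    sample_triangular,
    uncertainty_interval,
)
from audcea.economics import incremental
from audcea.psa import PsaDraws


class TestBetaFromMoments:
    def test_closed_form_on_published_utility(self):
        # hemorrhagic-stroke utility: mean 0.45, SE 0.03
        a, b = beta_from_moments(0.45, 0.03)
        k = 0.45 * 0.55 / 0.03**2 - 1
        assert a == pytest.approx(0.45 * k)
        assert b == pytest.approx(0.55 * k)
        assert a == pytest.approx(123.30, abs=0.01)
        assert b == pytest.approx(150.70, abs=0.01)

    def test_moment_recovery_by_simulation(self, rng):
        a, b = beta_from_moments(0.45, 0.03)
        x = rng.beta(a, b, 10**6)
        assert x.mean() == pytest.approx(0.45, abs=3 * 0.03 / 1000)
        assert x.std() == pytest.approx(0.03, rel=0.01)

    def test_infeasible_se_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            beta_from_moments(0.5, 0.6)

    def test_degenerate_se_falls_back_to_point_mass(self, rng):
        spec = DistributionSpec("beta", 0.5, se=1e-15)
        assert spec.sample(rng) == 0.5


class TestGammaFromMoments:
    def test_closed_form_on_published_cost(self):
        # cirrhosis productivity loss: mean 15328.40, SD 31654.95
        shape, scale = gamma_from_moments(15328.40, 31654.95)
        assert shape == pytest.approx((15328.40 / 31654.95) ** 2)
        assert scale == pytest.approx(31654.95**2 / 15328.40)
        assert shape * scale == pytest.approx(15328.40, rel=1e-12)

    def test_sd_equal_mean_is_exponential(self):
        shape, _ = gamma_from_moments(100.0, 100.0)
        assert shape == pytest.approx(1.0)

    def test_moment_recovery_by_simulation(self, rng):
        shape, scale = gamma_from_moments(15328.40, 31654.95)
        x = rng.gamma(shape, scale, 10**6)
        se = 31654.95 / 1000
        assert x.mean() == pytest.approx(15328.40, abs=3 * se)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            gamma_from_moments(-1.0, 2.0)


class TestTriangular:
    def test_inverse_cdf_left_branch(self):
        assert sample_triangular(0.5, 0, 1, 0.125) == pytest.approx(0.25)

    def test_degenerate_min_equals_mode(self):
        assert sample_triangular(0.0, 0.0, 2.0, 1.0) == pytest.approx(2.0)
        assert sample_triangular(0.0, 0.0, 2.0, 0.0) == pytest.approx(0.0)

    def test_mean_recovery_by_simulation(self, rng):
        lo, mode, hi = 6897.99, 14416.13, 31978.39
        x = sample_triangular(mode, lo, hi, rng.random(10**6))
        expected = (lo + mode + hi) / 3
        assert x.mean() == pytest.approx(expected, abs=3 * x.std() / 1000)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            sample_triangular(5.0, 10.0, 1.0, 0.5)

    def test_mode_clamped_with_warning(self, caplog):
        spec = DistributionSpec.triangular_clamped(14416.73, 6897.99, 14416.13)
        assert spec.mean == pytest.approx(14416.13)


class TestUncertaintyInterval:
    def test_linear_interpolation_convention(self):
        samples = np.arange(1, 1001, dtype=float)
        lo, hi = uncertainty_interval(samples)
        assert lo == pytest.approx(np.percentile(samples, 2.5))
        assert hi == pytest.approx(np.percentile(samples, 97.5))

    def test_constant_samples_collapse(self):
        assert uncertainty_interval([3.0, 3.0, 3.0]) == (3.0, 3.0)

    def test_symmetric_samples_symmetric_interval(self, rng):
        v = rng.normal(0, 1, 5000)
        x = np.concatenate([v, -v])
        lo, hi = uncertainty_interval(x)
        assert lo == pytest.approx(-hi, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            uncertainty_interval([1.0])


class TestSampling:
    def test_fixed_items_untouched(self, params, rng):
        sampled = sample_parameter_set(params, rng)
        # fixed-cost items keep their point estimates
        for key, item in params.event_costs.items():
            if item.spec.family == "fixed":
                assert sampled.event_costs[key].mean == item.mean

    def test_uncertain_items_move(self, params, rng):
        sampled = sample_parameter_set(params, rng)
        moved = sum(
            sampled.event_costs[k].mean != params.event_costs[k].mean
            for k in params.event_costs
        )
        assert moved > 0
        assert all(
            sampled.utilities_events[e].utility != params.utilities_events[e].utility
            for e in params.utilities_events
        )

    def test_base_params_not_mutated(self, params, rng):
        before = {k: v.mean for k, v in params.event_costs.items()}
        sample_parameter_set(params, rng)
        assert {k: v.mean for k, v in params.event_costs.items()} == before


class TestRunPsa:
    def _all_fixed(self, params):
        fixed_drl = {
            k: dataclasses.replace(v, se=0.0) for k, v in params.utilities_drl.items()
        }
        fixed_ev = {
            k: dataclasses.replace(v, se=0.0, family="fixed")
            for k, v in params.utilities_events.items()
        }
        fixed_costs = {
            k: dataclasses.replace(v, spec=DistributionSpec("fixed", v.mean))
            for k, v in params.event_costs.items()
        }
        return dataclasses.replace(
            params, utilities_drl=fixed_drl, utilities_events=fixed_ev, event_costs=fixed_costs
        )

    def test_degenerate_psa_reproduces_base_case(self, params, config):
        from audcea import run_base_case

        p = self._all_fixed(params)
        draws = run_psa(p, config, seed=1, n_iterations=5)
        base = run_base_case(p, config)
        for arm in ("BSCT", "MET"):
            for r in draws.arm_results[arm]:
                assert r.qalys == pytest.approx(base["arms"][arm].qalys, rel=1e-12)
                assert r.total_societal_cost == pytest.approx(
                    base["arms"][arm].total_societal_cost, rel=1e-12
                )

    def test_degenerate_interval_collapses_to_point(self, params, config):
        p = self._all_fixed(params)
        draws = run_psa(p, config, seed=1, n_iterations=10)
        qs = [r.qalys for r in draws.arm_results["BSCT"]]
        lo, hi = uncertainty_interval(qs)
        assert lo == pytest.approx(hi)

    def test_seed_determinism(self, params, config):
        d1 = run_psa(params, config, seed=7, n_iterations=20)
        d2 = run_psa(params, config, seed=7, n_iterations=20)
        for a, b in zip(d1.incrementals, d2.incrementals):
            assert a.delta_societal_cost == b.delta_societal_cost
            assert a.delta_qalys == b.delta_qalys

    def test_pairing_shares_parameters_within_iteration(self, params, config, rng):
        """Both arms see identical sampled parameters (common random draws)."""
        sampled = sample_parameter_set(params, rng)
        from audcea import evaluate_arm

        r1 = evaluate_arm("BSCT", sampled, config)
        r2 = evaluate_arm("MET", sampled, config)
        # re-evaluating either arm on the same sampled set is bit-identical
        assert evaluate_arm("BSCT", sampled, config).qalys == r1.qalys
        assert evaluate_arm("MET", sampled, config).qalys == r2.qalys


def _draws_from_pairs(pairs):
    draws = PsaDraws()
    for dq, dc in pairs:
        b = ArmResult("BSCT", 0.0, 0.0, 0.0, 1.0 + dq)
        m = ArmResult("MET", -dc, 0.0, 0.0, 1.0)
        draws.arm_results["BSCT"].append(b)
        draws.arm_results["MET"].append(m)
        draws.incrementals.append(incremental(b, m))
    return draws


class TestCeacLogic:
    def test_southeast_quadrant_gives_certain_cost_effectiveness(self):
        draws = _draws_from_pairs([(0.05, -100.0), (0.02, -40.0), (0.07, -5.0)])
        _, ceac = ce_plane_and_ceac(draws, [1e-9, 1000, 50000, 200000])
        assert (ceac["probability"] == 1.0).all()

    def test_step_at_icer_for_identical_northeast_draws(self):
        draws = _draws_from_pairs([(0.05, 500.0)] * 10)
        icer = 500.0 / 0.05
        _, ceac = ce_plane_and_ceac(draws, [icer - 1, icer + 1])
        assert ceac["probability"].tolist() == [0.0, 1.0]

    def test_ceac_non_decreasing_when_all_gains_positive(self, rng):
        pairs = [(float(q), float(c)) for q, c in
                 zip(rng.uniform(0.01, 0.1, 50), rng.normal(0, 300, 50))]
        draws = _draws_from_pairs(pairs)
        _, ceac = ce_plane_and_ceac(draws, np.linspace(0, 100000, 21))
        assert (np.diff(ceac["probability"]) >= 0).all()

    def test_plane_points_exported_verbatim(self):
        pairs = [(0.01, -5.0), (0.02, 7.0)]
        draws = _draws_from_pairs(pairs)
        plane, _ = ce_plane_and_ceac(draws, [0.0])
        assert plane["delta_qaly"].tolist() == pytest.approx([0.01, 0.02])
        assert plane["delta_cost"].tolist() == pytest.approx([-5.0, 7.0])
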