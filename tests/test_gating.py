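"""Scaling, density-minimum gating and subgroup co-expression statistics."""

import numpy as np
import pandas as pd
import pytest

from subelim._rng import spawn
from subelim.cytometry import NoValleyError, gate, normalize_scale, subgroup_stats


def _table(values, condition="control", prefix="comp_"):
    return pd.DataFrame({"condition": condition, f"{prefix}ch": values})


class TestNormalizeScale:
    def test_reference_mean_equals_scale_constant(self):
        rng = spawn(0, "norm")
        table = _table(rng.lognormal(4, 0.5, 500))
        out = normalize_scale(table, "control", channels=["ch"])
        assert out["scaled_ch"].mean() == pytest.approx(1.0, abs=1e-9)
        out2 = normalize_scale(table, "control", channels=["ch"], scale_constant=1000)
        assert out2["scaled_ch"].mean() == pytest.approx(1000.0, abs=1e-6)

    def test_all_equal_intensities_become_the_constant(self):
        out = normalize_scale(_table(np.full(10, 42.0)), "control", channels=["ch"])
        np.testing.assert_allclose(out["scaled_ch"], 1.0)

    def test_condition_ratio_preserved(self):
        rng = spawn(1, "norm")
        ctrl = _table(rng.lognormal(4, 0.3, 400))
        stim = _table(1.8 * rng.lognormal(4, 0.3, 400), condition="stim")
        table = pd.concat([ctrl, stim], ignore_index=True)
        out = normalize_scale(table, "control", channels=["ch"])
        by_cond = out.groupby("condition")["scaled_ch"].mean()
        assert by_cond["stim"] / by_cond["control"] == pytest.approx(1.8, rel=0.05)

    def test_idempotent_after_first_application(self):
        rng = spawn(2, "norm")
        table = _table(rng.lognormal(4, 0.5, 300))
        once = normalize_scale(table, "control", channels=["ch"])
        twice = normalize_scale(once, "control", channels=["ch"],
                                in_prefix="scaled_", out_prefix="scaled_")
        assert np.max(np.abs(twice["scaled_ch"] - once["scaled_ch"])) < 1e-12

    def test_missing_reference_condition_rejected(self):
        with pytest.raises(ValueError, match="reference condition"):
            normalize_scale(_table(np.ones(5)), "unstimulated", channels=["ch"])

    def test_odd_scale_constant_rejected(self):
        with pytest.raises(ValueError, match="scale_constant"):
            normalize_scale(_table(np.ones(5)), "control", channels=["ch"], scale_constant=7)


def _bimodal(rng, n, weight, lo=100.0, hi=1500.0, sigma=0.45):
    pos = rng.random(n) < weight
    return np.where(pos, rng.lognormal(np.log(hi), sigma, n),
                    rng.lognormal(np.log(lo), sigma, n)), pos


class TestGate:
    def test_symmetric_mixture_splits_at_half(self):
        rng = spawn(3, "gate")
        values, _ = _bimodal(rng, 6000, 0.5)
        res = gate(values, method="density_minimum")
        # threshold near the geometric midpoint of the two modes
        assert np.sqrt(100 * 1500) * 0.6 < res.threshold < np.sqrt(100 * 1500) * 1.7
        assert res.percent_positive == pytest.approx(50.0, abs=2.0)

    def test_naive_culture_positive_fraction_recovered(self):
        # 44% positives among 8453 neurons, generator defaults
        rng = spawn(4, "gate")
        values, pos = _bimodal(rng, 8453, 0.44)
        res = gate(values, method="density_minimum")
        assert res.percent_positive == pytest.approx(44.0, abs=2.0)
        assert res.ci_low < res.percent_positive < res.ci_high

    def test_unimodal_distribution_raises_no_valley(self):
        rng = spawn(5, "gate")
        with pytest.raises(NoValleyError, match="fixed threshold"):
            gate(rng.lognormal(4, 0.4, 2000), method="density_minimum")

    def test_fixed_threshold_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            gate(np.linspace(1, 2, 200), method="fixed", fixed_threshold=5.0)

    def test_density_gate_needs_enough_values(self):
        with pytest.raises(ValueError, match="100"):
            gate(np.ones(50), method="density_minimum")

    def test_gating_bias_below_one_point_over_replicate_simulations(self):
        # 200 simulations, n = 3000, mode separation 4 log-SD, weight 0.45
        recovered = []
        for i in range(200):
            rng = spawn(6, "bias", i)
            sigma = 0.45
            values, _ = _bimodal(rng, 3000, 0.45, lo=100.0,
                                 hi=100.0 * np.exp(4 * sigma), sigma=sigma)
            recovered.append(gate(values, method="density_minimum").percent_positive)
        assert abs(np.mean(recovered) - 45.0) < 1.0


class TestSubgroupStats:
    def test_identical_channels_coexpress_fully(self):
        rng = spawn(7, "stats")
        values, _ = _bimodal(rng, 3000, 0.4)
        table = pd.DataFrame({"experiment": "e1", "scaled_a": values, "scaled_b": values})
        g = gate(values, method="density_minimum")
        out = subgroup_stats(table, "a", "b", g, g)
        assert out["percent_b_given_a"] == 100.0
        assert out["intensity_ratio_b_in_a"] > 1.0

    def test_independent_gates_follow_product_law(self):
        rng = spawn(8, "stats")
        a_vals, a_pos = _bimodal(rng, 12000, 0.4)
        b_vals, b_pos = _bimodal(rng, 12000, 0.25)
        table = pd.DataFrame({"experiment": "e1", "scaled_a": a_vals, "scaled_b": b_vals})
        ga = gate(a_vals, method="density_minimum")
        gb = gate(b_vals, method="density_minimum")
        out = subgroup_stats(table, "a", "b", ga, gb)
        # under independence, P(B+|A+) ~ P(B+); 3 binomial SE on ~4800 A+ cells
        se = 100 * np.sqrt(0.25 * 0.75 / ga.n_positive)
        assert abs(out["percent_b_given_a"] - out["percent_positive_b"]) < 3 * se

    def test_rare_marker_coexpression_with_positive_subgroup(self):
        # CART-like marker: 2.9% of neurons, 79% of them TRPV1(+)
        from subelim.population import PopulationConfig, make_population
        from subelim.simulate import simulate_single_cell_table

        pop = make_population(PopulationConfig.from_neurons(11091), seed=9)
        table, _ = simulate_single_cell_table(pop, seed=10)
        table["scaled_ch2"] = table["true_ch2"]
        table["scaled_ch3"] = table["true_ch3"]
        g2 = gate(table["scaled_ch2"], method="density_minimum")
        g3 = gate(table["scaled_ch3"], method="density_minimum")
        out = subgroup_stats(table, "ch3", "ch2", g3, g2)
        assert g3.percent_positive == pytest.approx(2.9, abs=0.5)
        n_cart = g3.n_positive
        se = 100 * np.sqrt(0.79 * 0.21 / n_cart)
        assert abs(out["percent_b_given_a"] - 79.0) < 3 * se

    def test_paired_test_across_experiments(self):
        rng = spawn(11, "stats")
        frames = []
        for exp in ("e1", "e2", "e3"):
            a_vals, a_pos = _bimodal(rng, 2000, 0.4)
            b_vals = np.where(a_pos, rng.lognormal(np.log(500), 0.3, 2000),
                              rng.lognormal(np.log(200), 0.3, 2000))
            frames.append(pd.DataFrame({"experiment": exp, "scaled_a": a_vals, "scaled_b": b_vals}))
        table = pd.concat(frames, ignore_index=True)
        ga = gate(table["scaled_a"], method="density_minimum")
        gb = gate(table["scaled_b"], method="fixed", fixed_threshold=320.0)
        out = subgroup_stats(table, "a", "b", ga, gb)
        assert out["paired_t_p"] is not None and out["paired_t_p"] < 0.05
        assert out["intensity_ratio_b_in_a"] == pytest.approx(2.5, rel=0.2)
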