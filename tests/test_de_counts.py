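"""Sequencing branch: size factors, RPKM, normalization, NB exact test."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from subelim._rng import spawn
from subelim.containers import CountMatrix
from subelim.de import (
    compute_rpkm,
    estimate_size_factors,
    filter_expressed_rpkm,
    nbinom_exact_test,
    normalize_counts,
)
from subelim.de.counts import _exact_split_pvalue


def _count_matrix(counts, conditions=None, lengths=None, gc=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"g{i}" for i in range(len(counts))]
    counts.columns = [f"s{j}" for j in range(counts.shape[1])]
    n = len(counts)
    if lengths is None:
        lengths = pd.Series(1000, index=counts.index)
    if gc is None:
        gc = pd.Series(0.5, index=counts.index)
    if conditions is None:
        half = counts.shape[1] // 2
        conditions = ["control"] * half + ["depleted"] * (counts.shape[1] - half)
    return CountMatrix(counts, lengths, gc, pd.Series(conditions, index=counts.columns))


class TestSizeFactors:
    def test_doubled_sample_splits_the_ratio_geometrically(self):
        counts = pd.DataFrame({"a": [10, 20, 40], "b": [20, 40, 80]})
        sf = estimate_size_factors(counts)
        assert sf["a"] == pytest.approx(2**-0.5, abs=1e-12)
        assert sf["b"] == pytest.approx(2**0.5, abs=1e-12)

    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 9, 3], "b": [5, 9, 3], "c": [5, 9, 3]})
        np.testing.assert_allclose(estimate_size_factors(counts), 1.0)

    def test_scaling_equivariance(self):
        rng = spawn(0, "sf")
        base = pd.DataFrame(rng.poisson(100, size=(200, 3)), columns=list("abc")) + 1
        sf0 = estimate_size_factors(base)
        scaled = base.copy()
        scaled["b"] = base["b"] * 4
        sf1 = estimate_size_factors(scaled)
        # ratios to the geometric mean shift by 4 for b, constant otherwise
        assert sf1["b"] / sf0["b"] * (sf1["a"] / sf0["a"]) ** -1 == pytest.approx(4.0, rel=1e-9)

    def test_needs_a_fully_observed_gene(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="all-positive"):
            estimate_size_factors(counts)


class TestRpkm:
    def test_direct_arithmetic(self):
        counts = pd.DataFrame({"s": [200]}, index=["g"])
        lengths = pd.Series([2000], index=["g"])
        totals = pd.Series([10_000_000], index=["s"])
        assert compute_rpkm(counts, lengths, totals).iloc[0, 0] == pytest.approx(10.0)

    def test_zero_count_gives_zero(self):
        counts = pd.DataFrame({"s": [0]}, index=["g"])
        assert compute_rpkm(counts, pd.Series([500], index=["g"]),
                            pd.Series([1e6], index=["s"])).iloc[0, 0] == 0.0

    def test_homogeneity_in_depth(self):
        counts = pd.DataFrame({"s": [300]}, index=["g"])
        lengths = pd.Series([1500], index=["g"])
        a = compute_rpkm(counts, lengths, pd.Series([1e6], index=["s"]))
        b = compute_rpkm(2 * counts, lengths, pd.Series([2e6], index=["s"]))
        pd.testing.assert_frame_equal(a, b)

    def test_expression_filter_is_strict(self):
        rpkm = pd.DataFrame({"s1": [0.1, 0.2, 0.05], "s2": [0.1, 0.3, 0.05]},
                            index=["boundary", "kept", "weak"])
        kept = filter_expressed_rpkm(rpkm, 0.1)
        assert list(kept) == ["kept"]

    def test_constructed_fraction_below_threshold(self):
        rng = spawn(1, "rpkm")
        values = np.concatenate([rng.uniform(0.001, 0.05, 30), rng.uniform(0.5, 50, 70)])
        rpkm = pd.DataFrame({"s": values})
        assert len(filter_expressed_rpkm(rpkm, 0.1)) == 70


class TestNormalizeCounts:
    def _matrix_with_gc_trend(self, slope, n_genes=1000, seed=2):
        rng = spawn(seed, "gc")
        gc = pd.Series(rng.uniform(0.3, 0.7, n_genes))
        mu = 200 * np.exp(slope * (gc - 0.5))
        counts = pd.DataFrame(
            {f"s{j}": rng.poisson(mu) for j in range(4)}
        )
        gc.index = counts.index = [f"g{i}" for i in range(n_genes)]
        return _count_matrix(counts, gc=gc)

    def test_gc_independent_counts_are_nearly_unchanged(self):
        cm = self._matrix_with_gc_trend(0.0)
        out = normalize_counts(cm)
        rel = np.abs(out.counts.to_numpy() - cm.counts.to_numpy()) / (cm.counts.to_numpy() + 1)
        assert np.median(rel) < 0.05

    def test_injected_gc_trend_removed(self):
        cm = self._matrix_with_gc_trend(3.0)
        out = normalize_counts(cm)
        log_c = np.log(out.counts.iloc[:, 0].to_numpy() + 0.5)
        slope = np.polyfit(cm.gc.to_numpy(), log_c - log_c.mean(), 1)[0]
        assert abs(slope) < 0.05 * 3.0 / 0.4  # flat within 5% of the injected trend

    def test_identical_lanes_pass_through(self):
        rng = spawn(3, "gc")
        col = rng.poisson(150, 500)
        counts = pd.DataFrame({"a": col, "b": col})
        cm = _count_matrix(counts, gc=pd.Series(rng.uniform(0.3, 0.7, 500),
                                                index=[f"g{i}" for i in range(500)]))
        out = normalize_counts(cm)
        pd.testing.assert_series_equal(
            out.counts.iloc[:, 0], out.counts.iloc[:, 1], check_names=False
        )

    def test_few_genes_skip_loess_with_warning(self):
        cm = _count_matrix(np.ones((50, 2), dtype=int) * 7)
        with pytest.warns(UserWarning, match="skipping GC loess"):
            out = normalize_counts(cm)
        np.testing.assert_array_equal(out.counts.to_numpy(), 7)


def _brute_force_p(k_a, k_b, mean_a, var_a, mean_b, var_b):
    """Independent oracle: linear-space enumeration over all splits of S."""

    def pmf(k, mean, var):
        if var <= mean:
            return stats.poisson.pmf(k, mean)
        r = mean**2 / (var - mean)
        return stats.nbinom.pmf(k, r, r / (r + mean))

    total = k_a + k_b
    probs = np.array([pmf(a, mean_a, var_a) * pmf(total - a, mean_b, var_b)
                      for a in range(total + 1)])
    observed = probs[k_a]
    return probs[probs <= observed * (1 + 1e-9)].sum() / probs.sum()


class TestExactTest:
    def test_balanced_split_is_null(self):
        cm = _count_matrix([[10, 10]], conditions=["control", "depleted"])
        res = nbinom_exact_test(cm, size_factors=pd.Series([1.0, 1.0], index=cm.samples))
        assert res.table["p_value"].iloc[0] == pytest.approx(1.0)

    def test_poisson_split_of_six_matches_enumeration(self):
        # S = 6 under equal means and zero dispersion: all 7 splits enumerated
        p = _exact_split_pvalue(1, 5, 3.0, 3.0, 3.0, 3.0)
        assert p == pytest.approx(_brute_force_p(1, 5, 3.0, 3.0, 3.0, 3.0), abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_for_small_totals(self, seed):
        # exact equality against brute force for condition sums <= 30
        rng = spawn(seed, "exact")
        k_a = int(rng.integers(0, 16))
        k_b = int(rng.integers(0, 31 - k_a))
        if k_a + k_b == 0:
            k_a = 1
        mean_a = rng.uniform(0.5, 12)
        mean_b = rng.uniform(0.5, 12)
        alpha = rng.uniform(0, 0.5)
        var_a = mean_a + alpha * mean_a**2
        var_b = mean_b + alpha * mean_b**2
        p = _exact_split_pvalue(k_a, k_b, mean_a, var_a, mean_b, var_b)
        assert p == pytest.approx(
            _brute_force_p(k_a, k_b, mean_a, var_a, mean_b, var_b), abs=1e-10
        )

    def test_scaling_counts_and_size_factors_together(self):
        rng = spawn(5, "scale")
        counts = rng.poisson(40, size=(50, 4))
        cm1 = _count_matrix(counts)
        sf1 = pd.Series(1.0, index=cm1.samples)
        disp = pd.Series(0.05, index=cm1.genes)
        res1 = nbinom_exact_test(cm1, size_factors=sf1, dispersions=disp)
        cm2 = _count_matrix(counts * 2)
        sf2 = pd.Series(2.0, index=cm2.samples)
        res2 = nbinom_exact_test(cm2, size_factors=sf2, dispersions=disp)
        # base means and fold-changes are exactly scale-invariant
        np.testing.assert_allclose(res1.table["base_mean"], res2.table["base_mean"])
        np.testing.assert_allclose(res1.table["fold_change"], res2.table["fold_change"])
        # p-values follow the same conditional law at the doubled total
        log_ratio = np.log(res2.table["p_value"] / res1.table["p_value"])
        assert np.median(np.abs(log_ratio)) < 0.35

    def test_all_zero_gene_flagged(self):
        cm = _count_matrix([[0, 0, 0, 0], [5, 6, 4, 5]])
        res = nbinom_exact_test(cm, size_factors=pd.Series(1.0, index=cm.samples))
        assert bool(res.table["all_zero"].iloc[0])
        assert res.table["p_value"].iloc[0] == 1.0

    def test_detects_a_strong_depletion_signal(self):
        rng = spawn(6, "power")
        control = rng.poisson(200, size=(1, 3))
        depleted = rng.poisson(40, size=(1, 3))
        null = rng.poisson(100, size=(30, 6))
        counts = np.vstack([np.hstack([control, depleted]), null])
        cm = _count_matrix(counts, conditions=["control"] * 3 + ["depleted"] * 3)
        sf = pd.Series(1.0, index=cm.samples)
        # blind (condition-pooled) dispersion is deliberately conservative
        # for differential genes, but a 5x change still reaches significance
        blind = nbinom_exact_test(cm, size_factors=sf)
        assert blind.table["p_value"].iloc[0] < 0.05
        # with the true (small) dispersion supplied, the evidence is strong
        known = nbinom_exact_test(
            cm, size_factors=sf, dispersions=pd.Series(0.01, index=cm.genes)
        )
        assert known.table["p_value"].iloc[0] < 1e-6
        assert known.table["fold_change"].iloc[0] == pytest.approx(5.0, rel=0.3)
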