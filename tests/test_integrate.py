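"""Cross-platform merge, concordance, ranking, and overlap enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from subelim._rng import spawn
from subelim.integrate import (
    MergedPlatforms,
    concordance,
    merge_platforms,
    overlap_enrichment,
    rank_table,
)


def _stats(genes, fc, adjp, rpkm=None):
    out = pd.DataFrame({"gene": genes, "fold_change": fc, "adj_p": adjp})
    if rpkm is not None:
        out["rpkm"] = rpkm
    return out.set_index("gene")


class TestMergePlatforms:
    def test_single_platform_significance_qualifies(self):
        arr = _stats(["g1", "g2"], [2.0, 1.1], [0.01, 0.5])
        seq = _stats(["g1", "g3"], [1.2, 0.4], [0.8, 0.001], rpkm=[5.0, 9.0])
        merged = merge_platforms(arr, seq)
        assert merged.table.loc["g1", "candidate"]  # array qualifies
        assert merged.table.loc["g1", "direction"] == "up_in_subgroup"
        assert merged.table.loc["g3", "candidate"]  # seq qualifies, down
        assert merged.table.loc["g3", "direction"] == "down_in_subgroup"
        assert not merged.table.loc["g2", "candidate"]
        assert merged.n_up == 1 and merged.n_down == 1

    def test_fold_change_cut_is_strict(self):
        arr = _stats(["g"], [1.5], [0.001])
        seq = _stats(["g"], [1.0], [0.9], rpkm=[1.0])
        assert not merge_platforms(arr, seq).table.loc["g", "candidate"]

    def test_discordant_genes_excluded_and_counted(self):
        arr = _stats(["g"], [2.0], [0.01])
        seq = _stats(["g"], [0.4], [0.01], rpkm=[1.0])
        merged = merge_platforms(arr, seq)
        assert merged.n_discordant == 1
        assert not merged.table.loc["g", "candidate"]

    def test_duplicate_probes_collapse_to_best_adjusted_p(self):
        arr = pd.DataFrame(
            {"gene": ["g", "g"], "fold_change": [1.2, 3.0], "adj_p": [0.5, 0.001]},
            index=["probeA", "probeB"],
        )
        seq = _stats(["g"], [2.0], [0.2], rpkm=[1.0])
        merged = merge_platforms(arr, seq)
        assert merged.table.loc["g", "fc_array"] == 3.0

    def test_symmetric_in_platform_content(self):
        arr = _stats(["g1", "g2"], [2.0, 0.5], [0.01, 0.01])
        seq = _stats(["g2", "g1"], [0.5, 2.0], [0.01, 0.01], rpkm=[1.0, 1.0])
        merged = merge_platforms(arr, seq)
        assert merged.n_up == 1 and merged.n_down == 1 and merged.n_discordant == 0

    def test_recovers_simulated_truth_on_both_platforms(self):
        # 100 clearly enriched genes with noisy FC/p on both platforms
        rng = spawn(7, "merge")
        n_genes, n_true = 800, 100
        genes = [f"g{i}" for i in range(n_genes)]
        true = np.zeros(n_genes, dtype=bool)
        true[rng.choice(n_genes, n_true, replace=False)] = True
        factors = np.where(true, rng.uniform(3, 10, n_genes), 1.0)

        def platform(noise_seed):
            noise = spawn(noise_seed, "platform").normal(0, 0.15, n_genes)
            fc = factors * 2**noise
            p = np.where(true, rng.uniform(0, 1e-4, n_genes), rng.uniform(0.05, 1, n_genes))
            return _stats(genes, fc, p, rpkm=np.full(n_genes, 5.0))

        merged = merge_platforms(platform(1), platform(2))
        recovered = merged.candidates("up_in_subgroup").index
        assert np.isin(np.array(genes)[true], recovered).sum() >= 90


class TestConcordance:
    def test_identical_and_reversed_orders(self):
        fc = [1.2, 2.0, 3.5, 0.4, 5.0]
        rho, _ = concordance(fc, fc, n_permutations=200, seed=0)
        assert rho == pytest.approx(1.0)
        rho, _ = concordance(fc, [-v for v in fc], n_permutations=200, seed=0)
        assert rho == pytest.approx(-1.0)

    def test_gaussian_copula_correlation_recovered(self):
        # target rho = 0.66 at n = 110, Fisher-z sampling error
        rng = spawn(8, "copula")
        n, rho = 110, 0.66
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        fc = np.exp(xy)  # monotone map: Spearman rho preserved
        est, p = concordance(fc[:, 0], fc[:, 1], n_permutations=2000, seed=1)
        z = np.arctanh
        assert abs(z(est) - z(rho)) < 3 / np.sqrt(n - 3)
        assert p < 0.01

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError, match=">= 3"):
            concordance([1, 2], [1, 2])


def _brute_force_hypergeom(k, big_n, big_k, n):
    total = math.comb(big_n, n)
    return sum(
        math.comb(big_k, i) * math.comb(big_n - big_k, n - i)
        for i in range(k, min(n, big_k) + 1)
    ) / total


class TestOverlapEnrichment:
    def test_empty_overlap_is_certain(self):
        res = overlap_enrichment(["a", "b"], ["c", "d"], universe_size=100)
        assert res.overlap == 0 and res.p_value == 1.0

    def test_worked_example(self):
        # N=10, K=5, n=4, k=3 -> 55/210
        cand = ["r1", "r2", "r3", "x1"]
        ref = ["r1", "r2", "r3", "r4", "r5"]
        res = overlap_enrichment(cand, ref, universe_size=10)
        assert res.p_value == pytest.approx(55 / 210, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_for_small_universes(self, seed):
        rng = spawn(seed, "hyper")
        big_n = int(rng.integers(10, 61))
        big_k = int(rng.integers(1, big_n))
        n = int(rng.integers(1, big_n))
        universe = [f"u{i}" for i in range(big_n)]
        ref = list(rng.choice(universe, big_k, replace=False))
        cand = list(rng.choice(universe, n, replace=False))
        res = overlap_enrichment(cand, ref, universe_size=big_n)
        assert res.p_value == pytest.approx(
            _brute_force_hypergeom(res.overlap, big_n, big_k, n), abs=1e-12
        )

    def test_p_monotone_decreasing_in_overlap(self):
        ps = []
        ref = [f"r{i}" for i in range(20)]
        for k in range(0, 10):
            cand = ref[:k] + [f"x{i}" for i in range(10 - k)]
            ps.append(overlap_enrichment(cand, ref, universe_size=200).p_value)
        assert all(b <= a for a, b in zip(ps, ps[1:]))

    def test_orthologue_screen_overlap(self):
        # 6 shared genes between 235 candidates and a 580-gene screen in a
        # 22777-gene universe is no more than chance expectation (p ~ 0.56)
        ref = [f"screen{i}" for i in range(574)] + list("ABCDEF")
        cand = [f"cand{i}" for i in range(229)] + list("ABCDEF")
        res = overlap_enrichment(cand, ref)
        assert res.overlap == 6
        assert res.expected_overlap == pytest.approx(235 * 580 / 22777)
        assert res.p_value == pytest.approx(0.56, abs=0.02)

    def test_reference_larger_than_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_enrichment(["a"], [f"r{i}" for i in range(50)], universe_size=10)


class TestRankTable:
    def _merged(self, table):
        up = int((table["direction"] == "up_in_subgroup").sum())
        return MergedPlatforms(table=table, n_up=up, n_down=0, n_discordant=0)

    def test_empty_candidates_give_empty_report(self):
        table = pd.DataFrame(
            columns=["fc_array", "fc_seq", "adjp_array", "adjp_seq", "rpkm",
                     "candidate", "discordant", "direction"]
        )
        assert rank_table(self._merged(table)).empty

    def test_leading_order_by_best_platform_fold_change(self):
        table = pd.DataFrame(
            {
                "fc_array": [11.6, 11.0],
                "fc_seq": [7.5, 8.9],
                "adjp_array": [6.1e-7, 1.9e-7],
                "adjp_seq": [4.6e-26, 3.7e-38],
                "rpkm": [19.5, 9.9],
                "candidate": True,
                "discordant": False,
                "direction": "up_in_subgroup",
            },
            index=["Iapp", "Cartpt"],
        )
        ranked = rank_table(self._merged(table))
        assert list(ranked.index) == ["Iapp", "Cartpt"]

    def test_weakly_expressed_genes_filtered(self):
        table = pd.DataFrame(
            {
                "fc_array": [3.0, 2.0],
                "fc_seq": [np.nan, 2.0],
                "adjp_array": [0.001, 0.001],
                "adjp_seq": [np.nan, 0.001],
                "rpkm": [0.4, 2.0],
                "candidate": True,
                "discordant": False,
                "direction": "up_in_subgroup",
            },
            index=["weak", "kept"],
        )
        ranked = rank_table(self._merged(table))
        assert list(ranked.index) == ["kept"]
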