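import itertools
import math

import numpy as np
import pandas as pd
import pytest

from synerdeg import Contrast, SimConfig, generate_factorial
from synerdeg.rankprod import estimate_pfp, pairwise_lfc, rank_product

from conftest import make_matrix


def brute_force_rank_products(values, treat_cols, ctrl_cols, direction):
    """Independent oracle: explicit loop over every replicate pair, ranking
    fold changes by sorting (assumes no ties)."""
    n = values.shape[0]
    log_rp = np.zeros(n)
    n_pairs = 0
    for t in treat_cols:
        for c in ctrl_cols:
            lfc = values[:, t] - values[:, c]
            order = np.argsort(-lfc if direction == "up" else lfc)
            ranks = np.empty(n)
            for pos, g in enumerate(order):
                ranks[g] = pos + 1
            log_rp += np.log(ranks)
            n_pairs += 1
    return np.exp(log_rp / n_pairs)


class TestPairwiseLfc:
    def test_one_vs_one_is_column_difference(self):
        m = make_matrix([[1.0, 4.0], [2.0, 2.5]], conditions=["mock", "AB"])
        lfc = pairwise_lfc(m, Contrast("c", ["AB_1"], ["mock_1"]))
        assert np.array_equal(lfc.to_numpy().ravel(), [3.0, 0.5])

    def test_four_vs_four_yields_sixteen_comparisons(self):
        matrix, _, _ = generate_factorial(SimConfig(n_genes=10, seed=0))
        c = Contrast("c", matrix.samples_for("AB"), matrix.samples_for("mock"))
        assert pairwise_lfc(matrix, c).shape == (10, 16)

    def test_zero_noise_gene_gives_constant_pairwise_lfc(self):
        cfg = SimConfig(n_genes=20, noise_sd=0.0, seed=1,
                        class_fractions={"null": 0.5, "a_only": 0.5},
                        effect_ranges={**SimConfig().effect_ranges,
                                       "single": (3.0, 3.0)})
        matrix, truth, _ = generate_factorial(cfg)
        c = Contrast("c", matrix.samples_for("A"), matrix.samples_for("mock"))
        lfc = pairwise_lfc(matrix, c)
        planted = truth.loc[truth.gene_class == "a_only", "gene_id"]
        vals = lfc.loc[planted].to_numpy()
        assert np.allclose(np.abs(vals), 3.0, atol=1e-12)

    def test_overlapping_sample_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            Contrast("c", ["x", "y"], ["y", "z"])


class TestRankProduct:
    def test_gene_most_extreme_everywhere_has_rp_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (6, 4))
        x[0, 2:] += 100  # top-ranked in every AB-vs-mock pair
        m = make_matrix(x, conditions=["mock", "mock", "AB", "AB"])
        rp = rank_product(m, Contrast("c", ["AB_1", "AB_2"],
                                      ["mock_1", "mock_2"]), "up")
        assert rp.iloc[0] == 1.0

    def test_ranks_one_and_four_give_rp_two(self):
        # gene g1: rank 1 in the first comparison, rank 4 in the second
        values = np.array([
            [0.0, 0.0, 10.0, 1.0],
            [0.0, 0.0, 9.0, 2.0],
            [0.0, 0.0, 8.0, 3.0],
            [0.0, 0.0, 7.0, 4.0],
        ])
        m = make_matrix(values, conditions=["mock", "mock", "AB", "AB"])
        # use the two comparisons against mock_1 only (1 control replicate)
        rp = rank_product(m, Contrast("c", ["AB_1", "AB_2"], ["mock_1"]), "up")
        assert rp.loc["g1"] == pytest.approx(math.sqrt(1 * 4), abs=1e-12)

    def test_matches_brute_force_enumeration_two_vs_two(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (5, 4))
        m = make_matrix(x, conditions=["mock", "mock", "AB", "AB"])
        contrast = Contrast("c", ["AB_1", "AB_2"], ["mock_1", "mock_2"])
        for direction in ("up", "down"):
            got = rank_product(m, contrast, direction).to_numpy()
            want = brute_force_rank_products(x, [2, 3], [0, 1], direction)
            assert np.allclose(got, want, atol=1e-12)

    def test_all_tied_comparison_warns_and_uses_average_ranks(self):
        m = make_matrix([[5.0, 5.0], [3.0, 3.0]], conditions=["mock", "AB"])
        with pytest.warns(UserWarning, match="tied"):
            rp = rank_product(m, Contrast("c", ["AB_1"], ["mock_1"]), "up")
        assert np.array_equal(rp.to_numpy(), [1.5, 1.5])


class TestEstimatePfp:
    def test_direction_symmetry_under_negation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (30, 8))
        m = make_matrix(x, conditions=["mock"] * 4 + ["AB"] * 4)
        mneg = make_matrix(-x, conditions=["mock"] * 4 + ["AB"] * 4)
        c = Contrast("c", [f"AB_{i}" for i in range(1, 5)],
                     [f"mock_{i}" for i in range(1, 5)])
        r = estimate_pfp(m, c, n_permutations=50, seed=9)
        rneg = estimate_pfp(mneg, c, n_permutations=50, seed=9)
        assert np.array_equal(r["rp_up"], rneg["rp_down"])
        assert np.array_equal(r["pfp_up"], rneg["pfp_down"])
        assert np.array_equal(r["rp_down"], rneg["rp_up"])
        assert np.array_equal(r["pfp_down"], rneg["pfp_up"])

    def test_constant_sample_shift_leaves_rp_and_pfp_unchanged(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (25, 4))
        shifted = x.copy()
        shifted[:, 3] += 7.5  # plate/array offset on one treatment sample
        conds = ["mock", "mock", "AB", "AB"]
        c = Contrast("c", ["AB_1", "AB_2"], ["mock_1", "mock_2"])
        r1 = estimate_pfp(make_matrix(x, conditions=conds), c,
                          n_permutations=40, seed=1)
        r2 = estimate_pfp(make_matrix(shifted, conditions=conds), c,
                          n_permutations=40, seed=1)
        for col in ("rp_up", "rp_down", "pfp_up", "pfp_down"):
            assert np.array_equal(r1[col], r2[col])

    def test_dominant_gene_has_zero_pfp_at_top_rank(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 0.2, (50, 8))
        x[0, 4:] += 50.0
        m = make_matrix(x, conditions=["mock"] * 4 + ["AB"] * 4)
        c = Contrast("c", [f"AB_{i}" for i in range(1, 5)],
                     [f"mock_{i}" for i in range(1, 5)])
        r = estimate_pfp(m, c, n_permutations=100, seed=0)
        assert r["rp_up"].iloc[0] == 1.0
        assert r["pfp_up"].iloc[0] == 0.0

    def test_exact_mode_matches_full_joint_permutation_enumeration(self):
        # independent oracle: enumerate every combination of within-comparison
        # permutations of a 4-gene, 2-vs-1 instance ((4!)^2 = 576 joints)
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, (4, 3))
        m = make_matrix(x, conditions=["mock", "AB", "AB"])
        c = Contrast("c", ["AB_1", "AB_2"], ["mock_1"])
        res = estimate_pfp(m, c, exact=True)

        lfc = np.column_stack([x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]])
        n, k = lfc.shape
        obs_ranks = np.empty_like(lfc)
        for j in range(k):
            obs_ranks[np.argsort(-lfc[:, j]), j] = np.arange(1, n + 1)
        obs_prod = obs_ranks.prod(axis=1)

        all_perms = list(itertools.permutations(range(1, n + 1)))
        joint_products = []
        for combo in itertools.product(all_perms, repeat=k):
            for g in range(n):
                joint_products.append(math.prod(p[g] for p in combo))
        joint_products = np.sort(joint_products)
        n_joints = len(all_perms) ** k

        order = np.argsort(obs_prod)
        efp = np.searchsorted(joint_products, obs_prod[order],
                              side="right") / n_joints
        pfp_sorted = np.minimum(
            np.maximum.accumulate(efp / np.arange(1, n + 1)), 1.0)
        expected = np.empty(n)
        expected[order] = pfp_sorted
        assert np.allclose(res["pfp_up"].to_numpy(), expected, atol=1e-12)

    def test_monotone_pfp_along_sorted_rank_products(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, (60, 8))
        m = make_matrix(x, conditions=["mock"] * 4 + ["AB"] * 4)
        c = Contrast("c", [f"AB_{i}" for i in range(1, 5)],
                     [f"mock_{i}" for i in range(1, 5)])
        r = estimate_pfp(m, c, n_permutations=60, seed=2)
        for direction in ("up", "down"):
            s = r.sort_values(f"rp_{direction}")[f"pfp_{direction}"].to_numpy()
            assert (np.diff(s) >= 0).all()
            assert (s >= 0).all() and (s <= 1).all()

    def test_low_permutation_count_warns_about_resolution(self):
        m = make_matrix([[1.0, 2.0], [3.0, 1.0]], conditions=["mock", "AB"])
        with pytest.warns(UserWarning, match="resolution"):
            estimate_pfp(m, Contrast("c", ["AB_1"], ["mock_1"]),
                         n_permutations=5, seed=0)

    def test_planted_effects_outrank_null_genes(self, recovery_run):
        # effect >= 3 log2 at noise 0.25: planted up-responders sit below the
        # 1st percentile of the null rank-product distribution
        truth = recovery_run.truth.set_index("gene_id")
        rp = recovery_run.rankprod["AB_vs_mock"]
        null_rp = rp.loc[rp.index.intersection(
            truth.index[truth.gene_class == "null"]), "rp_up"]
        planted = rp.index.intersection(truth.index[truth.true_lfc_ab >= 3.0])
        frac = (rp.loc[planted, "rp_up"] < null_rp.quantile(0.01)).mean()
        assert frac >= 0.99
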