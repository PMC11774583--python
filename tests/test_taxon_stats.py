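"""Sign tests, weighted Welch t-tests, Holm correction, centroids, ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import codivscan as cs
from codivscan.taxon_stats import (
    genus_unique_branch_length,
    pairwise_phylum_tests,
)

from test_scan import brute_force_holm


class TestSignTest:
    def test_twelve_of_fifteen(self):
        assert cs.sign_test(12, 15) == pytest.approx(0.0176, abs=5e-5)

    def test_all_successes(self):
        assert cs.sign_test(15, 15) == pytest.approx(0.5**15)

    def test_zero_successes_full_tail(self):
        assert cs.sign_test(0, 15) == 1.0

    def test_complementarity(self):
        # P(X >= k) + P(X <= k-1) = 1 for every k
        n = 15
        for k in range(1, n + 1):
            upper = cs.sign_test(k, n)
            lower = float(stats.binom.cdf(k - 1, n, 0.5))
            assert upper + lower == pytest.approx(1.0)

    def test_two_sided_option(self):
        assert cs.sign_test(99, 156, alternative="two-sided") == pytest.approx(
            0.000966, abs=2e-6
        )

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            cs.sign_test(5, 4)


class TestWeightedTTest:
    def test_equal_weights_reduce_to_welch(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 2, 14)
        t, p = cs.weighted_t_test(a, np.ones(10), b, np.ones(14))
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_identical_groups(self):
        vals, w = [0.1, 0.4, 0.7], [1.0, 2.0, 3.0]
        t, p = cs.weighted_t_test(vals, w, vals, w)
        assert t == 0.0 and p == 1.0

    def test_weight_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        wa, wb = rng.uniform(0.5, 3, 8), rng.uniform(0.5, 3, 9)
        t1, p1 = cs.weighted_t_test(a, wa, b, wb)
        t2, p2 = cs.weighted_t_test(a, 2 * wa, b, 2 * wb)
        assert t1 == pytest.approx(t2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_degenerate_groups_raise(self):
        with pytest.raises(ValueError):
            cs.weighted_t_test([1.0], [1.0], [1.0, 2.0], [1.0, 1.0])


class TestHolm:
    def test_single_value(self):
        assert cs.holm_correction([0.05]) == [pytest.approx(0.05)]

    def test_hand_step_down(self):
        assert cs.holm_correction([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 25))
            np.testing.assert_allclose(cs.holm_correction(p), brute_force_holm(p), rtol=1e-12)

    def test_holm_at_least_bh(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.001, 1.0, 20)
        holm = np.asarray(cs.holm_correction(p))
        bh = np.asarray(cs.adjust_bh(p))
        assert (holm >= bh - 1e-12).all()

    def test_output_at_least_input(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.001, 1.0, 15)
        assert (np.asarray(cs.holm_correction(p)) >= p - 1e-12).all()


class TestCentroids:
    def make_report(self, r_values, weights, genera):
        clades, results = {}, []
        tips_rows = []
        for k, ((rp, rg), w, g) in enumerate(zip(r_values, weights, genera)):
            nid = f"n{k}"
            tip = f"t{k}"
            clades[nid] = cs.CladeSpec(nid, (tip,), 0.0, w, None)
            results.append(
                cs.CladeTestResult(nid, 1, 2, 2, rp, 0.01, 0.01, rg, 0.5, 0.5, rp - rg, "none")
            )
            tips_rows.append([tip, "H", "G", "S", "PhyA", g])
        tips = pd.DataFrame(
            tips_rows,
            columns=["tip_id", "host_taxon_id", "host_genus", "site_id", "phylum", "genus"],
        )
        return cs.ScanReport(results, clades, cs.ScanParams(), 1.0, {}, {}), tips

    def test_equal_weights_equal_arithmetic_mean(self):
        report, tips = self.make_report(
            [(0.2, 0.1), (0.8, 0.3)], [1.0, 1.0], ["g1", "g1"]
        )
        out = cs.weighted_centroids(report, tips, "genus")
        assert out.loc[0, "weighted_mean_r_phylo"] == pytest.approx(0.5)

    def test_single_node_group(self):
        report, tips = self.make_report([(0.42, -0.1)], [2.0], ["g1"])
        out = cs.weighted_centroids(report, tips, "genus")
        assert out.loc[0, "weighted_mean_r_phylo"] == pytest.approx(0.42)
        assert out.loc[0, "weighted_mean_r_geo"] == pytest.approx(-0.1)

    def test_hand_weighted_mean(self):
        report, tips = self.make_report(
            [(0.2, 0.0), (0.8, 0.0)], [1.0, 3.0], ["g1", "g1"]
        )
        out = cs.weighted_centroids(report, tips, "genus")
        assert out.loc[0, "weighted_mean_r_phylo"] == pytest.approx(0.65)

    def test_centroid_in_convex_hull(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-1, 1, size=(6, 2))
        report, tips = self.make_report(
            [tuple(p) for p in pts], rng.uniform(0.1, 2, 6), ["g1"] * 6
        )
        out = cs.weighted_centroids(report, tips, "genus")
        assert pts[:, 0].min() <= out.loc[0, "weighted_mean_r_phylo"] <= pts[:, 0].max()
        assert pts[:, 1].min() <= out.loc[0, "weighted_mean_r_geo"] <= pts[:, 1].max()

    def test_mixed_rank_assignment(self):
        tips = pd.DataFrame(
            {
                "tip_id": ["a", "b"],
                "host_taxon_id": ["H", "H"],
                "host_genus": ["G", "G"],
                "site_id": ["S", "S"],
                "phylum": ["P1", "P1"],
                "genus": ["g1", "g2"],
            }
        )
        assert cs.assign_clade_taxon(["a", "b"], tips, "phylum") == "P1"
        assert cs.assign_clade_taxon(["a", "b"], tips, "genus") is None


def test_genus_unique_branch_length_counts_edges_once():
    tree = cs.parse_newick("(((A:1,B:2):3,C:4):5,D:6);")
    # spanning subtree of {A, B}: edges A, B only (stem above their LCA excluded)
    assert genus_unique_branch_length(tree, ["A", "B"]) == pytest.approx(3.0)
    # spanning subtree of {A, C}: edges A, (AB):3, C
    assert genus_unique_branch_length(tree, ["A", "C"]) == pytest.approx(8.0)


def test_pairwise_phylum_tests_respects_min_genera():
    rng = np.random.default_rng(6)
    genera = [f"g{i}" for i in range(12)]
    summaries = pd.DataFrame(
        {
            "taxon": genera,
            "weighted_mean_delta": rng.normal(0, 1, 12),
        }
    )
    phylum = {g: ("A" if i < 6 else "B") for i, g in enumerate(genera)}
    weights = {g: 1.0 for g in genera}
    out = pairwise_phylum_tests(summaries, phylum, weights, min_genera=5)
    assert len(out) == 1
    out2 = pairwise_phylum_tests(summaries, phylum, weights, min_genera=7)
    assert len(out2) == 0


class TestPhylogeneticAnova:
    def star_tree(self, n):
        newick = "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
        return cs.parse_newick(newick)

    def test_constant_trait(self):
        tree = self.star_tree(8)
        trait = {f"t{i}": 1.0 for i in range(8)}
        groups = {f"t{i}": "a" if i < 4 else "b" for i in range(8)}
        f, p = cs.phylogenetic_anova(tree, trait, groups, 100, 0)
        assert f == 0.0 and p == 1.0

    def test_identical_seed_identical_result(self):
        tree = self.star_tree(10)
        rng = np.random.default_rng(7)
        trait = {f"t{i}": float(rng.normal()) for i in range(10)}
        groups = {f"t{i}": "a" if i < 5 else "b" for i in range(10)}
        r1 = cs.phylogenetic_anova(tree, trait, groups, 500, 42)
        r2 = cs.phylogenetic_anova(tree, trait, groups, 500, 42)
        assert r1 == r2

    def test_degenerate_groups_raise(self):
        tree = self.star_tree(4)
        trait = {f"t{i}": float(i) for i in range(4)}
        groups = {f"t{i}": "a" for i in range(4)}
        with pytest.raises(ValueError):
            cs.phylogenetic_anova(tree, trait, groups, 10, 0)

    def test_star_tree_matches_standard_anova(self):
        """BM on a star = i.i.d. normals, so the simulation p must agree with
        the parametric F-distribution p (small run; the acceptance suite runs
        the full-size check)."""
        tree = self.star_tree(24)
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 24)
        x[12:] += 0.8
        trait = {f"t{i}": float(x[i]) for i in range(24)}
        groups = {f"t{i}": "a" if i < 12 else "b" for i in range(24)}
        f, p = cs.phylogenetic_anova(tree, trait, groups, 4000, 3)
        p_std = float(stats.f_oneway(x[:12], x[12:]).pvalue)
        se = math.sqrt(p_std * (1 - p_std) / 4000)
        assert abs(p - p_std) <= 2 * se + 2.0 / 4001
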