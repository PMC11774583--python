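"""Clade enumeration, BH adjustment, classification and branch fractions."""

import math

import numpy as np
import pandas as pd
import pytest

import codivscan as cs
from codivscan.scan import PHYLO_POSITIVE, classify_clade

PARAMS = cs.ScanParams()


def brute_force_bh(p):
    """Oracle: step-up BH by direct definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = min(1.0, val)
        prev = val
    return adj


def brute_force_holm(p):
    """Oracle: step-down Holm by direct definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order, start=1):
        running = max(running, (m - rank + 1) * p[i])
        adj[i] = min(1.0, running)
    return adj


class TestEnumeration:
    def test_cherry_qualifies_root_does_not(self):
        # caterpillar of diameter 10 with a tight 4-tip distal clade
        tree = cs.parse_newick(
            "((((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05):4.75,E:3):2,(F:2,G:2):3);"
        )
        params = cs.ScanParams(min_tips=4)
        specs = cs.enumerate_testable_nodes(tree, params)
        tip_sets = {frozenset(s.tip_set) for s in specs}
        assert frozenset("ABCD") in tip_sets
        assert all(len(s.tip_set) < 7 for s in specs)  # root never qualifies

    def test_star_tree_root_excluded(self):
        tree = cs.parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        specs = cs.enumerate_testable_nodes(tree, cs.ScanParams(min_tips=4))
        assert specs == []

    def test_equality_case_included(self):
        # EFGH diameter 1.0 = exactly 10% of the tree diameter 10.0
        tree = cs.parse_newick(
            "(((A:0.5,B:0.5):0.1,(C:0.5,D:0.5):0.1):4.4,"
            "((E:0.25,F:0.25):0.25,(G:0.25,H:0.25):0.25):4.5);"
        )
        diam = cs.tree_diameter(tree)
        distal = tree.lca(["E", "H"])
        from codivscan.trees import clade_diameters

        assert clade_diameters(tree)[id(distal)] == pytest.approx(0.1 * diam)
        specs = cs.enumerate_testable_nodes(tree, cs.ScanParams(min_tips=4))
        assert frozenset("EFGH") in {frozenset(s.tip_set) for s in specs}
        assert frozenset("ABCD") not in {frozenset(s.tip_set) for s in specs}


class TestAdjustBH:
    def test_single_value(self):
        assert cs.adjust_bh([0.05]) == [pytest.approx(0.05)]

    def test_hand_step_up(self):
        assert cs.adjust_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 30))
            np.testing.assert_allclose(cs.adjust_bh(p), brute_force_bh(p), rtol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0.001, 1.0, 12)
        perm = rng.permutation(12)
        adj = np.asarray(cs.adjust_bh(p))
        adj_perm = np.asarray(cs.adjust_bh(p[perm]))
        np.testing.assert_allclose(adj[perm], adj_perm, rtol=1e-12)

    def test_empty_and_invalid(self):
        assert cs.adjust_bh([]) == []
        with pytest.raises(ValueError):
            cs.adjust_bh([0.0, 0.5])


class TestClassification:
    def test_phylo_independent_of_geo(self):
        assert (
            classify_clade(0.9, 0.01, 0.2, 0.6, PARAMS) == "phylo_independent_of_geo"
        )

    def test_both_when_delta_small(self):
        assert classify_clade(0.75, 0.01, 0.72, 0.01, PARAMS) == "both"

    def test_phylo_associated_with_untestable_geo(self):
        nan = float("nan")
        assert classify_clade(0.71, 0.049, nan, nan, PARAMS) == "phylo_associated"

    def test_geo_mirror(self):
        assert classify_clade(0.2, 0.6, 0.9, 0.01, PARAMS) == "geo_independent_of_phylo"

    def test_none_and_untestable(self):
        nan = float("nan")
        assert classify_clade(0.2, 0.9, 0.1, 0.8, PARAMS) == "none"
        assert classify_clade(nan, nan, nan, nan, PARAMS) == "untestable"


class TestBranchFraction:
    def test_empty_list_is_zero(self, toy_tree):
        assert cs.significant_branch_fraction(toy_tree, []) == 0.0

    def test_three_tip_conventions(self, toy_tree):
        cherry = toy_tree.lca(["A", "B"])
        spec = cs.CladeSpec("x", ("A", "B"), 2.0, 3.0, cherry)
        assert cs.significant_branch_fraction(toy_tree, [spec]) == pytest.approx(3 / 5)
        assert cs.significant_branch_fraction(
            toy_tree, [spec], include_subtending=False
        ) == pytest.approx(2 / 5)

    def test_nested_clades_counted_once(self):
        tree = cs.parse_newick(
            "((((A:1,B:1):1,(C:1,D:1):1):2,((E:1,F:1):1,(G:1,H:1):1):2):4,(I:3,J:3):4);"
        )
        outer = tree.lca(["A", "D"])
        inner = tree.lca(["A", "B"])
        s_outer = cs.CladeSpec("o", tuple("ABCD"), 0, 0, outer)
        s_inner = cs.CladeSpec("i", tuple("AB"), 0, 0, inner)
        f_both = cs.significant_branch_fraction(tree, [s_outer, s_inner])
        f_outer = cs.significant_branch_fraction(tree, [s_outer])
        # union of nested clades equals the outer clade alone: 8/30 by hand
        assert f_both == pytest.approx(f_outer) == pytest.approx(8 / 30)


@pytest.fixture(scope="module")
def perfect_dataset():
    """20 zero-noise co-diversifying clades, one strain per host taxon."""
    cfg = cs.SyntheticConfig(
        n_codiv_clades=20,
        n_geo_clades=0,
        n_random_clades=0,
        strains_per_host_taxon=1,
        within_taxon_noise_sd=0.0,
        rng_seed=3,
    )
    return cs.assemble_dataset(cfg)


class TestScan:
    def test_perfect_codiv_clades_all_recovered(self, perfect_dataset):
        ds = perfect_dataset
        model = cs.CodiversificationScan(
            ds.tree, ds.tips, ds.sites, ds.host_tree, cs.ScanParams(rng_seed=1)
        )
        res = model.fit()
        frame = res.frame.set_index("node_id")
        roots = ds.truth.frame["root_node_id"]
        assert len(roots) == 20
        sub = frame.loc[roots]
        assert (sub["r_phylo"] > 0.999).all()
        assert sub["classification"].isin(PHYLO_POSITIVE).all()

    def test_single_taxon_clade_untestable_phylo_geo_still_run(self, toy_metadata):
        _, _, sites, host = toy_metadata
        tree = cs.parse_newick(
            "((a:0.01,b:0.015,c:0.02,d:0.01,e:0.03,f:0.02):5,(g:0.01,h:0.01,i:0.01,j:0.02,k:0.01,l:0.01):5);"
        )
        tips = pd.DataFrame(
            {
                "tip_id": list("abcdefghijkl"),
                "host_taxon_id": ["H1"] * 6 + ["H2"] * 6,
                "host_genus": ["G1"] * 6 + ["G2"] * 6,
                "site_id": ["X", "Y"] * 6,
                "phylum": ["P"] * 12,
                "genus": ["g"] * 12,
            }
        )
        model = cs.CodiversificationScan(
            tree, tips, sites, host, cs.ScanParams(n_permutations=99, rng_seed=0)
        )
        res = model.fit()
        for r in res.report.results:
            assert r.untestable_phylo  # one host taxon within each tested clade
            assert not r.untestable_geo  # two sites: geo test ran
            assert math.isnan(r.r_phylo) and not math.isnan(r.r_geo)

    def test_deterministic_report_bytes(self, small_dataset, tmp_path):
        ds = small_dataset
        outs = []
        for rep in ("r1", "r2"):
            model = cs.CodiversificationScan(
                ds.tree, ds.tips, ds.sites, ds.host_tree,
                cs.ScanParams(n_permutations=199, rng_seed=9),
            )
            res = model.fit()
            d = tmp_path / rep
            res.save(d)
            outs.append((d / "nodes.tsv").read_bytes())
        assert outs[0] == outs[1]

    def test_counts_invariant_to_metadata_row_order(self, small_dataset):
        ds = small_dataset
        params = cs.ScanParams(n_permutations=199, rng_seed=2)
        res1 = cs.CodiversificationScan(
            ds.tree, ds.tips, ds.sites, ds.host_tree, params
        ).fit()
        shuffled = ds.tips.sample(frac=1.0, random_state=8).reset_index(drop=True)
        res2 = cs.CodiversificationScan(
            ds.tree, shuffled, ds.sites, ds.host_tree, params
        ).fit()
        assert res1.classification_counts == res2.classification_counts
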