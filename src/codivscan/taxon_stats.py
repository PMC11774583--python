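"""Taxon-level aggregation: weighted centroids, sign tests, weighted Welch
t-tests between phyla, and a simulation-based phylogenetic ANOVA.

Clade-level Mantel correlations are summarised per bacterial taxon using
branch-length weights, on the view that a long-branch clade represents more
unique evolutionary history than a short one.  Phylum/genus assignment of a
clade requires taxonomic uniformity of its tips at that rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode
from statsmodels.stats.multitest import multipletests

from .scan import ScanReport


def assign_clade_taxon(tip_labels, tips: pd.DataFrame, rank: str) -> str | None:
    """Taxon of a clade at ``rank`` ('phylum'|'genus'), or None if mixed."""
    if rank not in ("phylum", "genus"):
        raise ValueError("rank must be 'phylum' or 'genus'")
    lookup = dict(zip(tips["tip_id"], tips[rank]))
    taxa = {lookup[t] for t in tip_labels}
    if len(taxa) == 1:
        return next(iter(taxa))
    return None


@dataclass
class TaxonSummary:
    taxon: str
    rank: str
    n_nodes: int
    weight: float
    weighted_mean_r_phylo: float
    weighted_mean_r_geo: float
    weighted_mean_delta: float


def weighted_centroids(report: ScanReport, tips: pd.DataFrame, rank: str) -> pd.DataFrame:
    """Branch-length-weighted mean (r_phylo, r_geo, delta) per taxon.

    Node weight = clade branch length; nodes untestable on an axis are
    excluded from that axis's mean; taxa with no testable node on either
    axis are omitted.  Nested nodes both contribute (no de-overlap).
    """
    groups: dict[str, list] = {}
    for res in report.results:
        spec = report.clades[res.node_id]
        taxon = assign_clade_taxon(spec.tip_set, tips, rank)
        if taxon is None:
            continue
        groups.setdefault(taxon, []).append((res, spec.clade_branch_length))

    rows = []
    for taxon, members in sorted(groups.items()):
        def wmean(attr):
            vals = np.array([getattr(r, attr) for r, _ in members])
            w = np.array([w_ for _, w_ in members])
            ok = np.isfinite(vals) & (w > 0)
            if not ok.any():
                return float("nan")
            return float(np.average(vals[ok], weights=w[ok]))

        mp, mg, md = wmean("r_phylo"), wmean("r_geo"), wmean("delta")
        if not (np.isfinite(mp) or np.isfinite(mg)):
            continue
        rows.append(
            {
                "taxon": taxon,
                "rank": rank,
                "n_nodes": len(members),
                "weight": float(sum(w_ for _, w_ in members)),
                "weighted_mean_r_phylo": mp,
                "weighted_mean_r_geo": mg,
                "weighted_mean_delta": md,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "taxon",
            "rank",
            "n_nodes",
            "weight",
            "weighted_mean_r_phylo",
            "weighted_mean_r_geo",
            "weighted_mean_delta",
        ],
    )


def sign_test(successes: int, n: int, alternative: str = "greater") -> float:
    """Exact binomial sign test against p = 1/2.

    Default is the one-sided upper tail P(X >= successes); pass
    ``alternative='two-sided'`` for the two-sided exact test.
    """
    if not 0 <= successes <= n or n < 1:
        raise ValueError("need 0 <= successes <= n and n >= 1")
    return float(stats.binomtest(successes, n, 0.5, alternative=alternative).pvalue)


def weighted_t_test(values_a, weights_a, values_b, weights_b) -> tuple[float, float]:
    """Welch-type t-test on weighted means with effective sample sizes.

    For each group, the mean and (unbiased, reliability-weighted) variance
    use the normalised weights; the effective sample size is
    n_eff = (sum w)^2 / sum w^2, the standard error of the mean is
    sqrt(var / n_eff), and the degrees of freedom follow Satterthwaite on the
    effective sizes.  With equal weights this reduces exactly to the ordinary
    Welch t-test.  Rescaling all weights by a constant changes nothing.
    """

    def moments(x, w):
        x = np.asarray(x, dtype=float)
        w = np.asarray(w, dtype=float)
        if x.size < 2 or (w > 0).sum() < 2:
            raise ValueError("each group needs >= 2 entries with positive weight")
        if w.sum() <= 0:
            raise ValueError("zero total weight")
        m = np.average(x, weights=w)
        n_eff = w.sum() ** 2 / (w**2).sum()
        # reliability-weight unbiased variance
        v = np.average((x - m) ** 2, weights=w) * n_eff / (n_eff - 1.0)
        return m, v, n_eff

    ma, va, na = moments(values_a, weights_a)
    mb, vb, nb = moments(values_b, weights_b)
    se2a, se2b = va / na, vb / nb
    se = np.sqrt(se2a + se2b)
    if se == 0:
        return 0.0, 1.0
    t = (ma - mb) / se
    df = (se2a + se2b) ** 2 / (se2a**2 / (na - 1.0) + se2b**2 / (nb - 1.0))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(1.0, p))


def holm_correction(p_values) -> list[float]:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="holm")[1])


def genus_unique_branch_length(tree: TreeNode, tip_labels) -> float:
    """Total branch length of the minimal subtree spanning the given tips.

    Edges are counted once; the stem above the tips' common ancestor is not
    included.
    """
    tip_labels = list(tip_labels)
    if len(tip_labels) == 1:
        return 0.0
    lca = tree.lca(tip_labels)
    wanted = set(tip_labels)
    total = 0.0
    marked: dict[int, bool] = {}
    for node in lca.postorder(include_self=True):
        if node.is_tip():
            marked[id(node)] = node.name in wanted
        else:
            marked[id(node)] = any(marked[id(c)] for c in node.children)
        if node is not lca and marked[id(node)]:
            total += node.length or 0.0
    return float(total)


def pairwise_phylum_tests(
    genus_summaries: pd.DataFrame,
    genus_phylum: dict[str, str],
    genus_weights: dict[str, float],
    value_column: str = "weighted_mean_delta",
    min_genera: int = 5,
) -> pd.DataFrame:
    """Weighted Welch t-tests of per-genus values between all phylum pairs.

    Phyla with fewer than ``min_genera`` genera are excluded; p-values are
    Holm-adjusted across all pairs tested.
    """
    df = genus_summaries.copy()
    df["phylum"] = df["taxon"].map(genus_phylum)
    df["w"] = df["taxon"].map(genus_weights)
    df = df.dropna(subset=["phylum", "w", value_column])
    sizes = df.groupby("phylum").size()
    eligible = sorted(sizes[sizes >= min_genera].index)
    rows = []
    for i, pa in enumerate(eligible):
        for pb in eligible[i + 1 :]:
            a = df[df["phylum"] == pa]
            b = df[df["phylum"] == pb]
            t, p = weighted_t_test(
                a[value_column], a["w"], b[value_column], b["w"]
            )
            rows.append({"phylum_a": pa, "phylum_b": pb, "t": t, "p": p})
    out = pd.DataFrame(rows, columns=["phylum_a", "phylum_b", "t", "p"])
    if len(out):
        out["p_holm"] = holm_correction(out["p"])
    else:
        out["p_holm"] = []
    return out


def _bm_covariance(tree: TreeNode, tip_order) -> np.ndarray:
    """Brownian-motion covariance: shared root-to-LCA path length per pair."""
    depth: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)
    tips = {t.name: t for t in tree.tips()}
    n = len(tip_order)
    C = np.zeros((n, n))
    for i, a in enumerate(tip_order):
        C[i, i] = depth[id(tips[a])]
        for j in range(i + 1, n):
            lca = tree.lca([a, tip_order[j]])
            C[i, j] = C[j, i] = depth[id(lca)]
    return C


def _anova_f(x: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """One-way ANOVA F; works on a vector or on a (n_sim, n) matrix."""
    X = np.atleast_2d(x)
    grand = X.mean(axis=1, keepdims=True)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    for idx in group_idx:
        g = X[:, idx]
        gm = g.mean(axis=1, keepdims=True)
        ssb += (idx.size * (gm - grand) ** 2).ravel()
        ssw += ((g - gm) ** 2).sum(axis=1)
    k, n = len(group_idx), X.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    f = np.where(np.isfinite(f), f, 0.0)
    return f if x.ndim > 1 else float(f[0])


def phylogenetic_anova(
    taxon_tree: TreeNode,
    trait: dict[str, float] | pd.Series,
    groups: dict[str, str] | pd.Series,
    n_simulations: int = 1000,
    rng_seed: int = 0,
) -> tuple[float, float]:
    """Simulation-based phylogenetic ANOVA (Brownian-motion null).

    The observed one-way ANOVA F on the trait is compared with F values from
    ``n_simulations`` Brownian-motion simulations of the trait along the
    taxon tree; the BM rate is the maximum-likelihood estimate from the
    observed trait (it cancels in F, but is simulated faithfully).  The
    p-value uses the +1 correction.  A constant trait returns (0, 1).
    """
    trait = pd.Series(trait)
    groups = pd.Series(groups)
    order = [t.name for t in taxon_tree.tips()]
    missing = set(order) - set(trait.index)
    if missing or set(order) - set(groups.index):
        raise ValueError("trait/groups must cover every tree tip")
    x = trait.loc[order].to_numpy(dtype=float)
    g = groups.loc[order]
    labels = sorted(g.unique())
    group_idx = [np.flatnonzero((g == lab).to_numpy()) for lab in labels]
    if len(labels) < 2 or sum(idx.size >= 2 for idx in group_idx) < 2:
        raise ValueError("need >= 2 groups with >= 2 members")
    if np.allclose(x, x[0]):
        return 0.0, 1.0
    f_obs = _anova_f(x, group_idx)

    C = _bm_covariance(taxon_tree, order)
    n = len(order)
    Cinv = np.linalg.pinv(C)
    one = np.ones(n)
    mu = float(one @ Cinv @ x / (one @ Cinv @ one))
    resid = x - mu
    sigma2 = float(resid @ Cinv @ resid / n)  # ML rate
    L = np.linalg.cholesky(C + 1e-12 * np.eye(n))
    rng = np.random.default_rng(rng_seed)
    z = rng.standard_normal((n_simulations, n))
    sims = mu + np.sqrt(sigma2) * (z @ L.T)
    f_sim = _anova_f(sims, group_idx)
    p = (1.0 + int(np.sum(f_sim >= f_obs))) / (1.0 + n_simulations)
    return float(f_obs), float(p)


def genus_representative_tree(tree: TreeNode, tips: pd.DataFrame) -> TreeNode:
    """Prune the strain tree to one representative tip per genus.

    The representative is the lexicographically first tip of each genus; tips
    are relabeled with the genus name.  Used as the taxon tree for the
    trait ANOVA when no independent genus-level phylogeny is supplied.
    """
    reps = (
        tips.sort_values("tip_id").groupby("genus")["tip_id"].first().to_dict()
    )
    pruned = tree.shear(list(reps.values()))
    pruned.prune()
    genus_of = {v: k for k, v in reps.items()}
    for tip in pruned.tips():
        tip.name = genus_of[tip.name]
    return pruned
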