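"""Synthetic cophylogeny datasets with known ground truth.

Generates complete inputs for the scan — strain phylogeny, tip metadata, site
table, host tree — from three generative regimes:

``codiv``
    Partner fidelity: the clade topology mirrors the host tree, so strain
    distances are proportional to host patristic distances; each host taxon
    contributes a small fan of strains with half-normal branch-length noise,
    sampled from the sites in that taxon's range.
``geo``
    Isolation by distance: a site-level tree is built by average-linkage
    agglomeration of the (noise-perturbed) great-circle distances among
    sites; strains attach to their site's tip and host taxa are drawn from
    whatever taxa occur at the site, decoupling host identity from the tree.
``random``
    Neutral null: a random coalescent-style topology with exponential branch
    lengths, host taxon and site assigned at random (site within the taxon's
    range).

The default design emulates a six-taxon African-ape-like host clade (three
chimpanzee-like subspecies plus a bonobo analog in one genus; two gorilla-like
species in another) sampled at 17 equatorial sites, two of which host both
genera (sympatry).  All clades are normalised to tip-to-tip diameter 1 before
noise and hang from a long-edged star backbone, which guarantees they fall in
the distal tenth of the assembled tree and that no backbone node does.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from skbio import TreeNode

from .distances import site_distance_matrix
from .trees import node_id_for_tips, parse_newick, to_newick, tree_diameter

# Six-taxon host tree: within-genus splits shallow, Pan-Gorilla divergence
# deep (tip-to-tip diameter 6.0 arbitrary units).
DEFAULT_HOST_NEWICK = (
    "(((P_troglodytes_verus:0.3,(P_troglodytes_troglodytes:0.2,"
    "P_troglodytes_schweinfurthii:0.2):0.1):0.5,P_paniscus:0.8):2.2,"
    "(G_gorilla:0.9,G_beringei:0.9):2.1);"
)

HOST_GENUS = {
    "P_troglodytes_verus": "Pan",
    "P_troglodytes_troglodytes": "Pan",
    "P_troglodytes_schweinfurthii": "Pan",
    "P_paniscus": "Pan",
    "G_gorilla": "Gorilla",
    "G_beringei": "Gorilla",
}

# 17 sampling sites across equatorial Africa (decimal degrees, realistic
# spread: far-west chimp sites, central sites, eastern sites, a southern
# bonobo block).  S07 and S10 host both genera.
DEFAULT_SITES = [
    ("S01", 9.5, -13.7),
    ("S02", 8.4, -9.3),
    ("S03", 5.8, -7.3),
    ("S04", 7.3, -8.6),
    ("S05", 2.9, 10.6),
    ("S06", -0.2, 11.6),
    ("S07", -1.6, 9.9),
    ("S08", 0.4, 30.4),
    ("S09", 1.8, 31.7),
    ("S10", -2.5, 28.8),
    ("S11", -2.6, 20.9),
    ("S12", -1.9, 21.1),
    ("S13", -0.2, 22.5),
    ("S14", -2.1, 23.3),
    ("S15", -1.2, 19.8),
    ("S16", -2.9, 22.0),
    ("S17", -0.8, 20.7),
]

# Geographic range of each host taxon (site ids); the two gorilla-like
# species each occupy a single site shared with a chimpanzee-like subspecies.
DEFAULT_RANGES = {
    "P_troglodytes_verus": ("S01", "S02", "S03", "S04"),
    "P_troglodytes_troglodytes": ("S05", "S06", "S07"),
    "P_troglodytes_schweinfurthii": ("S08", "S09", "S10"),
    "P_paniscus": ("S11", "S12", "S13", "S14", "S15", "S16", "S17"),
    "G_gorilla": ("S07",),
    "G_beringei": ("S10",),
}

PHYLA = (
    "Bacteroidota",
    "Firmicutes",
    "Firmicutes_A",
    "Proteobacteria",
    "Actinobacteriota",
    "Verrucomicrobiota",
)


class ConfigurationError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Study-design parameters of the generator.

    Defaults define the reference simulation: 20 clades per regime, 3 strains
    per host taxon (18 tips per clade), branch-length noise 0.05 (clade
    diameters are normalised to 1, so this is 5% of the clade diameter),
    50 km of noise on the site distances entering the geo-regime site tree,
    and backbone edges of 25 clade-diameter units.
    """

    n_codiv_clades: int = 20
    n_geo_clades: int = 20
    n_random_clades: int = 20
    strains_per_host_taxon: int = 3
    within_taxon_noise_sd: float = 0.05
    geo_tree_noise_sd: float = 50.0
    backbone_scale: float = 25.0
    host_newick: str = DEFAULT_HOST_NEWICK
    sites: Sequence[tuple[str, float, float]] = field(default_factory=lambda: list(DEFAULT_SITES))
    ranges: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_RANGES))
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("n_codiv_clades", "n_geo_clades", "n_random_clades"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.strains_per_host_taxon < 1:
            raise ConfigurationError("strains_per_host_taxon must be >= 1")
        if self.within_taxon_noise_sd < 0 or self.geo_tree_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")

    def host_tree(self) -> TreeNode:
        return parse_newick(self.host_newick, assume_zero_lengths=True)

    def site_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sites, columns=["site_id", "latitude", "longitude"])


@dataclass
class SyntheticTruth:
    """Regime label and generating parameters per simulated clade."""

    frame: pd.DataFrame  # clade_id, regime, root_node_id, n_tips, tip_ids

    def regimes(self) -> dict[str, str]:
        return dict(zip(self.frame["clade_id"], self.frame["regime"]))


@dataclass
class Dataset:
    tree: TreeNode
    tips: pd.DataFrame
    sites: pd.DataFrame
    host_tree: TreeNode
    truth: SyntheticTruth


def _scale_tree(tree: TreeNode, target_diameter: float = 1.0) -> None:
    d = tree_diameter(tree)
    if d <= 0:
        return
    f = target_diameter / d
    for node in tree.traverse(include_self=False):
        node.length = (node.length or 0.0) * f


def _clade_rng(clade_seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(int(clade_seed)))


def simulate_codiv_clade(
    config: SyntheticConfig, clade_seed: int, clade_id: str = "codiv"
) -> tuple[TreeNode, list[dict]]:
    """Partner-fidelity regime: clade topology mirrors the host tree."""
    rng = _clade_rng(clade_seed)
    tree = config.host_tree()
    _scale_tree(tree, 1.0)
    meta: list[dict] = []
    counter = 0
    for host_tip in list(tree.tips()):
        taxon = host_tip.name
        host_tip.name = None
        for _ in range(config.strains_per_host_taxon):
            label = f"{clade_id}|t{counter:03d}"
            counter += 1
            child = TreeNode(name=label, length=abs(rng.normal(0.0, config.within_taxon_noise_sd)))
            host_tip.append(child)
            site = str(rng.choice(list(config.ranges[taxon])))
            meta.append(
                {
                    "tip_id": label,
                    "host_taxon_id": taxon,
                    "host_genus": HOST_GENUS.get(taxon, taxon.split("_")[0]),
                    "site_id": site,
                }
            )
    return tree, meta


def _site_tree_from_linkage(sites: pd.DataFrame, rng, noise_sd: float) -> TreeNode:
    """Ultrametric site tree by average-linkage on noisy haversine distances.

    Branch lengths are set so that the patristic distance between two site
    tips equals their cophenetic (merge) distance.
    """
    dm = site_distance_matrix(sites)
    n = len(dm.ids)
    iu = np.triu_indices(n, k=1)
    condensed = dm.data[iu]
    if noise_sd > 0:
        condensed = np.clip(condensed + rng.normal(0.0, noise_sd, size=condensed.size), 1e-9, None)
    Z = linkage(condensed, method="average")
    # build TreeNode bottom-up; node height = merge distance / 2
    nodes: list[TreeNode] = [TreeNode(name=s) for s in dm.ids]
    heights = [0.0] * n
    for a, b, dist, _ in Z:
        a, b = int(a), int(b)
        h = dist / 2.0
        parent = TreeNode()
        for child_idx in (a, b):
            child = nodes[child_idx]
            child.length = max(0.0, h - heights[child_idx])
            parent.append(child)
        nodes.append(parent)
        heights.append(h)
    return nodes[-1]


def simulate_geo_clade(
    config: SyntheticConfig, clade_seed: int, clade_id: str = "geo"
) -> tuple[TreeNode, list[dict]]:
    """Isolation-by-distance regime: strains cluster by site, not host."""
    sites = config.site_frame()
    if len(sites) < 3:
        raise ConfigurationError("geo regime requires >= 3 sites")
    rng = _clade_rng(clade_seed)
    tree = _site_tree_from_linkage(sites, rng, config.geo_tree_noise_sd)
    _scale_tree(tree, 1.0)

    occupants: dict[str, list[str]] = {s: [] for s in sites["site_id"]}
    for taxon, rng_sites in config.ranges.items():
        for s in rng_sites:
            if s in occupants:
                occupants[s].append(taxon)
    sympatric = [
        s for s, taxa in occupants.items() if len({HOST_GENUS.get(t, t) for t in taxa}) >= 2
    ]

    n_total = config.strains_per_host_taxon * len(config.ranges)
    assignments: list[tuple[str, str]] = []  # (site, taxon)
    # guarantee heterogeneric co-occurrence at every sympatric site
    for s in sympatric:
        taxa = occupants[s]
        genera: dict[str, list[str]] = {}
        for t in taxa:
            genera.setdefault(HOST_GENUS.get(t, t), []).append(t)
        for genus_taxa in genera.values():
            assignments.append((s, str(rng.choice(genus_taxa))))
    usable = [s for s, taxa in occupants.items() if taxa]
    while len(assignments) < n_total:
        s = str(rng.choice(usable))
        assignments.append((s, str(rng.choice(occupants[s]))))

    meta: list[dict] = []
    site_nodes = {t.name: t for t in tree.tips()}
    labels: list[str] = []
    for k, (site, taxon) in enumerate(assignments):
        label = f"{clade_id}|t{k:03d}"
        labels.append(label)
        child = TreeNode(name=label, length=abs(rng.normal(0.0, config.within_taxon_noise_sd)))
        site_nodes[site].append(child)
        meta.append(
            {
                "tip_id": label,
                "host_taxon_id": taxon,
                "host_genus": HOST_GENUS.get(taxon, taxon.split("_")[0]),
                "site_id": site,
            }
        )
    tree = tree.shear(labels)
    tree.prune()
    return tree, meta


def simulate_random_clade(
    config: SyntheticConfig, clade_seed: int, clade_id: str = "rand"
) -> tuple[TreeNode, list[dict]]:
    """Neutral regime: random topology, random host/site assignment."""
    rng = _clade_rng(clade_seed)
    n = config.strains_per_host_taxon * len(config.ranges)
    nodes = [TreeNode(name=f"{clade_id}|t{k:03d}", length=float(rng.exponential(0.1))) for k in range(n)]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = TreeNode(length=float(rng.exponential(0.1)))
        parent.append(a)
        parent.append(b)
        nodes = [x for x in nodes if x is not a and x is not b] + [parent]
    tree = nodes[0]
    tree.length = None
    _scale_tree(tree, 1.0)
    taxa = sorted(config.ranges)
    meta = []
    for tip in tree.tips():
        taxon = str(rng.choice(taxa))
        site = str(rng.choice(list(config.ranges[taxon])))
        meta.append(
            {
                "tip_id": tip.name,
                "host_taxon_id": taxon,
                "host_genus": HOST_GENUS.get(taxon, taxon.split("_")[0]),
                "site_id": site,
            }
        )
    return tree, meta


_SIMULATORS = {
    "codiv": simulate_codiv_clade,
    "geo": simulate_geo_clade,
    "random": simulate_random_clade,
}


def assemble_dataset(config: SyntheticConfig) -> Dataset:
    """Graft all simulated clades onto a star backbone and emit the dataset.

    Backbone edges have length ``backbone_scale``; a configuration whose
    clades are too large relative to the backbone (diameter > 10% of the
    assembled tree's diameter) raises :class:`ConfigurationError` naming the
    offending clade.
    """
    plan = (
        [("codiv", k) for k in range(config.n_codiv_clades)]
        + [("geo", k) for k in range(config.n_geo_clades)]
        + [("random", k) for k in range(config.n_random_clades)]
    )
    root = TreeNode(name="root")
    tips_rows: list[dict] = []
    truth_rows: list[dict] = []
    diameters: dict[str, float] = {}
    for idx, (regime, k) in enumerate(plan):
        clade_id = f"{regime}{k:02d}"
        clade_seed = int(
            np.random.SeedSequence([int(config.rng_seed), idx]).generate_state(1)[0] % (2**31)
        )
        tree, meta = _SIMULATORS[regime](config, clade_seed, clade_id=clade_id)
        phylum = PHYLA[idx % len(PHYLA)]
        genus = f"g_{clade_id}"
        for row in meta:
            row["phylum"] = phylum
            row["genus"] = genus
        tips_rows.extend(meta)
        diameters[clade_id] = tree_diameter(tree)
        tree.length = config.backbone_scale
        tree.name = clade_id
        root.append(tree)
        truth_rows.append(
            {
                "clade_id": clade_id,
                "regime": regime,
                "clade_seed": clade_seed,
                "n_tips": len(meta),
                "root_node_id": node_id_for_tips([r["tip_id"] for r in meta]),
                "tip_ids": ";".join(r["tip_id"] for r in meta),
            }
        )

    if not plan:
        # minimal backbone: two placeholder tips so the tree stays valid
        taxon = sorted(config.ranges)[0]
        site = config.ranges[taxon][0]
        for k in range(2):
            label = f"placeholder|t{k}"
            root.append(TreeNode(name=label, length=config.backbone_scale))
            tips_rows.append(
                {
                    "tip_id": label,
                    "host_taxon_id": taxon,
                    "host_genus": HOST_GENUS.get(taxon, taxon.split("_")[0]),
                    "site_id": site,
                    "phylum": PHYLA[0],
                    "genus": "g_placeholder",
                }
            )
    else:
        max_diam = max(diameters.values())
        if config.backbone_scale <= 10.0 * max_diam:
            worst = max(diameters, key=diameters.get)
            raise ConfigurationError(
                f"backbone_scale {config.backbone_scale} too small: clade {worst} has "
                f"diameter {diameters[worst]:.3f} (need backbone_scale > 10 x max diameter)"
            )
        full_diam = tree_diameter(root)
        for cid, d in diameters.items():
            if d > 0.1 * full_diam:
                raise ConfigurationError(
                    f"clade {cid} diameter {d:.3f} exceeds the distal tenth "
                    f"({0.1 * full_diam:.3f}) of the assembled tree"
                )

    tips = pd.DataFrame(
        tips_rows, columns=["tip_id", "host_taxon_id", "host_genus", "site_id", "phylum", "genus"]
    )
    truth = SyntheticTruth(
        frame=pd.DataFrame(
            truth_rows,
            columns=["clade_id", "regime", "clade_seed", "n_tips", "root_node_id", "tip_ids"],
        )
    )
    return Dataset(
        tree=root,
        tips=tips,
        sites=config.site_frame(),
        host_tree=config.host_tree(),
        truth=truth,
    )


def zero_noise(config: SyntheticConfig) -> SyntheticConfig:
    """The same design with all stochastic branch-length noise removed."""
    return replace(config, within_taxon_noise_sd=0.0, geo_tree_noise_sd=0.0)


def write_dataset(dataset: Dataset, out_dir) -> dict[str, str]:
    """Write strains.nwk, tips.tsv, sites.tsv, host.nwk and truth.tsv."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "tree": os.path.join(out_dir, "strains.nwk"),
        "tips": os.path.join(out_dir, "tips.tsv"),
        "sites": os.path.join(out_dir, "sites.tsv"),
        "host_tree": os.path.join(out_dir, "host.nwk"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    with open(paths["tree"], "w", encoding="utf-8") as fh:
        fh.write(to_newick(dataset.tree))
    dataset.tips.to_csv(paths["tips"], sep="\t", index=False)
    dataset.sites.to_csv(paths["sites"], sep="\t", index=False)
    with open(paths["host_tree"], "w", encoding="utf-8") as fh:
        fh.write(to_newick(dataset.host_tree))
    dataset.truth.frame.to_csv(paths["truth"], sep="\t", index=False)
    return paths
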