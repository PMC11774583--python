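"""Distal-tenth clade enumeration, per-node Mantel tests and classification.

The scan walks every internal node whose clade is "distal": its maximum
within-clade tip-to-tip distance is at most a fixed fraction (default 10%,
inclusive) of the whole tree's maximum tip-to-tip distance.  Each such clade
is tested for association of its strain distances with host-phylogenetic and
with geographic reference distances via one-tailed Mantel permutation tests;
p-values are Benjamini-Hochberg adjusted separately within the host-phylogeny
family and the geography family, and each clade is classified from the two
correlations (r_phylo, r_geo), their difference delta = r_phylo - r_geo, and
the adjusted p-values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from statsmodels.stats.multitest import multipletests

from .distances import ReferenceMatrices
from .mantel import mantel_permutation_test
from .trees import (
    clade_branch_length,
    clade_diameters,
    node_id,
    total_branch_length,
)

CLASSIFICATIONS = (
    "phylo_associated",
    "geo_associated",
    "both",
    "phylo_independent_of_geo",
    "geo_independent_of_phylo",
    "none",
    "untestable",
)

#: classifications implying a significant host-phylogeny association
PHYLO_POSITIVE = ("phylo_associated", "phylo_independent_of_geo", "both")
#: classifications implying a significant geography association
GEO_POSITIVE = ("geo_associated", "geo_independent_of_phylo", "both")

RESULT_COLUMNS = [
    "node_id",
    "n_tips",
    "n_host_taxa",
    "n_sites",
    "r_phylo",
    "p_phylo",
    "q_phylo",
    "r_geo",
    "p_geo",
    "q_geo",
    "delta",
    "classification",
]


@dataclass
class ScanParams:
    """Tunable parameters of the co-diversification scan.

    max_diameter_fraction
        Distal-window width: clades qualify when their diameter is at most
        this fraction of the tree diameter (inclusive).  Default 0.1.
    n_permutations
        Mantel null-distribution size.  Default 1000.
    r_threshold, alpha
        Significance thresholds: r > 0.7 and BH-adjusted p < 0.05.
    delta_threshold
        |r_phylo - r_geo| above which a significant clade counts as
        associated with one reference *independently* of the other (0.5).
    min_tips
        Smallest clade tested; 6 tips give >= 720 distinct permutations.
    min_distinct_reference_values
        Minimum distinct host taxa (resp. sites) for a reference to be
        testable within a clade.
    """

    max_diameter_fraction: float = 0.1
    n_permutations: int = 1000
    r_threshold: float = 0.7
    delta_threshold: float = 0.5
    alpha: float = 0.05
    min_tips: int = 6
    min_distinct_reference_values: int = 2
    rng_seed: int = 0
    include_subtending_edge: bool = True

    def __post_init__(self):
        if not 0 < self.max_diameter_fraction <= 1:
            raise ValueError("max_diameter_fraction must be in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.min_tips < 4:
            raise ValueError("min_tips must be >= 4")


@dataclass
class CladeSpec:
    """One enumerated (testable) node of the strain phylogeny."""

    node_id: str
    tip_set: tuple[str, ...]
    diameter: float
    clade_branch_length: float
    node: TreeNode = field(repr=False, compare=False)


@dataclass
class CladeTestResult:
    """Mantel-test outcome and classification for one clade."""

    node_id: str
    n_tips: int
    n_host_taxa: int
    n_sites: int
    r_phylo: float
    p_phylo: float
    q_phylo: float
    r_geo: float
    p_geo: float
    q_geo: float
    delta: float
    classification: str
    untestable_phylo: bool = False
    untestable_geo: bool = False


@dataclass
class ScanReport:
    """All per-node results plus dataset-level summaries."""

    results: list[CladeTestResult]
    clades: dict[str, CladeSpec]
    params: ScanParams
    tree_total_branch_length: float
    classification_counts: dict[str, int]
    branch_fractions: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [{c: getattr(r, c) for c in RESULT_COLUMNS} for r in self.results]
        return pd.DataFrame(rows, columns=RESULT_COLUMNS)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "classification": c,
                "n_clades": self.classification_counts.get(c, 0),
                "branch_length_fraction": self.branch_fractions.get(c, 0.0),
            }
            for c in CLASSIFICATIONS
        ]
        return pd.DataFrame(rows)

    def write(self, out_dir) -> None:
        """Write nodes.tsv, summary.tsv and params.json into ``out_dir``."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        frame = self.to_frame()
        frame.to_csv(
            os.path.join(out_dir, "nodes.tsv"), sep="\t", index=False, float_format="%.10g"
        )
        self.summary_frame().to_csv(
            os.path.join(out_dir, "summary.tsv"), sep="\t", index=False, float_format="%.10g"
        )
        with open(os.path.join(out_dir, "params.json"), "w", encoding="utf-8") as fh:
            json.dump(asdict(self.params), fh, indent=2, sort_keys=True)
            fh.write("\n")


def enumerate_testable_nodes(tree: TreeNode, params: ScanParams) -> list[CladeSpec]:
    """All internal nodes in the distal window with enough tips.

    Inclusive comparison ("10% or less"); nested qualifying nodes are all
    returned.  Ordering is by postorder position, but downstream results do
    not depend on it (per-node RNG streams are keyed by node_id).
    """
    diam = clade_diameters(tree)
    tree_diam = diam[id(tree)]
    cutoff = params.max_diameter_fraction * tree_diam
    specs: list[CladeSpec] = []
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            continue
        tips = tuple(t.name for t in node.tips())
        if len(tips) < params.min_tips:
            continue
        d = diam[id(node)]
        if d <= cutoff + 1e-12 * max(1.0, tree_diam):
            specs.append(
                CladeSpec(
                    node_id=node_id(node),
                    tip_set=tips,
                    diameter=d,
                    clade_branch_length=clade_branch_length(
                        node, include_subtending=params.include_subtending_edge
                    ),
                    node=node,
                )
            )
    return specs


def adjust_bh(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def _node_rng(seed: int, nid: str, family: str = "") -> np.random.Generator:
    """Per-node, per-family RNG stream keyed by a stable hash of the node id."""
    key = f"{nid}:{family}".encode("utf-8")
    h = int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed), h]))


def classify_clade(
    r_phylo: float,
    q_phylo: float,
    r_geo: float,
    q_geo: float,
    params: ScanParams,
) -> str:
    """Classification from thresholds on r, BH-adjusted p, and delta.

    nan r/q values mean the corresponding reference was untestable for this
    clade; the testable side is still classified on its own.
    """
    phylo_testable = np.isfinite(r_phylo)
    geo_testable = np.isfinite(r_geo)
    phylo_ok = phylo_testable and r_phylo > params.r_threshold and q_phylo < params.alpha
    geo_ok = geo_testable and r_geo > params.r_threshold and q_geo < params.alpha
    delta = r_phylo - r_geo if (phylo_testable and geo_testable) else float("nan")
    if phylo_ok and geo_ok:
        return "both"
    if phylo_ok:
        if np.isfinite(delta) and delta > params.delta_threshold and q_geo > params.alpha:
            return "phylo_independent_of_geo"
        return "phylo_associated"
    if geo_ok:
        if np.isfinite(delta) and -delta > params.delta_threshold and q_phylo > params.alpha:
            return "geo_independent_of_phylo"
        return "geo_associated"
    if not phylo_testable and not geo_testable:
        return "untestable"
    return "none"


def significant_branch_fraction(
    tree: TreeNode,
    clades: Iterable[CladeSpec],
    include_subtending: bool = True,
) -> float:
    """Branch-length fraction of the union of the listed clades.

    Edges lying inside more than one clade (nested/overlapping nodes) are
    counted once; the fraction is relative to the whole tree's total branch
    length.
    """
    total = total_branch_length(tree)
    if total <= 0:
        return 0.0
    seen: set[int] = set()
    length = 0.0
    for spec in clades:
        node = spec.node
        for n in node.traverse(include_self=False):
            if id(n) not in seen:
                seen.add(id(n))
                length += n.length or 0.0
        if include_subtending and node.parent is not None and id(node) not in seen:
            seen.add(id(node))
            length += node.length or 0.0
    return float(length / total)


def _submatrix(dm: DistanceMatrix, index: dict[str, int], labels: Sequence[str]) -> np.ndarray:
    idx = np.array([index[t] for t in labels])
    return dm.data[np.ix_(idx, idx)]


def scan(
    tree: TreeNode,
    refs: ReferenceMatrices,
    tips: pd.DataFrame,
    params: ScanParams | None = None,
) -> ScanReport:
    """Run the full per-node co-diversification scan.

    For every enumerated clade, Mantel permutation tests are run against the
    host-phylogeny and geography references restricted to the clade's tips;
    a reference with fewer than ``min_distinct_reference_values`` distinct
    host taxa (resp. sites) within the clade is flagged untestable for that
    clade and excluded from its BH family.  Deterministic given the seed.
    """
    params = params or ScanParams()
    specs = enumerate_testable_nodes(tree, params)
    ref_index = {t: k for k, t in enumerate(refs.ids)}
    missing = [t.name for t in tree.tips() if t.name not in ref_index]
    if missing:
        raise KeyError(f"reference matrices missing tree tip(s): {missing[:5]}")
    taxon_of = dict(zip(tips["tip_id"], tips["host_taxon_id"]))
    site_of = dict(zip(tips["tip_id"], tips["site_id"]))

    raw: list[dict] = []
    for spec in specs:
        labels = list(spec.tip_set)
        clade_D = spec.node.tip_tip_distances(endpoints=labels).filter(labels).data
        host_sub = _submatrix(refs.host_phylo, ref_index, labels)
        geo_sub = _submatrix(refs.geo, ref_index, labels)
        n_taxa = len({taxon_of[t] for t in labels})
        n_sites = len({site_of[t] for t in labels})
        entry = {
            "spec": spec,
            "n_host_taxa": n_taxa,
            "n_sites": n_sites,
            "r_phylo": float("nan"),
            "p_phylo": float("nan"),
            "r_geo": float("nan"),
            "p_geo": float("nan"),
            "untestable_phylo": True,
            "untestable_geo": True,
        }
        if n_taxa >= params.min_distinct_reference_values:
            rng = _node_rng(params.rng_seed, spec.node_id, "phylo")
            res = mantel_permutation_test(clade_D, host_sub, params.n_permutations, rng)
            if res.testable:
                entry.update(r_phylo=res.r, p_phylo=res.p, untestable_phylo=False)
        if n_sites >= params.min_distinct_reference_values:
            rng = _node_rng(params.rng_seed, spec.node_id, "geo")
            res = mantel_permutation_test(clade_D, geo_sub, params.n_permutations, rng)
            if res.testable:
                entry.update(r_geo=res.r, p_geo=res.p, untestable_geo=False)
        raw.append(entry)

    # BH within each reference family, over tested nodes only
    for key in ("phylo", "geo"):
        tested = [e for e in raw if not e[f"untestable_{key}"]]
        q = adjust_bh([e[f"p_{key}"] for e in tested])
        for e, qv in zip(tested, q):
            e[f"q_{key}"] = qv
        for e in raw:
            e.setdefault(f"q_{key}", float("nan"))

    results: list[CladeTestResult] = []
    for e in raw:
        spec = e["spec"]
        delta = (
            e["r_phylo"] - e["r_geo"]
            if np.isfinite(e["r_phylo"]) and np.isfinite(e["r_geo"])
            else float("nan")
        )
        cls = classify_clade(e["r_phylo"], e["q_phylo"], e["r_geo"], e["q_geo"], params)
        results.append(
            CladeTestResult(
                node_id=spec.node_id,
                n_tips=len(spec.tip_set),
                n_host_taxa=e["n_host_taxa"],
                n_sites=e["n_sites"],
                r_phylo=e["r_phylo"],
                p_phylo=e["p_phylo"],
                q_phylo=e["q_phylo"],
                r_geo=e["r_geo"],
                p_geo=e["p_geo"],
                q_geo=e["q_geo"],
                delta=delta,
                classification=cls,
                untestable_phylo=e["untestable_phylo"],
                untestable_geo=e["untestable_geo"],
            )
        )

    by_id = {s.node_id: s for s in specs}
    counts = {c: 0 for c in CLASSIFICATIONS}
    for r in results:
        counts[r.classification] = counts.get(r.classification, 0) + 1
    fractions = {}
    for c in CLASSIFICATIONS:
        members = [by_id[r.node_id] for r in results if r.classification == c]
        fractions[c] = significant_branch_fraction(
            tree, members, include_subtending=params.include_subtending_edge
        )
    return ScanReport(
        results=results,
        clades=by_id,
        params=params,
        tree_total_branch_length=total_branch_length(tree),
        classification_counts=counts,
        branch_fractions=fractions,
    )
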