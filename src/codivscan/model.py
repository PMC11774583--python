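"""Model/results interface to the co-diversification scan.

:class:`CodiversificationScan` bundles the four inputs (strain tree, tip
metadata, site table, host tree) with the scan parameters; :meth:`fit` runs
validation, builds the reference matrices, executes the per-node Mantel scan
and returns a :class:`CodiversificationResults` carrying the per-clade
estimates, adjusted p-values, classifications and dataset-level summaries,
with the sympatry fidelity test and the taxon-level aggregations hanging off
the results object.
"""

from __future__ import annotations

import pandas as pd
from skbio import TreeNode
from statsmodels.iolib.table import SimpleTable

from . import io as cio
from .distances import ReferenceMatrices, expand_to_tips, host_taxon_distances
from .scan import (
    GEO_POSITIVE,
    PHYLO_POSITIVE,
    ScanParams,
    ScanReport,
    scan,
)
from .sympatry import SympatryVerdict, run_sympatry, verdicts_frame
from .taxon_stats import (
    genus_unique_branch_length,
    pairwise_phylum_tests,
    weighted_centroids,
)
from .trees import read_newick


class CodiversificationScan:
    """Per-node Mantel scan of a strain phylogeny against host and geography.

    Parameters
    ----------
    tree : skbio.TreeNode
        Rooted strain phylogeny with branch lengths.
    tips : pandas.DataFrame
        Tip metadata (tip_id, host_taxon_id, host_genus, site_id, phylum,
        genus).
    sites : pandas.DataFrame
        Site table (site_id, latitude, longitude).
    host_tree : skbio.TreeNode
        Host phylogeny whose tips are host_taxon_ids.
    params : ScanParams, optional
    """

    def __init__(
        self,
        tree: TreeNode,
        tips: pd.DataFrame,
        sites: pd.DataFrame,
        host_tree: TreeNode,
        params: ScanParams | None = None,
    ):
        self.tree = tree
        self.tips = tips
        self.sites = sites
        self.host_tree = host_tree
        self.params = params or ScanParams()
        report = cio.validate_dataset(tree, tips, sites, host_tree)
        if not report.valid:
            raise ValueError(f"invalid dataset: {report}")
        self.validation = report

    @classmethod
    def from_files(cls, tree_path, tips_path, sites_path, host_tree_path, params=None):
        return cls(
            tree=read_newick(tree_path),
            tips=cio.read_tip_table(tips_path),
            sites=cio.read_site_table(sites_path),
            host_tree=read_newick(host_tree_path),
            params=params,
        )

    def reference_matrices(self) -> ReferenceMatrices:
        host_D = host_taxon_distances(self.host_tree)
        return expand_to_tips(self.tips, host_D, self.sites)

    def fit(self, seed: int | None = None) -> "CodiversificationResults":
        """Run the scan; ``seed`` overrides ``params.rng_seed``."""
        params = self.params
        if seed is not None:
            params = ScanParams(**{**params.__dict__, "rng_seed": int(seed)})
        refs = self.reference_matrices()
        report = scan(self.tree, refs, self.tips, params)
        return CodiversificationResults(self, report)


class CodiversificationResults:
    """Fitted scan: per-clade statistics plus downstream analyses."""

    def __init__(self, model: CodiversificationScan, report: ScanReport):
        self.model = model
        self.report = report

    @property
    def frame(self) -> pd.DataFrame:
        """One row per tested clade (node_id, r/p/q values, classification)."""
        return self.report.to_frame()

    @property
    def classification_counts(self) -> dict[str, int]:
        return self.report.classification_counts

    @property
    def branch_fractions(self) -> dict[str, float]:
        return self.report.branch_fractions

    def n_phylo_associated(self) -> int:
        return sum(self.classification_counts.get(c, 0) for c in PHYLO_POSITIVE)

    def n_geo_associated(self) -> int:
        return sum(self.classification_counts.get(c, 0) for c in GEO_POSITIVE)

    def sympatry(
        self,
        classifications: tuple[str, ...] = PHYLO_POSITIVE,
        method: str = "min",
        unanimity: bool = True,
    ) -> list[SympatryVerdict]:
        """Sympatry fidelity verdicts for clades of the given classes."""
        return run_sympatry(
            self.model.tree,
            self.report,
            self.model.tips,
            classifications=classifications,
            method=method,
            unanimity=unanimity,
        )

    def sympatry_frame(self, **kwargs) -> pd.DataFrame:
        return verdicts_frame(self.sympatry(**kwargs))

    def taxon_summaries(self, rank: str = "phylum") -> pd.DataFrame:
        """Branch-length-weighted per-taxon centroids of (r_phylo, r_geo)."""
        return weighted_centroids(self.report, self.model.tips, rank)

    def phylum_pairwise_tests(self, min_genera: int = 5) -> pd.DataFrame:
        """Weighted Welch t-tests of per-genus delta between phyla."""
        genus_summaries = self.taxon_summaries(rank="genus")
        tips = self.model.tips
        genus_phylum = (
            tips.groupby("genus")["phylum"].agg(lambda s: s.iloc[0]).to_dict()
        )
        genus_weights = {
            g: genus_unique_branch_length(self.model.tree, sub["tip_id"])
            for g, sub in tips.groupby("genus")
        }
        return pairwise_phylum_tests(
            genus_summaries, genus_phylum, genus_weights, min_genera=min_genera
        )

    def summary(self) -> str:
        """Human-readable summary of the fitted scan."""
        counts = self.classification_counts
        fracs = self.branch_fractions
        rows = [
            [c, str(counts.get(c, 0)), f"{100 * fracs.get(c, 0.0):.2f}%"]
            for c in counts
        ]
        table = SimpleTable(
            rows,
            headers=["classification", "n clades", "branch length"],
            title=(
                f"Co-diversification scan: {len(self.report.results)} clades tested, "
                f"{self.n_phylo_associated()} host-associated, "
                f"{self.n_geo_associated()} geography-associated"
            ),
        )
        return table.as_text()

    def save(self, out_dir) -> None:
        self.report.write(out_dir)
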