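"""Tabular metadata I/O and whole-dataset validation.

All tables are UTF-8, tab-separated with a header row.  The tip table links
every strain-tree tip to a host taxon (a tip of the host tree), a sampling
site, and its bacterial taxonomy; the site table carries decimal-degree
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from skbio import TreeNode

TIP_COLUMNS = ["tip_id", "host_taxon_id", "host_genus", "site_id", "phylum", "genus"]
SITE_COLUMNS = ["site_id", "latitude", "longitude"]


class TableFormatError(ValueError):
    """A metadata table is missing required columns or has bad values."""


def read_tip_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TIP_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"tip table missing column(s): {missing}")
    if df["tip_id"].duplicated().any():
        dups = df.loc[df["tip_id"].duplicated(), "tip_id"].tolist()
        raise TableFormatError(f"duplicate tip_id(s): {dups[:5]}")
    return df[TIP_COLUMNS]


def read_site_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"site table missing column(s): {missing}")
    df = df[SITE_COLUMNS].copy()
    df["site_id"] = df["site_id"].astype(str)
    if df["site_id"].duplicated().any():
        raise TableFormatError("duplicate site_id in site table")
    lat, lon = df["latitude"], df["longitude"]
    if ((lat < -90) | (lat > 90)).any():
        raise TableFormatError("latitude outside [-90, 90]")
    if ((lon < -180) | (lon > 180)).any():
        raise TableFormatError("longitude outside [-180, 180]")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


@dataclass
class ValidationReport:
    """Outcome of joining strain tree, tip table, site table and host tree."""

    tips_missing_metadata: list[str] = field(default_factory=list)
    metadata_missing_from_tree: list[str] = field(default_factory=list)
    unknown_references: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not (
            self.tips_missing_metadata
            or self.metadata_missing_from_tree
            or self.unknown_references
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.valid:
            return "dataset valid"
        parts = []
        if self.tips_missing_metadata:
            parts.append(f"tips without metadata: {self.tips_missing_metadata}")
        if self.metadata_missing_from_tree:
            parts.append(f"metadata rows not in tree: {self.metadata_missing_from_tree}")
        if self.unknown_references:
            parts.append(f"unknown references: {self.unknown_references}")
        return "; ".join(parts)


def validate_dataset(
    tree: TreeNode,
    tips: pd.DataFrame,
    sites: pd.DataFrame,
    host_tree: TreeNode,
) -> ValidationReport:
    """Cross-check the four inputs; report rather than raise.

    The dataset is valid iff every strain-tree tip has a metadata row, every
    metadata row names a strain-tree tip, and every host_taxon_id / site_id
    resolves against the host tree / site table.
    """
    report = ValidationReport()
    tree_tips = {t.name for t in tree.tips()}
    meta_tips = set(tips["tip_id"])
    report.tips_missing_metadata = sorted(tree_tips - meta_tips)
    report.metadata_missing_from_tree = sorted(meta_tips - tree_tips)
    host_taxa = {t.name for t in host_tree.tips()}
    site_ids = set(sites["site_id"])
    unknown = []
    for _, row in tips.iterrows():
        if row["host_taxon_id"] not in host_taxa:
            unknown.append(f"host_taxon_id:{row['host_taxon_id']}")
        if row["site_id"] not in site_ids:
            unknown.append(f"site_id:{row['site_id']}")
    report.unknown_references = sorted(set(unknown))
    return report
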