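"""Reference distance matrices: host phylogeny and geography.

Every clade test correlates within-clade strain distances against one of two
tip-level reference matrices: (i) host-phylogenetic patristic distances,
expanded from the species/subspecies host tree so that conspecific strains sit
at distance 0, and (ii) great-circle distances between sampling sites, so that
strains from one site sit at distance 0.  Sites, not recorded coordinates, are
the unit of geography.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

#: Mean Earth radius in kilometres.
EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance in km between two decimal-degree coordinates."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ValueError(f"longitude {lon} outside [-180, 180]")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * radius * math.asin(min(1.0, math.sqrt(a)))


def site_distance_matrix(sites: pd.DataFrame, radius: float = EARTH_RADIUS_KM) -> DistanceMatrix:
    """Pairwise haversine distances among sites, labeled by site_id."""
    ids = list(sites["site_id"])
    lat = np.radians(sites["latitude"].to_numpy(dtype=float))
    lon = np.radians(sites["longitude"].to_numpy(dtype=float))
    dphi = lat[:, None] - lat[None, :]
    dlam = lon[:, None] - lon[None, :]
    a = np.sin(dphi / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlam / 2.0) ** 2
    d = 2.0 * radius * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against fp jitter
    return DistanceMatrix(d, ids)


def host_taxon_distances(host_tree: TreeNode) -> DistanceMatrix:
    """Patristic distances among host-tree tips (species/subspecies)."""
    return host_tree.tip_tip_distances()


@dataclass
class ReferenceMatrices:
    """Host-phylogenetic and geographic distances over the same strain tips."""

    host_phylo: DistanceMatrix
    geo: DistanceMatrix

    def __post_init__(self):
        if tuple(self.host_phylo.ids) != tuple(self.geo.ids):
            raise ValueError("reference matrices must share one label ordering")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.host_phylo.ids)


def expand_to_tips(
    tips: pd.DataFrame,
    host_D: DistanceMatrix,
    sites: pd.DataFrame,
    radius: float = EARTH_RADIUS_KM,
) -> ReferenceMatrices:
    """Lift host-taxon and site distances to the strain-tip level.

    ``host_phylo(i, j) = host_D(taxon_i, taxon_j)`` and
    ``geo(i, j) = haversine(site_i, site_j)``; both are exactly 0 for tips
    sharing a host taxon or a site.  Row order of ``tips`` fixes the label
    ordering.
    """
    tip_ids = list(tips["tip_id"])
    host_index = {t: k for k, t in enumerate(host_D.ids)}
    try:
        taxon_idx = np.array([host_index[t] for t in tips["host_taxon_id"]])
    except KeyError as exc:
        raise KeyError(f"host taxon not in host tree: {exc.args[0]!r}") from None
    site_D = site_distance_matrix(sites, radius=radius)
    site_index = {s: k for k, s in enumerate(site_D.ids)}
    try:
        site_idx = np.array([site_index[s] for s in tips["site_id"]])
    except KeyError as exc:
        raise KeyError(f"site not in site table: {exc.args[0]!r}") from None
    host = host_D.data[np.ix_(taxon_idx, taxon_idx)].copy()
    geo = site_D.data[np.ix_(site_idx, site_idx)].copy()
    np.fill_diagonal(host, 0.0)
    np.fill_diagonal(geo, 0.0)
    return ReferenceMatrices(
        host_phylo=DistanceMatrix(host, tip_ids),
        geo=DistanceMatrix(geo, tip_ids),
    )
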