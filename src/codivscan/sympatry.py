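"""Partner-fidelity tests at sympatric sites.

Where two host genera (the Pan and Gorilla analogs) co-occur at one sampling
site, partner fidelity predicts that a strain from one genus remains closer
to strains from allopatric congeneric hosts than to strains from sympatric
heterogeneric hosts; pure isolation-by-distance predicts the opposite.  The
test is distance-based: for each candidate strain, the minimum patristic
distance to each comparator set is compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .scan import PHYLO_POSITIVE, ScanReport
from .trees import patristic_distances


@dataclass
class MagRecord:
    tip_id: str
    dist_allopatric_congeneric: float
    dist_sympatric_heterogeneric: float
    faithful: bool
    tied: bool = False


@dataclass
class SympatryVerdict:
    """Per-clade outcome of the sympatry fidelity test."""

    node_id: str
    sympatric_sites: list[str]
    n_mags_evaluated: int
    records: list[MagRecord] = field(default_factory=list)
    clade_verdict: str = "not_applicable"  # host_faithful | geography_faithful | mixed


def find_heterogeneric_sympatric_clades(
    report: ScanReport,
    tips: pd.DataFrame,
    classifications: tuple[str, ...] = PHYLO_POSITIVE,
) -> list[str]:
    """Clades (filtered by classification) holding two genera at one site."""
    genus_of = dict(zip(tips["tip_id"], tips["host_genus"]))
    site_of = dict(zip(tips["tip_id"], tips["site_id"]))
    out = []
    for res in report.results:
        if classifications and res.classification not in classifications:
            continue
        spec = report.clades[res.node_id]
        by_site: dict[str, set[str]] = {}
        for t in spec.tip_set:
            by_site.setdefault(site_of[t], set()).add(genus_of[t])
        if any(len(g) >= 2 for g in by_site.values()):
            out.append(res.node_id)
    return out


def sympatry_fidelity_test(
    clade_D: DistanceMatrix,
    tips: pd.DataFrame,
    node_id: str = "",
    method: str = "min",
    unanimity: bool = True,
) -> SympatryVerdict:
    """Evaluate host fidelity for every strain at a heterogeneric site.

    A strain is evaluated when its site holds clade members of both host
    genera.  A(i) = ``method`` (min or mean) patristic distance to strains of
    the same genus at a *different* site; B(i) = same to strains of a
    *different* genus at the *same* site; faithful iff A < B (ties count as
    not faithful and are flagged).  The clade verdict is host_faithful when
    every evaluated strain is faithful, geography_faithful when none is,
    mixed otherwise, and not_applicable when no strain has both comparator
    sets non-empty (under ``unanimity=False`` a majority rule replaces the
    all/none rule).
    """
    if method not in ("min", "mean"):
        raise ValueError("method must be 'min' or 'mean'")
    labels = list(clade_D.ids)
    sub = tips.set_index("tip_id").loc[labels]
    genus = sub["host_genus"].to_numpy()
    site = sub["site_id"].to_numpy()
    D = clade_D.data
    agg = np.min if method == "min" else np.mean

    by_site_genera: dict[str, set[str]] = {}
    for g, s in zip(genus, site):
        by_site_genera.setdefault(s, set()).add(g)
    hetero_sites = sorted(s for s, gs in by_site_genera.items() if len(gs) >= 2)

    records: list[MagRecord] = []
    for i, t in enumerate(labels):
        if site[i] not in hetero_sites:
            continue
        allo_mask = (genus == genus[i]) & (site != site[i])
        symp_mask = (genus != genus[i]) & (site == site[i])
        if not allo_mask.any() or not symp_mask.any():
            continue
        a = float(agg(D[i, allo_mask]))
        b = float(agg(D[i, symp_mask]))
        records.append(
            MagRecord(
                tip_id=t,
                dist_allopatric_congeneric=a,
                dist_sympatric_heterogeneric=b,
                faithful=a < b,
                tied=a == b,
            )
        )

    verdict = SympatryVerdict(
        node_id=node_id,
        sympatric_sites=hetero_sites,
        n_mags_evaluated=len(records),
        records=records,
    )
    if not records:
        verdict.clade_verdict = "not_applicable"
        return verdict
    n_faithful = sum(r.faithful for r in records)
    if unanimity:
        if n_faithful == len(records):
            verdict.clade_verdict = "host_faithful"
        elif n_faithful == 0:
            verdict.clade_verdict = "geography_faithful"
        else:
            verdict.clade_verdict = "mixed"
    else:
        verdict.clade_verdict = (
            "host_faithful" if 2 * n_faithful > len(records) else "geography_faithful"
        )
    return verdict


def run_sympatry(
    tree: TreeNode,
    report: ScanReport,
    tips: pd.DataFrame,
    classifications: tuple[str, ...] = PHYLO_POSITIVE,
    method: str = "min",
    unanimity: bool = True,
) -> list[SympatryVerdict]:
    """Fidelity test for every candidate clade in a scan report."""
    verdicts = []
    for nid in find_heterogeneric_sympatric_clades(report, tips, classifications):
        spec = report.clades[nid]
        clade_D = patristic_distances(spec.node, list(spec.tip_set))
        verdicts.append(
            sympatry_fidelity_test(clade_D, tips, node_id=nid, method=method, unanimity=unanimity)
        )
    return verdicts


def verdicts_frame(verdicts: list[SympatryVerdict]) -> pd.DataFrame:
    rows = [
        {
            "node_id": v.node_id,
            "sympatric_sites": ";".join(v.sympatric_sites),
            "n_mags_evaluated": v.n_mags_evaluated,
            "n_faithful": sum(r.faithful for r in v.records),
            "clade_verdict": v.clade_verdict,
        }
        for v in verdicts
    ]
    return pd.DataFrame(
        rows,
        columns=["node_id", "sympatric_sites", "n_mags_evaluated", "n_faithful", "clade_verdict"],
    )
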