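"""Mantel correlation and its one-tailed permutation test.

The statistic is the Pearson correlation over strictly-upper-triangle entries
of two labeled distance matrices.  Significance comes from jointly permuting
the rows and columns of the reference matrix; the p-value is one-tailed
(greater, as co-diversification predicts positive association) with the +1
small-sample correction, and permuted statistics tying the observed one count
toward the numerator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix


def _as_array(d) -> np.ndarray:
    if isinstance(d, DistanceMatrix):
        return d.data
    return np.asarray(d, dtype=float)


def _align(d1, d2) -> tuple[np.ndarray, np.ndarray]:
    a1, a2 = _as_array(d1), _as_array(d2)
    if isinstance(d1, DistanceMatrix) and isinstance(d2, DistanceMatrix):
        if set(d1.ids) != set(d2.ids):
            raise ValueError("distance matrices do not share a label set")
        if tuple(d1.ids) != tuple(d2.ids):
            a2 = d2.filter(list(d1.ids)).data
    if a1.shape != a2.shape or a1.shape[0] != a1.shape[1]:
        raise ValueError("distance matrices must be square and equally sized")
    return a1, a2


def mantel_r(d1, d2) -> float:
    """Pearson correlation of the strictly-upper triangles.

    Returns ``nan`` when either triangle has zero variance (the correlation
    is then undefined; callers treat the clade as untestable rather than
    crashing).
    """
    a1, a2 = _align(d1, d2)
    iu = np.triu_indices(a1.shape[0], k=1)
    x, y = a1[iu], a2[iu]
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int

    @property
    def testable(self) -> bool:
        return np.isfinite(self.r)


UNTESTABLE = MantelResult(r=float("nan"), p=float("nan"), n_permutations=0)


def mantel_permutation_test(
    symbiont_D,
    reference_D,
    n_permutations: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> MantelResult:
    """One-tailed (greater) Mantel permutation test.

    ``p = (1 + #{r_perm >= r_obs}) / (1 + n_permutations)`` under joint random
    relabelings of the reference matrix's rows and columns.  Identical seed
    implies identical p.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    a1, a2 = _align(symbiont_D, reference_D)
    n = a1.shape[0]
    if n < 4:
        raise ValueError("Mantel permutation test needs >= 4 labels")
    iu, ju = np.triu_indices(n, k=1)
    x = a1[iu, ju]
    y = a2[iu, ju]
    if x.std() == 0.0 or y.std() == 0.0:
        return MantelResult(r=float("nan"), p=float("nan"), n_permutations=n_permutations)
    r_obs = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))

    rng = np.random.default_rng(rng)
    perms = np.empty((n_permutations, n), dtype=np.intp)
    for k in range(n_permutations):
        perms[k] = rng.permutation(n)
    # permuted upper-triangle values of the reference matrix, one row per perm
    y_perm = a2[perms[:, iu], perms[:, ju]]
    r_perm = _rowwise_pearson(x, y_perm)
    # ties count toward the numerator (conservative); tolerance absorbs fp noise
    n_ge = int(np.sum(r_perm >= r_obs - 1e-12))
    p = (1.0 + n_ge) / (1.0 + n_permutations)
    return MantelResult(r=r_obs, p=p, n_permutations=n_permutations)


def _rowwise_pearson(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r of fixed vector ``x`` against each row of ``Y``."""
    xc = x - x.mean()
    xn = np.sqrt((xc**2).sum())
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Yn = np.sqrt((Yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc @ xc) / (Yn * xn)
    # a permutation can in principle produce a constant triangle only if the
    # original was constant, which is excluded above; guard anyway
    return np.nan_to_num(r, nan=-np.inf)
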