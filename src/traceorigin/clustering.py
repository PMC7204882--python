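"""Hierarchical clustering of bird fingerprints with AU/BP cluster support.

Agglomeration follows the Lance–Williams recurrences.  ``ward.D`` applies
the Ward coefficients to the supplied (unsquared) dissimilarities — the
classic convention of R's ``hclust(method="ward.D")`` — while ``ward.D2``
squares them first, and ``average`` is UPGMA.

Cluster support uses multiscale bootstrap resampling of the feature
(element) columns: for a grid of scales r the data are resampled to
round(r * n_features) columns, reclustered, and each original clade's
bootstrap probability BP(r) recorded.  Fitting the probit transform
psi(r) = sqrt(r) v + c / sqrt(r) by weighted least squares yields the
approximately unbiased p-value AU = 1 - Phi(v - c); clades with AU >= 0.95
are conventionally called strongly supported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from .preprocess import ZMatrix

logger = logging.getLogger(__name__)

__all__ = ["Dendrogram", "ClusterSupport", "pairwise_distance", "agglomerate",
           "cut", "multiscale_bootstrap", "clades_of"]

LINKAGES = ("ward.D", "ward.D2", "average")
METRICS = ("euclidean", "correlation")


@dataclass
class Dendrogram:
    """Agglomerative merge tree in scipy linkage-matrix form.

    ``merges`` is the (n-1, 4) linkage matrix: each row merges two node ids
    (leaves are 0..n-1, internal nodes n, n+1, ...) at the given height.
    """

    labels: list[str]
    merges: np.ndarray
    linkage: str
    metric: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def pairwise_distance(z, metric: str = "euclidean") -> np.ndarray:
    """Square distance matrix between bird rows.

    metric="euclidean" is the plain L2 distance; metric="correlation" is
    1 - Pearson r between rows (range [0, 2]); rows with zero variance have
    no defined correlation and raise.
    """
    if isinstance(z, ZMatrix):
        X = z.values
        ids = list(z.meta["bird_id"])
    else:
        X = np.asarray(z, dtype=float)
        ids = [str(i) for i in range(len(X))]
    if len(X) < 2:
        raise ValueError("need at least 2 rows")
    if metric == "euclidean":
        d = pdist(X, metric="euclidean")
    elif metric == "correlation":
        sd = X.std(axis=1)
        if (sd == 0).any():
            bad = [ids[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"zero-variance row(s) under correlation metric: {bad}")
        d = pdist(X, metric="correlation")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return squareform(d)


def _linkage_from_condensed(cond: np.ndarray, linkage: str) -> np.ndarray:
    if linkage == "average":
        return hierarchy.linkage(cond, method="average")
    if linkage == "ward.D2":
        return hierarchy.linkage(cond, method="ward")
    if linkage == "ward.D":
        # Ward's Lance-Williams recurrence on UNSQUARED dissimilarities:
        # running scipy's ward (which squares internally) on sqrt(d) and
        # squaring the resulting heights reproduces it exactly, merge
        # order included (monotone transform).
        Z = hierarchy.linkage(np.sqrt(cond), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
        return Z
    raise ValueError(f"unknown linkage {linkage!r}")


def agglomerate(dist: np.ndarray, linkage: str = "ward.D",
                labels: list[str] | None = None,
                metric: str = "euclidean") -> Dendrogram:
    """Agglomerative clustering of a square dissimilarity matrix."""
    dist = np.asarray(dist, dtype=float)
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains NaN")
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("expected a square distance matrix")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = dist.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    cond = squareform(dist, checks=False)
    Z = _linkage_from_condensed(cond, linkage)
    return Dendrogram(labels=list(labels), merges=Z, linkage=linkage,
                      metric=metric)


def cut(tree: Dendrogram, *, height: float | None = None,
        k: int | None = None) -> np.ndarray:
    """Flat cluster labels from severing merges above a height, or the
    smallest height that yields exactly k clusters."""
    if (height is None) == (k is None):
        raise ValueError("give exactly one of height= or k=")
    n = tree.n_leaves
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        return hierarchy.cut_tree(tree.merges, n_clusters=k).ravel()
    return hierarchy.fcluster(tree.merges, t=height, criterion="distance") - 1


def clades_of(tree: Dendrogram) -> list[frozenset[int]]:
    """Leaf-index sets of the n-1 internal nodes, in merge order."""
    n = tree.n_leaves
    sets: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    out = []
    for row in tree.merges:
        s = sets[int(row[0])] | sets[int(row[1])]
        sets.append(s)
        out.append(s)
    return out


@dataclass
class ClusterSupport:
    """Multiscale-bootstrap support for every internal node of a tree.

    ``table`` has one row per internal node (merge order) with AU, BP
    (observed at scale 1), the fitted probit-curve parameters v and c, and
    a flag column (``ok``, ``saturated_high``, ``saturated_low``,
    ``undefined``).  ``bp_by_scale`` holds the raw per-scale bootstrap
    probabilities.
    """

    table: pd.DataFrame
    bp_by_scale: pd.DataFrame
    scales: tuple[float, ...]
    B: int
    seed: int
    linkage: str = ""
    metric: str = ""
    tree: Dendrogram | None = field(default=None, repr=False)


def _fit_au(bp: np.ndarray, scales: np.ndarray, B: int,
            constrain_c: bool = False) -> tuple[float, float, float, str]:
    """Fit psi(r) = sqrt(r) v + c/sqrt(r) by binomial-weighted LS.

    Returns (au, v, c, flag).  BP values of 0/1 are clamped to 1/(2B) and
    1 - 1/(2B) before the probit transform (continuity correction).  With
    ``constrain_c`` the curvature term is dropped (c = 0), which needs only
    one scale and makes AU collapse to BP at r = 1.
    """
    if np.all(bp >= 1.0):
        return 1.0, -np.inf, np.inf, "saturated_high"
    if np.all(bp <= 0.0):
        return 0.0, np.inf, -np.inf, "saturated_low"
    if len(scales) < (1 if constrain_c else 2):
        return np.nan, np.nan, np.nan, "undefined"
    eps = 1.0 / (2.0 * B)
    bp_c = np.clip(bp, eps, 1.0 - eps)
    psi = norm.ppf(1.0 - bp_c)
    if constrain_c:
        X = np.sqrt(scales)[:, None]
    else:
        X = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
    # delta-method weights: var(psi) ~ bp(1-bp) / (B phi(psi)^2)
    w = B * norm.pdf(psi) ** 2 / (bp_c * (1.0 - bp_c))
    XtW = X.T * w
    try:
        beta = np.linalg.solve(XtW @ X, XtW @ psi)
    except np.linalg.LinAlgError:
        return np.nan, np.nan, np.nan, "undefined"
    if constrain_c:
        v, c = float(beta[0]), 0.0
    else:
        v, c = float(beta[0]), float(beta[1])
    au = float(1.0 - norm.cdf(v - c))
    return au, v, c, "ok"


def multiscale_bootstrap(z, *, metric: str = "correlation",
                         linkage: str = "average",
                         scales=(0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4),
                         B: int = 1000, seed: int = 0,
                         constrain_c: bool = False) -> ClusterSupport:
    """AU/BP support values for every clade of the full-data tree.

    For each scale r, draws B resamples of round(r * n_features) feature
    columns with replacement, reclusters, and records the fraction of
    replicates containing each original clade.  Deterministic for a fixed
    seed.
    """
    if isinstance(z, ZMatrix):
        X = z.values
        labels = list(z.meta["bird_id"])
    else:
        X = np.asarray(z, dtype=float)
        labels = [str(i) for i in range(len(X))]
    scales = np.asarray(sorted(float(r) for r in scales))
    if B < 1:
        raise ValueError("B must be positive")
    if (scales <= 0).any():
        raise ValueError("scales must be positive")
    n, m = X.shape
    tree = agglomerate(pairwise_distance(X, metric), linkage,
                       labels=labels, metric=metric)
    target = clades_of(tree)
    target_index = {s: i for i, s in enumerate(target)}
    counts = np.zeros((len(target), len(scales)), dtype=np.int64)
    rng = np.random.default_rng(seed)
    for si, r in enumerate(scales):
        m_r = max(2, int(round(r * m)))
        for _ in range(B):
            cols = rng.integers(0, m, size=m_r)
            Xb = X[:, cols]
            try:
                tb = agglomerate(pairwise_distance(Xb, metric), linkage)
            except ValueError:
                continue  # e.g. zero-variance row under correlation
            for s in clades_of(tb):
                idx = target_index.get(s)
                if idx is not None:
                    counts[idx, si] += 1
    bp = counts / B
    rows = []
    for ci in range(len(target)):
        au, v, c, flag = _fit_au(bp[ci], scales, B, constrain_c=constrain_c)
        # BP reported at scale 1 (observed if on the grid, else fitted)
        one = np.flatnonzero(np.isclose(scales, 1.0))
        if one.size:
            bp1 = float(bp[ci, one[0]])
        elif flag == "ok":
            bp1 = float(1.0 - norm.cdf(v + c))
        else:
            bp1 = float(np.nan)
        rows.append({"node": ci, "au": au, "bp": bp1, "v": v, "c": c,
                     "flag": flag})
    table = pd.DataFrame(rows).set_index("node")
    bp_df = pd.DataFrame(bp, columns=[f"r={r:g}" for r in scales])
    bp_df.index.name = "node"
    return ClusterSupport(table=table, bp_by_scale=bp_df,
                          scales=tuple(scales), B=B, seed=seed,
                          linkage=linkage, metric=metric, tree=tree)
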