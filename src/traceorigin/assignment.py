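"""Assigning fall-caught "problem birds" to natal sites.

A problem bird's canonical scores are normalized by each site's centroid
(ratio of score to centroid value), so a bird sitting exactly on a site's
centroid scores 1 on every function for that site.  The bird is assigned to
the site whose ratio vector is closest to all-ones; birds whose canonical
position is too far from every centroid — beyond a chi-square cut on the
Mahalanobis D² — are flagged immigrant/unassigned, i.e. likely natal to an
unsampled source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .discriminant import DiscriminantFit, FingerprintLibrary

logger = logging.getLogger(__name__)

__all__ = ["OriginAssignment", "ContributionSummary", "centroid_normalize",
           "assign_origin", "summarize_by_context", "IMMIGRANT_LABEL"]

IMMIGRANT_LABEL = "immigrant_unassigned"

#: Centroid components smaller than this are treated as undefined ratio
#: cells.  Canonical scores have pooled within-group SD 1, so a centroid
#: component below half a within-SD is statistically indistinguishable from
#: zero and the ratio to it is pure noise amplification.
CENTROID_EPS = 0.5


@dataclass
class OriginAssignment:
    """Per-bird assignment table plus the threshold that produced it.

    ``table`` columns: bird_id, canonical scores (f1..fm), per-site
    closeness d_<site>, min_d2 (Mahalanobis to nearest centroid),
    assigned_site, flagged (immigrant/unassigned).
    """

    table: pd.DataFrame
    site_order: list[str]
    method: str
    tau: float
    retained: int

    @property
    def assigned(self) -> pd.Series:
        return self.table["assigned_site"]

    @property
    def flagged(self) -> pd.Series:
        return self.table["flagged"]


def centroid_normalize(fit: DiscriminantFit | FingerprintLibrary,
                       scores: np.ndarray) -> np.ndarray:
    """Ratio of each bird's canonical scores to each site centroid.

    Returns an (n_birds, n_sites, n_retained) array rho with
    rho[i, s, j] = f_j(bird i) / centroid_{s,j}.  Cells whose centroid
    component is numerically zero are NaN (undefined) and excluded from
    closeness downstream.
    """
    if isinstance(fit, FingerprintLibrary):
        fit = fit.fit
    nf = fit.retained
    scores = np.asarray(scores, dtype=float)[:, :nf]
    cents = fit.centroids[:, :nf]
    safe = np.where(np.abs(cents) < CENTROID_EPS, np.nan, cents)
    if np.isnan(safe).any():
        logger.debug("centroid component(s) below %.1g treated as undefined",
                     CENTROID_EPS)
    return scores[:, None, :] / safe[None, :, :]


def assign_origin(lib: FingerprintLibrary | DiscriminantFit,
                  scores: np.ndarray,
                  bird_ids=None, *,
                  method: str = "ratio",
                  tau: float | None = None,
                  immigrant_alpha: float = 0.05) -> OriginAssignment:
    """Assign each bird to the closest library site, or flag it immigrant.

    method="ratio" (the centroid-ratio reading): closeness to site s is the
    Euclidean distance of the ratio vector rho_s from all-ones, over defined
    cells.  method="mahalanobis": closeness is D² to the centroid in
    retained canonical space.  Either way a bird is flagged
    immigrant/unassigned when its smallest D² exceeds ``tau`` (default: the
    chi-square (1 - alpha) quantile with df = retained functions).
    """
    fit = lib.fit if isinstance(lib, FingerprintLibrary) else lib
    if method not in ("ratio", "mahalanobis"):
        raise ValueError(f"unknown method {method!r}")
    nf = fit.retained
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if bird_ids is None:
        bird_ids = [f"bird{i}" for i in range(n)]
    if tau is None:
        tau = float(stats.chi2.ppf(1.0 - immigrant_alpha, df=nf))

    cents = fit.centroids[:, :nf]
    d2 = ((scores[:, None, :nf] - cents[None, :, :]) ** 2).sum(axis=2)
    if method == "ratio":
        rho = centroid_normalize(fit, scores)
        dev = (rho - 1.0) ** 2
        with np.errstate(invalid="ignore"):
            closeness = np.sqrt(np.nansum(dev, axis=2))
        all_nan = np.isnan(dev).all(axis=2)
        closeness[all_nan] = np.nan
    else:
        closeness = d2.astype(float)
    if np.isnan(closeness).all(axis=1).any():
        raise ValueError("bird with no defined closeness to any site")

    pick = np.nanargmin(closeness, axis=1)
    assigned = np.array([fit.site_order[i] for i in pick], dtype=object)
    min_d2 = d2.min(axis=1)
    flagged = min_d2 > tau
    assigned[flagged] = IMMIGRANT_LABEL

    out = pd.DataFrame({"bird_id": list(bird_ids)})
    for j in range(nf):
        out[f"f{j + 1}"] = scores[:, j]
    for s_i, s in enumerate(fit.site_order):
        out[f"d_{s}"] = closeness[:, s_i]
    out["min_d2"] = min_d2
    out["assigned_site"] = assigned
    out["flagged"] = flagged
    return OriginAssignment(table=out, site_order=list(fit.site_order),
                            method=method, tau=tau, retained=nf)


@dataclass
class ContributionSummary:
    """Percentage of birds in one capture context traced to each source."""

    context: str
    counts: pd.Series       # per source site + immigrant/unassigned
    percentages: pd.Series
    region_percentages: pd.Series | None = None


def summarize_by_context(assignment: OriginAssignment,
                         contexts: pd.Series | np.ndarray,
                         regions: dict[str, list[str]] | None = None
                         ) -> dict[str, ContributionSummary]:
    """Per-context source contributions (counts and percentages).

    ``regions`` optionally maps region names (e.g. north/central/south) to
    site lists for a coarser roll-up; flagged birds count as
    immigrant/unassigned in both tables.
    """
    contexts = pd.Series(np.asarray(contexts, dtype=object),
                         index=assignment.table.index)
    known = {"vineyard_orchard", "dairy_feedlot", "library", "unknown"}
    bad = set(contexts) - known
    if bad:
        raise ValueError(f"unknown context value(s): {sorted(bad)}")
    cats = assignment.site_order + [IMMIGRANT_LABEL]
    out: dict[str, ContributionSummary] = {}
    for ctx in pd.unique(contexts):
        sub = assignment.table.loc[contexts == ctx, "assigned_site"]
        counts = sub.value_counts().reindex(cats, fill_value=0)
        pct = counts / counts.sum() * 100.0
        region_pct = None
        if regions:
            site_to_region = {s: r for r, sites in regions.items() for s in sites}
            rolled = sub.map(lambda s: site_to_region.get(s, s))
            rcats = list(regions) + [IMMIGRANT_LABEL]
            rcounts = rolled.value_counts().reindex(rcats, fill_value=0)
            region_pct = rcounts / rcounts.sum() * 100.0
        out[str(ctx)] = ContributionSummary(context=str(ctx), counts=counts,
                                            percentages=pct,
                                            region_percentages=region_pct)
    return out
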