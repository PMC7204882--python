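"""One-way MANOVA on the standardized element matrix using Wilks' lambda.

Wilks' Lambda = det(W) / det(W + B), the ratio of within-group to total
scatter; values near zero indicate strong multivariate separation between
capture sites.  Significance uses Rao's F approximation, which is exact for
common small cases and reproduces the (df1, df2) pair printed by standard
statistical packages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ManovaResult", "manova_wilks", "rao_f_approximation",
           "scatter_matrices", "wilks_from_scatter"]


@dataclass(frozen=True)
class ManovaResult:
    wilks_lambda: float
    f_stat: float
    df1: int
    df2: float
    p_value: float
    N: int
    p: int
    k: int


def scatter_matrices(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-group (W) and between-group (B) scatter matrices.

    W = sum over groups of the centered cross-products; B = sum over groups
    of n_g (m_g - m)(m_g - m)' about the grand mean.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    grand = X.mean(axis=0)
    p = X.shape[1]
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for g in np.unique(labels):
        Xg = X[labels == g]
        mg = Xg.mean(axis=0)
        C = Xg - mg
        W += C.T @ C
        d = (mg - grand)[:, None]
        B += len(Xg) * (d @ d.T)
    return W, B


def wilks_from_scatter(W: np.ndarray, B: np.ndarray) -> float:
    """Lambda = det(W)/det(W+B) via log-determinants for stability."""
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    if sign_w <= 0 or sign_t <= 0:
        raise np.linalg.LinAlgError(
            "within-group scatter is singular; reduce variables or add samples"
        )
    return float(np.exp(logdet_w - logdet_t))


def rao_f_approximation(lam: float, p: int, k: int, N: int) -> tuple[float, int, float]:
    """Rao's F transform of Wilks' Lambda.

    m = N - 1 - (p + k)/2,  t = sqrt((p^2 (k-1)^2 - 4)/(p^2 + (k-1)^2 - 5))
    (t = 1 when the denominator is <= 0), df1 = p (k-1),
    df2 = m t - df1/2 + 1,  F = ((1 - L^(1/t)) / L^(1/t)) * (df2/df1).
    """
    m = N - 1 - (p + k) / 2.0
    denom = p * p + (k - 1) ** 2 - 5
    t = np.sqrt((p * p * (k - 1) ** 2 - 4.0) / denom) if denom > 0 else 1.0
    df1 = p * (k - 1)
    df2 = m * t - df1 / 2.0 + 1.0
    lam_t = lam ** (1.0 / t)
    f_stat = (1.0 - lam_t) / lam_t * (df2 / df1)
    return float(f_stat), int(df1), float(df2)


def manova_wilks(X: np.ndarray, labels) -> ManovaResult:
    """One-way MANOVA across the groups in ``labels``.

    Parameters
    ----------
    X
        (N, p) matrix of standardized element ratios (or any responses).
    labels
        Length-N group labels (capture sites).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    N, p = X.shape
    groups = np.unique(labels)
    k = len(groups)
    if k < 2:
        raise ValueError("MANOVA needs at least 2 groups")
    if N <= p + k:
        raise ValueError(
            f"too few samples (N={N}) for p={p} variables and k={k} groups"
        )
    W, B = scatter_matrices(X, labels)
    lam = wilks_from_scatter(W, B)
    f_stat, df1, df2 = rao_f_approximation(lam, p, k, N)
    f_stat = max(f_stat, 0.0)
    p_value = float(stats.f.sf(f_stat, df1, df2))
    return ManovaResult(wilks_lambda=lam, f_stat=f_stat, df1=df1, df2=df2,
                        p_value=p_value, N=N, p=p, k=k)
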