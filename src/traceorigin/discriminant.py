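"""Stepwise canonical discriminant analysis: the fingerprint library.

Builds the classifier that turns known-origin juvenile birds into a
"fingerprint library": greedy stepwise variable selection with partial-F
entry/removal gating (Wilks' Lambda or closest-pair Mahalanobis criterion),
canonical discriminant functions from the eigen-decomposition of W^-1 B,
nearest-centroid classification in canonical space, leave-one-out
cross-validation, and Press's Q for classification significance.

Conventions follow the classical (SPSS-style) discriminant analysis:
equal priors, coefficients scaled so every canonical score has pooled
within-group variance 1 — which makes squared Euclidean distance to a
centroid in canonical space a Mahalanobis D².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .manova import scatter_matrices, wilks_from_scatter
from .preprocess import ZMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "StepwiseTrace", "StepRecord", "DiscriminantFit", "ClassificationReport",
    "FingerprintLibrary", "stepwise_select", "fit_canonical", "classify",
    "loo_crossvalidate", "press_q", "subset_wilks",
]


def _coerce(z, labels=None) -> tuple[pd.DataFrame, np.ndarray]:
    if isinstance(z, ZMatrix):
        df = z.z
        if labels is None:
            labels = z.meta["site"].to_numpy()
    else:
        df = pd.DataFrame(z)
    if labels is None:
        raise ValueError("labels are required")
    return df.reset_index(drop=True), np.asarray(labels)


def subset_wilks(df: pd.DataFrame, labels: np.ndarray, cols: list[str]) -> float:
    """Wilks' Lambda restricted to a variable subset."""
    W, B = scatter_matrices(df[cols].to_numpy(), labels)
    return wilks_from_scatter(W, B)


def _min_pairwise_d2(df: pd.DataFrame, labels: np.ndarray, cols: list[str]) -> float:
    """Smallest pairwise Mahalanobis D^2 between group centroids,
    with covariance = pooled within-group covariance of ``cols``."""
    X = df[cols].to_numpy()
    groups = [str(g) for g in pd.unique(labels)]
    N, k = len(X), len(groups)
    W, _ = scatter_matrices(X, labels)
    Sw = W / (N - k)
    chol = linalg.cho_factor(Sw)
    means = {g: X[labels == g].mean(axis=0) for g in groups}
    best = np.inf
    for i in range(k):
        for j in range(i + 1, k):
            d = means[groups[i]] - means[groups[j]]
            d2 = float(d @ linalg.cho_solve(chol, d))
            best = min(best, d2)
    return best


@dataclass(frozen=True)
class StepRecord:
    step: int
    action: str            # "enter" | "remove"
    element: str
    criterion_value: float  # model criterion after the action
    partial_f: float


@dataclass
class StepwiseTrace:
    steps: list[StepRecord]
    selected: list[str]
    criterion: str
    f_enter: float
    f_remove: float
    flagged_empty: bool = False


def _partial_f_enter(lam_with: float, lam_without: float,
                     N: int, k: int, q: int) -> float:
    """Partial F to enter, with q variables already in the model."""
    plam = lam_with / lam_without
    return (N - k - q) / (k - 1) * (1.0 - plam) / plam


def _partial_f_remove(lam_model: float, lam_without: float,
                      N: int, k: int, q: int) -> float:
    """Partial F of an included variable; q = current model size."""
    plam = lam_model / lam_without
    return (N - k - q + 1) / (k - 1) * (1.0 - plam) / plam


def stepwise_select(z, labels=None, *, criterion: str = "mahalanobis_closest_pair",
                    f_enter: float = 3.84, f_remove: float = 2.71,
                    max_steps: int = 200) -> StepwiseTrace:
    """Greedy forward selection with backward removal of element predictors.

    At each step the excluded variable with partial F >= ``f_enter`` that
    most improves the model criterion is entered (criterion ``"wilks"``:
    smallest model Lambda; ``"mahalanobis_closest_pair"``: largest smallest
    pairwise centroid D², the classical choice when many variables compete);
    then any included variable whose partial F falls below ``f_remove`` is
    removed (smallest first).  Stops when no entry or removal is possible.
    """
    if criterion not in ("wilks", "mahalanobis_closest_pair"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if not f_enter > f_remove:
        raise ValueError("f_enter must exceed f_remove")
    df, labels = _coerce(z, labels)
    candidates = list(df.columns)
    N = len(df)
    k = len(pd.unique(labels))
    if k < 2:
        raise ValueError("need at least 2 groups")

    selected: list[str] = []
    steps: list[StepRecord] = []
    lam_model = 1.0
    seen: set[frozenset] = set()
    step_no = 0

    def crit_value(cols: list[str]) -> float:
        if criterion == "wilks":
            return subset_wilks(df, labels, cols)
        return _min_pairwise_d2(df, labels, cols)

    while step_no < max_steps:
        if N <= k + len(selected):
            logger.warning("stepwise stopped: too few cases to grow the model")
            break
        # --- entry scan ---
        best_elem, best_crit, best_f, best_lam = None, None, None, None
        q = len(selected)
        for x in (c for c in candidates if c not in selected):
            cols = selected + [x]
            try:
                lam_with = subset_wilks(df, labels, cols)
            except np.linalg.LinAlgError:
                logger.warning("skipping collinear candidate %s", x)
                continue
            pf = _partial_f_enter(lam_with, lam_model, N, k, q)
            if pf < f_enter:
                continue
            try:
                cv = crit_value(cols)
            except (np.linalg.LinAlgError, linalg.LinAlgError):
                logger.warning("skipping candidate %s (singular criterion)", x)
                continue
            better = (
                best_elem is None
                or (criterion == "wilks" and cv < best_crit)
                or (criterion == "mahalanobis_closest_pair" and cv > best_crit)
            )
            if better:
                best_elem, best_crit, best_f, best_lam = x, cv, pf, lam_with
        if best_elem is None:
            break
        selected.append(best_elem)
        lam_model = best_lam
        step_no += 1
        steps.append(StepRecord(step_no, "enter", best_elem,
                                float(best_crit), float(best_f)))
        # --- removal scan ---
        while len(selected) > 1:
            q = len(selected)
            worst_elem, worst_f = None, np.inf
            for x in selected:
                rest = [c for c in selected if c != x]
                lam_without = subset_wilks(df, labels, rest)
                pf = _partial_f_remove(lam_model, lam_without, N, k, q)
                if pf < worst_f:
                    worst_elem, worst_f = x, pf
            if worst_f >= f_remove:
                break
            selected.remove(worst_elem)
            lam_model = subset_wilks(df, labels, selected)
            step_no += 1
            steps.append(StepRecord(step_no, "remove", worst_elem,
                                    float(crit_value(selected)), float(worst_f)))
            key = frozenset(selected)
            if key in seen:   # cycling guard
                break
            seen.add(key)
        key = frozenset(selected)
        if key in seen:
            break
        seen.add(key)

    flagged = len(selected) == 0
    if flagged:
        logger.warning("stepwise selection is empty: no variable met f_enter")
    return StepwiseTrace(steps=steps, selected=selected, criterion=criterion,
                         f_enter=f_enter, f_remove=f_remove,
                         flagged_empty=flagged)


@dataclass
class DiscriminantFit:
    """Canonical discriminant functions trained on the selected elements.

    ``coefficients`` (p_sel x m) and ``constants`` (m,) map a row of
    selected z-scores to canonical scores with pooled within-group variance
    1 per function; ``centroids`` (k x m) are the per-site mean scores.
    """

    elements: list[str]
    site_order: list[str]
    coefficients: np.ndarray
    constants: np.ndarray
    std_coefficients: np.ndarray
    eigenvalues: np.ndarray
    canonical_correlations: np.ndarray
    variance_shares: np.ndarray
    residual_wilks: np.ndarray
    bartlett_chi2: np.ndarray
    bartlett_df: np.ndarray
    bartlett_p: np.ndarray
    centroids: np.ndarray
    pooled_within_cov: np.ndarray
    group_sizes: dict[str, int]
    retained: int
    N: int = 0
    k: int = 0

    @property
    def n_functions(self) -> int:
        return self.coefficients.shape[1]

    @property
    def wilks_lambda(self) -> float:
        return float(np.prod(1.0 / (1.0 + self.eigenvalues)))

    def transform(self, X) -> np.ndarray:
        """Canonical scores for rows of selected-element z-scores."""
        if isinstance(X, pd.DataFrame):
            missing = [e for e in self.elements if e not in X.columns]
            if missing:
                raise ValueError(f"missing elements: {missing}")
            X = X[self.elements].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        return X @ self.coefficients + self.constants


def fit_canonical(z, labels=None, *, site_order: list[str] | None = None,
                  retention_threshold: float = 1.0) -> DiscriminantFit:
    """Fit canonical discriminant functions on the given (selected) columns.

    Solves the generalized eigenproblem B a = lambda W a; coefficients are
    scaled so each canonical score has pooled within-group variance 1.
    Functions with eigenvalue above ``retention_threshold`` are marked
    retained (at least one is always retained); all functions are reported.
    """
    df, labels = _coerce(z, labels)
    labels = labels.astype(str)
    if site_order is None:
        site_order = [str(g) for g in pd.unique(labels)]
    X = df.to_numpy(dtype=float)
    N, p = X.shape
    k = len(site_order)
    if k < 2:
        raise ValueError("need at least 2 groups")
    W, B = scatter_matrices(X, labels)
    sign, _ = np.linalg.slogdet(W)
    if sign <= 0:
        raise np.linalg.LinAlgError("pooled within-group scatter is singular")
    m = min(p, k - 1)
    # eigh solves B v = theta W v with v' W v = 1, eigenvalues ascending
    theta, V = linalg.eigh(B, W)
    idx = np.argsort(theta)[::-1][:m]
    eigvals = np.clip(theta[idx], 0.0, None)
    # v' W v = 1  =>  pooled within variance of score = v' (W/(N-k)) v = 1/(N-k)
    A = V[:, idx] * np.sqrt(N - k)
    # sign convention: largest-|loading| coefficient positive per function
    for j in range(m):
        lead = np.argmax(np.abs(A[:, j]))
        if A[lead, j] < 0:
            A[:, j] = -A[:, j]
    grand = X.mean(axis=0)
    constants = -grand @ A
    scores = X @ A + constants
    centroids = np.vstack([scores[labels == g].mean(axis=0) for g in site_order])
    Sw = W / (N - k)
    std_A = A * np.sqrt(np.diag(Sw))[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        rc = np.sqrt(eigvals / (1.0 + eigvals))
    total = eigvals.sum()
    shares = eigvals / total if total > 0 else np.zeros_like(eigvals)
    # residual tests: Lambda_j = prod_{i>j} 1/(1+lambda_i), j functions removed
    resid = np.array([np.prod(1.0 / (1.0 + eigvals[j:])) for j in range(m)])
    bart_c = N - 1 - (p + k) / 2.0
    chi2 = -bart_c * np.log(np.clip(resid, 1e-300, None))
    bdf = np.array([(p - j) * (k - 1 - j) for j in range(m)], dtype=int)
    bart_p = stats.chi2.sf(chi2, bdf)
    retained = int(max(1, np.sum(eigvals > retention_threshold)))
    sizes = {g: int(np.sum(labels == g)) for g in site_order}
    return DiscriminantFit(
        elements=list(df.columns), site_order=list(site_order),
        coefficients=A, constants=constants, std_coefficients=std_A,
        eigenvalues=eigvals, canonical_correlations=rc,
        variance_shares=shares, residual_wilks=resid, bartlett_chi2=chi2,
        bartlett_df=bdf, bartlett_p=bart_p, centroids=centroids,
        pooled_within_cov=Sw, group_sizes=sizes, retained=retained,
        N=N, k=k,
    )


def classify(fit: DiscriminantFit, z, *, n_functions: int | None = None
             ) -> tuple[np.ndarray, pd.DataFrame]:
    """Nearest-centroid classification in canonical space.

    Returns predicted site labels and the per-site squared distances
    (Mahalanobis D² under the unit within-score covariance).  Ties go to
    the first site in library order; ``n_functions`` defaults to the fit's
    retained count.
    """
    nf = fit.retained if n_functions is None else n_functions
    scores = fit.transform(z)[:, :nf]
    cents = fit.centroids[:, :nf]
    d2 = ((scores[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    pred = np.array([fit.site_order[i] for i in np.argmin(d2, axis=1)])
    return pred, pd.DataFrame(d2, columns=fit.site_order)


@dataclass
class ClassificationReport:
    site_order: list[str]
    confusion_resub: pd.DataFrame    # counts, rows=true, cols=predicted
    confusion_loo: pd.DataFrame
    per_site_pct_resub: pd.Series
    per_site_pct_loo: pd.Series
    overall_pct_resub: float
    overall_pct_loo: float
    N: int
    K: int
    n_correct_resub: int
    n_correct_loo: int
    press_q: float
    press_q_p: float

    def confusion_pct(self, which: str = "loo") -> pd.DataFrame:
        """Row-percentage confusion matrix (each row sums to 100)."""
        cm = self.confusion_loo if which == "loo" else self.confusion_resub
        return cm.div(cm.sum(axis=1), axis=0) * 100.0


def press_q(N: int, K: int, n_correct: int) -> tuple[float, float]:
    """Press's Q = (N - n K)^2 / (N (K-1)), chi-square with 1 df.

    Tests whether ``n_correct`` correct calls out of ``N`` beat the chance
    rate for ``K`` equally likely classes.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if not 0 <= n_correct <= N:
        raise ValueError("n_correct must lie in [0, N]")
    q = (N - n_correct * K) ** 2 / (N * (K - 1))
    return float(q), float(stats.chi2.sf(q, 1))


def _confusion(true_lab, pred_lab, site_order) -> pd.DataFrame:
    cm = pd.DataFrame(0, index=site_order, columns=site_order, dtype=int)
    for t, p in zip(true_lab, pred_lab):
        cm.loc[t, p] += 1
    return cm


def loo_crossvalidate(z, labels=None, *, selected: list[str] | None = None,
                      site_order: list[str] | None = None,
                      retention_threshold: float = 1.0,
                      n_functions: int | None = None) -> ClassificationReport:
    """Leave-one-out cross-validated classification.

    Each bird is classified by canonical functions refit on the remaining
    N-1 birds; the variable selection is held fixed (pass ``selected``).
    Press's Q is computed from the cross-validated correct count.
    """
    df, labels = _coerce(z, labels)
    labels = labels.astype(str)
    if selected is not None:
        df = df[list(selected)]
    if site_order is None:
        site_order = [str(g) for g in pd.unique(labels)]
    full = fit_canonical(df, labels, site_order=site_order,
                         retention_threshold=retention_threshold)
    nf = full.retained if n_functions is None else n_functions
    pred_resub, _ = classify(full, df, n_functions=nf)
    N = len(df)
    pred_loo = np.empty(N, dtype=object)
    mask = np.ones(N, dtype=bool)
    for i in range(N):
        mask[i] = False
        sub_labels = labels[mask]
        present = [s for s in site_order if (sub_labels == s).any()]
        if len(present) < len(site_order):
            logger.warning("holdout of bird %d removed site %s from training",
                           i, set(site_order) - set(present))
        fit_i = fit_canonical(df.loc[mask], sub_labels, site_order=present,
                              retention_threshold=retention_threshold)
        p_i, _ = classify(fit_i, df.iloc[[i]],
                          n_functions=min(nf, fit_i.n_functions))
        pred_loo[i] = p_i[0]
        mask[i] = True
    cm_resub = _confusion(labels, pred_resub, site_order)
    cm_loo = _confusion(labels, pred_loo, site_order)
    n_ok_resub = int(np.sum(pred_resub == labels))
    n_ok_loo = int(np.sum(pred_loo == labels))
    K = len(site_order)
    q, qp = press_q(N, K, n_ok_loo)
    diag = lambda cm: pd.Series(np.diag(cm), index=site_order)
    row_n = cm_loo.sum(axis=1)
    return ClassificationReport(
        site_order=list(site_order),
        confusion_resub=cm_resub, confusion_loo=cm_loo,
        per_site_pct_resub=diag(cm_resub) / row_n * 100.0,
        per_site_pct_loo=diag(cm_loo) / row_n * 100.0,
        overall_pct_resub=100.0 * n_ok_resub / N,
        overall_pct_loo=100.0 * n_ok_loo / N,
        N=N, K=K, n_correct_resub=n_ok_resub, n_correct_loo=n_ok_loo,
        press_q=q, press_q_p=qp,
    )


@dataclass
class FingerprintLibrary:
    """Everything needed to place a new bird in the library's space.

    Bundles the element panel, the training Scaler (the library defines the
    z-score reference frame for problem birds), the stepwise trace and the
    canonical fit.
    """

    panel: "object"
    scaler: "object"
    trace: StepwiseTrace
    fit: DiscriminantFit
    config: dict = field(default_factory=dict)

    def scores_for(self, table) -> tuple[pd.DataFrame, np.ndarray]:
        """Canonical scores for the birds of a raw SampleTable."""
        from .preprocess import apply_scaler, normalize_to_calcium

        ratio = normalize_to_calcium(table, self.panel)
        zm = apply_scaler(self.scaler, ratio)
        return zm.meta, self.fit.transform(zm.z)
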