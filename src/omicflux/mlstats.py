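"""Statistical and machine-learning feature extraction.

Implements the four downstream analyses applied to transcript, flux and
fused fold-change matrices:

* PCA with variable contributions, cos2 quality scores and pathway-level
  aggregation of component contributions;
* silhouette-guided k-means (correlation distance for the cluster-count
  scan, city-block for the final clustering) with a squared-stress
  nonmetric MDS embedding for display;
* LASSO regression against growth rates with mean-predictor-coefficient
  (MPC) filtering;
* Pearson correlation against growth rates with t-based p-values,
  Fisher-z 95% confidence intervals, and pathway-level binning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist
from sklearn.linear_model import lasso_path
from sklearn.metrics import silhouette_score

from .model import SubsystemIndex

__all__ = [
    "PcaResult",
    "LassoResult",
    "CorrResult",
    "pca_fit",
    "pathway_pca_aggregate",
    "pc_flux_association",
    "correlation_distance",
    "silhouette_scan",
    "kmeans_cluster",
    "nonmetric_mds",
    "lasso_mpc",
    "pearson_with_ci",
    "top_k_predictors",
    "pathway_correlation",
]

logger = logging.getLogger(__name__)

#: half-open bin edges for pathway-level correlation counts
CORRELATION_BINS = [-0.7, -0.5, -0.3, -0.1, 0.1, 0.3, 0.5, 0.7]

#: relative tolerance below which a column/row counts as constant.
#: Flux vectors carry optimizer noise around 1e-9; standardizing such
#: near-constant features would amplify pure noise into spurious
#: statistics, so anything with sd <= tol * max(1, |mean|) is treated
#: exactly like a constant feature.
VARIANCE_RTOL = 1e-8


def _near_constant(sd: np.ndarray, mean: np.ndarray, rtol: float = VARIANCE_RTOL):
    return sd <= rtol * np.maximum(1.0, np.abs(mean))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    """PCA of a standardized conditions x features matrix.

    Conventions follow the common multivariate-analysis definitions:
    variables are centered and scaled with the population (1/n)
    denominator; eigenvalues are those of the correlation matrix and sum
    to the number of (non-constant) standardized variables; variable
    coordinates are loading * sqrt(eigenvalue); contributions are
    100 * coordinate^2 / eigenvalue per component; individual cos2 is
    the squared coordinate normalized over all components.
    """

    eigenvalues: np.ndarray
    ind_coord: pd.DataFrame
    var_coord: pd.DataFrame
    var_contrib: pd.DataFrame
    ind_cos2: pd.DataFrame
    loadings: pd.DataFrame
    center: np.ndarray
    scale: np.ndarray


def pca_fit(matrix, standardize: bool = True) -> PcaResult:
    """PCA of a conditions x features table.

    Constant columns carry no variance: they are kept in the outputs
    with zero coordinates/contributions (their scale is pinned to 1 to
    avoid division by zero) and are excluded from the eigenvalue total.
    """
    values = matrix.values if hasattr(matrix, "feature_kind") else matrix
    if not isinstance(values, pd.DataFrame):
        values = pd.DataFrame(np.asarray(values, dtype=float))
    X = values.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 rows (conditions)")

    center = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0)  # population denominator
        constant = _near_constant(scale, center)
        if constant.any():
            logger.warning("%d constant columns contribute no variance", constant.sum())
        scale = np.where(constant, 1.0, scale)
    else:
        scale = np.ones(p)
        constant = np.zeros(p, dtype=bool)
    Z = (X - center) / scale
    Z[:, constant] = 0.0

    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    tol = max(n, p) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    k = max(int((s > tol).sum()), 1)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # sign convention: largest-magnitude loading positive per component
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0

    eigenvalues = s**2 / n
    comp = [f"Dim.{i + 1}" for i in range(k)]
    ind_coord = pd.DataFrame(U * s, index=values.index, columns=comp)
    loadings = pd.DataFrame(Vt.T, index=values.columns, columns=comp)
    var_coord = loadings * np.sqrt(eigenvalues)
    var_contrib = 100.0 * var_coord**2 / eigenvalues
    sq = ind_coord**2
    denom = sq.sum(axis=1).replace(0.0, np.nan)
    ind_cos2 = sq.div(denom, axis=0)
    return PcaResult(
        eigenvalues=eigenvalues,
        ind_coord=ind_coord,
        var_coord=var_coord,
        var_contrib=var_contrib,
        ind_cos2=ind_cos2,
        loadings=loadings,
        center=center,
        scale=scale,
    )


def pathway_pca_aggregate(
    contrib: pd.DataFrame | np.ndarray, index: SubsystemIndex
) -> pd.DataFrame:
    """Sum and average the first two component contributions per subsystem.

    Rows of ``contrib`` align with reactions; a reaction belonging to k
    subsystems adds its contribution to all k rows of the output.
    Empty subsystems report sums and averages of 0 (logged).
    """
    arr = contrib.to_numpy() if isinstance(contrib, pd.DataFrame) else np.asarray(contrib)
    if arr.shape[1] < 2:
        raise ValueError("need contributions for at least two components")
    rows = []
    for name, members, card in zip(index.names, index.membership, index.cardinality):
        if card == 0:
            logger.warning("subsystem %r has no member reactions", name)
            s1 = s2 = a1 = a2 = 0.0
        else:
            s1 = float(arr[members, 0].sum())
            s2 = float(arr[members, 1].sum())
            a1, a2 = s1 / card, s2 / card
        rows.append(
            {
                "Subsystem": name,
                "PC1 Sum": s1,
                "PC1 Average": a1,
                "PC2 Sum": s2,
                "PC2 Average": a2,
                "Cardinality": int(card),
            }
        )
    return pd.DataFrame(rows).set_index("Subsystem")


def pc_flux_association(ind_coord_column, flux_column):
    """Pearson r plus least-squares line between a PC coordinate and a flux.

    Returns (r, slope, intercept) of flux ~ coordinate. Zero-variance
    input yields r = NaN.
    """
    x = np.asarray(ind_coord_column, dtype=float)
    y = np.asarray(flux_column, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("inputs must be equal-length vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    slope, intercept = np.polyfit(x, y, 1)
    return r, float(slope), float(intercept)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def _zscore(X: np.ndarray, ddof: int = 1) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=ddof, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def correlation_distance(matrix) -> np.ndarray:
    """Condensed pairwise 1 - Pearson r between rows of standardized data.

    Rows are z-scored first (which leaves the correlation distance
    unchanged but mirrors the documented procedure); constant rows have undefined
    correlation and get distance 1 to every other row (logged).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    n = X.shape[0]
    means = X.mean(axis=1)
    centered = X - means[:, None]
    norms = np.linalg.norm(centered, axis=1)
    constant = _near_constant(norms / np.sqrt(X.shape[1]), means)
    if constant.any():
        logger.warning("%d constant rows: correlation undefined, distance set to 1", constant.sum())
    safe = np.where(constant, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    dist = 1.0 - corr
    dist[constant, :] = 1.0
    dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    return squareform(dist, checks=False)


def _init_centroids(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.choice(X.shape[0], size=k, replace=False)
    return X[idx].copy()


def _kmeans_once(X, k, metric, rng, max_iter=300):
    n = X.shape[0]
    if metric == "correlation":
        Xw = _zscore(X, ddof=0)
        Xw /= np.maximum(np.linalg.norm(Xw, axis=1, keepdims=True), 1e-12)
    else:
        Xw = X
    C = _init_centroids(Xw, k, rng)
    labels = np.full(n, -1)
    for _ in range(max_iter):
        if metric == "cityblock":
            D = np.abs(Xw[:, None, :] - C[None, :, :]).sum(axis=2)
        else:  # correlation: 1 - dot on unit-norm rows
            D = 1.0 - Xw @ C.T
        new_labels = D.argmin(axis=1)
        # keep clusters non-empty: move the farthest point into empty ones
        for c in range(k):
            if not (new_labels == c).any():
                far = D[np.arange(n), new_labels].argmax()
                new_labels[far] = c
        if (new_labels == labels).all():
            break
        labels = new_labels
        for c in range(k):
            members = Xw[labels == c]
            if metric == "cityblock":
                C[c] = np.median(members, axis=0)
            else:
                m = members.mean(axis=0)
                C[c] = m / max(np.linalg.norm(m), 1e-12)
    if metric == "cityblock":
        inertia = float(np.abs(Xw - C[labels]).sum())
    else:
        inertia = float((1.0 - (Xw * C[labels]).sum(axis=1)).sum())
    return labels, C, inertia


def kmeans_cluster(
    matrix,
    k: int,
    metric: str = "cityblock",
    restarts: int = 5,
    seed: int = 0,
    centroid_update: str = "median",
):
    """K-means over rows with city-block or correlation distance.

    City-block clustering uses per-coordinate medians as centroids (the
    distance's minimizer); ``centroid_update='mean'`` is accepted as a
    compatibility mode with mean-update implementations. The best of
    ``restarts`` random initializations (by total within-cluster
    distance) is returned; a fixed seed makes the result deterministic.
    """
    X = np.asarray(matrix, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError(f"k = {k} exceeds the number of points ({X.shape[0]})")
    if metric not in ("cityblock", "correlation"):
        raise ValueError(f"unsupported metric {metric!r}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(restarts, 1)):
        labels, C, inertia = _kmeans_once(X, k, metric, rng)
        if centroid_update == "mean" and metric == "cityblock":
            for c in range(k):
                C[c] = X[labels == c].mean(axis=0)
        if best is None or inertia < best[2]:
            best = (labels, C, inertia)
    return best[0], best[1]


def silhouette_scan(
    matrix,
    k_range=range(2, 31),
    restarts: int = 5,
    seed: int = 0,
) -> tuple[dict[int, float], int]:
    """Mean silhouette (correlation distance) per cluster count.

    Clusters each k with correlation-distance k-means and scores the
    partition with the mean silhouette over the same distance; returns
    the per-k scores and the argmax k. Values of k at or beyond the row
    count are skipped with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    D = squareform(correlation_distance(X), checks=False)
    scores: dict[int, float] = {}
    for k in k_range:
        if k >= X.shape[0]:
            logger.warning("skipping k=%d (only %d rows)", k, X.shape[0])
            continue
        labels, _ = kmeans_cluster(X, k, metric="correlation", restarts=restarts, seed=seed)
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = float(silhouette_score(D, labels, metric="precomputed"))
    if not scores:
        raise ValueError("no feasible cluster count in k_range")
    best_k = max(scores, key=lambda k: (scores[k], -k))
    return scores, best_k


def _sstress(flat, delta_sq, n, dims):
    Y = flat.reshape(n, dims)
    diff = Y[:, None, :] - Y[None, :, :]
    d_sq = (diff**2).sum(axis=2)
    iu = np.triu_indices(n, 1)
    resid = d_sq[iu] - delta_sq
    val = float((resid**2).sum())
    G = np.zeros_like(Y)
    R = np.zeros((n, n))
    R[iu] = resid
    R = R + R.T
    G = 4.0 * (R[:, :, None] * diff).sum(axis=1)
    return val, G.ravel()


def nonmetric_mds(
    distances: np.ndarray,
    dims: int = 2,
    max_iter: int = 500,
    seed: int = 0,
    retries: int = 10,
) -> tuple[np.ndarray, float]:
    """Squared-stress MDS embedding from a seeded random start.

    Minimizes sum over pairs of (d_ij^2 - delta_ij^2)^2 with L-BFGS-B
    (at most ``max_iter`` iterations). If the embedding degenerates
    (co-located points), the dissimilarities are multiplied by 1.01 and
    the fit restarts, up to ``retries`` times; persistent degeneracy is
    an error. Returns (embedding, normalized square-root stress).
    """
    delta = np.asarray(distances, dtype=float).copy()
    n = int(round((1 + np.sqrt(1 + 8 * len(delta))) / 2))
    if n * (n - 1) // 2 != len(delta):
        raise ValueError("distances must be a condensed pairwise vector")
    rng = np.random.default_rng(seed)
    scale = np.max(delta) if np.max(delta) > 0 else 1.0
    for attempt in range(retries + 1):
        delta_sq = delta**2
        y0 = rng.normal(scale=scale, size=n * dims)
        res = minimize(
            _sstress,
            y0,
            args=(delta_sq, n, dims),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter},
        )
        Y = res.x.reshape(n, dims)
        # degenerate when two embedded points coincide
        diff = Y[:, None, :] - Y[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
        iu = np.triu_indices(n, 1)
        if np.all(d[iu] > 1e-9 * max(scale, 1.0)):
            denom = float((delta_sq**2).sum()) or 1.0
            stress = float(np.sqrt(res.fun / denom))
            return Y, stress
        logger.warning(
            "MDS degenerate on attempt %d: scaling dissimilarities by 1.01", attempt + 1
        )
        delta = delta * 1.01
    raise RuntimeError("nonmetric MDS failed: embedding degenerate after retries")


# ---------------------------------------------------------------------------
# LASSO
# ---------------------------------------------------------------------------


@dataclass
class LassoResult:
    lambda_path: np.ndarray
    coef_path: pd.DataFrame  # predictors x lambdas, original scale
    mpc: pd.Series
    retained: pd.DataFrame  # |mpc| > cutoff, sorted by mpc descending


def lasso_mpc(
    X,
    y,
    cutoff: float = 0.01,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-4,
    nonzero_only: bool = False,
) -> LassoResult:
    """L1 regularization path with mean-predictor-coefficient filtering.

    Predictors are standardized internally; coefficients are reported on
    the original scale. The geometric penalty grid runs from lambda_max
    (the smallest penalty with an all-zero solution) down by
    ``lambda_min_ratio``. The MPC of a predictor is the mean of its
    coefficients across the whole path (zeros included by default;
    ``nonzero_only=True`` averages only nonzero path entries). Retained
    predictors satisfy |MPC| > cutoff and are sorted by MPC descending.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    Xa = Xdf.to_numpy(dtype=float)
    ya = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    if len(ya) != n:
        raise ValueError("X and y dimensions do not match")

    mu = Xa.mean(axis=0)
    sd = Xa.std(axis=0, ddof=1)
    constant = _near_constant(sd, mu)
    sd = np.where(constant, 1.0, sd)
    Xs = (Xa - mu) / sd
    Xs[:, constant] = 0.0  # constant predictors can never be selected
    yc = ya - ya.mean()

    alphas, coefs, _ = lasso_path(
        Xs, yc, eps=lambda_min_ratio, alphas=n_lambdas, max_iter=10000
    )
    coef_orig = coefs / sd[:, None]
    coef_path = pd.DataFrame(
        coef_orig,
        index=Xdf.columns,
        columns=[f"lambda_{i}" for i in range(len(alphas))],
    )
    if nonzero_only:
        arr = coef_orig.copy()
        mask = arr != 0
        with np.errstate(invalid="ignore"):
            means = np.where(mask.any(axis=1), arr.sum(axis=1) / np.maximum(mask.sum(axis=1), 1), 0.0)
        mpc = pd.Series(means, index=Xdf.columns, name="mpc")
    else:
        mpc = pd.Series(coef_orig.mean(axis=1), index=Xdf.columns, name="mpc")
    keep = mpc[mpc.abs() > cutoff].sort_values(ascending=False)
    retained = pd.DataFrame({"mpc": keep})
    return LassoResult(
        lambda_path=alphas, coef_path=coef_path, mpc=mpc, retained=retained
    )


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrResult:
    table: pd.DataFrame  # columns: r, pval, lb95, ub95 (rows = features)

    @property
    def r(self) -> pd.Series:
        return self.table["r"]


def pearson_with_ci(X, y, n_min_ci: int = 4) -> CorrResult:
    """Per-feature Pearson r, two-sided p-value and Fisher-z 95% CI.

    p comes from t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom;
    the interval is tanh(atanh(r) +/- 1.96/sqrt(n-3)). Zero-variance
    features yield NaN throughout; |r| = 1 collapses the interval.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    ya = np.asarray(y, dtype=float)
    n = len(ya)
    if Xdf.shape[0] != n:
        raise ValueError("X rows must match y length")
    if n < n_min_ci:
        raise ValueError(f"need at least {n_min_ci} observations for the 95% CI")
    yc = ya - ya.mean()
    ynorm = np.linalg.norm(yc)
    out = np.full((Xdf.shape[1], 4), np.nan)
    Xa = Xdf.to_numpy(dtype=float)
    for j in range(Xa.shape[1]):
        mu_j = Xa[:, j].mean()
        xc = Xa[:, j] - mu_j
        xnorm = np.linalg.norm(xc)
        if _near_constant(xnorm / np.sqrt(n), mu_j) or ynorm == 0:
            continue
        r = float(np.clip(xc @ yc / (xnorm * ynorm), -1.0, 1.0))
        if abs(r) == 1.0:
            p = 0.0
            lo = hi = r
        else:
            tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
            p = 2.0 * t_dist.sf(abs(tstat), n - 2)
            half = 1.96 / np.sqrt(n - 3)
            z = np.arctanh(r)
            lo, hi = np.tanh(z - half), np.tanh(z + half)
        out[j] = (r, p, lo, hi)
    table = pd.DataFrame(out, index=Xdf.columns, columns=["r", "pval", "lb95", "ub95"])
    return CorrResult(table=table)


def top_k_predictors(
    result: CorrResult, X: pd.DataFrame | None = None, k: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k positively and top-k negatively correlated features.

    NaN correlations are excluded; ties are broken by feature id so the
    selection is deterministic. When ``X`` is given, the per-condition
    values of the selected features are attached for plotting.
    """
    tab = result.table.dropna(subset=["r"])
    tab = tab.sort_index(kind="stable")
    pos = tab.sort_values("r", ascending=False, kind="stable").head(k)
    neg = tab.sort_values("r", ascending=True, kind="stable").head(k)
    if X is not None:
        pos = pos.join(X.T, how="left")
        neg = neg.join(X.T, how="left")
    return pos, neg


def pathway_correlation(
    result: CorrResult, index: SubsystemIndex
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subsystem mean |r| and counts of r in seven half-open bins.

    NaN coefficients are set to 0 before aggregation. The bins partition
    [-0.7, 0.7): [-0.7,-0.5), [-0.5,-0.3), [-0.3,-0.1), [-0.1,0.1),
    [0.1,0.3), [0.3,0.5), [0.5,0.7). Coefficients outside that range
    land in an explicit 'overflow' column rather than being dropped.
    """
    r = result.table["r"].to_numpy(dtype=float).copy()
    r[np.isnan(r)] = 0.0
    labels = [
        f"[{CORRELATION_BINS[i]:g}, {CORRELATION_BINS[i + 1]:g})"
        for i in range(len(CORRELATION_BINS) - 1)
    ]
    mean_rows, bin_rows = [], []
    for name, members, card in zip(index.names, index.membership, index.cardinality):
        vals = r[members]
        mean_abs = float(np.abs(vals).mean()) if card else 0.0
        counts = {
            lab: int(
                ((vals >= CORRELATION_BINS[i]) & (vals < CORRELATION_BINS[i + 1])).sum()
            )
            for i, lab in enumerate(labels)
        }
        counts["overflow"] = int(
            ((vals < CORRELATION_BINS[0]) | (vals >= CORRELATION_BINS[-1])).sum()
        )
        mean_rows.append({"Subsystem": name, "mean_abs_r": mean_abs, "n_reactions": int(card)})
        bin_rows.append({"Subsystem": name, **counts})
    mean_df = pd.DataFrame(mean_rows).set_index("Subsystem")
    bins_df = pd.DataFrame(bin_rows).set_index("Subsystem")
    return mean_df, bins_df
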