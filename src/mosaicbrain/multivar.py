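"""Phylogenetically corrected PCA and phylogenetic flexible discriminant analysis.

pPCA eigen-decomposes the evolutionary (GLS-estimated) trait covariance
matrix, centered on the phylogenetic mean, so species scores describe trait
variation net of the expected covariance induced by shared ancestry.
Individual-level observations can then be projected onto the species-mean
rotation. pFDA first chooses the Pagel's lambda that minimizes the residual
sum of squares of the regression of group indicators on traits after
whitening both by the inverse Cholesky factor of the lambda-scaled
phylogenetic correlation, then performs flexible discriminant analysis (via
optimal scoring) in that whitened space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .phylo import Phylogeny, lambda_transform, shared_path_times

__all__ = [
    "PPCAResult",
    "PFDAResult",
    "ppca_fit",
    "ppca_project",
    "zscore_normalize",
    "score_trait_correlation",
    "pfda_optimize_lambda",
    "pfda_fit_predict",
]


@dataclass
class PPCAResult:
    phylo_mean: pd.Series           # GLS mean per trait
    evol_cov: pd.DataFrame          # evolutionary covariance among traits
    eigenvalues: np.ndarray         # descending
    eigenvectors: pd.DataFrame      # columns PC1.., rows = traits, unit norm
    scores: pd.DataFrame            # species x PCs
    percent_variance: np.ndarray
    mode: str                       # "cov" or "corr"

    def n_components(self) -> int:
        return len(self.eigenvalues)


def _phylo_mean_and_cov(
    X: np.ndarray, Cinv: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    one = np.ones(X.shape[0])
    denom = one @ Cinv @ one
    a = (one @ Cinv @ X) / denom
    Xc = X - a
    R = Xc.T @ Cinv @ Xc / (X.shape[0] - 1)
    return a, R


def ppca_fit(
    traits: pd.DataFrame, tree: Phylogeny, mode: str = "cov"
) -> PPCAResult:
    """Phylogenetic PCA on a species x trait matrix of species means.

    The phylogenetic mean is the GLS estimate a = (1'C^-1 1)^-1 1'C^-1 X
    under the Brownian covariance C; the evolutionary covariance is
    R = (X-a)' C^-1 (X-a)/(n-1). Scores are (X - a) @ eigenvectors. With
    ``mode="corr"`` R is rescaled to a correlation matrix before the
    eigen-decomposition. Sign convention: each eigenvector's
    largest-magnitude loading is positive.
    """
    if traits.shape[1] < 2:
        raise ValueError("need >= 2 traits")
    if traits.shape[0] < 3:
        raise ValueError("need >= 3 species")
    if traits.isna().any().any():
        raise ValueError("missing values in trait matrix")
    if mode not in ("cov", "corr"):
        raise ValueError(f"mode must be 'cov' or 'corr', got {mode!r}")
    C = shared_path_times(tree)
    order = [s for s in C.index if s in set(traits.index.astype(str))]
    if len(order) != traits.shape[0]:
        missing = sorted(set(traits.index.astype(str)) - set(C.index))
        raise ValueError(f"species not in tree: {missing}")
    X = traits.loc[order].to_numpy(dtype=float)
    Cm = C.loc[order, order].to_numpy()
    Cinv = linalg.inv(Cm)
    a, R = _phylo_mean_and_cov(X, Cinv)
    if mode == "corr":
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    evals, evecs = linalg.eigh(R)
    idx = np.argsort(evals)[::-1]
    evals = evals[idx]
    evecs = evecs[:, idx]
    # deterministic sign: largest-magnitude loading positive
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] *= -1.0
    pcs = [f"PC{j + 1}" for j in range(evecs.shape[1])]
    scores = (X - a) @ evecs
    pct = 100.0 * evals / evals.sum()
    return PPCAResult(
        phylo_mean=pd.Series(a, index=traits.columns),
        evol_cov=pd.DataFrame(R, index=traits.columns, columns=traits.columns),
        eigenvalues=evals,
        eigenvectors=pd.DataFrame(evecs, index=traits.columns, columns=pcs),
        scores=pd.DataFrame(scores, index=order, columns=pcs),
        percent_variance=pct,
        mode=mode,
    )


def ppca_project(individuals: pd.DataFrame, fit: PPCAResult) -> pd.DataFrame:
    """Project individual-level rows onto a fitted species-mean rotation."""
    cols = list(fit.eigenvectors.index)
    missing = [c for c in cols if c not in individuals.columns]
    if missing:
        raise ValueError(f"trait columns missing from individuals: {missing}")
    X = individuals[cols].to_numpy(dtype=float)
    scores = (X - fit.phylo_mean.to_numpy()) @ fit.eigenvectors.to_numpy()
    return pd.DataFrame(scores, index=individuals.index, columns=fit.eigenvectors.columns)


def zscore_normalize(traits: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores (mean 0, sample SD 1)."""
    sd = traits.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance trait column(s): {list(zero.index)}")
    return (traits - traits.mean()) / sd


def score_trait_correlation(scores, trait, method: str = "spearman"):
    """Rank correlation between a PC score vector and a trait vector."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(trait, dtype=float)
    if len(s) != len(t) or len(s) < 4:
        raise ValueError("need equal-length vectors of length >= 4")
    if np.ptp(s) == 0 or np.ptp(t) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method != "spearman":
        raise ValueError("only the rank-based (spearman) method is implemented")
    rho, p = stats.spearmanr(s, t)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# phylogenetic flexible discriminant analysis


@dataclass
class PFDAResult:
    lam: float
    coefficients: pd.DataFrame      # traits x discriminant axes
    group_means: pd.DataFrame       # groups x axes (centroids in axis space)
    scores: pd.DataFrame            # observations x axes
    predicted: pd.Series
    confusion: pd.DataFrame
    eigenvalues: np.ndarray


def _phylo_correlation(tree: Phylogeny, order: list[str]) -> np.ndarray:
    C = shared_path_times(tree).loc[order, order].to_numpy()
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


def _whiten(X: np.ndarray, Y: np.ndarray, V: np.ndarray):
    L = linalg.cholesky(V, lower=True)
    return (
        linalg.solve_triangular(L, X, lower=True),
        linalg.solve_triangular(L, Y, lower=True),
    )


def _indicator(groups: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(groups.astype(str).unique())
    Y = np.zeros((len(groups), len(levels)))
    for j, lev in enumerate(levels):
        Y[:, j] = (groups.astype(str) == lev).to_numpy(dtype=float)
    return Y, levels


def _rss_at_lambda(
    X: np.ndarray, Y: np.ndarray, Ctilde: np.ndarray, lam: float
) -> float:
    V = lambda_transform(Ctilde, lam)
    Xw, Yw = _whiten(np.column_stack([np.ones(len(X)), X]), Y, V)
    B, _, rank, _ = np.linalg.lstsq(Xw, Yw, rcond=None)
    if rank < Xw.shape[1]:
        raise np.linalg.LinAlgError(f"singular whitened design at lambda={lam}")
    resid = Yw - Xw @ B
    return float(np.sum(resid**2))


def pfda_optimize_lambda(
    traits: pd.DataFrame,
    groups: pd.Series,
    tree: Phylogeny,
    grid: np.ndarray | None = None,
) -> tuple[float, pd.DataFrame]:
    """Grid search for the lambda minimizing whitened-regression RSS.

    Returns ``(lambda_star, curve)`` where ``curve`` has columns ``lambda``
    and ``rss``; the argmin of the curve is exactly ``lambda_star`` (ties
    broken toward smaller lambda by the stable scan order).
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 10)
    grid = np.asarray(grid, dtype=float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("lambda grid must lie within [0, 1]")
    if groups.astype(str).nunique() < 2:
        raise ValueError("need >= 2 groups")
    C = shared_path_times(tree)
    order = [s for s in C.index if s in set(traits.index.astype(str))]
    X = traits.loc[order].to_numpy(dtype=float)
    Y, _ = _indicator(groups.loc[order])
    Ct = _phylo_correlation(tree, order)
    rss = np.array([_rss_at_lambda(X, Y, Ct, l) for l in grid])
    lam_star = float(grid[int(np.argmin(rss))])
    return lam_star, pd.DataFrame({"lambda": grid, "rss": rss})


def pfda_fit_predict(
    traits: pd.DataFrame,
    groups: pd.Series,
    tree: Phylogeny,
    lam: float,
) -> PFDAResult:
    """Flexible discriminant analysis on lambda-whitened data (optimal scoring).

    Group indicators are regressed on the whitened traits; the fitted-score
    cross-product Y'Yhat is eigen-decomposed (generalized by class counts) to
    give at most (g - 1) canonical axes. Observations are classified by the
    nearest group centroid in discriminant space, and a training confusion
    table is returned.
    """
    groups = groups.astype(str)
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("need >= 2 groups")
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"groups with < 2 members: {dict(small)}")
    C = shared_path_times(tree)
    order = [s for s in C.index if s in set(traits.index.astype(str))]
    X = traits.loc[order].to_numpy(dtype=float)
    g = groups.loc[order]
    Y, levels = _indicator(g)
    Ct = _phylo_correlation(tree, order)
    V = lambda_transform(Ct, lam)
    n, J = Y.shape

    X1 = np.column_stack([np.ones(n), X])
    Xw, Yw = _whiten(X1, Y, V)
    B, _, rank, _ = np.linalg.lstsq(Xw, Yw, rcond=None)
    if rank < Xw.shape[1]:
        raise np.linalg.LinAlgError("singular whitened design")
    Yhat = Xw @ B

    # optimal scoring: generalized eigenproblem Y'Yhat th = ev * diag(N_j) th,
    # restricted to class scores orthogonal (in the count metric) to the
    # constant score, which removes the trivial dimension and leaves J-1 axes
    M = Y.T @ Yhat
    Dp = np.diag(Y.sum(axis=0))
    u = Dp @ np.ones(J)
    K = linalg.null_space(u[None, :])           # J x (J-1)
    evals, etas = linalg.eigh(K.T @ (M + M.T) @ K / 2.0, K.T @ Dp @ K)
    idx = np.argsort(evals)[::-1]
    evals = evals[idx]
    thetas = K @ etas[:, idx]
    A = B[1:, :] @ thetas            # trait-space coefficients per axis
    # deterministic sign: largest-magnitude coefficient positive
    for j in range(A.shape[1]):
        i = np.argmax(np.abs(A[:, j]))
        if A[i, j] < 0:
            A[:, j] *= -1.0
            thetas[:, j] *= -1.0
    axes = [f"DA{j + 1}" for j in range(A.shape[1])]
    scores = (Yhat - Yhat.mean(axis=0)) @ thetas  # centered discriminant variates

    centroids = np.vstack([scores[(g == lev).to_numpy()].mean(axis=0) for lev in levels])
    d2 = ((scores[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    pred = pd.Series(
        [levels[i] for i in np.argmin(d2, axis=1)], index=order, name="predicted"
    )
    confusion = pd.crosstab(g, pred).reindex(
        index=levels, columns=levels, fill_value=0
    )
    return PFDAResult(
        lam=lam,
        coefficients=pd.DataFrame(A, index=traits.columns, columns=axes),
        group_means=pd.DataFrame(centroids, index=levels, columns=axes),
        scores=pd.DataFrame(scores, index=order, columns=axes),
        predicted=pred,
        confusion=confusion,
        eigenvalues=evals,
    )
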