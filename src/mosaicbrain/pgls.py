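"""PGLS with maximum-likelihood Pagel's lambda, phylogenetic ANCOVA, and
information-criterion model selection.

All fits operate on species means. The residual covariance is the Brownian
shared-path-time matrix under Pagel's lambda transform; lambda is either fixed
or profiled by maximum likelihood over [0, 1]. The phylogenetically corrected
ANCOVA tests slope homogeneity (group x covariate interaction) and intercept
homogeneity (group term given a common slope) with GLS F-tests from nested
model comparisons, holding the full-model lambda-hat fixed across the nested
fits so that the models remain comparable. Pairwise post-hoc contrasts use
the GLS coefficient covariance with a Bonferroni correction, and effect sizes
are Cohen's d: the adjusted-mean contrast divided by the GLS residual SD of
the common-slope model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .phylo import Phylogeny, lambda_transform, shared_path_times

__all__ = [
    "ModelSpec",
    "PGLSFit",
    "AncovaResult",
    "PosthocResult",
    "fit_pgls",
    "ancova_groups",
    "pairwise_posthoc",
    "information_criteria",
    "candidate_model_selection",
    "cohens_d",
]


class SingularDesignError(ValueError):
    """Design matrix is rank deficient."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative regression specification.

    ``interaction`` adds group x covariate terms for the *first* covariate
    (the allometric covariate), which is the ANCOVA slope-heterogeneity term.
    """

    response: str
    covariates: tuple[str, ...] = ()
    group: str | None = None
    interaction: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.covariates, str):
            object.__setattr__(self, "covariates", (self.covariates,))
        else:
            object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.response in self.covariates:
            raise ValueError("response cannot appear among covariates")
        if self.interaction and (self.group is None or not self.covariates):
            raise ValueError("interaction requires both a group and a covariate")

    def label(self) -> str:
        parts = list(self.covariates)
        if self.group:
            parts.append(self.group)
        if self.interaction:
            parts.append(f"{self.group}x{self.covariates[0]}")
        return f"{self.response} ~ " + (" + ".join(parts) if parts else "1")


@dataclass
class PGLSFit:
    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    lam: float
    lam_profiled: bool
    sigma2: float                   # ML residual variance (per unit V0 scale)
    loglik: float
    n: int
    n_params: int                   # coefficients + variance (+ lambda if profiled)
    fitted: pd.Series
    resid: pd.Series
    rss_whitened: float
    design_columns: list[str]

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def aicc(self) -> float:
        p = self.n_params
        if self.n - p - 1 <= 0:
            raise ValueError(f"AICc undefined: n={self.n} <= p+1={p + 1}")
        return self.aic + 2.0 * p * (p + 1) / (self.n - p - 1)

    @property
    def resid_sd(self) -> float:
        """Unbiased GLS residual SD (whitened scale)."""
        return float(np.sqrt(self.rss_whitened / (self.n - len(self.params))))


def _design_matrix(
    spec: ModelSpec, data: pd.DataFrame
) -> tuple[np.ndarray, list[str], pd.DataFrame | None]:
    """Build the design matrix: intercept, covariates, group dummies, interaction."""
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(data))}
    for c in spec.covariates:
        if c not in data.columns:
            raise ValueError(f"covariate column '{c}' missing from data")
        cols[c] = data[c].to_numpy(dtype=float)
    dummies = None
    if spec.group is not None:
        if spec.group not in data.columns:
            raise ValueError(f"group column '{spec.group}' missing from data")
        g = data[spec.group].astype(str)
        levels = sorted(g.unique())
        if len(levels) < 2:
            raise ValueError(f"group factor '{spec.group}' needs >= 2 levels")
        dummies = pd.get_dummies(pd.Categorical(g, categories=levels), drop_first=True)
        for lev in dummies.columns:
            cols[f"{spec.group}[{lev}]"] = dummies[lev].to_numpy(dtype=float)
        if spec.interaction:
            x0 = data[spec.covariates[0]].to_numpy(dtype=float)
            for lev in dummies.columns:
                cols[f"{spec.group}[{lev}]:{spec.covariates[0]}"] = (
                    dummies[lev].to_numpy(dtype=float) * x0
                )
    X = np.column_stack(list(cols.values()))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            f"rank-deficient design ({np.linalg.matrix_rank(X)} < {X.shape[1]}): "
            + ", ".join(cols)
        )
    return X, list(cols), dummies


def _align(data: pd.DataFrame, tree: Phylogeny) -> tuple[pd.DataFrame, np.ndarray]:
    """Align data rows with tree tips; return data in tip order plus V0 = shared times."""
    species = list(data.index.astype(str))
    tips = tree.tip_labels
    missing = sorted(set(species) - set(tips))
    extra = sorted(set(tips) - set(species))
    if missing:
        raise ValueError(f"species not in tree: {missing}")
    if extra:
        raise ValueError(f"tree tips without data: {extra}")
    C = shared_path_times(tree)
    order = [s for s in C.index if s in set(species)]
    V0 = C.loc[order, order].to_numpy()
    # unit mean diagonal: a pure rescaling (exact for ultrametric trees) that
    # leaves estimates, tests and the profiled log-likelihood unchanged but
    # puts the residual SD on the trait scale (used by Cohen's d)
    return data.loc[order], V0 / np.mean(np.diag(V0))


def _gls_profile(
    y: np.ndarray, X: np.ndarray, V0: np.ndarray, lam: float
) -> tuple[float, np.ndarray, np.ndarray, float, float, np.ndarray]:
    """Fit GLS at fixed lambda; return (loglik, beta, cov_beta_unit, sigma2, rss, L).

    sigma2 is the ML estimate; cov_beta must be scaled by rss/(n-p) outside
    for unbiased standard errors.
    """
    n, p = X.shape
    V = lambda_transform(V0, lam)
    L = linalg.cholesky(V, lower=True)
    z = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, z, rcond=None)
    if rank < p:
        raise SingularDesignError("rank-deficient whitened design")
    resid = z - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + n + logdet)
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    return loglik, beta, XtX_inv, sigma2, rss, L


def _reml_loglik(y: np.ndarray, X: np.ndarray, V0: np.ndarray, lam: float) -> float:
    """Restricted log-likelihood at fixed lambda (used for lambda in tests)."""
    n, p = X.shape
    V = lambda_transform(V0, lam)
    L = linalg.cholesky(V, lower=True)
    z = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    beta, _, _, _ = np.linalg.lstsq(Xw, z, rcond=None)
    resid = z - Xw @ beta
    rss = float(resid @ resid)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    _, ld_x = np.linalg.slogdet(Xw.T @ Xw)
    return -0.5 * (
        (n - p) * np.log(2.0 * np.pi * rss / (n - p)) + (n - p) + logdet + ld_x
    )


def fit_pgls(
    spec: ModelSpec,
    data: pd.DataFrame,
    tree: Phylogeny,
    lam: float | str = "ML",
) -> PGLSFit:
    """Phylogenetic GLS regression under Pagel's lambda.

    ``data`` is a species-mean table indexed by species label (matching the
    tree's tips exactly). With ``lam="ML"`` the profile log-likelihood is
    maximized over lambda in [0, 1] (bounded scalar search, tolerance 1e-6,
    endpoints checked, ties broken toward the smaller lambda); ``lam="REML"``
    profiles the restricted likelihood instead (preferred when the fit feeds
    hypothesis tests, since it debiases the residual variance); a float fixes
    lambda. At lambda = 0 every quantity reduces to ordinary least squares.
    The reported ``loglik`` is always the ML log-likelihood at lambda-hat, so
    AIC/AICc remain comparable across fits.
    """
    used = [spec.response, *spec.covariates] + ([spec.group] if spec.group else [])
    miss = [c for c in used if c in data.columns and data[c].isna().any()]
    if miss:
        raise ValueError(f"missing values in columns: {miss}")
    data_al, V0 = _align(data, tree)
    y = data_al[spec.response].to_numpy(dtype=float)
    X, names, _ = _design_matrix(spec, data_al)
    n, p = X.shape

    profiled = isinstance(lam, str)
    if profiled:
        if lam not in ("ML", "REML"):
            raise ValueError(f"lam must be a float, 'ML' or 'REML', got {lam!r}")
        if lam == "ML":
            nll = lambda l: -_gls_profile(y, X, V0, l)[0]
        else:
            nll = lambda l: -_reml_loglik(y, X, V0, l)
        res = optimize.minimize_scalar(
            nll, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-6}
        )
        cands = [(nll(0.0), 0.0), (nll(1.0), 1.0), (res.fun, float(res.x))]
        lam_hat = min(cands, key=lambda t: (round(t[0], 10), t[1]))[1]
    else:
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {lam}")
        lam_hat = float(lam)

    loglik, beta, XtX_inv, sigma2, rss, _ = _gls_profile(y, X, V0, lam_hat)
    cov_beta = XtX_inv * rss / (n - p)
    bse = np.sqrt(np.diag(cov_beta))
    fitted = X @ beta
    idx = data_al.index
    return PGLSFit(
        spec=spec,
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        cov_params=pd.DataFrame(cov_beta, index=names, columns=names),
        lam=lam_hat,
        lam_profiled=profiled,
        sigma2=sigma2,
        loglik=loglik,
        n=n,
        n_params=p + 1 + int(profiled),
        fitted=pd.Series(fitted, index=idx),
        resid=pd.Series(y - fitted, index=idx),
        rss_whitened=rss,
        design_columns=names,
    )


# ---------------------------------------------------------------------------
# phylogenetic ANCOVA


@dataclass
class PosthocResult:
    performed: bool
    reason: str = ""
    n_pairs: int = 0
    slope_p: pd.DataFrame | None = None       # Bonferroni-adjusted
    intercept_p: pd.DataFrame | None = None   # Bonferroni-adjusted
    slope_p_raw: pd.DataFrame | None = None
    intercept_p_raw: pd.DataFrame | None = None
    cohens_d: pd.DataFrame | None = None


@dataclass
class AncovaResult:
    spec: ModelSpec
    lam: float
    slope_p: float
    slope_F: float
    intercept_p: float
    intercept_F: float
    full_fit: PGLSFit
    additive_fit: PGLSFit
    covariate_fit: PGLSFit
    groups: list[str]
    posthoc: PosthocResult | None = None


def _nested_f(fit_full: PGLSFit, fit_red: PGLSFit) -> tuple[float, float]:
    """F-test of nested GLS models sharing lambda, via whitened RSS."""
    df1 = len(fit_full.params) - len(fit_red.params)
    df2 = fit_full.n - len(fit_full.params)
    F = ((fit_red.rss_whitened - fit_full.rss_whitened) / df1) / (
        fit_full.rss_whitened / df2
    )
    return float(F), float(stats.f.sf(F, df1, df2))


def ancova_groups(
    spec: ModelSpec,
    data: pd.DataFrame,
    tree: Phylogeny,
    posthoc_alpha: float = 0.05,
    run_posthoc: bool = True,
) -> AncovaResult:
    """Phylogenetically corrected ANCOVA on grouped allometries.

    Fits the full interaction model with REML-profiled lambda (REML debiases
    the residual variance, keeping the F-tests calibrated at small n); the
    slope test compares the
    full model against the additive (common-slope) model, and the intercept
    test compares the additive model against the covariate-only model, with
    lambda-hat held fixed across the nested fits. Pairwise Bonferroni
    post-hoc contrasts are run only when the corresponding omnibus test is
    significant and there are >= 3 groups.
    """
    if spec.group is None or not spec.covariates:
        raise ValueError("ANCOVA requires a group factor and a covariate")
    g = data[spec.group].astype(str)
    counts = g.value_counts()
    if len(counts) < 2:
        raise ValueError("ANCOVA requires >= 2 groups")
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"groups with < 2 species: {dict(small)}")

    full_spec = ModelSpec(spec.response, spec.covariates, spec.group, interaction=True)
    add_spec = ModelSpec(spec.response, spec.covariates, spec.group, interaction=False)
    cov_spec = ModelSpec(spec.response, spec.covariates)

    full = fit_pgls(full_spec, data, tree, lam="REML")
    additive = fit_pgls(add_spec, data, tree, lam=full.lam)
    cov_only = fit_pgls(cov_spec, data, tree, lam=full.lam)

    slope_F, slope_p = _nested_f(full, additive)
    int_F, int_p = _nested_f(additive, cov_only)

    result = AncovaResult(
        spec=spec,
        lam=full.lam,
        slope_p=slope_p,
        slope_F=slope_F,
        intercept_p=int_p,
        intercept_F=int_F,
        full_fit=full,
        additive_fit=additive,
        covariate_fit=cov_only,
        groups=sorted(counts.index),
    )
    if run_posthoc:
        result.posthoc = pairwise_posthoc(result, alpha=posthoc_alpha)
    return result


def cohens_d(contrast: float, residual_sd: float) -> float:
    """Effect size d = contrast / residual SD (GLS residual SD, common-slope model)."""
    if residual_sd <= 0:
        raise ValueError("degenerate fit: residual SD must be > 0")
    return float(contrast / residual_sd)


def pairwise_posthoc(result: AncovaResult, alpha: float = 0.05) -> PosthocResult:
    """Pairwise group contrasts of slopes and adjusted means, Bonferroni-corrected.

    Slope contrasts come from the full-interaction fit; intercept contrasts
    are differences of adjusted means evaluated at the grand mean of the
    covariate, from the common-slope fit, each tested with a t statistic on
    the GLS coefficient covariance (df = n - p of the source model). Returns
    an explicit "not performed" marker when neither omnibus test is
    significant or there are fewer than 3 groups.
    """
    groups = result.groups
    if len(groups) < 3:
        return PosthocResult(performed=False, reason="fewer than 3 groups")
    if result.slope_p >= alpha and result.intercept_p >= alpha:
        return PosthocResult(
            performed=False,
            reason=f"no omnibus test significant at alpha={alpha}",
        )

    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    gname = result.spec.group
    xname = result.spec.covariates[0]
    ref = groups[0]  # dummy coding drops the first (sorted) level

    def contrast_test(fit: PGLSFit, vec: dict[str, float]) -> tuple[float, float]:
        c = np.zeros(len(fit.params))
        for name, w in vec.items():
            c[fit.design_columns.index(name)] = w
        est = float(c @ fit.params.to_numpy())
        se = float(np.sqrt(c @ fit.cov_params.to_numpy() @ c))
        df = fit.n - len(fit.params)
        t = est / se
        return est, 2.0 * float(stats.t.sf(abs(t), df))

    def mat() -> pd.DataFrame:
        return pd.DataFrame(np.nan, index=groups, columns=groups)

    slope_raw, int_raw, d_mat = mat(), mat(), mat()
    sd = result.additive_fit.resid_sd
    for a, b in pairs:
        # slope contrast: beta_a - beta_b (interaction terms, ref slope = base)
        vec_s: dict[str, float] = {}
        for lev, w in ((a, 1.0), (b, -1.0)):
            if lev != ref:
                vec_s[f"{gname}[{lev}]:{xname}"] = w
        _, p_s = contrast_test(result.full_fit, vec_s)
        # adjusted-mean contrast at the grand covariate mean: group dummies only
        vec_i: dict[str, float] = {}
        for lev, w in ((a, 1.0), (b, -1.0)):
            if lev != ref:
                vec_i[f"{gname}[{lev}]"] = w
        est_i, p_i = contrast_test(result.additive_fit, vec_i)
        slope_raw.loc[a, b] = slope_raw.loc[b, a] = p_s
        int_raw.loc[a, b] = int_raw.loc[b, a] = p_i
        dd = cohens_d(est_i, sd)
        d_mat.loc[a, b] = dd
        d_mat.loc[b, a] = -dd

    adjust = lambda df: (df * m).clip(upper=1.0)
    return PosthocResult(
        performed=True,
        n_pairs=m,
        slope_p=adjust(slope_raw),
        intercept_p=adjust(int_raw),
        slope_p_raw=slope_raw,
        intercept_p_raw=int_raw,
        cohens_d=d_mat,
    )


# ---------------------------------------------------------------------------
# information criteria and candidate-model selection


def information_criteria(
    fits: dict[str, PGLSFit] | list[PGLSFit], delta_cutoff: float = 2.0
) -> pd.DataFrame:
    """Rank a collection of fits of the same response by AICc.

    Returns a table sorted ascending by AICc with delta columns and a
    ``distinguishable`` flag (delta >= cutoff relative to the best model).
    Fits must share response data and n.
    """
    if isinstance(fits, list):
        fits = {f.spec.label(): f for f in fits}
    ns = {f.n for f in fits.values()}
    resp = {f.spec.response for f in fits.values()}
    if len(ns) > 1 or len(resp) > 1:
        raise ValueError("fits must share response and sample size")
    rows = []
    for name, f in fits.items():
        rows.append(
            {
                "model": name,
                "lambda": f.lam,
                "loglik": f.loglik,
                "n_params": f.n_params,
                "AIC": f.aic,
                "AICc": f.aicc,
            }
        )
    tab = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    tab["dAIC"] = tab["AIC"] - tab["AIC"].min()
    tab["dAICc"] = tab["AICc"] - tab["AICc"].min()
    tab["distinguishable"] = tab["dAICc"] >= delta_cutoff
    return tab


def candidate_model_selection(
    candidates: list[ModelSpec],
    data: pd.DataFrame,
    tree: Phylogeny,
    delta_cutoff: float = 2.0,
) -> tuple[pd.DataFrame, dict[str, PGLSFit]]:
    """Fit candidate PGLS models (ML lambda) and rank them by AICc."""
    fits = {spec.label(): fit_pgls(spec, data, tree, lam="ML") for spec in candidates}
    return information_criteria(fits, delta_cutoff=delta_cutoff), fits
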