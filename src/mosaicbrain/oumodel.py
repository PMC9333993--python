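"""Bivariate multiregime Ornstein--Uhlenbeck allometric model.

The model: log response y (e.g. log10 brain mass) relates to log predictor x
(e.g. log10 body mass) through regime-specific allometries. Regimes are
painted onto the phylogeny by shifts on branches; regime r carries a slope
beta_r and intercept theta_r, and the trait is pulled toward the moving
optimum theta_r + beta_r x with attraction alpha and diffusion variance
sigma2. Under the Hansen formulation the expectation of tip i is the
weight-matrix combination of regime optima,

    E[y_i] = sum_r W_ir(alpha) (theta_r + beta_r x_i),

and the covariance is the root-conditioned OU matrix plus per-tip
intraspecific sampling variance diag(se^2).

Inference is by reversible-jump MCMC over the number and placement of
shifts, with half-Cauchy priors on alpha and sigma2, a conditional Poisson
prior on the shift count k (uniform over branch placements), and normal
priors on slopes and intercepts. Marginal likelihoods for fixed-shift
hypothesis models come from stepping-stone sampling over a Beta-quantile
power-posterior schedule, and models are compared on the 2 ln BF scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import gammaln, logsumexp

from .phylo import Phylogeny, RegimePainting, ou_weights, paint_regimes, _shared_times_arr

__all__ = [
    "OUAllomParams",
    "PriorSpec",
    "ChainConfig",
    "ChainSamples",
    "PosteriorSummary",
    "MarginalLikelihoodResult",
    "ShiftModel",
    "ou_allom_loglik",
    "log_prior",
    "rjmcmc_run",
    "summarize_posterior",
    "convergence_diagnostics",
    "stepping_stone",
    "stepping_stone_logml",
    "bayes_factor_2ln",
    "fixed_shift_model",
    "empirical_regression_prior",
]


# ---------------------------------------------------------------------------
# parameters and priors


@dataclass
class OUAllomParams:
    """One point in the multiregime OU parameter space.

    ``shifts`` lists ``(branch_id, relative_position)``; shift *i* opens
    regime *i + 1*, so ``beta`` and ``theta`` have length ``k + 1`` with the
    root regime first.
    """

    alpha: float
    sigma2: float
    shifts: list[tuple[int, float]]
    beta: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        k = len(self.shifts)
        if len(self.beta) != k + 1 or len(self.theta) != k + 1:
            raise ValueError(
                f"need {k + 1} regime slopes/intercepts, got "
                f"{len(self.beta)}/{len(self.theta)}"
            )
        if not (
            np.isfinite(self.alpha)
            and np.isfinite(self.sigma2)
            and self.alpha > 0
            and self.sigma2 > 0
        ):
            raise ValueError("alpha and sigma2 must be finite and positive")

    @property
    def k(self) -> int:
        return len(self.shifts)


@dataclass
class PriorSpec:
    """Priors for the multiregime OU allometric model.

    alpha and sigma2 get half-Cauchy priors; k gets a Poisson truncated to
    ``0..k_max`` and renormalized, with branch placements uniform over
    k-subsets of the non-root branches; slopes and intercepts get normal
    priors. Default Poisson parameters follow the 1% / 5%-of-branches rule
    (see :meth:`from_tree`).
    """

    alpha_scale: float = 0.1
    sigma2_scale: float = 0.1
    k_mean: float = 1.0
    k_max: int = 5
    beta_mean: float = 0.0
    beta_sd: float = 1.0
    theta_mean: float = 0.0
    theta_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_scale <= 0 or self.sigma2_scale <= 0:
            raise ValueError("half-Cauchy scales must be > 0")
        if not self.k_max >= self.k_mean > 0:
            raise ValueError("need k_max >= k_mean > 0")
        if self.beta_sd <= 0 or self.theta_sd <= 0:
            raise ValueError("prior SDs must be > 0")

    @classmethod
    def from_tree(cls, tree: Phylogeny, **kwargs) -> "PriorSpec":
        """Poisson mean = 1% and max = 5% of branch count (each at least 1)."""
        B = len(tree.branch_ids())
        kwargs.setdefault("k_mean", max(1.0, 0.01 * B))
        kwargs.setdefault("k_max", max(1, round(0.05 * B)))
        return cls(**kwargs)

    def k_log_pmf(self) -> np.ndarray:
        if not hasattr(self, "_k_log_pmf"):
            ks = np.arange(self.k_max + 1)
            raw = ks * np.log(self.k_mean) - gammaln(ks + 1)
            object.__setattr__(self, "_k_log_pmf", raw - logsumexp(raw))
        return self._k_log_pmf


def _half_cauchy_logpdf(v: float, scale: float) -> float:
    if v <= 0:
        return -np.inf
    return math.log(2.0 / (math.pi * scale)) - math.log1p((v / scale) ** 2)


_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _normal_logpdf_sum(v: np.ndarray, mean: float, sd: float) -> float:
    v = np.asarray(v, dtype=float)
    return float(
        -v.size * (_LOG_SQRT_2PI + math.log(sd))
        - 0.5 * np.sum(((v - mean) / sd) ** 2)
    )


def log_prior(params: OUAllomParams, prior: PriorSpec, tree: Phylogeny) -> float:
    """Joint log prior density; -inf when k exceeds the truncation bound."""
    k = params.k
    if k > prior.k_max:
        return -np.inf
    B = len(tree.branch_ids())
    lp = _half_cauchy_logpdf(params.alpha, prior.alpha_scale)
    lp += _half_cauchy_logpdf(params.sigma2, prior.sigma2_scale)
    lp += float(prior.k_log_pmf()[k])
    # uniform over k-subsets of branches
    lp -= gammaln(B + 1) - gammaln(k + 1) - gammaln(B - k + 1)
    lp += _normal_logpdf_sum(params.beta, prior.beta_mean, prior.beta_sd)
    lp += _normal_logpdf_sum(params.theta, prior.theta_mean, prior.theta_sd)
    return lp


def empirical_regression_prior(
    fits: "pd.DataFrame | list", round_sd_to: float = 0.1
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Derive (mu, sd) normal priors for slope and intercept from grouped fits.

    ``fits`` is a DataFrame with columns ``slope`` and ``intercept`` (one row
    per taxonomic group regression, e.g. per-order PGLS fits). The prior mean
    is the mean across groups; the prior SD is the across-group SD rounded up
    to the next ``round_sd_to``.
    """
    tab = pd.DataFrame(fits)
    if not {"slope", "intercept"} <= set(tab.columns):
        raise ValueError("need columns 'slope' and 'intercept'")
    if len(tab) < 2:
        raise ValueError("need >= 2 group fits to form an empirical prior")

    def up(v: float) -> float:
        return math.ceil(v / round_sd_to - 1e-12) * round_sd_to

    b = (float(tab["slope"].mean()), up(float(tab["slope"].std(ddof=1))))
    t = (float(tab["intercept"].mean()), up(float(tab["intercept"].std(ddof=1))))
    return b, t


# ---------------------------------------------------------------------------
# likelihood


def _align_vec(v, labels: list[str]) -> np.ndarray:
    if isinstance(v, pd.Series):
        return v.loc[labels].to_numpy(dtype=float)
    arr = np.asarray(v, dtype=float)
    if arr.shape != (len(labels),):
        raise ValueError(f"expected length {len(labels)}, got {arr.shape}")
    return arr


class _LikelihoodEngine:
    """Caches tree quantities and factorizations for repeated OU evaluations."""

    def __init__(self, tree: Phylogeny, x, y, se, unit_height: bool = False):
        self.tree = tree
        C, labels = _shared_times_arr(tree)
        self.scale = 1.0
        if unit_height:
            self.scale = float(np.max(np.diag(C)))
            C = C / self.scale
        self.C = C
        self.labels = labels
        self.T = np.diag(C).copy()
        self.D = self.T[:, None] + self.T[None, :] - 2.0 * C
        self.expo_base = -np.expm1(-2.0 * 1.0 * C)  # placeholder, per-alpha below
        self.x = _align_vec(x, labels) if x is not None else None
        self.y = _align_vec(y, labels) if y is not None else None
        self.se2 = (
            _align_vec(se, labels) ** 2 if se is not None else np.zeros(len(labels))
        )
        self.n = len(labels)
        # per-tip ancestry masks for the fast weight matrix
        below = tree.tips_below()
        tip_pos = {t: j for j, t in enumerate(tree.tip_indices)}
        depths = tree.depths()
        self.branch_mask = {}
        self.branch_mid = {}
        for b in tree.branch_ids():
            m = np.zeros(self.n, dtype=bool)
            for t in below[b]:
                m[tip_pos[t]] = True
            self.branch_mask[b] = m
            t1 = depths[b] / self.scale
            t0 = depths[tree.parent[b]] / self.scale
            self.branch_mid[b] = (t0, t1)
        self._chol_key = None
        self._chol = None
        self._logdet = None

    def weights(self, alpha: float, shifts: list[tuple[int, float]]) -> np.ndarray:
        """Hansen weight matrix via telescoping over shift points on each path."""
        n = self.n
        W = np.zeros((n, len(shifts) + 1))
        cur = np.zeros(n, dtype=int)
        last = np.zeros(n)
        mids = []
        for i, (b, pos) in enumerate(shifts):
            t0, t1 = self.branch_mid[b]
            mids.append((t0 + pos * (t1 - t0), b, i + 1))
        mids.sort()
        rows = np.arange(n)
        for tm, b, reg in mids:
            M = self.branch_mask[b]
            contrib = np.exp(-alpha * (self.T[M] - tm)) - np.exp(
                -alpha * (self.T[M] - last[M])
            )
            np.add.at(W, (rows[M], cur[M]), contrib)
            cur[M] = reg
            last[M] = tm
        np.add.at(W, (rows, cur), 1.0 - np.exp(-alpha * (self.T - last)))
        W[:, 0] += np.exp(-alpha * self.T)
        return W

    def ou_matrix(self, alpha: float) -> np.ndarray:
        """sigma2-free covariance kernel M with Cov = sigma2 * M + diag(se^2)."""
        return (
            (1.0 / (2.0 * alpha))
            * np.exp(-alpha * self.D)
            * (-np.expm1(-2.0 * alpha * self.C))
        )

    def chol(self, alpha: float, sigma2: float):
        key = (alpha, sigma2)
        if key != self._chol_key:
            V = sigma2 * self.ou_matrix(alpha) + np.diag(self.se2)
            jitter = 0.0
            tr = np.trace(V)
            for _ in range(6):
                try:
                    L = linalg.cholesky(V + jitter * np.eye(self.n), lower=True)
                    break
                except linalg.LinAlgError:
                    jitter = max(jitter * 10.0, 1e-12 * tr)
            else:
                raise linalg.LinAlgError(
                    "OU covariance not positive definite after jitter"
                )
            self._chol = L
            self._logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
            self._chol_key = key
        return self._chol, self._logdet

    def mean(self, W: np.ndarray, beta: np.ndarray, theta: np.ndarray) -> np.ndarray:
        return W @ theta + (W @ beta) * self.x

    def loglik(self, params: OUAllomParams) -> float:
        W = self.weights(params.alpha, params.shifts)
        return self.loglik_cached(params, W)

    def loglik_cached(self, params: OUAllomParams, W: np.ndarray) -> float:
        L, logdet = self.chol(params.alpha, params.sigma2)
        r = self.y - self.mean(W, params.beta, params.theta)
        z = linalg.solve_triangular(L, r, lower=True)
        return -0.5 * (self.n * math.log(2.0 * math.pi) + logdet + float(z @ z))


def ou_allom_loglik(
    tree: Phylogeny,
    painting: RegimePainting | None,
    params: OUAllomParams,
    x,
    y,
    se=None,
) -> float:
    """Log-likelihood of the bivariate multiregime OU allometric model.

    ``x``, ``y``, ``se`` are per-tip vectors (pandas Series indexed by tip
    label, or arrays in tip-label order). ``painting`` is derived from
    ``params.shifts`` when omitted. Intraspecific SE enters as added
    independent tip variance.
    """
    for name, v in (("x", x), ("y", y)):
        arr = np.asarray(v, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite values in {name}")
    eng = _LikelihoodEngine(tree, x, y, se)
    if painting is not None:
        W = ou_weights(tree, painting, params.alpha)
        return eng.loglik_cached(params, W)
    return eng.loglik(params)


# ---------------------------------------------------------------------------
# reversible-jump MCMC


@dataclass
class ChainConfig:
    """Sampler configuration.

    ``iterations`` counts main-phase iterations; samples are recorded every
    ``thin`` iterations and the first ``burnin_frac`` of *retained samples*
    is discarded at summary time. ``priming`` iterations precede the main
    phase with the shift count frozen (no birth/death/move proposals) so
    continuous parameters equilibrate first.
    """

    iterations: int = 100_000
    thin: int = 100
    burnin_frac: float = 0.3
    priming: int = 10_000
    seed: int = 0
    n_chains: int = 1
    rj_prob: float = 0.6            # chance of attempting a trans-model move
    rj_attempts: int = 1            # trans-model proposal attempts per iteration
    move_frac: float = 0.3          # fraction of RJ attempts that relocate a shift
    alpha_step: float = 0.8         # log-scale multiplier half-width
    sigma2_step: float = 0.8
    beta_step: float = 0.1
    theta_step: float = 0.1
    shift_position: float = 0.5
    prior_only: bool = False
    unit_height: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.burnin_frac < 1.0:
            raise ValueError("burnin_frac must be in [0, 1)")
        if self.thin < 1:
            raise ValueError("thinning must be >= 1")
        if self.iterations < self.thin:
            raise ValueError("iterations must be >= thinning interval")


@dataclass
class ChainSamples:
    """Thinned samples from one chain."""

    iteration: np.ndarray
    loglik: np.ndarray
    logprior: np.ndarray
    alpha: np.ndarray
    sigma2: np.ndarray
    k: np.ndarray
    shifts: list[tuple[int, ...]]
    beta: list[np.ndarray]          # aligned with shifts; index 0 = root regime
    theta: list[np.ndarray]
    config: ChainConfig = field(repr=False, default=None)
    accept_rate: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.iteration)

    def post_burnin(self) -> "ChainSamples":
        start = int(self.config.burnin_frac * len(self)) if self.config else 0
        return ChainSamples(
            iteration=self.iteration[start:],
            loglik=self.loglik[start:],
            logprior=self.logprior[start:],
            alpha=self.alpha[start:],
            sigma2=self.sigma2[start:],
            k=self.k[start:],
            shifts=self.shifts[start:],
            beta=self.beta[start:],
            theta=self.theta[start:],
            config=replace(self.config, burnin_frac=0.0) if self.config else None,
            accept_rate=self.accept_rate,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": self.iteration,
                "logLik": self.loglik,
                "logPrior": self.logprior,
                "alpha": self.alpha,
                "sigma2": self.sigma2,
                "k": self.k,
                "shift_branches": [";".join(map(str, s)) for s in self.shifts],
                "beta": [";".join(f"{v:.6g}" for v in b) for b in self.beta],
                "theta": [";".join(f"{v:.6g}" for v in t) for t in self.theta],
                "beta0": [b[0] for b in self.beta],
                "theta0": [t[0] for t in self.theta],
            }
        )


class _Sampler:
    """Reversible-jump sampler over shift configurations and OU parameters."""

    def __init__(
        self,
        tree: Phylogeny,
        x,
        y,
        se,
        prior: PriorSpec,
        config: ChainConfig,
        rng: np.random.Generator,
        fixed_shifts: list[tuple[int, float]] | None = None,
        share_slope: bool = False,
        power: float = 1.0,
    ):
        self.tree = tree
        self.prior = prior
        self.cfg = config
        self.rng = rng
        self.share_slope = share_slope
        self.power = power
        self.fixed = fixed_shifts is not None
        self.branches = [b for b in tree.branch_ids()]
        self.B = len(self.branches)
        self.eng = (
            None
            if config.prior_only
            else _LikelihoodEngine(tree, x, y, se, unit_height=config.unit_height)
        )
        # initial state from the prior
        if fixed_shifts is not None:
            shifts = list(fixed_shifts)
        else:
            k0 = int(
                rng.choice(prior.k_max + 1, p=np.exp(prior.k_log_pmf()))
            )
            shifts = [
                (int(b), config.shift_position)
                for b in rng.choice(self.branches, size=k0, replace=False)
            ]
        k = len(shifts)
        self.state = OUAllomParams(
            alpha=float(abs(rng.standard_cauchy()) * prior.alpha_scale) + 1e-6,
            sigma2=float(abs(rng.standard_cauchy()) * prior.sigma2_scale) + 1e-6,
            shifts=shifts,
            beta=rng.normal(prior.beta_mean, prior.beta_sd, k + 1),
            theta=rng.normal(prior.theta_mean, prior.theta_sd, k + 1),
        )
        if share_slope:
            self.state.beta[:] = self.state.beta[0]
        self.W = (
            self.eng.weights(self.state.alpha, self.state.shifts)
            if self.eng
            else None
        )
        self.ll = self._loglik(self.state, self.W)
        self.lp = self._logprior(self.state)
        self.n_prop = {}
        self.n_acc = {}

    # -- densities -------------------------------------------------------

    def _loglik(self, params: OUAllomParams, W) -> float:
        if self.eng is None:
            return 0.0
        return self.eng.loglik_cached(params, W)

    def _logprior(self, params: OUAllomParams) -> float:
        lp = log_prior(params, self.prior, self.tree)
        if self.share_slope and params.k > 0:
            # one shared slope: remove the duplicated slope densities
            lp -= _normal_logpdf_sum(
                params.beta[1:], self.prior.beta_mean, self.prior.beta_sd
            )
        return lp

    def _target(self, ll: float, lp: float) -> float:
        return self.power * ll + lp

    # -- bookkeeping -----------------------------------------------------

    def _tally(self, kind: str, accepted: bool) -> None:
        self.n_prop[kind] = self.n_prop.get(kind, 0) + 1
        if accepted:
            self.n_acc[kind] = self.n_acc.get(kind, 0) + 1

    def _accept(self, kind: str, new: OUAllomParams, W_new, log_hastings: float = 0.0):
        ll_new = self._loglik(new, W_new)
        lp_new = self._logprior(new)
        if not np.isfinite(lp_new):
            self._tally(kind, False)
            return
        loga = (
            self._target(ll_new, lp_new)
            - self._target(self.ll, self.lp)
            + log_hastings
        )
        if math.log(self.rng.random()) < loga:
            self.state, self.W, self.ll, self.lp = new, W_new, ll_new, lp_new
            self._tally(kind, True)
        else:
            self._tally(kind, False)

    # -- continuous-parameter moves --------------------------------------

    def _update_alpha(self) -> None:
        u = self.rng.uniform(-self.cfg.alpha_step, self.cfg.alpha_step)
        new = replace(
            self.state,
            alpha=self.state.alpha * math.exp(u),
            beta=self.state.beta.copy(),
            theta=self.state.theta.copy(),
            shifts=list(self.state.shifts),
        )
        W_new = self.eng.weights(new.alpha, new.shifts) if self.eng else None
        self._accept("alpha", new, W_new, log_hastings=u)

    def _update_sigma2(self) -> None:
        u = self.rng.uniform(-self.cfg.sigma2_step, self.cfg.sigma2_step)
        new = replace(
            self.state,
            sigma2=self.state.sigma2 * math.exp(u),
            beta=self.state.beta.copy(),
            theta=self.state.theta.copy(),
            shifts=list(self.state.shifts),
        )
        self._accept("sigma2", new, self.W, log_hastings=u)

    def _update_regression(self) -> None:
        k = self.state.k
        r = int(self.rng.integers(0, k + 1))
        beta = self.state.beta.copy()
        theta = self.state.theta.copy()
        if self.share_slope:
            if r == 0:
                beta[:] = beta[0] + self.rng.normal(0.0, self.cfg.beta_step)
        else:
            beta[r] += self.rng.normal(0.0, self.cfg.beta_step)
        theta[r] += self.rng.normal(0.0, self.cfg.theta_step)
        new = replace(
            self.state, beta=beta, theta=theta, shifts=list(self.state.shifts)
        )
        self._accept("regression", new, self.W)

    # -- trans-model moves ------------------------------------------------

    def _pb(self, k: int) -> float:
        if k == 0:
            return 1.0
        if k >= self.prior.k_max:
            return 0.0
        return 0.5

    def _rj_move(self) -> None:
        k = self.state.k
        occupied = {b for b, _ in self.state.shifts}
        # decide relocate vs birth/death before looking at k so the gate
        # probability cancels in the birth/death Hastings ratio
        if self.rng.random() < self.cfg.move_frac:
            if k == 0:
                return
            # relocate: symmetric (uniform shift x uniform free branch)
            free = [b for b in self.branches if b not in occupied]
            if not free:
                return
            i = int(self.rng.integers(0, k))
            b_new = int(self.rng.choice(free))
            shifts = list(self.state.shifts)
            shifts[i] = (b_new, self.cfg.shift_position)
            new = replace(
                self.state,
                shifts=shifts,
                beta=self.state.beta.copy(),
                theta=self.state.theta.copy(),
            )
            W_new = self.eng.weights(new.alpha, shifts) if self.eng else None
            self._accept("move", new, W_new)
            return

        birth = self.rng.random() < self._pb(k)
        if birth:
            free = [b for b in self.branches if b not in occupied]
            b_new = int(self.rng.choice(free))
            beta_new = (
                self.state.beta[0]
                if self.share_slope
                else self.rng.normal(self.prior.beta_mean, self.prior.beta_sd)
            )
            theta_new = self.rng.normal(self.prior.theta_mean, self.prior.theta_sd)
            shifts = list(self.state.shifts) + [(b_new, self.cfg.shift_position)]
            new = replace(
                self.state,
                shifts=shifts,
                beta=np.append(self.state.beta, beta_new),
                theta=np.append(self.state.theta, theta_new),
            )
            # prior density of drawn params cancels the proposal; see docs
            lh = (
                math.log(1.0 - self._pb(k + 1))
                - math.log(k + 1)
                - math.log(self._pb(k))
                + math.log(self.B - k)
                - _normal_logpdf_sum(
                    np.array([theta_new]), self.prior.theta_mean, self.prior.theta_sd
                )
            )
            if not self.share_slope:
                lh -= _normal_logpdf_sum(
                    np.array([beta_new]), self.prior.beta_mean, self.prior.beta_sd
                )
            W_new = self.eng.weights(new.alpha, shifts) if self.eng else None
            self._accept("birth", new, W_new, log_hastings=lh)
        else:
            if k == 0:
                return
            i = int(self.rng.integers(0, k))
            shifts = [s for j, s in enumerate(self.state.shifts) if j != i]
            keep = [0] + [j + 1 for j in range(k) if j != i]
            beta_rm = float(self.state.beta[i + 1])
            theta_rm = float(self.state.theta[i + 1])
            new = replace(
                self.state,
                shifts=shifts,
                beta=self.state.beta[keep],
                theta=self.state.theta[keep],
            )
            lh = (
                math.log(self._pb(k - 1))
                - math.log(self.B - (k - 1))
                - math.log(1.0 - self._pb(k))
                + math.log(k)
                + _normal_logpdf_sum(
                    np.array([theta_rm]), self.prior.theta_mean, self.prior.theta_sd
                )
            )
            if not self.share_slope:
                lh += _normal_logpdf_sum(
                    np.array([beta_rm]), self.prior.beta_mean, self.prior.beta_sd
                )
            W_new = self.eng.weights(new.alpha, shifts) if self.eng else None
            self._accept("death", new, W_new, log_hastings=lh)

    # -- main loop --------------------------------------------------------

    def step(self, allow_rj: bool) -> None:
        if self.eng is not None:
            self._update_alpha()
            self._update_sigma2()
        else:
            # prior-only mode still explores alpha/sigma2 from the prior
            self._update_alpha()
            self._update_sigma2()
        self._update_regression()
        if allow_rj and not self.fixed:
            for _ in range(self.cfg.rj_attempts):
                if self.rng.random() < self.cfg.rj_prob:
                    self._rj_move()

    def run(self) -> ChainSamples:
        for _ in range(self.cfg.priming):
            self.step(allow_rj=False)
        rec: dict[str, list] = {
            "it": [], "ll": [], "lp": [], "a": [], "s2": [], "k": [],
            "shifts": [], "beta": [], "theta": [],
        }
        for it in range(1, self.cfg.iterations + 1):
            self.step(allow_rj=True)
            if it % self.cfg.thin == 0:
                rec["it"].append(it)
                rec["ll"].append(self.ll)
                rec["lp"].append(self.lp)
                rec["a"].append(self.state.alpha)
                rec["s2"].append(self.state.sigma2)
                rec["k"].append(self.state.k)
                rec["shifts"].append(tuple(b for b, _ in self.state.shifts))
                rec["beta"].append(self.state.beta.copy())
                rec["theta"].append(self.state.theta.copy())
        acc = {
            kind: self.n_acc.get(kind, 0) / n
            for kind, n in self.n_prop.items()
        }
        for kind, rate in acc.items():
            if rate == 0.0 and self.n_prop[kind] > 50:
                import warnings

                warnings.warn(
                    f"no '{kind}' proposals accepted "
                    f"({self.n_prop[kind]} attempts); consider smaller steps",
                    stacklevel=2,
                )
        return ChainSamples(
            iteration=np.array(rec["it"]),
            loglik=np.array(rec["ll"]),
            logprior=np.array(rec["lp"]),
            alpha=np.array(rec["a"]),
            sigma2=np.array(rec["s2"]),
            k=np.array(rec["k"], dtype=int),
            shifts=rec["shifts"],
            beta=rec["beta"],
            theta=rec["theta"],
            config=self.cfg,
            accept_rate=acc,
        )


def rjmcmc_run(
    tree: Phylogeny,
    x,
    y,
    se,
    prior: PriorSpec,
    config: ChainConfig,
    share_slope: bool = False,
) -> list[ChainSamples]:
    """Run reversible-jump chains over shift number, placement and parameters.

    Each chain is primed for ``config.priming`` iterations with the shift
    count frozen before birth/death/move proposals are enabled. Chains are
    independently seeded from the master seed; an identical configuration
    reproduces identical chains.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = []
    for ss in seeds:
        rng = np.random.Generator(np.random.PCG64(ss))
        sampler = _Sampler(
            tree, x, y, se, prior, config, rng, share_slope=share_slope
        )
        chains.append(sampler.run())
    return chains


# ---------------------------------------------------------------------------
# posterior summaries and diagnostics


@dataclass
class PosteriorSummary:
    branch_prob: pd.Series
    shifts: pd.DataFrame            # branches above threshold with beta/theta summaries
    params: pd.DataFrame            # alpha/sigma2/k/beta0/theta0 summaries
    diagnostics: pd.DataFrame | None
    threshold: float
    n_samples: int


def summarize_posterior(
    chains: list[ChainSamples],
    tree: Phylogeny,
    threshold: float = 0.2,
) -> PosteriorSummary:
    """Pool chains after burn-in and summarize shifts and parameters.

    Branch posterior probability is the fraction of pooled samples whose
    shift configuration contains the branch; branches above ``threshold``
    are reported with the posterior median and 95% credible interval of
    their regime's slope and intercept conditional on shift presence.
    """
    pooled = [c.post_burnin() for c in chains]
    if sum(len(c) for c in pooled) == 0:
        raise ValueError("no post-burn-in samples")
    n = sum(len(c) for c in pooled)
    counts: dict[int, int] = {}
    cond: dict[int, list[tuple[float, float]]] = {}
    for c in pooled:
        for shifts, beta, theta in zip(c.shifts, c.beta, c.theta):
            for j, b in enumerate(shifts):
                counts[b] = counts.get(b, 0) + 1
                cond.setdefault(b, []).append((beta[j + 1], theta[j + 1]))
    branch_prob = pd.Series(
        {b: counts.get(b, 0) / n for b in tree.branch_ids()}, name="posterior_prob"
    ).sort_index()

    rows = []
    for b, p in branch_prob.items():
        if p > threshold:
            bt = np.array(cond[b])
            rows.append(
                {
                    "branch": b,
                    "posterior_prob": p,
                    "beta_median": float(np.median(bt[:, 0])),
                    "beta_lo": float(np.quantile(bt[:, 0], 0.025)),
                    "beta_hi": float(np.quantile(bt[:, 0], 0.975)),
                    "theta_median": float(np.median(bt[:, 1])),
                    "theta_lo": float(np.quantile(bt[:, 1], 0.025)),
                    "theta_hi": float(np.quantile(bt[:, 1], 0.975)),
                }
            )
    shifts_tab = pd.DataFrame(
        rows,
        columns=[
            "branch", "posterior_prob", "beta_median", "beta_lo", "beta_hi",
            "theta_median", "theta_lo", "theta_hi",
        ],
    )

    def summ(vals: np.ndarray) -> dict:
        return {
            "median": float(np.median(vals)),
            "lo95": float(np.quantile(vals, 0.025)),
            "hi95": float(np.quantile(vals, 0.975)),
        }

    stacked = {
        "alpha": np.concatenate([c.alpha for c in pooled]),
        "sigma2": np.concatenate([c.sigma2 for c in pooled]),
        "k": np.concatenate([c.k for c in pooled]).astype(float),
        "beta0": np.concatenate([[b[0] for b in c.beta] for c in pooled]),
        "theta0": np.concatenate([[t[0] for t in c.theta] for c in pooled]),
    }
    params = pd.DataFrame({k: summ(v) for k, v in stacked.items()}).T
    diagnostics = convergence_diagnostics(pooled) if len(pooled) >= 1 else None
    return PosteriorSummary(
        branch_prob=branch_prob,
        shifts=shifts_tab,
        params=params,
        diagnostics=diagnostics,
        threshold=threshold,
        n_samples=n,
    )


def convergence_diagnostics(
    chains: "list[ChainSamples] | dict[str, np.ndarray]",
) -> pd.DataFrame:
    """Effective sample size and Gelman-Rubin R-hat per scalar parameter.

    Accepts either a list of chains (alpha, sigma2, k, beta0, theta0 are
    summarized) or a dict mapping parameter names to (n_chains, n_draws)
    arrays. R-hat requires >= 2 chains and is NaN otherwise; a constant
    chain yields NaN ESS (an explicit undefined marker, not an error).
    """
    import arviz as az

    if isinstance(chains, dict):
        arrays = {k: np.atleast_2d(np.asarray(v, dtype=float)) for k, v in chains.items()}
    else:
        m = min(len(c) for c in chains)
        arrays = {
            "alpha": np.stack([c.alpha[:m] for c in chains]),
            "sigma2": np.stack([c.sigma2[:m] for c in chains]),
            "k": np.stack([c.k[:m].astype(float) for c in chains]),
            "beta0": np.stack([[b[0] for b in c.beta[:m]] for c in chains]),
            "theta0": np.stack([[t[0] for t in c.theta[:m]] for c in chains]),
        }
    rows = {}
    for name, arr in arrays.items():
        if np.allclose(arr, arr.flat[0]):
            rows[name] = {"ess": np.nan, "rhat": np.nan}
            continue
        ess = float(az.ess(arr.astype(float)))
        rhat = float(az.rhat(arr, method="identity")) if arr.shape[0] >= 2 else np.nan
        rows[name] = {"ess": ess, "rhat": rhat}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# stepping-stone marginal likelihood


@dataclass
class MarginalLikelihoodResult:
    logml: float
    steps: np.ndarray               # power schedule, strictly increasing to 1
    contributions: np.ndarray       # per-rung log ratio estimates

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.steps) > 0):
            raise ValueError("power schedule must be strictly increasing")


@dataclass
class ShiftModel:
    """A fixed shift configuration for hypothesis testing.

    ``shifts`` may be empty (single global allometry). ``share_slope``
    constrains all regimes to one slope (intercept-only shifts).
    """

    shifts: list[tuple[int, float]]
    share_slope: bool = False

    @property
    def n_regimes(self) -> int:
        return len(self.shifts) + 1


def fixed_shift_model(
    tree: Phylogeny,
    branches: list[int],
    share_slope: bool = False,
    position: float = 0.5,
) -> ShiftModel:
    """Build a fixed-shift hypothesis model; validates branches via painting."""
    shifts = [(int(b), position) for b in branches]
    paint_regimes(tree, shifts)  # raises on unknown/duplicate branches
    return ShiftModel(shifts=shifts, share_slope=share_slope)


def beta_quantile_schedule(steps: int, shape: tuple[float, float]) -> np.ndarray:
    """Power schedule at Beta(a, b) quantiles: steps+1 points from 0 to 1."""
    q = np.arange(steps + 1) / steps
    return stats.beta.ppf(q, shape[0], shape[1])


def stepping_stone(
    draw_loglik,
    steps: int = 50,
    shape: tuple[float, float] = (0.3, 1.0),
    iterations_per_step: int = 1000,
    rng: np.random.Generator | None = None,
) -> MarginalLikelihoodResult:
    """Generic stepping-stone estimator of a log marginal likelihood.

    ``draw_loglik(power, n, rng)`` must return ``n`` log-likelihood values of
    samples from the power posterior at the given power (power 0 = prior).
    The log marginal likelihood is assembled from per-rung importance ratios:
    log r_s = logmeanexp((b_{s+1} - b_s) * loglik samples at power b_s).
    """
    rng = np.random.default_rng() if rng is None else rng
    powers = beta_quantile_schedule(steps, shape)
    contribs = np.empty(steps)
    for s in range(steps):
        ll = np.asarray(draw_loglik(float(powers[s]), iterations_per_step, rng))
        d = powers[s + 1] - powers[s]
        c = logsumexp(d * ll) - math.log(len(ll))
        if not np.isfinite(c):
            raise FloatingPointError(
                f"divergent stepping-stone estimate at rung {s} (power {powers[s]:.4g})"
            )
        contribs[s] = c
    return MarginalLikelihoodResult(
        logml=float(np.sum(contribs)), steps=powers[1:], contributions=contribs
    )


def stepping_stone_logml(
    model: ShiftModel,
    tree: Phylogeny,
    x,
    y,
    se,
    prior: PriorSpec,
    steps: int = 50,
    shape: tuple[float, float] = (0.3, 1.0),
    iterations_per_step: int = 10_000,
    thin: int = 10,
    burnin_frac: float = 0.2,
    seed: int = 0,
) -> MarginalLikelihoodResult:
    """Stepping-stone log marginal likelihood of a fixed-shift OU model.

    At each rung an MCMC chain samples the continuous parameters (shift
    locations fixed) from the power posterior; the first ``burnin_frac`` of
    each rung's chain is discarded and the chain is warm-started from the
    previous rung's end state.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    cfg = ChainConfig(
        iterations=max(iterations_per_step, thin),
        thin=thin,
        burnin_frac=0.0,
        priming=0,
        seed=seed,
    )
    sampler_box: dict = {}

    def draw(power: float, n_iter: int, rng_: np.random.Generator) -> np.ndarray:
        if "s" not in sampler_box:
            sampler_box["s"] = _Sampler(
                tree, x, y, se, prior, cfg, rng_,
                fixed_shifts=model.shifts,
                share_slope=model.share_slope,
                power=power,
            )
        s = sampler_box["s"]
        s.power = power  # warm start from previous rung
        lls = []
        nburn = int(burnin_frac * n_iter)
        for i in range(n_iter):
            s.step(allow_rj=False)
            if i >= nburn and (i - nburn) % thin == 0:
                lls.append(s.ll)
        return np.array(lls)

    return stepping_stone(
        draw,
        steps=steps,
        shape=shape,
        iterations_per_step=iterations_per_step,
        rng=rng,
    )


def bayes_factor_2ln(logml_a: float, logml_b: float) -> float:
    """Bayes factor on the 2 ln BF reporting scale: 2 (logml_a - logml_b)."""
    if not (np.isfinite(logml_a) and np.isfinite(logml_b)):
        raise ValueError("log marginal likelihoods must be finite")
    return 2.0 * (logml_a - logml_b)
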