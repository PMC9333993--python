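"""OU allometric likelihood, priors, RJ-MCMC, diagnostics, stepping stone."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mosaicbrain import simulate as sim
from mosaicbrain.phylo import ou_vcv, ou_weights, paint_regimes, read_newick, shared_path_times
from mosaicbrain.oumodel import (
    ChainConfig,
    MarginalLikelihoodResult,
    OUAllomParams,
    PriorSpec,
    _LikelihoodEngine,
    bayes_factor_2ln,
    convergence_diagnostics,
    fixed_shift_model,
    log_prior,
    ou_allom_loglik,
    rjmcmc_run,
    stepping_stone,
    stepping_stone_logml,
    summarize_posterior,
)


class TestLikelihood:
    @pytest.mark.parametrize("n_tips,seed", [(3, 1), (10, 2)])
    def test_matches_dense_mvn_oracle(self, n_tips, seed):
        tree = (
            read_newick("((A:1,B:1):1,C:2);")
            if n_tips == 3
            else sim.simulate_tree(10, 1.0, 0.0, seed=seed)
        )
        rng = np.random.default_rng(seed)
        b = tree.branch_ids()[1]
        painting = paint_regimes(tree, [b])
        params = OUAllomParams(
            alpha=0.8, sigma2=0.5, shifts=[(b, 0.5)],
            beta=[0.6, 1.1], theta=[0.2, -0.4],
        )
        x = rng.normal(size=n_tips)
        y = rng.normal(size=n_tips)
        se = rng.uniform(0.0, 0.2, n_tips)
        ll = ou_allom_loglik(tree, painting, params, x, y, se)
        W = ou_weights(tree, painting, params.alpha)
        mean = W @ params.theta + (W @ params.beta) * x
        V = ou_vcv(tree, params.alpha, params.sigma2).to_numpy() + np.diag(se**2)
        oracle = stats.multivariate_normal.logpdf(y, mean, V)
        assert abs(ll - oracle) < 1e-6

    def test_white_noise_limit(self, cherry3):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=3), rng.normal(size=3)
        se = np.array([0.1, 0.0, 0.2])
        params = OUAllomParams(1e3, 2.0, [], [0.7], [0.1])
        ll = ou_allom_loglik(cherry3, paint_regimes(cherry3, []), params, x, y, se)
        iid = stats.norm.logpdf(y, 0.1 + 0.7 * x, np.sqrt(2.0 / 2e3 + se**2)).sum()
        assert abs(ll - iid) < 1e-3

    def test_brownian_limit_matches_gls_density(self, balanced4):
        """At alpha -> 0 the OU model collapses to a Brownian regression."""
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=4), rng.normal(size=4)
        alpha = 1e-8
        params = OUAllomParams(alpha, 0.9, [], [0.5], [0.0])
        ll = ou_allom_loglik(balanced4, paint_regimes(balanced4, []), params, x, y, None)
        C = 0.9 * shared_path_times(balanced4).to_numpy()
        oracle = stats.multivariate_normal.logpdf(y, 0.0 + 0.5 * x, C)
        assert abs(ll - oracle) < 1e-3

    def test_perfect_fit_likelihood_increases_as_sigma_shrinks(self, cherry3):
        x = np.array([1.0, 2.0, 3.0])
        y = 0.3 + 0.9 * x
        painting = paint_regimes(cherry3, [])
        lls = [
            ou_allom_loglik(
                cherry3, painting,
                OUAllomParams(1e3, s2, [], [0.9], [0.3]), x, y, None,
            )
            for s2 in (1.0, 0.1, 0.01)
        ]
        assert lls[0] < lls[1] < lls[2]

    def test_nonfinite_inputs_rejected(self, cherry3):
        params = OUAllomParams(1.0, 1.0, [], [1.0], [0.0])
        with pytest.raises(ValueError, match="non-finite"):
            ou_allom_loglik(
                cherry3, None, params, np.array([1.0, np.nan, 2.0]), np.zeros(3)
            )


class TestPrior:
    def test_half_cauchy_at_scale_point(self, cherry3):
        s = 0.1
        prior = PriorSpec(alpha_scale=s, sigma2_scale=s, k_mean=1, k_max=2)
        p0 = OUAllomParams(s, s, [], [0.0], [0.0])
        lp = log_prior(p0, prior, cherry3)
        # each half-Cauchy contributes log(1/(pi s)) at v = s
        expected_hc = 2 * math.log(1.0 / (math.pi * s))
        other = (
            float(prior.k_log_pmf()[0])
            + 2 * stats.norm.logpdf(0.0, 0.0, 1.0)
        )
        assert lp == pytest.approx(expected_hc + other, abs=1e-10)

    def test_k_above_truncation_impossible(self, balanced4):
        prior = PriorSpec(k_mean=1, k_max=1)
        params = OUAllomParams(
            0.1, 0.1, [(1, 0.5), (2, 0.5)], [0, 1, 2], [0, 1, 2]
        )
        assert log_prior(params, prior, balanced4) == -np.inf

    def test_truncated_poisson_normalizes(self):
        prior = PriorSpec(k_mean=2.0, k_max=6)
        assert np.exp(prior.k_log_pmf()).sum() == pytest.approx(1.0, abs=1e-12)


class TestRJMCMC:
    def test_seed_reproducibility(self, cherry3):
        rng = np.random.default_rng(6)
        x = pd.Series(rng.normal(size=3), index=cherry3.tip_labels)
        y = pd.Series(rng.normal(size=3), index=cherry3.tip_labels)
        se = pd.Series(0.05, index=cherry3.tip_labels)
        prior = PriorSpec(k_mean=1, k_max=2)
        cfg = ChainConfig(iterations=2000, thin=10, priming=100, seed=99, n_chains=2)
        a = rjmcmc_run(cherry3, x, y, se, prior, cfg)
        b = rjmcmc_run(cherry3, x, y, se, prior, cfg)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.alpha, cb.alpha)
            np.testing.assert_array_equal(ca.k, cb.k)
            assert ca.shifts == cb.shifts

    def test_prior_only_recovers_k_prior(self, balanced4):
        """With the likelihood switched off the chain must sample the
        conditional-Poisson prior on the shift count."""
        prior = PriorSpec(k_mean=1.0, k_max=4)
        cfg = ChainConfig(
            iterations=150_000, thin=5, priming=0, seed=17,
            prior_only=True, rj_prob=0.9, rj_attempts=4,
        )
        ch = rjmcmc_run(balanced4, None, None, None, prior, cfg)[0]
        obs = np.array([np.sum(ch.k == k) for k in range(prior.k_max + 1)])
        expected = np.exp(prior.k_log_pmf()) * len(ch.k)
        chi2 = ((obs - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, prior.k_max)
        assert p > 0.01

    def test_prior_only_branch_placement_uniform(self, balanced4):
        """Conditional on k = 1 every branch is equally likely."""
        prior = PriorSpec(k_mean=1.0, k_max=2)
        cfg = ChainConfig(
            iterations=100_000, thin=5, priming=0, seed=18,
            prior_only=True, rj_prob=0.9, rj_attempts=4,
        )
        ch = rjmcmc_run(balanced4, None, None, None, prior, cfg)[0]
        singles = [s[0] for s in ch.shifts if len(s) == 1]
        counts = pd.Series(singles).value_counts()
        B = len(balanced4.branch_ids())
        assert len(counts) == B
        freq = counts / len(singles)
        assert (np.abs(freq - 1.0 / B) < 4 * np.sqrt((1 / B) * (1 - 1 / B) / len(singles)) + 0.01).all()

    def test_visit_frequencies_match_marginalized_posterior(self):
        """Detailed-balance check: on a 4-tip tree with k_max = 1, RJ visit
        frequencies of each shift configuration match the posterior computed
        by analytic marginalization over (beta, theta) and Monte-Carlo
        integration over (alpha, sigma2)."""
        tree = read_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        rng = np.random.default_rng(12)
        x = pd.Series([0.5, 1.5, -0.5, 1.0], index=tree.tip_labels)
        y = pd.Series([0.4, 1.2, -0.2, 0.9], index=tree.tip_labels)
        se = pd.Series(0.05, index=tree.tip_labels)
        prior = PriorSpec(
            alpha_scale=0.5, sigma2_scale=0.5, k_mean=1.0, k_max=1,
            beta_mean=0.5, beta_sd=0.5, theta_mean=0.0, theta_sd=0.5,
        )
        B = len(tree.branch_ids())
        eng = _LikelihoodEngine(tree, x, y, se)
        xv = x.to_numpy()

        def config_marginal(shifts, n_mc=2500):
            """E_prior[ integral over beta,theta of L ] via conjugacy."""
            lls = np.empty(n_mc)
            R = len(shifts) + 1
            m0 = np.concatenate(
                [np.full(R, prior.theta_mean), np.full(R, prior.beta_mean)]
            )
            S0 = np.diag(
                np.concatenate([np.full(R, prior.theta_sd**2), np.full(R, prior.beta_sd**2)])
            )
            for i in range(n_mc):
                a = abs(rng.standard_cauchy()) * prior.alpha_scale
                s2 = abs(rng.standard_cauchy()) * prior.sigma2_scale
                W = eng.weights(a, shifts)
                M = np.hstack([W, W * xv[:, None]])
                V = s2 * eng.ou_matrix(a) + np.diag(se.to_numpy() ** 2)
                cov = V + M @ S0 @ M.T
                lls[i] = stats.multivariate_normal.logpdf(
                    y.to_numpy(), M @ m0, cov, allow_singular=True
                )
            from scipy.special import logsumexp

            return logsumexp(lls) - math.log(n_mc)

        configs = [()] + [(b,) for b in tree.branch_ids()]
        kpmf = prior.k_log_pmf()
        logw = []
        for cfg_branches in configs:
            shifts = [(b, 0.5) for b in cfg_branches]
            k = len(shifts)
            struct = float(kpmf[k]) - (math.log(B) if k == 1 else 0.0)
            logw.append(struct + config_marginal(shifts))
        logw = np.array(logw)
        target = np.exp(logw - logw.max())
        target /= target.sum()

        cfg = ChainConfig(
            iterations=200_000, thin=10, priming=500, seed=13, rj_prob=0.8
        )
        ch = rjmcmc_run(tree, x, y, se, prior, cfg)[0]
        visits = pd.Series([s if s else () for s in ch.shifts]).value_counts()
        freq = np.array(
            [visits.get(c, 0) for c in configs], dtype=float
        ) / len(ch.shifts)
        # loose bound: both sides carry Monte-Carlo error
        assert np.abs(freq - target).max() < 0.05

    def test_planted_shift_recovered_quick(self):
        """A strong planted shift on 32 tips becomes the top-probability branch."""
        tree = sim.simulate_tree(32, 1.0, 0.0, seed=300)
        below = tree.tips_below()
        shift_branch = next(
            b for b in tree.branch_ids() if 6 <= len(below[b]) <= 12
        )
        depth = tree.depths().max()
        alpha, sigma2 = 4.0 / depth, 0.02 * 8.0 / depth
        sd = math.sqrt(sigma2 / (2 * alpha))
        x = sim.simulate_bm_predictor(tree, 2.0, 1.0 / depth, seed=301)
        painting = paint_regimes(tree, [shift_branch])
        params = OUAllomParams(
            alpha, sigma2, [(shift_branch, 0.5)], [0.5, 0.8], [0.0, 5 * sd]
        )
        se = pd.Series(0.02, index=tree.tip_labels)
        y = sim.simulate_ou_allometry(tree, painting, params, x, se=se, seed=302)
        prior = PriorSpec.from_tree(tree, beta_mean=0.5, beta_sd=0.3)
        cfg = ChainConfig(iterations=25_000, thin=25, priming=1500, seed=303)
        chains = rjmcmc_run(tree, x, y, se, prior, cfg)
        summ = summarize_posterior(chains, tree)
        top = summ.branch_prob.idxmax()
        assert top == shift_branch
        assert summ.branch_prob.loc[top] > 0.3


class TestSummaries:
    def _hand_chain(self, shifts_list, cfg=None):
        n = len(shifts_list)
        from mosaicbrain.oumodel import ChainSamples

        return ChainSamples(
            iteration=np.arange(n),
            loglik=np.zeros(n),
            logprior=np.zeros(n),
            alpha=np.ones(n),
            sigma2=np.ones(n),
            k=np.array([len(s) for s in shifts_list]),
            shifts=shifts_list,
            beta=[np.zeros(len(s) + 1) for s in shifts_list],
            theta=[np.zeros(len(s) + 1) for s in shifts_list],
            config=cfg or ChainConfig(iterations=10, thin=1, burnin_frac=0.0, priming=0),
        )

    def test_branch_probability_counting(self, balanced4):
        shifts = [(1,)] * 3 + [()] * 7
        summ = summarize_posterior([self._hand_chain(shifts)], balanced4, threshold=0.2)
        assert summ.branch_prob.loc[1] == pytest.approx(0.3)
        assert summ.shifts["branch"].tolist() == [1]
        summ2 = summarize_posterior([self._hand_chain(shifts)], balanced4, threshold=0.35)
        assert summ2.shifts.empty

    def test_no_shift_samples(self, balanced4):
        summ = summarize_posterior([self._hand_chain([()] * 10)], balanced4)
        assert (summ.branch_prob == 0).all()
        assert summ.shifts.empty
        assert summ.params.loc["k", "median"] == 0

    def test_empty_chain_rejected(self, balanced4):
        with pytest.raises(ValueError, match="post-burn-in"):
            summarize_posterior([self._hand_chain([])], balanced4)


class TestDiagnostics:
    def test_iid_ess_close_to_n(self, rng):
        draws = rng.standard_normal((1, 10_000))
        d = convergence_diagnostics({"x": draws})
        assert abs(d.loc["x", "ess"] - 10_000) / 10_000 < 0.15

    def test_rhat_near_one_for_same_distribution(self, rng):
        draws = rng.standard_normal((2, 10_000))
        d = convergence_diagnostics({"x": draws})
        assert d.loc["x", "rhat"] < 1.01

    def test_rhat_large_for_separated_chains(self, rng):
        draws = np.stack(
            [rng.standard_normal(10_000), rng.standard_normal(10_000) + 10]
        )
        d = convergence_diagnostics({"x": draws})
        assert d.loc["x", "rhat"] > 2.0

    def test_constant_chain_marker(self):
        d = convergence_diagnostics({"x": np.ones((2, 100))})
        assert np.isnan(d.loc["x", "ess"])


class TestSteppingStone:
    def test_zero_information_data(self):
        """If every sample has the same log-likelihood c, log ML = c."""
        res = stepping_stone(
            lambda power, n, rng: np.full(n, -3.7), steps=10,
            iterations_per_step=50, rng=np.random.default_rng(0),
        )
        assert res.logml == pytest.approx(-3.7, abs=1e-12)

    def test_conjugate_normal_toy_exact_sampler(self):
        rng0 = np.random.default_rng(21)
        n = 20
        y = rng0.normal(1.0, 1.0, n)
        ybar = y.mean()

        def draw(power, n_iter, rng):
            prec = power * n + 1.0
            mu = rng.normal(power * n * ybar / prec, 1 / np.sqrt(prec), n_iter)
            return np.array([stats.norm.logpdf(y, m, 1.0).sum() for m in mu])

        res = stepping_stone(
            draw, steps=50, shape=(0.3, 1.0), iterations_per_step=500,
            rng=np.random.default_rng(22),
        )
        truth = stats.multivariate_normal.logpdf(
            y, np.zeros(n), np.eye(n) + np.ones((n, n))
        )
        assert abs(res.logml - truth) < 0.1

    def test_mc_error_scales_with_iterations(self):
        """Doubling per-rung samples should shrink the estimator SD ~ sqrt(2)."""
        rng0 = np.random.default_rng(23)
        n = 20
        y = rng0.normal(0.5, 1.0, n)
        ybar = y.mean()

        def draw(power, n_iter, rng):
            prec = power * n + 1.0
            mu = rng.normal(power * n * ybar / prec, 1 / np.sqrt(prec), n_iter)
            return -0.5 * n * math.log(2 * math.pi) - 0.5 * (
                ((y[None, :] - mu[:, None]) ** 2).sum(axis=1)
            )

        def sd_at(iters, seeds):
            vals = [
                stepping_stone(
                    draw, steps=20, iterations_per_step=iters,
                    rng=np.random.default_rng(s),
                ).logml
                for s in seeds
            ]
            return np.std(vals)

        sd1 = sd_at(50, range(100, 120))
        sd2 = sd_at(200, range(200, 220))
        assert sd2 < sd1  # 4x samples: clear reduction beyond noise

    def test_schedule_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            MarginalLikelihoodResult(0.0, np.array([0.5, 0.4, 1.0]), np.zeros(3))

    def test_ou_stepping_stone_prefers_true_shift_model(self):
        """2 ln BF favors the generating shift configuration over no shift."""
        tree = sim.simulate_tree(24, 1.0, 0.0, seed=400)
        below = tree.tips_below()
        shift_branch = next(b for b in tree.branch_ids() if 5 <= len(below[b]) <= 10)
        depth = tree.depths().max()
        alpha, sigma2 = 2.0 / depth, 0.02 * 4.0 / depth
        sd = math.sqrt(sigma2 / (2 * alpha))
        x = sim.simulate_bm_predictor(tree, 2.0, 1.0 / depth, seed=401)
        painting = paint_regimes(tree, [shift_branch])
        params = OUAllomParams(
            alpha, sigma2, [(shift_branch, 0.5)], [0.5, 0.7], [0.0, 8 * sd]
        )
        se = pd.Series(0.02, index=tree.tip_labels)
        y = sim.simulate_ou_allometry(tree, painting, params, x, se=se, seed=402)
        prior = PriorSpec.from_tree(tree, beta_mean=0.5, beta_sd=0.3)
        shift_model = fixed_shift_model(tree, [shift_branch])
        null_model = fixed_shift_model(tree, [])
        kw = dict(steps=20, iterations_per_step=1200, thin=4, seed=403)
        ml_shift = stepping_stone_logml(shift_model, tree, x, y, se, prior, **kw)
        ml_null = stepping_stone_logml(null_model, tree, x, y, se, prior, **kw)
        assert bayes_factor_2ln(ml_shift.logml, ml_null.logml) > 5


class TestFixedShiftModels:
    def test_empty_branch_set_is_global_model(self, balanced4):
        m = fixed_shift_model(balanced4, [])
        assert m.n_regimes == 1

    def test_regime_count(self, tree20):
        m = fixed_shift_model(tree20, [2, 5, 9])
        assert m.n_regimes == 4

    def test_intercept_only_mode_shares_slope(self, tree20):
        m = fixed_shift_model(tree20, [2, 5], share_slope=True)
        assert m.share_slope and m.n_regimes == 3

    def test_unknown_branch_rejected(self, balanced4):
        with pytest.raises(ValueError, match="does not exist"):
            fixed_shift_model(balanced4, [42])


class TestBayesFactor:
    @pytest.mark.parametrize("a,b,expected", [(0, 0, 0), (14, 0, 28), (0, 14, -28)])
    def test_scale_and_antisymmetry(self, a, b, expected):
        assert bayes_factor_2ln(a, b) == expected
        assert bayes_factor_2ln(b, a) == -expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            bayes_factor_2ln(np.inf, 0.0)
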