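"""Unit tests of the sampler's full conditional distributions.

Each conditional is checked on a fixed state against an independent oracle:
closed-form inverse cdfs, direct density-ratio computation, or quadrature
over a parameter grid. Chain-level correctness (that the composition of all
updates preserves the joint) is covered by the successive-conditional test
in the acceptance suite.
"""

import numpy as np
import pytest
from scipy import integrate, stats

from esmmtx import ESMModel, GenerativeSpec, PriorConfig, generate_esm_gene, run_gibbs
from esmmtx.gibbs import (
    Workspace,
    _bounds_from,
    _theta_logpost,
    coefficient_bounds,
    init_state,
    marginal_coef_loglik,
    sample_beta_and_zeta,
    sample_censored_latents,
    sample_rho,
    sample_slice_variables,
    sample_thetas_mh,
    sample_U_and_L,
    sample_variances,
    sweep,
)


@pytest.fixture()
def state_and_data(small_gene, fast_prior):
    data, _, spec = small_gene
    cfg = PriorConfig(**{**fast_prior.__dict__, "C": spec.C})
    rng = np.random.default_rng(3)
    state = init_state(data, cfg, rng)
    for _ in range(5):  # settle into a generic consistent state
        sweep(state, data, cfg, rng)
    return state, data, cfg, rng


class TestCensoredLatents:
    def test_truncated_exponential_cdf(self, state_and_data):
        state, data, cfg, rng = state_and_data
        draws = []
        for _ in range(400):
            sample_censored_latents(state, data, cfg, rng)
            draws.append(state.y_tilde.copy())
        draws = np.stack(draws)
        assert draws.min() >= 0 and draws.max() < cfg.C
        # per-observation inverse-cdf oracle on the first censored obs
        scale = (state.mu(data) * state.U)[data.y == 0][0]
        x = draws[:, 0]
        ks = stats.kstest(
            x, lambda q: np.expm1(-q / scale) / np.expm1(-cfg.C / scale)
        )
        assert ks.pvalue > 0.001

    def test_flat_limit_is_uniform(self, state_and_data):
        # mu*U >> C: the truncated exponential is flat on [0, C)
        state, data, cfg, rng = state_and_data
        state.U[:] = 1e9
        sample_censored_latents(state, data, cfg, rng)
        assert stats.kstest(state.y_tilde / cfg.C, "uniform").pvalue > 1e-4 or len(
            state.y_tilde
        ) < 20


class TestSliceVariables:
    def test_support_and_shifted_exponential(self, state_and_data):
        state, data, cfg, rng = state_and_data
        lower = state.ydot(data) / (state.mu(data) * state.U)
        draws = []
        for _ in range(300):
            sample_slice_variables(state, data, rng)
            draws.append(state.e.copy())
        draws = np.stack(draws)
        assert np.all(draws > lower)
        ks = stats.kstest((draws - lower).ravel(), stats.expon.cdf)
        assert ks.pvalue > 0.001


class TestCoefficientBounds:
    def test_single_observation(self):
        lo, hi = _bounds_from(np.array([1.0]), np.array([-0.3]))
        assert lo == pytest.approx(-0.3) and hi == np.inf

    def test_two_sided(self):
        # constraints: coef*1 > -1 and coef*(-1) > -2  =>  -1 < coef < 2
        lo, hi = _bounds_from(np.array([1.0, -1.0]), np.array([-1.0, -2.0]))
        assert (lo, hi) == (-1.0, 2.0)

    def test_binary_covariate_upper_always_inf(self, state_and_data):
        state, data, cfg, _ = state_and_data
        lo, hi = coefficient_bounds(state, data, "beta")
        assert hi == np.inf
        assert lo < state.beta or state.beta == 0.0

    def test_current_state_always_inside(self, state_and_data):
        state, data, cfg, _ = state_and_data
        lo, hi = coefficient_bounds(state, data, "alpha")
        assert lo < state.alpha < hi
        for r in range(data.n_subjects):
            lo, hi = coefficient_bounds(state, data, "eta", r)
            assert hi == np.inf and lo < state.eta[r]


class TestUAndL:
    def test_u_update_moments(self, state_and_data):
        state, data, cfg, rng = state_and_data
        ydot = state.ydot(data)
        mu = state.mu(data)
        shape = np.where(state.L == 1, state.theta1, state.theta2) + 2.0
        scale = ydot / mu + np.where(state.L == 1, state.theta1, state.theta2)
        L_fixed = state.L.copy()
        draws = []
        for _ in range(600):
            state.L = L_fixed.copy()
            sample_U_and_L(state, data, rng)
            draws.append(state.U.copy())
        draws = np.stack(draws)
        expected = scale / (shape - 1.0)  # IG mean
        assert np.allclose(draws.mean(axis=0), expected, rtol=0.35)

    def test_equal_thetas_allocate_at_rho(self, state_and_data):
        state, data, cfg, rng = state_and_data
        state.theta1 = state.theta2 = 0.7
        state.rho = 0.3
        hits = []
        for _ in range(300):
            sample_U_and_L(state, data, rng)
            hits.append((state.L == 1).mean())
        assert np.mean(hits) == pytest.approx(0.3, abs=0.03)

    def test_allocation_matches_density_ratio(self, state_and_data):
        # calibration of Pr(L=1 | U) against the scipy density-ratio oracle:
        # over many (U, L) draws the empirical allocation frequency within
        # oracle-probability bins must match the bin's mean probability
        state, data, cfg, rng = state_and_data
        state.theta1, state.theta2, state.rho = 1.5, 0.05, 0.4
        us, ls = [], []
        for _ in range(200):
            state.theta1, state.theta2, state.rho = 1.5, 0.05, 0.4
            sample_U_and_L(state, data, rng)
            us.append(state.U.copy())
            ls.append(state.L.copy())
        u = np.concatenate(us)
        l1 = np.concatenate(ls) == 1
        w1 = np.log(0.4) + stats.invgamma.logpdf(u, 2.5, scale=1.5)
        w2 = np.log(0.6) + stats.invgamma.logpdf(u, 1.05, scale=0.05)
        p1 = 1.0 / (1.0 + np.exp(w2 - w1))
        for lo, hi in [(0.0, 0.25), (0.25, 0.75), (0.75, 1.0)]:
            mask = (p1 >= lo) & (p1 < hi)
            if mask.sum() > 200:
                assert l1[mask].mean() == pytest.approx(p1[mask].mean(), abs=0.05)


class TestRho:
    def test_beta_posterior_counts(self, state_and_data):
        state, data, cfg, rng = state_and_data
        state.L[:] = 1
        state.L[:10] = 2
        n1 = (state.L == 1).sum()
        n2 = (state.L == 2).sum()
        draws = [sample_rho(state, rng) or state.rho for _ in range(4000)]
        expected = (n1 + 1) / (n1 + n2 + 2)
        assert np.mean(draws) == pytest.approx(expected, abs=0.01)

    def test_counts_conserved(self, state_and_data):
        state, data, cfg, rng = state_and_data
        assert ((state.L == 1).sum() + (state.L == 2).sum()) == data.n_obs


class TestBetaZeta:
    def test_no_information_gives_prior_probability(self, small_gene, fast_prior):
        # all s = 0: no constraints on beta and sum(s) = 0, so the inclusion
        # probability collapses to pi
        data, _, spec = small_gene
        data.s[:] = 0.0
        cfg = PriorConfig(**{**fast_prior.__dict__, "C": spec.C, "pi": 0.5})
        rng = np.random.default_rng(0)
        state = init_state(data, cfg, rng)
        state.beta = 0.0
        state.zeta = 0
        sample_slice_variables(state, data, rng)
        zetas = []
        for _ in range(2000):
            sample_beta_and_zeta(state, data, cfg, rng)
            zetas.append(state.zeta)
            state.beta, state.zeta = 0.0, 0  # reset so bounds stay trivial
        assert np.mean(zetas) == pytest.approx(0.5, abs=0.04)

    def test_spike_excluded_forces_inclusion(self, state_and_data):
        state, data, cfg, rng = state_and_data
        # force a state where beta = 0 violates a slice constraint
        state.beta = 2.0
        lp = state.linpred(data)
        state.e = state.ydot(data) / (np.exp(lp) * state.U) + 0.01
        lo, hi = coefficient_bounds(state, data, "beta")
        if lo > 0:  # constraint region excludes zero
            sample_beta_and_zeta(state, data, cfg, rng)
            assert state.zeta == 1 and state.beta > 0

    def test_inclusion_probability_matches_quadrature(self, small_gene):
        # brute-force the joint over beta on a grid and compare the
        # Bernoulli probability of inclusion
        data, _, spec = small_gene
        cfg = PriorConfig(C=spec.C, n_iter=10, n_burn=0, seed=1)
        rng = np.random.default_rng(8)
        state = init_state(data, cfg, rng)
        for _ in range(3):
            sweep(state, data, cfg, rng)
        z = data.s
        lp_rest = state.linpred(data) - state.beta * z
        c = np.log(state.ydot(data)) - np.log(state.e) - np.log(state.U) - lp_rest
        lower, upper = _bounds_from(z, c)
        S = z.sum()
        tau2 = state.tau2
        # oracle: h1 = int exp(-beta*S) N(beta|0,tau2) over the feasible window
        h1, _ = integrate.quad(
            lambda b: np.exp(-b * S) * stats.norm.pdf(b, 0, np.sqrt(tau2)),
            max(lower, -50), min(upper, 50),
        )
        h0 = 1.0 if lower < 0 < upper else 0.0
        p_oracle = cfg.pi * h1 / ((1 - cfg.pi) * h0 + cfg.pi * h1)
        hits = []
        beta0, zeta0 = state.beta, state.zeta
        for _ in range(3000):
            state.beta, state.zeta = beta0, zeta0
            sample_beta_and_zeta(state, data, cfg, rng)
            hits.append(state.zeta)
        se = np.sqrt(p_oracle * (1 - p_oracle) / len(hits)) + 1e-4
        assert np.mean(hits) == pytest.approx(p_oracle, abs=4 * se + 0.02)


class TestVariances:
    def test_zero_coefficient_gives_stated_ig(self, state_and_data):
        state, data, cfg, rng = state_and_data
        state.alpha = 0.0
        b_fixed = 2.0
        draws = []
        for _ in range(4000):
            state.b_sigma2 = b_fixed
            sample_variances(state, cfg, rng)
            draws.append(state.sigma2)
        # sigma2 ~ IG(1, 1/b): compare medians (mean is infinite)
        expected_median = stats.invgamma.median(1.0, scale=1.0 / b_fixed)
        assert np.median(draws) == pytest.approx(expected_median, rel=0.1)

    def test_half_cauchy_marginal_of_tau(self, fast_prior, small_gene, rng):
        # iterating the two-level IG hierarchy reproduces C+(0, psi)
        psi = 3.0
        b = 1.0 / rng.gamma(0.5, 1.0 / (1.0 / psi**2), size=100_000)
        tau2 = 1.0 / rng.gamma(0.5, 1.0 / (1.0 / b))
        tau = np.sqrt(tau2)
        ks = stats.kstest(tau, stats.halfcauchy(scale=psi).cdf)
        assert ks.pvalue > 0.01

    def test_random_effect_variance_counts(self, state_and_data):
        state, data, cfg, rng = state_and_data
        state.eta[:] = 0.0
        R = len(state.eta)
        b_fixed = 1.5
        draws = []
        for _ in range(4000):
            state.b_phi2 = b_fixed
            sample_variances(state, cfg, rng)
            draws.append(state.phi2)
        ref = stats.invgamma.median(R / 2 + 0.5, scale=1.0 / b_fixed)
        assert np.median(draws) == pytest.approx(ref, rel=0.1)


class TestThetaMH:
    def test_empty_component_targets_prior(self, state_and_data):
        state, data, cfg, rng = state_and_data
        state.L[:] = 1  # component 2 empty
        draws = []
        for _ in range(6000):
            sample_thetas_mh(state, cfg, rng)
            draws.append(state.theta2)
        # prior Exp(rate xi): median log(2)/xi
        assert np.median(draws[1000:]) == pytest.approx(np.log(2) / cfg.xi, rel=0.25)

    def test_stationary_density_matches_quadrature(self, state_and_data):
        state, data, cfg, rng = state_and_data
        state.L[:] = 1
        u = state.U[:40]
        state.U = u
        state.L = np.ones(40, dtype=np.int64)
        data_u = u
        grid = np.linspace(1e-3, 8, 4000)
        logpost = np.array([_theta_logpost(t, data_u, cfg.xi) for t in grid])
        w = np.exp(logpost - logpost.max())
        w /= np.trapezoid(w, grid)
        cdf = np.concatenate([[0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(grid))])
        cdf /= cdf[-1]
        draws = []
        for _ in range(20000):
            sample_thetas_mh(state, cfg, rng)
            draws.append(state.theta1)
        draws = np.array(draws[2000:])
        oracle_q = np.interp([0.25, 0.5, 0.75], cdf, grid)
        sample_q = np.quantile(draws, [0.25, 0.5, 0.75])
        assert np.allclose(sample_q, oracle_q, rtol=0.15)

    def test_adaptation_reaches_target_window(self, small_gene):
        data, _, spec = small_gene
        cfg = PriorConfig(C=spec.C, n_iter=600, n_burn=400, seed=2)
        chain = run_gibbs(data, cfg)
        assert np.all(chain.mh_acceptance > 0.1) and np.all(chain.mh_acceptance < 0.7)


class TestSweepInvariants:
    def test_slice_constraints_hold_after_every_sweep(self, small_gene, fast_prior):
        data, _, spec = small_gene
        cfg = PriorConfig(**{**fast_prior.__dict__, "C": spec.C})
        rng = np.random.default_rng(10)
        state = init_state(data, cfg, rng)
        for _ in range(30):
            sweep(state, data, cfg, rng)
            slack = state.e - state.ydot(data) / (state.mu(data) * state.U)
            assert np.all(slack > 0)
            assert np.all(state.U > 0)
            assert 0 < state.rho < 1
            assert (state.zeta == 0) == (state.beta == 0.0)
            assert np.all(state.y_tilde >= 0) and np.all(state.y_tilde < cfg.C)

    def test_same_seed_identical_chains(self, small_gene):
        data, _, spec = small_gene
        cfg = PriorConfig(C=spec.C, n_iter=100, n_burn=40, seed=77)
        c1 = run_gibbs(data, cfg)
        c2 = run_gibbs(data, cfg)
        assert np.array_equal(c1.beta, c2.beta)
        assert np.array_equal(c1.alpha, c2.alpha)
        assert np.array_equal(c1.theta1, c2.theta1)

    def test_constant_s_gives_uninformative_zeta(self, small_gene):
        data, _, spec = small_gene
        data.s[:] = 1.0
        cfg = PriorConfig(C=spec.C, n_iter=800, n_burn=200, seed=3)
        chain = run_gibbs(data, cfg)
        # likelihood carries information only through bounds; the PIP should
        # stay in the interior, not collapse to 0 or 1 deterministically
        assert 0.01 < chain.pip < 0.99


class TestMarginalLoglik:
    def test_matches_direct_mixture_computation(self, small_gene, fast_prior):
        data, _, spec = small_gene
        cfg = PriorConfig(**{**fast_prior.__dict__, "C": spec.C})
        rng = np.random.default_rng(4)
        state = init_state(data, cfg, rng)
        ws = Workspace(data)
        lp = state.linpred(data)
        ours = marginal_coef_loglik(lp, ws, state.theta1, state.theta2, state.rho, cfg.C)
        mu = np.exp(lp)
        ref = 0.0
        for yi, mui in zip(data.y, mu):
            f1 = stats.lomax(state.theta1 + 1, scale=mui * state.theta1)
            f2 = stats.lomax(state.theta2 + 1, scale=mui * state.theta2)
            if yi > 0:
                ref += np.log(state.rho * f1.pdf(yi) + (1 - state.rho) * f2.pdf(yi))
            else:
                ref += np.log(state.rho * f1.cdf(cfg.C) + (1 - state.rho) * f2.cdf(cfg.C))
        assert ours == pytest.approx(ref, rel=1e-9)


class TestRunGibbs:
    def test_recovers_strong_signal_direction(self):
        spec = GenerativeSpec(
            n_samples=120, n_subjects=30, taxa_per_sample=3, alpha=1.0,
            beta=np.log(10), theta1=2.0, theta2=0.05, rho=0.6, seed=21,
        )
        data, truth = generate_esm_gene(spec)
        res = ESMModel(data, PriorConfig(C=spec.C, n_iter=800, n_burn=400, seed=5)).fit()
        assert res.pip > 0.9
        b = res.chain.beta[res.chain.zeta == 1]
        assert abs(b.mean() - np.log(10)) < 4 * b.std() + 0.3

    def test_null_gene_pip_stays_low(self):
        spec = GenerativeSpec(
            n_samples=120, n_subjects=30, taxa_per_sample=3, alpha=1.0,
            beta=0.0, theta1=2.0, theta2=0.05, rho=0.6, seed=22,
        )
        data, _ = generate_esm_gene(spec)
        res = ESMModel(data, PriorConfig(C=spec.C, n_iter=800, n_burn=400, seed=6)).fit()
        assert res.pip < 0.5
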