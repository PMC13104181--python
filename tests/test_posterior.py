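"""Sampler, diagnostics, KDE marginal, entropy, and summary tests.

The sampler is validated against three independent routes: a conjugate
closed form (gamma0 from a single pure-water measurement), a dense-grid
numerical posterior on a reduced problem, and emcee run on the identical
unconstrained target.
"""

import math

import numpy as np
import pytest
from scipy import integrate

import cmcbed as cb
from cmcbed.isotherm import Dataset, IsothermParams, Measurement, NoiseModel, PriorSpec
from cmcbed.posterior import (
    MarginalDensity,
    SamplerSettings,
    _log_post_unconstrained,
    cmc_density_from_draws,
    convergence_diagnostics,
    credible_interval,
    differential_entropy,
    effective_sample_size,
    marginal_cmc_density,
    posterior_mode_cmc,
    sample_posterior,
    silverman_bandwidth,
    split_rhat,
    theta_to_unconstrained,
    unconstrained_to_theta,
)


def make_samples(draws, n_chains=4):
    """Wrap an (N, 4) array as PosteriorSamples with balanced chain ids."""
    draws = np.asarray(draws, dtype=float)
    n = draws.shape[0] - draws.shape[0] % n_chains
    draws = draws[:n]
    from cmcbed.posterior import DiagnosticReport, PosteriorSamples

    return PosteriorSamples(
        draws=draws,
        chain_id=np.repeat(np.arange(n_chains), n // n_chains),
        diagnostics=DiagnosticReport(rhat={}, ess={}, passed=False),
    )


def uniform_cmc_samples(n=10_000, lo=0.0, hi=30.0, seed=0):
    rng = np.random.default_rng(seed)
    draws = np.column_stack(
        [
            np.full(n, 0.0718),
            np.full(n, 0.01),
            np.full(n, 1.0),
            rng.uniform(lo, hi, n),
        ]
    )
    return make_samples(draws)


class TestTransforms:
    def test_round_trip(self, otg_prior, triton_prior):
        for prior in (otg_prior, triton_prior):
            lo, hi = prior.cmc_bounds
            th = np.array(
                [[0.0718, 0.01, 5.0, (lo + hi) / 3 + 0.01], [0.07, 0.05, 900.0, hi * 0.9]]
            )
            back = unconstrained_to_theta(theta_to_unconstrained(th, prior), prior)
            assert np.allclose(back, th, rtol=1e-9)

    def test_unconstrained_target_matches_scalar_posterior(self, otg_prior, otg_data5, noise):
        """Vectorized x-space target = scalar log posterior + logit Jacobians."""
        th = np.array([[0.0715, 0.012, 4.2, 9.5], [0.0720, 0.03, 100.0, 20.0]])
        x = theta_to_unconstrained(th, otg_prior)
        got = _log_post_unconstrained(x, otg_data5, otg_prior, noise)
        from scipy.special import log_expit

        for i in range(2):
            theta = IsothermParams.from_array(th[i])
            base = cb.log_unnormalized_posterior(theta, otg_data5, otg_prior, noise)
            jac = 0.0
            for col, width in ((1, 0.099), (2, 10000.0), (3, 30.0)):
                jac += math.log(width) + float(log_expit(x[i, col])) + float(log_expit(-x[i, col]))
            assert got[i] == pytest.approx(base + jac, rel=1e-10)


class TestSamplePosterior:
    def test_conjugate_gamma0_from_pure_water(self, otg_prior, noise):
        """One c = 0 measurement updates gamma0 conjugately:
        posterior N((m + y)/2, sigma^2/2)."""
        y = otg_prior.gamma0_mean + 0.0012
        data = Dataset([Measurement(0.0, y)])
        fit = sample_posterior(data, otg_prior, noise, SamplerSettings(seed=5))
        g0 = fit.column("gamma0")
        mean_true = (otg_prior.gamma0_mean + y) / 2
        sd_true = noise.sigma / math.sqrt(2)
        ess = max(fit.diagnostics.ess["gamma0"], 50.0)
        mc_se = g0.std() / math.sqrt(ess)
        assert abs(g0.mean() - mean_true) < 4 * mc_se
        assert g0.std() == pytest.approx(sd_true, rel=0.10)

    def test_empty_data_recovers_prior(self, otg_prior, noise):
        fit = sample_posterior(Dataset([]), otg_prior, noise, SamplerSettings(seed=8))
        cmc = fit.cmc
        assert abs(cmc.mean() - 15.0) < 1.0
        ent = differential_entropy(marginal_cmc_density(fit, otg_prior))
        assert ent == pytest.approx(math.log(30.0), abs=0.1)

    def test_seed_determinism_bitwise(self, otg_prior, otg_data5, noise):
        s = SamplerSettings(n_chains=16, n_warmup=300, n_draws=150, seed=21)
        a = sample_posterior(otg_data5, otg_prior, noise, s)
        b = sample_posterior(otg_data5, otg_prior, noise, s)
        assert np.array_equal(a.draws, b.draws)
        ea = differential_entropy(marginal_cmc_density(a, otg_prior))
        eb = differential_entropy(marginal_cmc_density(b, otg_prior))
        assert ea == eb

    def test_draws_inside_prior_support(self, otg_fit5, otg_prior):
        d = otg_fit5.draws
        assert np.all(d[:, 1] >= 0.001) and np.all(d[:, 1] <= 0.1)
        assert np.all(d[:, 2] > 0) and np.all(d[:, 2] <= 10000.0)
        assert np.all(d[:, 3] >= 0.0) and np.all(d[:, 3] <= 30.0)
        assert np.unique(otg_fit5.chain_id).size == 32

    def test_recovers_truth_with_informative_data(self, otg_fit5):
        lo, hi = credible_interval(otg_fit5, "cmc", 0.90)
        assert lo < 9.7 < hi
        assert hi - lo < 8.0

    def test_odd_chain_count_rejected(self, otg_prior, otg_data5, noise):
        with pytest.raises(ValueError):
            sample_posterior(otg_data5, otg_prior, noise, SamplerSettings(n_chains=7, seed=1))

    def test_warm_start_requires_samples(self, otg_prior, otg_data5, noise):
        with pytest.raises(ValueError):
            sample_posterior(
                otg_data5, otg_prior, noise, SamplerSettings(init_strategy="warm_start", seed=1)
            )

    def test_mcmc_matches_dense_grid_marginal(self, noise):
        """Reduced 2-parameter problem (a, k pinned by tight bounds): the
        MCMC c* marginal must match the dense-grid numerical posterior with
        total variation below 0.05."""
        a0, k0 = 0.0115, 4.0
        prior = PriorSpec(
            a_bounds=(a0 - 1e-7, a0 + 1e-7),
            k_bounds=(k0 - 1e-6, k0 + 1e-6),
            cmc_bounds=(0.0, 30.0),
            cmc_prior_kind="uniform",
        )
        truth = IsothermParams(0.0718, a0, k0, 9.7)
        rng = np.random.default_rng(3)
        concs = [0.0, 4.0, 8.0, 11.0, 30.0]
        data = Dataset(
            [
                Measurement(c, float(cb.evaluate_isotherm(truth, c) + noise.sigma * rng.standard_normal()))
                for c in concs
            ]
        )
        fit = sample_posterior(data, prior, noise, SamplerSettings(seed=17))

        # dense-grid oracle over (gamma0, c*)
        g_grid = np.linspace(0.0718 - 0.005, 0.0718 + 0.005, 201)
        c_grid = np.linspace(0.0, 30.0, 601)
        lp = np.empty((g_grid.size, c_grid.size))
        for i, g in enumerate(g_grid):
            for j, cstar in enumerate(c_grid):
                theta = IsothermParams(g, a0, k0, max(cstar, 1e-9))
                lp[i, j] = cb.log_unnormalized_posterior(theta, data, prior, noise)
        p = np.exp(lp - lp.max())
        marg = np.trapezoid(p, g_grid, axis=0)
        marg /= np.trapezoid(marg, c_grid)

        edges = np.linspace(0.0, 30.0, 61)
        grid_mass = np.array(
            [
                np.trapezoid(
                    marg[(c_grid >= lo) & (c_grid <= hi)], c_grid[(c_grid >= lo) & (c_grid <= hi)]
                )
                for lo, hi in zip(edges[:-1], edges[1:])
            ]
        )
        grid_mass /= grid_mass.sum()
        mcmc_mass, _ = np.histogram(fit.cmc, bins=edges)
        mcmc_mass = mcmc_mass / mcmc_mass.sum()
        tv = 0.5 * np.abs(grid_mass - mcmc_mass).sum()
        assert tv < 0.05

    def test_matches_emcee_on_same_target(self, otg_prior, otg_data5, noise, otg_fit5):
        """Independent-sampler cross-check: emcee on the identical
        unconstrained target must give the same c* quantiles."""
        emcee = pytest.importorskip("emcee")
        nw = 32
        rng = np.random.default_rng(9)
        idx = rng.integers(0, otg_fit5.n_samples, nw)
        x0 = theta_to_unconstrained(otg_fit5.draws[idx], otg_prior)
        x0 += 0.01 * rng.standard_normal(x0.shape)
        sampler = emcee.EnsembleSampler(
            nw,
            4,
            lambda X: _log_post_unconstrained(X, otg_data5, otg_prior, noise),
            vectorize=True,
            moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
        )
        sampler.random_state = np.random.RandomState(4).get_state()
        sampler.run_mcmc(x0, 1500, skip_initial_state_check=True)
        chain = sampler.get_chain(discard=500).reshape(-1, 4)
        cmc_emcee = unconstrained_to_theta(chain, otg_prior)[:, 3]
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            a = np.quantile(otg_fit5.cmc, q)
            b = np.quantile(cmc_emcee, q)
            assert a == pytest.approx(b, abs=0.6)


class TestDiagnostics:
    def test_iid_chains_rhat_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((4, 5000))
        assert split_rhat(chains) < 1.01
        assert effective_sample_size(chains) > 10_000

    def test_disjoint_chains_fail(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((2, 1000))
        chains[1] += 10.0
        assert split_rhat(chains) > 1.1
        draws = np.column_stack([np.abs(chains.ravel()) + 0.01] * 4)
        samples = make_samples(draws, n_chains=2)
        report = convergence_diagnostics(samples)
        assert not report.passed

    def test_constant_chain_defined(self):
        chains = np.ones((4, 500))
        r = split_rhat(chains)
        assert not np.isfinite(r) or r == pytest.approx(1.0)

    def test_single_chain_rejected(self):
        samples = make_samples(np.abs(np.random.default_rng(0).standard_normal((100, 4))) + 0.01, n_chains=1)
        with pytest.raises(ValueError):
            convergence_diagnostics(samples)

    def test_matches_arviz(self):
        """Cross-check the numpy split-R-hat / ESS against arviz."""
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(7)
        # AR(1) chains with modest autocorrelation
        n, c, phi = 2000, 4, 0.6
        chains = np.empty((c, n))
        for i in range(c):
            e = rng.standard_normal(n)
            x = np.empty(n)
            x[0] = e[0]
            for t in range(1, n):
                x[t] = phi * x[t - 1] + e[t]
            chains[i] = x
        ours_rhat = split_rhat(chains)
        ours_ess = effective_sample_size(chains)
        theirs_rhat = float(az.rhat(chains, method="split"))
        theirs_ess = float(az.ess(chains, method="mean"))
        assert ours_rhat == pytest.approx(theirs_rhat, abs=0.01)
        assert ours_ess == pytest.approx(theirs_ess, rel=0.10)


class TestMarginalDensity:
    def test_uniform_draws_flat_density(self, otg_prior):
        samples = uniform_cmc_samples(seed=2)
        dens = marginal_cmc_density(samples, otg_prior)
        interior = np.linspace(3.0, 27.0, 25)
        vals = dens.evaluate(interior)
        assert np.all(np.abs(vals - 1.0 / 30.0) < 0.15 / 30.0)

    def test_normal_draws_peak_value(self, otg_prior):
        rng = np.random.default_rng(3)
        draws = np.column_stack(
            [np.full(10_000, 0.0718), np.full(10_000, 0.01), np.full(10_000, 1.0), rng.normal(10, 1, 10_000)]
        )
        dens = marginal_cmc_density(make_samples(draws), otg_prior)
        assert dens.evaluate(10.0) == pytest.approx(1 / math.sqrt(2 * math.pi), rel=0.10)

    def test_degenerate_draws_still_normalized(self, otg_prior):
        draws = np.column_stack([np.full(100, 0.0718), np.full(100, 0.01), np.full(100, 1.0), np.full(100, 9.7)])
        dens = marginal_cmc_density(make_samples(draws), otg_prior)
        assert dens.bandwidth == pytest.approx(1e-6 * 30.0)
        mass, _ = integrate.quad(dens.evaluate, 9.69, 9.71, limit=200, points=[9.7])
        assert mass == pytest.approx(1.0, rel=0.01)

    def test_integrates_to_one_over_support(self, otg_fit5, otg_prior):
        dens = marginal_cmc_density(otg_fit5, otg_prior)
        mass, _ = integrate.quad(
            dens.evaluate, *dens.support, limit=200, points=[np.median(dens.centers)]
        )
        assert mass == pytest.approx(1.0, rel=0.01)

    def test_log_space_density(self, triton_prior):
        rng = np.random.default_rng(5)
        n = 5000
        cmc = np.exp(rng.uniform(math.log(0.001), math.log(10.0), n))
        draws = np.column_stack([np.full(n, 0.0718), np.full(n, 0.008), np.full(n, 450.0), cmc])
        dens = marginal_cmc_density(make_samples(draws), triton_prior)
        assert dens.space == "log"
        width = math.log(10.0) - math.log(0.001)
        assert dens.evaluate(math.log(0.1)) == pytest.approx(1.0 / width, rel=0.2)

    def test_silverman_variant(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 2, 4000)
        sd = x.std(ddof=1)
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        expected = 0.9 * min(sd, iqr / 1.34) * 4000 ** (-0.2)
        assert silverman_bandwidth(x, 100.0) == pytest.approx(expected)


class StubDensity(MarginalDensity):
    """Analytic density wrapped in the MarginalDensity interface."""

    def __init__(self, fn, support, centers):
        self.centers = np.asarray(centers, dtype=float)
        self.bandwidth = 1.0
        self.support = support
        self.space = "linear"
        self._fn = fn
        self._norm = 1.0

    def evaluate(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = self._fn(t_arr)
        out[(t_arr < self.support[0]) | (t_arr > self.support[1])] = 0.0
        return out if np.ndim(t) else float(out[0])


class TestDifferentialEntropy:
    def test_exact_uniform(self):
        dens = StubDensity(lambda t: np.full(t.shape, 1 / 30.0), (0.0, 30.0), np.linspace(0, 30, 11))
        assert differential_entropy(dens) == pytest.approx(math.log(30.0), abs=1e-4)

    def test_exact_gaussian(self):
        dens = StubDensity(
            lambda t: np.exp(-0.5 * (t - 10.0) ** 2) / math.sqrt(2 * math.pi),
            (0.0, 30.0),
            np.linspace(5, 15, 11),
        )
        assert differential_entropy(dens) == pytest.approx(0.5 * math.log(2 * math.pi * math.e), abs=1e-3)

    def test_kde_of_gaussian_draws(self, otg_prior):
        rng = np.random.default_rng(9)
        dens = cmc_density_from_draws(rng.normal(10, 1, 10_000), otg_prior, space="linear")
        assert differential_entropy(dens) == pytest.approx(1.4189, abs=0.05)

    def test_kde_of_uniform_draws(self, otg_prior):
        rng = np.random.default_rng(10)
        dens = cmc_density_from_draws(rng.uniform(0, 30, 10_000), otg_prior, space="linear")
        assert differential_entropy(dens) == pytest.approx(math.log(30.0), abs=0.1)


class TestSummaries:
    def test_quantile_interval_integers(self):
        draws = np.column_stack([np.full(100, 0.07), np.full(100, 0.01), np.full(100, 1.0), np.arange(1.0, 101.0)])
        s = make_samples(draws)
        lo, hi = credible_interval(s, "cmc", 0.90)
        assert lo == pytest.approx(5.95)
        assert hi == pytest.approx(95.05)

    def test_small_level_collapses_to_median(self):
        rng = np.random.default_rng(2)
        draws = np.column_stack([np.full(1001, 0.07), np.full(1001, 0.01), np.full(1001, 1.0), rng.uniform(0, 30, 1001)])
        s = make_samples(draws)
        lo, hi = credible_interval(s, "cmc", 1e-9)
        med = np.median(s.cmc)
        assert lo == pytest.approx(med, abs=0.2) and hi == pytest.approx(med, abs=0.2)

    def test_uniform_draw_interval(self):
        s = uniform_cmc_samples(seed=6)
        lo, hi = credible_interval(s, "cmc", 0.90)
        assert lo == pytest.approx(1.5, abs=0.2)
        assert hi == pytest.approx(28.5, abs=0.2)

    def test_bad_level_rejected(self, otg_fit5):
        with pytest.raises(ValueError):
            credible_interval(otg_fit5, "cmc", 1.2)

    def test_mode_of_gaussian_kde(self, otg_prior):
        # 1e5 draws keep the KDE-mode sampling error well inside +-0.1
        rng = np.random.default_rng(4)
        dens = cmc_density_from_draws(rng.normal(10, 1, 100_000), otg_prior, space="linear")
        res = posterior_mode_cmc(dens)
        assert res.cmc == pytest.approx(10.0, abs=0.1)
        assert not res.multimodal

    def test_uniform_density_flagged(self, otg_prior):
        dens = cmc_density_from_draws(np.random.default_rng(5).uniform(0, 30, 10_000), otg_prior, space="linear")
        assert posterior_mode_cmc(dens).multimodal

    def test_two_spikes_global_argmax_and_flag(self, otg_prior):
        draws = np.concatenate([np.full(500, 8.0), np.full(500, 22.0)])
        dens = cmc_density_from_draws(draws, otg_prior, space="linear")
        res = posterior_mode_cmc(dens, n_grid=4096)
        assert res.multimodal
        assert min(abs(res.cmc - 8.0), abs(res.cmc - 22.0)) < 0.1
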