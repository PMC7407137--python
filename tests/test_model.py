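"""Model layer: likelihood contract, sampler behavior, rate summaries."""

import numpy as np
import pytest
from scipy import integrate, stats

from memflux.counting import CrossingCountSeries
from memflux.distributions import halfcauchy_logpdf, negbin_logpmf
from memflux.model import (
    FlowModelParams,
    PosteriorDraws,
    PriorSpec,
    log_likelihood,
    log_prior,
    sample_posterior,
    sample_rho_conditional,
    summarize_rates,
)
from memflux.synthetic import GeneratorConfig, simulate_count_series


def _params(lam, rho=0.5, sigma=0.4, nu=5.0, phi=1.0):
    return FlowModelParams(rho=rho, sigma=sigma, nu=nu, phi=phi, lam=np.asarray(lam))


class TestLogLikelihood:
    def test_sums_negbin_terms(self):
        y = np.array([0, 3, 1])
        lam = np.log([2.0, 2.0, 0.5])
        series = CrossingCountSeries(counts=y, window_ps=10.0)
        expected = float(np.sum(negbin_logpmf(y, np.exp(lam), 5.0)))
        assert log_likelihood(_params(lam, phi=5.0), series) == pytest.approx(expected)

    def test_length_mismatch_raises(self):
        series = CrossingCountSeries(counts=[1, 2, 3], window_ps=10.0)
        with pytest.raises(ValueError):
            log_likelihood(_params([0.0, 0.0]), series)

    def test_phi_prior_change_of_variables(self):
        """E[1/phi | y] is identical whether the 1-D integral is carried out
        in phi (with the Jacobian, as log_prior does) or directly in 1/phi.
        (E[phi] itself is log-divergent under the half-Cauchy-on-1/phi prior,
        so the bounded functional 1/phi is compared, on matched ranges.)"""
        y = np.array([0, 2, 5, 1, 3, 0, 4])
        lam = np.full(len(y), np.log(2.0))
        series = CrossingCountSeries(counts=y, window_ps=10.0)

        def unnorm_phi(phi):
            p = _params(lam, phi=phi)
            # log_prior includes the HalfCauchy on 1/phi plus |d(1/phi)/dphi|
            return np.exp(log_likelihood(p, series) + log_prior(p))

        def unnorm_invphi(ip):
            p = _params(lam, phi=1.0 / ip)
            return np.exp(log_likelihood(p, series) + halfcauchy_logpdf(ip, 5.0))

        lo, hi = 1e-4, 1e4  # phi range; 1/phi covers the same range mirrored
        pts = [0.01, 0.1, 0.5, 1.0, 2.0, 5.0, 20.0, 100.0]
        kw = dict(limit=500, points=pts)
        z1, _ = integrate.quad(unnorm_phi, lo, hi, **kw)
        m1, _ = integrate.quad(lambda f: (1.0 / f) * unnorm_phi(f), lo, hi, **kw)
        z2, _ = integrate.quad(unnorm_invphi, 1.0 / hi, 1.0 / lo, **kw)
        m2, _ = integrate.quad(lambda ip: ip * unnorm_invphi(ip), 1.0 / hi, 1.0 / lo, **kw)
        # lam1/rho/sigma/nu prior factors cancel in the ratios
        assert m1 / z1 == pytest.approx(m2 / z2, rel=1e-4)


class TestSummarizeRates:
    def _degenerate_draws(self, lam_value, n_windows=4, n_draws=50):
        lam = np.full((1, n_draws, n_windows), lam_value, dtype=np.float32)
        scalars = {k: np.full((1, n_draws), 0.5) for k in ("rho", "sigma", "nu", "phi")}
        return PosteriorDraws(scalars=scalars, lam=lam, diagnostics={}, seed=0)

    @pytest.mark.parametrize("rate,flow", [(0.37, 37.0), (0.07, 7.0)])
    def test_counts_per_window_to_molecules_per_ns(self, rate, flow):
        draws = self._degenerate_draws(np.log(rate))
        out = summarize_rates(draws, window_ps=10.0)
        assert np.allclose(out["median"], flow, rtol=1e-5)
        assert out["mean_flow_per_ns"] == pytest.approx(flow, rel=1e-5)

    def test_quantiles_match_direct_sorting(self, rng):
        lam = rng.normal(0.0, 1.0, size=(2, 200, 3)).astype(np.float32)
        scalars = {k: np.zeros((2, 200)) for k in ("rho", "sigma", "nu", "phi")}
        draws = PosteriorDraws(scalars=scalars, lam=lam, diagnostics={}, seed=0)
        out = summarize_rates(draws, window_ps=10.0)
        flows = np.exp(lam.reshape(-1, 3).astype(float)) / 0.01
        assert np.allclose(out["median"], np.quantile(flows, 0.5, axis=0))
        assert np.allclose(out["q2.5"], np.quantile(flows, 0.025, axis=0))


class TestSampler:
    def test_seeded_determinism(self):
        cfg = GeneratorConfig(n_windows=60, rho=0.8, sigma=0.3, nu=6, phi=1.0, seed=4)
        series = simulate_count_series(cfg).series
        kw = dict(n_chains=2, n_draws=50, n_warmup=100, seed=99, rhat_action="ignore")
        a = sample_posterior(series, **kw)
        b = sample_posterior(series, **kw)
        assert np.array_equal(a.scalars["rho"], b.scalars["rho"])
        assert np.array_equal(a.lam, b.lam)

    def test_all_zero_series_infers_low_rate(self):
        series = CrossingCountSeries(counts=np.zeros(100, dtype=int), window_ps=10.0)
        draws = sample_posterior(
            series, n_chains=2, n_draws=300, n_warmup=300, seed=3, rhat_action="warn"
        )
        median_rate = np.median(np.exp(draws.flat_lam().astype(float)), axis=0)
        assert np.all(median_rate < 0.05)

    def test_poisson_data_pushes_inv_phi_to_zero(self):
        cfg = GeneratorConfig(
            n_windows=400, rho=1.0, sigma=0.0, lambda1=np.log(4.0), phi=1e8, nu=5, seed=8
        )
        series = simulate_count_series(cfg).series
        draws = sample_posterior(
            series, n_chains=2, n_draws=300, n_warmup=300, seed=21, rhat_action="warn"
        )
        # posterior mass on 1/phi concentrates near 0 (phi large)
        assert np.median(1.0 / draws.flat("phi")) < 0.05

    def test_single_replicate_recovery(self):
        cfg = GeneratorConfig(
            n_windows=500, rho=0.9, sigma=0.4, nu=5.0, phi=0.6, lambda1=0.5, seed=17
        )
        series = simulate_count_series(cfg).series
        draws = sample_posterior(
            series, n_chains=2, n_draws=400, n_warmup=400, seed=5,
            max_depth=8, rhat_action="warn",
        )
        lo, hi = np.percentile(draws.flat("rho"), [2.5, 97.5])
        assert lo < 0.9 < hi
        assert abs(np.median(draws.flat("rho")) - 0.9) < 0.15
        assert draws.diagnostics["rho"]["rhat"] < 1.1

    def test_diagnostics_reported_for_all_parameters(self):
        cfg = GeneratorConfig(n_windows=60, seed=4)
        series = simulate_count_series(cfg).series
        draws = sample_posterior(
            series, n_chains=2, n_draws=50, n_warmup=100, seed=1, rhat_action="ignore"
        )
        for k in ("rho", "sigma", "nu", "phi"):
            assert set(draws.diagnostics[k]) == {"rhat", "ess_bulk"}
        assert set(draws.diagnostics["lam"]) == {"rhat_max", "ess_bulk_min"}

    def test_nondefault_priors_rejected_for_sampling(self):
        series = CrossingCountSeries(counts=[1, 2, 3], window_ps=10.0)
        with pytest.raises(NotImplementedError):
            sample_posterior(series, priors=PriorSpec(sigma_scale=2.0))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            sample_posterior(CrossingCountSeries(counts=[3], window_ps=10.0))


class TestRhoConditional:
    def test_sampler_matches_quadrature(self):
        """1-D posterior of rho given the true latent path: NUTS mean vs
        direct numerical integration."""
        cfg = GeneratorConfig(
            n_windows=20, rho=0.9, sigma=0.4, nu=5.0, phi=0.6, lambda1=0.5, seed=23
        )
        lam = simulate_count_series(cfg).latent_log_rate
        sigma, nu = 0.4, 5.0

        def unnorm(rho):
            lp = stats.norm.logpdf(rho) + np.sum(
                stats.t.logpdf((lam[1:] - rho * lam[:-1]) / sigma, nu) - np.log(sigma)
            )
            return np.exp(lp)

        z, _ = integrate.quad(unnorm, -3, 3, limit=200)
        m, _ = integrate.quad(lambda r: r * unnorm(r), -3, 3, limit=200)
        quad_mean = m / z

        draws = sample_rho_conditional(lam, sigma, nu, n_draws=2000, n_warmup=500, seed=6)
        assert abs(np.mean(draws) - quad_mean) < 0.05
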