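"""Simulation-based validation studies: parameter recovery and quadrature checks.

These are the package's own calibration experiments: draw count series from
the generative model at known parameters, re-fit with the sampler, and ask
whether the posterior finds the truth. Shared by the test suite and the
acceptance script so both run exactly the same study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .model import sample_posterior, sample_rho_conditional
from .synthetic import GeneratorConfig, simulate_count_series

__all__ = ["RecoveryStudy", "run_recovery_study", "rho_quadrature_check"]

# the bursty regime used for recovery experiments throughout
RECOVERY_TRUTH = {"rho": 0.9, "sigma": 0.4, "nu": 5.0, "phi": 0.6, "lambda1": 0.5}


@dataclass
class RecoveryStudy:
    """Outcome of a multi-replicate parameter-recovery experiment."""

    n_replicates: int
    coverage: dict  # parameter -> replicates whose 95% interval covers truth
    rho_medians: np.ndarray
    intervals: dict  # parameter -> (n_replicates, 2) array of 95% bounds
    truth: dict

    @property
    def joint_coverage(self) -> int:
        """Replicates in which all of (rho, sigma, phi) are covered."""
        per_rep = np.ones(self.n_replicates, dtype=bool)
        for k in ("rho", "sigma", "phi"):
            lo, hi = self.intervals[k][:, 0], self.intervals[k][:, 1]
            per_rep &= (lo <= self.truth[k]) & (self.truth[k] <= hi)
        return int(per_rep.sum())


def run_recovery_study(
    n_replicates: int = 20,
    n_windows: int = 2000,
    n_chains: int = 4,
    n_draws: int = 500,
    n_warmup: int = 500,
    seed: int = 0,
    max_depth: int = 8,
) -> RecoveryStudy:
    """Simulate-and-refit replicates at the bursty reference truth.

    Each replicate draws a fresh series from :data:`RECOVERY_TRUTH`, fits the
    posterior, and records the central 95% interval of (rho, sigma, phi) and
    the posterior median of rho. Replicates run with ``rhat_action="warn"``
    so a transient convergence blip still contributes its intervals rather
    than aborting the study.
    """
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(2 * n_replicates, dtype=np.uint32) % (2**31)
    params = ("rho", "sigma", "phi")
    intervals = {k: np.empty((n_replicates, 2)) for k in params}
    rho_medians = np.empty(n_replicates)
    for rep in range(n_replicates):
        cfg = GeneratorConfig(
            n_windows=n_windows,
            seed=int(rep_seeds[2 * rep]),
            **RECOVERY_TRUTH,
        )
        series = simulate_count_series(cfg).series
        draws = sample_posterior(
            series,
            n_chains=n_chains,
            n_draws=n_draws,
            n_warmup=n_warmup,
            seed=int(rep_seeds[2 * rep + 1]),
            max_depth=max_depth,
            rhat_action="warn",
        )
        for k in params:
            intervals[k][rep] = np.percentile(draws.flat(k), [2.5, 97.5])
        rho_medians[rep] = np.median(draws.flat("rho"))
    coverage = {
        k: int(np.sum((intervals[k][:, 0] <= RECOVERY_TRUTH[k]) & (RECOVERY_TRUTH[k] <= intervals[k][:, 1])))
        for k in params
    }
    return RecoveryStudy(
        n_replicates=n_replicates,
        coverage=coverage,
        rho_medians=rho_medians,
        intervals=intervals,
        truth={k: RECOVERY_TRUTH[k] for k in params},
    )


def rho_quadrature_check(
    n_windows: int = 20, seed: int = 23, n_draws: int = 2000, n_warmup: int = 500
) -> dict:
    """Sampler-versus-quadrature cross-check on the 1-D conditional for rho.

    Generates a short latent path at the reference truth, holds everything
    but rho fixed, and compares the NUTS posterior mean of rho with direct
    numerical integration of prior x transition densities.
    """
    cfg = GeneratorConfig(n_windows=n_windows, seed=seed, **RECOVERY_TRUTH)
    lam = simulate_count_series(cfg).latent_log_rate
    sigma, nu = RECOVERY_TRUTH["sigma"], RECOVERY_TRUTH["nu"]

    def unnorm(rho):
        lp = stats.norm.logpdf(rho) + np.sum(
            stats.t.logpdf((lam[1:] - rho * lam[:-1]) / sigma, nu) - np.log(sigma)
        )
        return np.exp(lp)

    z, _ = integrate.quad(unnorm, -3, 3, limit=200)
    m, _ = integrate.quad(lambda r: r * unnorm(r), -3, 3, limit=200)
    quad_mean = m / z
    draws = sample_rho_conditional(
        lam, sigma, nu, n_draws=n_draws, n_warmup=n_warmup, seed=seed + 1
    )
    return {
        "quadrature_mean": float(quad_mean),
        "sampler_mean": float(np.mean(draws)),
        "abs_difference": float(abs(np.mean(draws) - quad_mean)),
    }
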