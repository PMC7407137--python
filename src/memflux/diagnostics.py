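"""Burstiness diagnostics: marginal counts versus a matched Poisson.

A bursty event process shows per-window counts whose marginal distribution is
heavier-tailed than a Poisson with the same expectation. The comparison here
matches a Poisson to the observed sample mean and reports a dispersion index
(variance/mean) and a tail-mass ratio: the observed probability of exceeding
the Poisson's upper-tail threshold divided by the Poisson's own tail mass.
A ratio above 1 is the quantitative form of "heavier-tailed than Poisson".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .counting import CrossingCountSeries

__all__ = ["MarginalComparison", "compare_to_poisson", "plot_marginal_comparison"]


@dataclass
class MarginalComparison:
    """Observed count histogram against the mean-matched Poisson."""

    observed_histogram: dict  # count -> frequency
    poisson_pmf: np.ndarray  # pmf over 0..support_max at the matched mean
    matched_mean: float
    dispersion_index: float
    tail_threshold: Optional[int]  # k*; None when undefined (all-zero series)
    tail_mass_ratio: Optional[float]
    observed_tail_mass: Optional[float]
    poisson_tail_mass: Optional[float]
    poisson_sf: np.ndarray  # survival function P(Y >= k) over the same support
    n_windows: int
    degenerate: bool = False  # all-zero input; ratio undefined by convention

    def to_dict(self) -> dict:
        return {
            "matched_mean": self.matched_mean,
            "dispersion_index": self.dispersion_index,
            "tail_threshold": self.tail_threshold,
            "tail_mass_ratio": self.tail_mass_ratio,
            "observed_tail_mass": self.observed_tail_mass,
            "poisson_tail_mass": self.poisson_tail_mass,
            "n_windows": self.n_windows,
            "degenerate": self.degenerate,
            "observed_histogram": {int(k): int(v) for k, v in self.observed_histogram.items()},
            "poisson_pmf": [float(p) for p in self.poisson_pmf],
            "poisson_sf": [float(p) for p in self.poisson_sf],
        }


def compare_to_poisson(
    counts: CrossingCountSeries, tail_threshold_quantile: float = 0.99
) -> MarginalComparison:
    """Compare the marginal count distribution to a mean-matched Poisson.

    The tail threshold k* is the smallest k with Poisson
    P(Y >= k) <= 1 - tail_threshold_quantile at the matched mean; the
    tail-mass ratio is empirical P(Y >= k*) divided by Poisson P(Y >= k*).

    An all-zero series has dispersion index 1 by convention and an undefined
    tail ratio, flagged via ``degenerate``.
    """
    y = counts.counts
    if len(y) == 0:
        raise ValueError("empty count series")
    if not 0 < tail_threshold_quantile < 1:
        raise ValueError("tail_threshold_quantile must be in (0, 1)")
    n = len(y)
    mean = float(np.mean(y))
    values, freqs = np.unique(y, return_counts=True)
    hist = dict(zip(values.tolist(), freqs.tolist()))

    if mean == 0.0:
        return MarginalComparison(
            observed_histogram=hist,
            poisson_pmf=np.array([1.0]),
            matched_mean=0.0,
            dispersion_index=1.0,
            tail_threshold=None,
            tail_mass_ratio=None,
            observed_tail_mass=None,
            poisson_tail_mass=None,
            poisson_sf=np.array([1.0]),
            n_windows=n,
            degenerate=True,
        )

    var = float(np.var(y, ddof=1)) if n > 1 else 0.0
    dispersion = var / mean

    support_max = int(max(y.max(), stats.poisson.ppf(1 - 1e-12, mean))) + 1
    k = np.arange(support_max + 1)
    pmf = stats.poisson.pmf(k, mean)
    sf = stats.poisson.sf(k - 1, mean)  # P(Y >= k)

    alpha = 1.0 - tail_threshold_quantile
    k_star = int(np.argmax(sf <= alpha))  # smallest k with P(Y >= k) <= alpha
    poisson_tail = float(sf[k_star])
    observed_tail = float(np.mean(y >= k_star))
    ratio = observed_tail / poisson_tail

    return MarginalComparison(
        observed_histogram=hist,
        poisson_pmf=pmf,
        matched_mean=mean,
        dispersion_index=dispersion,
        tail_threshold=k_star,
        tail_mass_ratio=ratio,
        observed_tail_mass=observed_tail,
        poisson_tail_mass=poisson_tail,
        poisson_sf=sf,
        n_windows=n,
    )


def plot_marginal_comparison(comparison: MarginalComparison, path) -> None:
    """Histogram of observed counts with the matched-Poisson pmf overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ks = sorted(comparison.observed_histogram)
    freqs = np.array([comparison.observed_histogram[k] for k in ks], dtype=float)
    ax.bar(ks, freqs / comparison.n_windows, width=0.8, alpha=0.6, label="observed")
    support = np.arange(len(comparison.poisson_pmf))
    ax.plot(support, comparison.poisson_pmf, "k-", lw=1.5, label="Poisson, same mean")
    ax.set_yscale("log")
    ax.set_xlabel("transitions per window")
    ax.set_ylabel("probability")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_rate_function(summary: dict, path, times_ns=None) -> None:
    """Posterior median flow with the 95% band, as a function of time."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    med = np.asarray(summary["median"])
    lo = np.asarray(summary["q2.5"])
    hi = np.asarray(summary["q97.5"])
    if times_ns is None:
        times_ns = np.arange(len(med)) * summary["window_ps"] / 1000.0
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.fill_between(times_ns, lo, hi, alpha=0.3, lw=0)
    ax.plot(times_ns, med, lw=1.0)
    ax.set_xlabel("time (ns)")
    ax.set_ylabel("water flow (molecules/ns)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
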