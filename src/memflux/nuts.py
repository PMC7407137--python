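"""A No-U-Turn sampler (NUTS) with dual-averaging step-size adaptation.

Multinomial NUTS over a user-supplied log-density-and-gradient callable, with
a diagonal mass matrix adapted over Stan-style expanding warmup windows and
step size tuned by Nesterov dual averaging to a target acceptance statistic.
Trajectories double until the generalized U-turn criterion triggers or the
maximum tree depth is reached; sub-trees with an energy error above 1000 are
flagged divergent and rejected.

Deterministic given (seed, initial point, data): all randomness flows through
one ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

__all__ = ["NutsResult", "nuts_sample"]

_MAX_DEPTH = 10
_DIVERGENCE = 1000.0


@dataclass
class NutsResult:
    """Draws and per-iteration sampler statistics from one chain."""

    draws: np.ndarray  # (n_draws, dim)
    logp: np.ndarray
    step_size: float
    mass_inv: np.ndarray
    n_divergent: int
    accept_stat: np.ndarray
    tree_depth: np.ndarray


class _Tree:
    __slots__ = (
        "theta_minus", "p_minus", "grad_minus",
        "theta_plus", "p_plus", "grad_plus",
        "theta_prop", "logp_prop", "grad_prop",
        "log_weight", "ok", "divergent", "alpha", "n_alpha",
    )


def _leapfrog(logp_grad, theta, p, grad, eps, mass_inv):
    p = p + 0.5 * eps * grad
    theta = theta + eps * mass_inv * p
    logp, grad = logp_grad(theta)
    p = p + 0.5 * eps * grad
    return theta, p, logp, grad


def _kinetic(p, mass_inv):
    return 0.5 * float(np.dot(p * mass_inv, p))


def _no_uturn(theta_minus, theta_plus, p_minus, p_plus, mass_inv):
    d = theta_plus - theta_minus
    return (np.dot(d, mass_inv * p_minus) >= 0) and (np.dot(d, mass_inv * p_plus) >= 0)


def _build_tree(logp_grad, theta, p, grad, direction, depth, eps, h0, mass_inv, rng):
    if depth == 0:
        theta1, p1, logp1, grad1 = _leapfrog(
            logp_grad, theta, p, grad, direction * eps, mass_inv
        )
        h1 = -logp1 + _kinetic(p1, mass_inv)
        energy_err = h1 - h0
        t = _Tree()
        t.theta_minus = t.theta_plus = t.theta_prop = theta1
        t.p_minus = t.p_plus = p1
        t.grad_minus = t.grad_plus = t.grad_prop = grad1
        t.logp_prop = logp1
        t.log_weight = -energy_err if np.isfinite(energy_err) else -np.inf
        t.ok = energy_err <= _DIVERGENCE and np.isfinite(energy_err)
        t.divergent = not t.ok
        t.alpha = min(1.0, float(np.exp(min(0.0, -energy_err)))) if np.isfinite(energy_err) else 0.0
        t.n_alpha = 1
        return t

    first = _build_tree(logp_grad, theta, p, grad, direction, depth - 1, eps, h0, mass_inv, rng)
    if not first.ok:
        return first
    if direction == 1:
        second = _build_tree(
            logp_grad, first.theta_plus, first.p_plus, first.grad_plus,
            direction, depth - 1, eps, h0, mass_inv, rng,
        )
        first.theta_plus = second.theta_plus
        first.p_plus = second.p_plus
        first.grad_plus = second.grad_plus
    else:
        second = _build_tree(
            logp_grad, first.theta_minus, first.p_minus, first.grad_minus,
            direction, depth - 1, eps, h0, mass_inv, rng,
        )
        first.theta_minus = second.theta_minus
        first.p_minus = second.p_minus
        first.grad_minus = second.grad_minus

    first.alpha += second.alpha
    first.n_alpha += second.n_alpha
    if not second.ok:
        first.ok = False
        first.divergent = first.divergent or second.divergent
        return first
    first.divergent = first.divergent or second.divergent

    total = np.logaddexp(first.log_weight, second.log_weight)
    # multinomial sampling among the subtrees
    if np.log(rng.random()) < second.log_weight - total:
        first.theta_prop = second.theta_prop
        first.logp_prop = second.logp_prop
        first.grad_prop = second.grad_prop
    first.log_weight = total
    first.ok = _no_uturn(
        first.theta_minus, first.theta_plus, first.p_minus, first.p_plus, mass_inv
    )
    return first


def _find_initial_step(logp_grad, theta, logp, grad, mass_inv, rng):
    eps = 1.0
    p = rng.standard_normal(theta.shape[0]) / np.sqrt(mass_inv)
    h0 = -logp + _kinetic(p, mass_inv)
    _, p1, logp1, _ = _leapfrog(logp_grad, theta, p, grad, eps, mass_inv)
    h1 = -logp1 + _kinetic(p1, mass_inv)
    if not np.isfinite(h1):
        delta = -np.inf
    else:
        delta = h0 - h1
    direction = 1.0 if delta > np.log(0.8) else -1.0
    for _ in range(100):
        eps *= 2.0 ** direction
        _, p1, logp1, _ = _leapfrog(logp_grad, theta, p, grad, eps, mass_inv)
        h1 = -logp1 + _kinetic(p1, mass_inv)
        delta = h0 - h1 if np.isfinite(h1) else -np.inf
        if (direction > 0) != (delta > np.log(0.8)):
            break
    return eps


def _adaptation_windows(n_warmup: int):
    """Stan-style (init buffer, doubling metric windows, terminal buffer)."""
    if n_warmup >= 150:
        init_buf, term_buf, base = 75, 50, 25
    else:
        init_buf = max(1, int(0.15 * n_warmup))
        term_buf = max(1, int(0.10 * n_warmup))
        base = max(1, n_warmup - init_buf - term_buf)
    ends = []
    start = init_buf
    w = base
    while start + w < n_warmup - term_buf:
        # last window absorbs the remainder if doubling would overrun
        if start + w + 2 * w >= n_warmup - term_buf:
            w = n_warmup - term_buf - start
        ends.append(start + w)
        start += w
        w *= 2
    if not ends and n_warmup - term_buf > init_buf:
        ends.append(n_warmup - term_buf)
    return init_buf, ends, term_buf


def nuts_sample(
    logp_grad: Callable[[np.ndarray], tuple],
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    max_depth: int = _MAX_DEPTH,
) -> NutsResult:
    """Run one NUTS chain.

    Parameters
    ----------
    logp_grad : callable returning (log density, gradient) at a point
    theta0 : initial position
    n_warmup, n_draws : warmup (adaptation) and retained iterations
    rng : the chain's random generator (sole source of randomness)
    target_accept : dual-averaging target for the mean acceptance statistic
    """
    theta = np.array(theta0, dtype=float)
    dim = theta.shape[0]
    logp, grad = logp_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    mass_inv = np.ones(dim)
    eps = _find_initial_step(logp_grad, theta, logp, grad, mass_inv, rng)

    # dual averaging state
    mu = np.log(10.0 * eps)
    log_eps_bar = 0.0
    h_bar = 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    init_buf, window_ends, term_buf = _adaptation_windows(n_warmup)
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    accept_stat = np.empty(n_draws)
    tree_depth = np.empty(n_draws, dtype=np.int64)
    n_divergent = 0

    total_iter = n_warmup + n_draws
    for it in range(total_iter):
        in_warmup = it < n_warmup
        p0 = rng.standard_normal(dim) / np.sqrt(mass_inv)
        h0 = -logp + _kinetic(p0, mass_inv)

        t = _Tree()
        t.theta_minus = t.theta_plus = theta
        t.p_minus = t.p_plus = p0
        t.grad_minus = t.grad_plus = grad
        t.theta_prop = theta
        t.logp_prop = logp
        t.grad_prop = grad
        t.log_weight = 0.0
        alpha_sum, n_alpha = 0.0, 0
        depth = 0
        divergent = False
        while depth < max_depth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == 1:
                sub = _build_tree(
                    logp_grad, t.theta_plus, t.p_plus, t.grad_plus,
                    1, depth, eps, h0, mass_inv, rng,
                )
                t.theta_plus = sub.theta_plus
                t.p_plus = sub.p_plus
                t.grad_plus = sub.grad_plus
            else:
                sub = _build_tree(
                    logp_grad, t.theta_minus, t.p_minus, t.grad_minus,
                    -1, depth, eps, h0, mass_inv, rng,
                )
                t.theta_minus = sub.theta_minus
                t.p_minus = sub.p_minus
                t.grad_minus = sub.grad_minus
            alpha_sum += sub.alpha
            n_alpha += sub.n_alpha
            if not sub.ok:
                divergent = divergent or sub.divergent
                break
            # biased progressive sampling toward the new subtree
            if np.log(rng.random()) < sub.log_weight - t.log_weight:
                t.theta_prop = sub.theta_prop
                t.logp_prop = sub.logp_prop
                t.grad_prop = sub.grad_prop
            t.log_weight = np.logaddexp(t.log_weight, sub.log_weight)
            depth += 1
            if not _no_uturn(t.theta_minus, t.theta_plus, t.p_minus, t.p_plus, mass_inv):
                break

        theta, logp, grad = t.theta_prop, t.logp_prop, t.grad_prop
        mean_alpha = alpha_sum / max(n_alpha, 1)

        if in_warmup:
            # dual averaging
            da_count += 1
            frac = 1.0 / (da_count + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - mean_alpha)
            log_eps = mu - np.sqrt(da_count) / gamma * h_bar
            w = da_count ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = float(np.exp(log_eps))

            in_metric_window = init_buf <= it < (n_warmup - term_buf)
            if in_metric_window:
                welford_n += 1
                delta = theta - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (theta - welford_mean)
                if window_ends and it + 1 == window_ends[0]:
                    window_ends.pop(0)
                    if welford_n >= 3:
                        var = welford_m2 / (welford_n - 1)
                        mass_inv = (
                            welford_n / (welford_n + 5.0) * var
                            + 1e-3 * (5.0 / (welford_n + 5.0))
                        )
                    welford_n = 0
                    welford_mean[:] = 0.0
                    welford_m2[:] = 0.0
                    # restart step-size adaptation around the current eps
                    eps = _find_initial_step(logp_grad, theta, logp, grad, mass_inv, rng)
                    mu = np.log(10.0 * eps)
                    h_bar = 0.0
                    log_eps_bar = 0.0
                    da_count = 0
        else:
            j = it - n_warmup
            draws[j] = theta
            logps[j] = logp
            accept_stat[j] = mean_alpha
            tree_depth[j] = depth
            if divergent:
                n_divergent += 1

        if in_warmup and it == n_warmup - 1:
            eps = float(np.exp(log_eps_bar)) if da_count > 0 else eps

    return NutsResult(
        draws=draws,
        logp=logps,
        step_size=eps,
        mass_inv=mass_inv,
        n_divergent=n_divergent,
        accept_stat=accept_stat,
        tree_depth=tree_depth,
    )
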