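"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators live here:

* :func:`simulate_count_series` — forward simulation of the count model: a
  latent log-rate following a Student-t autoregression,
  ``lam_i = rho * lam_{i-1} + sigma * t_nu``, observed through a
  negative-binomial with mean ``exp(lam_i)`` and overdispersion ``phi``
  (Var = mu + mu^2/phi). This is the generative counterpart of the inference
  model, so parameter recovery can be tested against known truth.

* :func:`simulate_membrane_trajectory` — kinematic water trajectories over a
  membrane slab with a known crossing schedule, so the transition counter can
  be tested against exact ground truth. These are fixtures, not physics: each
  scheduled event produces exactly one complete slab traversal and no
  unscheduled traversal ever occurs.

Defaults mirror the MD sampling the analysis targets: 10 ps observation
windows, one saved frame per window (100 ns -> 10,001 frames -> 10,000
windows).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .counting import CrossingCountSeries, MembraneSlab, TrajectorySlice

__all__ = [
    "GeneratorConfig",
    "CrossingSchedule",
    "SimulatedCounts",
    "simulate_count_series",
    "simulate_membrane_trajectory",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the bursty count generator.

    Defaults are the regime used throughout testing: strong autocorrelation,
    moderately heavy-tailed innovations and strong overdispersion — the
    "bursty" character the model exists to capture.

    Parameters
    ----------
    n_windows : number of observation windows (>= 2)
    window_ps : window duration in ps (default 10)
    rho : latent autocorrelation (dimensionless)
    sigma : innovation scale on the log-rate scale (>= 0; 0 freezes the rate)
    nu : Student-t degrees of freedom (> 0; nu <= 2 has infinite innovation
        variance — permitted, the prior supports it, but expect wild paths)
    phi : negative-binomial overdispersion (> 0; large phi -> Poisson limit)
    lambda1 : initial log rate, log counts/window
    seed : RNG seed; identical config + seed reproduces output bit-for-bit
    """

    n_windows: int = 10_000
    window_ps: float = 10.0
    rho: float = 0.9
    sigma: float = 0.5
    nu: float = 4.0
    phi: float = 0.5
    lambda1: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("n_windows", self.n_windows >= 2),
            ("window_ps", self.window_ps > 0),
            ("sigma", self.sigma >= 0),
            ("nu", self.nu > 0),
            ("phi", self.phi > 0),
            ("lambda1", np.isfinite(self.lambda1)),
            ("rho", np.isfinite(self.rho)),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid GeneratorConfig field: {name}={getattr(self, name)}")


@dataclass
class SimulatedCounts:
    """A simulated count series plus its latent ground truth."""

    series: CrossingCountSeries
    latent_log_rate: np.ndarray
    config: GeneratorConfig


def simulate_count_series(config: GeneratorConfig) -> SimulatedCounts:
    """Draw a count series from the latent-rate / negative-binomial model.

    The latent recursion is ``lam_1 = config.lambda1`` and, for i >= 2,
    ``lam_i = rho * lam_{i-1} + sigma * e_i`` with ``e_i`` standard Student-t
    with ``nu`` degrees of freedom. Observations are
    ``Y_i ~ NegBin(mean = exp(lam_i), overdispersion = phi)``, drawn as a
    gamma-Poisson mixture so that Var(Y) = mu + mu^2/phi. The Poisson limit is
    reached by a large finite phi — no separate code path.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_windows
    lam = np.empty(n)
    lam[0] = config.lambda1
    if config.sigma > 0:
        innov = config.sigma * rng.standard_t(config.nu, size=n - 1)
    else:
        innov = np.zeros(n - 1)
    for i in range(1, n):
        lam[i] = config.rho * lam[i - 1] + innov[i - 1]
    mu = np.exp(lam)
    # NegBin(mu, phi) as Poisson mixed over Gamma(shape=phi, mean=mu)
    rates = rng.gamma(shape=config.phi, scale=mu / config.phi)
    counts = rng.poisson(rates)
    series = CrossingCountSeries(counts=counts, window_ps=config.window_ps)
    return SimulatedCounts(series=series, latent_log_rate=lam, config=config)


@dataclass(frozen=True)
class CrossingSchedule:
    """Ground-truth crossing events for trajectory fixtures.

    ``events`` holds (molecule_id, frame_index, direction) triples with
    direction "down" (above -> below) or "up". Per molecule, events must be
    strictly increasing in frame index and alternate in direction (a molecule
    that went down can only come back up).
    """

    events: tuple
    n_molecules: int
    n_frames: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(tuple(e) for e in self.events))
        if self.n_molecules < 1 or self.n_frames < 2:
            raise ValueError("need n_molecules >= 1 and n_frames >= 2")
        per_mol: dict = {}
        for mol, frame, direction in self.events:
            if direction not in ("down", "up"):
                raise ValueError(f"bad direction {direction!r}")
            if not (0 <= mol < self.n_molecules):
                raise ValueError(f"molecule id {mol} out of range")
            if not (1 <= frame <= self.n_frames - 1):
                raise ValueError(f"event frame {frame} outside [1, n_frames-1]")
            per_mol.setdefault(mol, []).append((frame, direction))
        for mol, evs in per_mol.items():
            frames = [f for f, _ in evs]
            if sorted(frames) != frames or len(set(frames)) != len(frames):
                raise ValueError(f"events for molecule {mol} not strictly increasing")
            for (_, d1), (_, d2) in zip(evs, evs[1:]):
                if d1 == d2:
                    raise ValueError(f"events for molecule {mol} do not alternate direction")
            # traversals occupy frames (f-1, f); consecutive events must not overlap
            for (f1, _), (f2, _) in zip(evs, evs[1:]):
                if f2 - f1 < 2:
                    raise ValueError(
                        f"events for molecule {mol} too close (frames {f1}, {f2})"
                    )

    def events_by_molecule(self) -> dict:
        out: dict = {m: [] for m in range(self.n_molecules)}
        for mol, frame, direction in self.events:
            out[mol].append((frame, direction))
        return out

    @property
    def n_events(self) -> int:
        return len(self.events)


def simulate_membrane_trajectory(
    schedule: CrossingSchedule,
    slab: MembraneSlab,
    seed: int = 0,
    frame_interval_ps: float = 10.0,
    box_z: Optional[float] = None,
    pbc_wraps: Sequence[tuple[int, int]] = (),
) -> TrajectorySlice:
    """Generate z-trajectories realizing a crossing schedule exactly.

    Molecules dwell in a bulk band on one side of the slab, jittering but
    never entering it, except at scheduled events: a traversal occupies two
    frames — the molecule sits inside the slab at frame f-1 and emerges on
    the far side at frame f (the completing frame, which is what the counter
    windows on).

    ``pbc_wraps`` lists (molecule_id, frame) pairs at which a periodic-image
    wrap is injected: the molecule teleports across the box (|dz| > box_z/2)
    to the bulk band on the other side. Requires ``box_z``. Wraps are not
    crossings and a correct counter must not count them.
    """
    if pbc_wraps and box_z is None:
        raise ValueError("pbc_wraps requires box_z")
    slab_width = slab.z_upper - slab.z_lower
    margin = max(1.0, 0.05 * slab_width)
    band = max(5.0, slab_width / 4)
    if box_z is not None:
        # bands must fit in the box with headroom so ordinary motion (band
        # jitter, traversals via the slab midpoint) never exceeds box_z/2
        top_limit = box_z / 2.0 - 1.0
        if slab.z_upper + margin + band > top_limit or slab.z_lower - margin - band < -top_limit:
            raise ValueError("box_z too small for slab plus bulk bands")

    rng = np.random.default_rng(seed)
    n_frames, n_mol = schedule.n_frames, schedule.n_molecules
    z = np.empty((n_frames, n_mol))
    events = schedule.events_by_molecule()
    wraps_by_mol: dict = {}
    for mol, frame in pbc_wraps:
        if not (1 <= frame <= n_frames - 1):
            raise ValueError(f"wrap frame {frame} outside [1, n_frames-1]")
        wraps_by_mol.setdefault(mol, []).append(frame)

    def band_positions(side: int, n: int) -> np.ndarray:
        # uniform jitter within the bulk band, strictly off the slab
        lo = slab.z_upper + margin if side > 0 else slab.z_lower - margin - band
        return lo + band * rng.random(n)

    for mol in range(n_mol):
        evs = events[mol]
        wraps = sorted(wraps_by_mol.get(mol, []))
        for wf in wraps:
            for f, _ in evs:
                if abs(wf - f) <= 1:
                    raise ValueError(f"wrap at frame {wf} collides with event for molecule {mol}")
        # starting side: opposite of first event's destination; else random
        if evs:
            side = 1 if evs[0][1] == "down" else -1
        else:
            side = 1 if rng.random() < 0.5 else -1
        col = band_positions(side, n_frames)
        # carve traversals
        for f, direction in evs:
            new_side = -1 if direction == "down" else 1
            mid = 0.5 * (slab.z_lower + slab.z_upper)
            col[f - 1] = mid + 0.2 * slab_width * (rng.random() - 0.5)
            tail = n_frames - f
            col[f:] = band_positions(new_side, tail)
            side = new_side
        # inject wraps after events so they overwrite the dwell segment;
        # the jump spans nearly the whole box so |dz| > box_z/2 holds
        for wf in wraps:
            cur_side = 1 if col[wf - 1] > slab.z_upper else -1
            edge = box_z / 2.0 - 0.5
            col[wf - 1] = cur_side * edge
            col[wf] = -cur_side * edge
            if wf + 1 < n_frames:
                col[wf + 1 :] = band_positions(-cur_side, n_frames - wf - 1)
        z[:, mol] = col

    times = frame_interval_ps * np.arange(n_frames)
    return TrajectorySlice(
        frames=np.arange(n_frames),
        times_ps=times,
        z=z,
        molecule_ids=list(range(n_mol)),
        box_z=box_z,
    )
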