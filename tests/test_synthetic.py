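"""Generator behavior: known limits, determinism, schedule validation."""

import numpy as np
import pytest

from memflux.counting import MembraneSlab, count_crossings
from memflux.synthetic import (
    CrossingSchedule,
    GeneratorConfig,
    simulate_count_series,
    simulate_membrane_trajectory,
)


class TestCountGenerator:
    def test_seed_determinism(self):
        cfg = GeneratorConfig(n_windows=500, seed=13)
        a = simulate_count_series(cfg)
        b = simulate_count_series(cfg)
        assert np.array_equal(a.series.counts, b.series.counts)
        assert np.array_equal(a.latent_log_rate, b.latent_log_rate)

    def test_poisson_limit_constant_rate(self):
        # sigma=0, rho=1 freezes lam at log 5; phi huge -> Poisson(5)
        cfg = GeneratorConfig(
            n_windows=10_000, rho=1.0, sigma=0.0, lambda1=np.log(5.0), phi=1e8, nu=4, seed=1
        )
        y = simulate_count_series(cfg).series.counts
        n = len(y)
        mean, var = y.mean(), y.var(ddof=1)
        se_mean = np.sqrt(5.0 / n)
        # Var(s^2) for Poisson(lam): (lam + 2*lam^2)/n to leading order
        se_var = np.sqrt((5.0 + 2 * 25.0) / n)
        assert abs(mean - 5.0) < 3 * se_mean
        assert abs(var - 5.0) < 3 * se_var

    def test_negbin_dispersion_index(self):
        # constant mu=0.4, phi=0.5 -> Var/mean = 1 + mu/phi = 1.8
        cfg = GeneratorConfig(
            n_windows=200_000, rho=1.0, sigma=0.0, lambda1=np.log(0.4), phi=0.5, nu=4, seed=2
        )
        y = simulate_count_series(cfg).series.counts
        d = y.var(ddof=1) / y.mean()
        # block-wise standard error of the dispersion index
        blocks = np.array_split(y, 20)
        bd = [b.var(ddof=1) / b.mean() for b in blocks]
        se = np.std(bd, ddof=1) / np.sqrt(len(bd))
        assert abs(d - 1.8) < 3 * se

    def test_latent_recursion_is_autoregressive(self):
        cfg = GeneratorConfig(n_windows=2000, rho=0.7, sigma=0.3, nu=30, seed=5)
        lam = simulate_count_series(cfg).latent_log_rate
        resid = lam[1:] - 0.7 * lam[:-1]
        # innovations should be mean ~0 scale ~0.3 (nu=30, near-normal)
        assert abs(np.mean(resid)) < 0.05
        assert np.std(resid) == pytest.approx(0.3, rel=0.15)

    @pytest.mark.parametrize(
        "bad", [{"n_windows": 1}, {"sigma": -0.1}, {"nu": 0.0}, {"phi": 0.0}, {"window_ps": 0.0}]
    )
    def test_invalid_config_names_field(self, bad):
        with pytest.raises(ValueError) as err:
            GeneratorConfig(**bad)
        assert list(bad)[0] in str(err.value)


class TestSchedule:
    def test_rejects_out_of_range_frames(self):
        with pytest.raises(ValueError):
            CrossingSchedule(events=[(0, 0, "down")], n_molecules=1, n_frames=10)
        with pytest.raises(ValueError):
            CrossingSchedule(events=[(0, 10, "down")], n_molecules=1, n_frames=10)

    def test_rejects_non_alternating_directions(self):
        with pytest.raises(ValueError):
            CrossingSchedule(
                events=[(0, 3, "down"), (0, 6, "down")], n_molecules=1, n_frames=10
            )

    def test_rejects_non_increasing_frames(self):
        with pytest.raises(ValueError):
            CrossingSchedule(
                events=[(0, 6, "down"), (0, 3, "up")], n_molecules=1, n_frames=10
            )


class TestTrajectoryGenerator:
    def test_empty_schedule_counts_zero(self, slab):
        sched = CrossingSchedule(events=[], n_molecules=50, n_frames=100)
        traj = simulate_membrane_trajectory(sched, slab, seed=0)
        series = count_crossings(traj, slab, window_ps=10.0)
        assert series.total == 0

    def test_scheduled_events_are_reproduced_exactly(self, slab):
        events = [
            (0, 40, "down"), (0, 200, "up"), (1, 77, "up"),
            (2, 300, "down"), (3, 123, "down"), (3, 400, "up"), (4, 499, "down"),
        ]
        sched = CrossingSchedule(events=events, n_molecules=10, n_frames=500)
        traj = simulate_membrane_trajectory(sched, slab, seed=3)
        series = count_crossings(traj, slab, window_ps=10.0)
        assert series.total == 7
        assert series.direction_totals == (4, 3)

    def test_pbc_wrap_is_not_a_crossing(self, slab):
        sched = CrossingSchedule(events=[], n_molecules=5, n_frames=100)
        traj = simulate_membrane_trajectory(
            sched, slab, seed=1, box_z=80.0, pbc_wraps=[(2, 50)]
        )
        # the wrap really is a near-box-height jump
        assert np.max(np.abs(np.diff(traj.z[:, 2]))) > 40.0
        series = count_crossings(traj, slab, window_ps=10.0)
        assert series.total == 0

    def test_seed_determinism(self, slab):
        sched = CrossingSchedule(events=[(0, 10, "up")], n_molecules=3, n_frames=50)
        a = simulate_membrane_trajectory(sched, slab, seed=9)
        b = simulate_membrane_trajectory(sched, slab, seed=9)
        assert np.array_equal(a.z, b.z)

    def test_wrap_requires_box(self, slab):
        sched = CrossingSchedule(events=[], n_molecules=2, n_frames=20)
        with pytest.raises(ValueError):
            simulate_membrane_trajectory(sched, slab, seed=0, pbc_wraps=[(0, 5)])
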