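"""Crossing counter: canonical cases, properties, and the brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memflux.counting import (
    CrossingCountSeries,
    MembraneSlab,
    TrajectorySlice,
    count_crossings,
    infer_slab,
)
from memflux.synthetic import CrossingSchedule, simulate_membrane_trajectory

from conftest import brute_force_crossings


def _traj(z_cols, dt=10.0, box_z=None):
    z = np.asarray(z_cols, dtype=float).T
    nf = z.shape[0]
    return TrajectorySlice(
        frames=np.arange(nf),
        times_ps=dt * np.arange(nf),
        z=z,
        molecule_ids=list(range(z.shape[1])),
        box_z=box_z,
    )


class TestStateMachine:
    def test_single_traversal_counted_in_completing_window(self, slab):
        traj = _traj([[25.0, 10.0, -25.0]])
        series = count_crossings(traj, slab, window_ps=10.0)
        assert series.counts.tolist() == [0, 1]
        assert series.direction_totals == (1, 0)

    def test_reentry_records_nothing(self, slab):
        traj = _traj([[25.0, 10.0, 25.0, 10.0, 25.0]])
        series = count_crossings(traj, slab, window_ps=10.0)
        assert series.total == 0

    def test_boundary_coordinate_is_inside(self, slab):
        # sitting exactly on the planes never yields a definite side
        traj = _traj([[18.0, -18.0, 18.0]])
        assert count_crossings(traj, slab, window_ps=10.0).total == 0

    def test_multiwindow_slow_traversal(self, slab):
        # enters the slab, lingers, exits below: one crossing at the exit frame
        traj = _traj([[25.0, 10.0, 3.0, -5.0, -25.0, -26.0]])
        series = count_crossings(traj, slab, window_ps=10.0)
        assert series.counts.tolist() == [0, 0, 0, 1, 0]

    def test_molecule_starting_inside_counts_on_first_full_exit_only(self, slab):
        # no definite origin side: first exit fixes the side, no count
        traj = _traj([[0.0, -25.0, -26.0, -25.0]])
        assert count_crossings(traj, slab, window_ps=10.0).total == 0

    def test_incommensurate_window_rejected(self, slab):
        traj = _traj([[25.0, 10.0, -25.0]])
        with pytest.raises(ValueError):
            count_crossings(traj, slab, window_ps=15.0)

    def test_wrap_resets_without_counting(self, slab):
        traj = _traj([[30.0, 38.0, -38.0, -30.0]], box_z=80.0)
        series = count_crossings(traj, slab, window_ps=10.0)
        assert series.total == 0


class TestAgainstOracle:
    def test_fixture_with_wraps_matches_schedule_and_oracle(self, slab):
        rng = np.random.default_rng(77)
        events = []
        frame_pool = rng.choice(np.arange(2, 498), size=13, replace=False)
        for mol, f in enumerate(sorted(frame_pool.tolist())):
            events.append((mol, f, "down" if mol % 2 else "up"))
        sched = CrossingSchedule(events=events, n_molecules=200, n_frames=500)
        traj = simulate_membrane_trajectory(
            sched, slab, seed=5, box_z=80.0, pbc_wraps=[(150, 100), (151, 400)]
        )
        series = count_crossings(traj, slab, window_ps=10.0)
        assert series.total == 13
        oracle_counts, oracle_dirs = brute_force_crossings(traj, slab, 10.0)
        assert np.array_equal(series.counts, oracle_counts)
        assert series.direction_totals == oracle_dirs

    def test_random_walks_match_oracle(self, slab, rng):
        # free diffusion with no construction guarantees at all
        for trial in range(5):
            z0 = rng.uniform(-40, 40, size=30)
            steps = rng.normal(0, 9.0, size=(120, 30))
            traj = TrajectorySlice(
                frames=np.arange(121),
                times_ps=10.0 * np.arange(121),
                z=np.vstack([z0, z0 + np.cumsum(steps, axis=0)]),
                molecule_ids=list(range(30)),
            )
            series = count_crossings(traj, slab, window_ps=40.0)
            oracle_counts, oracle_dirs = brute_force_crossings(traj, slab, 40.0)
            assert np.array_equal(series.counts, oracle_counts)
            assert series.direction_totals == oracle_dirs


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n_mol=st.integers(1, 12), n_frames=st.integers(8, 60))
def test_direction_antisymmetry(seed, n_mol, n_frames):
    """Reflecting z and swapping the slab planes swaps down/up and keeps Y_i."""
    rng = np.random.default_rng(seed)
    slab = MembraneSlab(-18.0, 18.0)
    z = np.cumsum(rng.normal(0, 10, size=(n_frames, n_mol)), axis=0)
    traj = TrajectorySlice(
        frames=np.arange(n_frames), times_ps=10.0 * np.arange(n_frames),
        z=z, molecule_ids=list(range(n_mol)),
    )
    mirrored = TrajectorySlice(
        frames=np.arange(n_frames), times_ps=10.0 * np.arange(n_frames),
        z=-z, molecule_ids=list(range(n_mol)),
    )
    a = count_crossings(traj, slab, 10.0)
    b = count_crossings(mirrored, slab, 10.0)
    assert np.array_equal(a.counts, b.counts)
    assert a.direction_totals == (b.direction_totals[1], b.direction_totals[0])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n_windows=st.integers(1, 10))
def test_window_refinement_conservation(seed, n_windows):
    """Halving the window pairs up into the coarser series."""
    rng = np.random.default_rng(seed)
    n_frames = 4 * n_windows + 1
    z = np.cumsum(rng.normal(0, 12, size=(n_frames, 6)), axis=0)
    traj = TrajectorySlice(
        frames=np.arange(n_frames), times_ps=10.0 * np.arange(n_frames),
        z=z, molecule_ids=list(range(6)),
    )
    slab = MembraneSlab(-15.0, 15.0)
    coarse = count_crossings(traj, slab, 40.0)
    fine = count_crossings(traj, slab, 20.0)
    paired = fine.counts.reshape(-1, 2).sum(axis=1)
    assert np.array_equal(coarse.counts, paired)
    assert coarse.total == fine.total


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_time_reversal_preserves_total(seed):
    rng = np.random.default_rng(seed)
    z = np.cumsum(rng.normal(0, 11, size=(41, 8)), axis=0)
    traj = TrajectorySlice(
        frames=np.arange(41), times_ps=10.0 * np.arange(41),
        z=z, molecule_ids=list(range(8)),
    )
    rev = TrajectorySlice(
        frames=np.arange(41), times_ps=10.0 * np.arange(41),
        z=z[::-1], molecule_ids=list(range(8)),
    )
    slab = MembraneSlab(-15.0, 15.0)
    a = count_crossings(traj, slab, 10.0)
    b = count_crossings(rev, slab, 10.0)
    assert a.total == b.total
    assert a.direction_totals == (b.direction_totals[1], b.direction_totals[0])


class TestInferSlab:
    def test_two_static_atoms(self):
        lipid_z = np.tile([-18.0, 18.0], (5, 1))
        slab = infer_slab(lipid_z)
        assert slab.z_lower == pytest.approx(-18.0)
        assert slab.z_upper == pytest.approx(18.0)

    def test_noisy_leaflets(self, rng):
        lower = -18.0 + rng.uniform(-1, 1, size=(100, 100))
        upper = 18.0 + rng.uniform(-1, 1, size=(100, 100))
        slab = infer_slab(np.hstack([lower, upper]))
        assert abs(slab.z_lower + 18.0) < 0.2
        assert abs(slab.z_upper - 18.0) < 0.2

    def test_single_frame(self):
        slab = infer_slab(np.array([[-20.0, 20.0]]))
        assert (slab.z_lower, slab.z_upper) == (-20.0, 20.0)

    def test_degenerate_leaflet_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            infer_slab(np.array([[1.0, 1.0, 1.0]]))


class TestSeriesInvariants:
    def test_direction_totals_must_sum(self):
        with pytest.raises(ValueError):
            CrossingCountSeries(counts=[1, 2], window_ps=10.0, direction_totals=(1, 1))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CrossingCountSeries(counts=[-1], window_ps=10.0)
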