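"""Shared fixtures and the independent brute-force crossing oracle."""

from __future__ import annotations

import numpy as np
import pytest

from memflux.counting import MembraneSlab, TrajectorySlice


def brute_force_crossings(traj: TrajectorySlice, slab: MembraneSlab, window_ps: float):
    """Reference crossing counter: plain per-molecule scalar replay.

    Deliberately independent of the package implementation: no shared code
    beyond the data types. Walks every molecule frame by frame, tracks the
    last definite side, treats |dz| > box_z/2 as an image wrap (state reset),
    and assigns each completed traversal to the window of its completing
    frame.
    """
    dt = traj.times_ps[1] - traj.times_ps[0]
    fpw = int(round(window_ps / dt))
    n_windows = -(-(traj.n_frames - 1) // fpw)
    counts = [0] * n_windows
    down = up = 0
    half_box = traj.box_z / 2.0 if traj.box_z is not None else float("inf")

    def side_of(z):
        if z > slab.z_upper:
            return 1
        if z < slab.z_lower:
            return -1
        return 0

    for m in range(traj.n_molecules):
        last = side_of(traj.z[0, m])
        for f in range(1, traj.n_frames):
            z_prev, z_cur = traj.z[f - 1, m], traj.z[f, m]
            cur = side_of(z_cur)
            if abs(z_cur - z_prev) > half_box:
                last = cur  # wrap: adopt new region silently (0 if inside)
                continue
            if cur != 0 and last != 0 and cur != last:
                counts[(f - 1) // fpw] += 1
                if cur == -1:
                    down += 1
                else:
                    up += 1
                last = cur
            elif cur != 0:
                last = cur
    return np.array(counts), (down, up)


@pytest.fixture
def slab():
    return MembraneSlab(z_lower=-18.0, z_upper=18.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
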