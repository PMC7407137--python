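"""Transition counting: from per-frame water z-coordinates to per-window counts.

A water molecule permeates the bilayer when it completes a traversal from the
aqueous region on one side of the membrane slab to the other. Counting is done
with a per-molecule three-state machine (above / inside / below the slab):
the molecule's *last definite side* is tracked, being "inside" preserves it
(implicit hysteresis against boundary jitter), and a crossing is recorded only
when the molecule first reaches the opposite definite side. Re-entries that
return to the origin side record nothing. Each crossing is assigned to the
observation window containing its completing frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TrajectorySlice",
    "MembraneSlab",
    "CrossingCountSeries",
    "infer_slab",
    "count_crossings",
]

# side codes for the state machine
_ABOVE = 1
_BELOW = -1
_INSIDE = 0
_UNKNOWN = 0  # for "last definite side": no definite side seen yet


@dataclass(frozen=True)
class MembraneSlab:
    """Two z-planes bounding the bilayer's hydrophobic slab (Å).

    Everything with z strictly above ``z_upper`` is "above", strictly below
    ``z_lower`` is "below"; a coordinate exactly on a plane counts as inside
    (deterministic tie-break).
    """

    z_lower: float
    z_upper: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.z_lower) or not np.isfinite(self.z_upper):
            raise ValueError("slab bounds must be finite")
        if not self.z_upper > self.z_lower:
            raise ValueError(
                f"z_upper ({self.z_upper}) must exceed z_lower ({self.z_lower})"
            )

    def classify(self, z: np.ndarray) -> np.ndarray:
        """Vectorized side classification: +1 above, -1 below, 0 inside."""
        z = np.asarray(z)
        return np.where(z > self.z_upper, _ABOVE, np.where(z < self.z_lower, _BELOW, _INSIDE))


@dataclass
class TrajectorySlice:
    """Per-frame z-coordinates of tracked molecules.

    Parameters
    ----------
    frames : (n_frames,) int array of frame indices
    times_ps : (n_frames,) strictly increasing times in ps
    z : (n_frames, n_molecules) z-coordinates in Å
    molecule_ids : stable identifiers, one per column of ``z``
    box_z : periodic box height in Å along z, or None for non-periodic input
    """

    frames: np.ndarray
    times_ps: np.ndarray
    z: np.ndarray
    molecule_ids: Sequence
    box_z: Optional[float] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2:
            raise ValueError("z must be 2-D (n_frames, n_molecules)")
        nf, nm = self.z.shape
        if len(self.frames) != nf or len(self.times_ps) != nf:
            raise ValueError("frames/times length must match z's first axis")
        if len(self.molecule_ids) != nm:
            raise ValueError("molecule_ids length must match z's second axis")
        if nf >= 2 and not np.all(np.diff(self.times_ps) > 0):
            raise ValueError("times_ps must be strictly increasing")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z contains non-finite values")
        if self.box_z is not None and not self.box_z > 0:
            raise ValueError("box_z must be positive")

    @property
    def n_frames(self) -> int:
        return self.z.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.z.shape[1]

    @property
    def frame_interval_ps(self) -> float:
        if self.n_frames < 2:
            raise ValueError("need at least two frames for a frame interval")
        dt = np.diff(self.times_ps)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("frame interval is not uniform")
        return float(dt[0])


@dataclass
class CrossingCountSeries:
    """Ordered per-window transition counts Y_i with window duration.

    ``direction_totals`` (down, up) is available when counts come from the
    counter; series loaded from plain CSV or drawn from the count model carry
    None there.
    """

    counts: np.ndarray
    window_ps: float
    direction_totals: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not self.window_ps > 0:
            raise ValueError("window_ps must be positive")
        if self.direction_totals is not None:
            down, up = self.direction_totals
            if down + up != int(self.counts.sum()):
                raise ValueError(
                    "direction totals do not sum to total count: "
                    f"{down}+{up} != {int(self.counts.sum())}"
                )

    @property
    def n_windows(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def infer_slab(lipid_z: np.ndarray) -> MembraneSlab:
    """Infer slab bounds from per-frame lipid reference-atom z-coordinates.

    Leaflets are split frame-by-frame at the median z; the slab planes are the
    time-averaged mean z of the lower and upper leaflet atoms. This is the
    usual permeation-analysis convention of placing boundary planes at the
    average phosphate positions.

    Parameters
    ----------
    lipid_z : (n_frames, n_atoms) array

    Raises
    ------
    ValueError
        If in some frame all reference atoms fall on one side of the median
        (degenerate leaflet assignment).
    """
    lipid_z = np.atleast_2d(np.asarray(lipid_z, dtype=float))
    if lipid_z.shape[1] < 2:
        raise ValueError("need at least one reference atom per leaflet")
    med = np.median(lipid_z, axis=1, keepdims=True)
    upper_mask = lipid_z > med
    lower_mask = lipid_z < med
    n_upper = upper_mask.sum(axis=1)
    n_lower = lower_mask.sum(axis=1)
    bad = np.nonzero((n_upper == 0) | (n_lower == 0))[0]
    if bad.size:
        raise ValueError(
            f"degenerate leaflet split in frame {int(bad[0])}: "
            "all reference atoms on one side of the median"
        )
    z_upper = float(np.mean(np.sum(lipid_z * upper_mask, axis=1) / n_upper))
    z_lower = float(np.mean(np.sum(lipid_z * lower_mask, axis=1) / n_lower))
    return MembraneSlab(z_lower=z_lower, z_upper=z_upper)


def count_crossings(
    traj: TrajectorySlice, slab: MembraneSlab, window_ps: float = 10.0
) -> CrossingCountSeries:
    """Count complete slab traversals per observation window.

    Replays a three-state machine over frames for every molecule. A crossing
    is recorded, in the window containing the completing frame, when a
    molecule whose last definite side was "above" first reaches "below"
    (direction down), or vice versa (up). Both directions contribute to Y_i.

    When ``traj.box_z`` is set, a consecutive-frame z displacement larger than
    ``box_z / 2`` is treated as a periodic-image wrap: the molecule's side is
    reset to its new definite region without recording a crossing.

    Parameters
    ----------
    traj : trajectory slice with uniform frame spacing
    slab : membrane slab definition
    window_ps : window duration; must be an integer multiple of the frame
        interval

    Returns
    -------
    CrossingCountSeries
        One count per window; the number of windows spans the trajectory
        duration ``(n_frames - 1) * frame_interval``.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least two frames to count crossings")
    dt = traj.frame_interval_ps
    ratio = window_ps / dt
    frames_per_window = int(round(ratio))
    if frames_per_window < 1 or abs(ratio - frames_per_window) > 1e-6:
        raise ValueError(
            f"window_ps={window_ps} is not an integer multiple of the "
            f"frame interval {dt} ps"
        )
    n_windows = (traj.n_frames - 1 + frames_per_window - 1) // frames_per_window
    counts = np.zeros(n_windows, dtype=np.int64)
    down_total = 0
    up_total = 0

    sides = slab.classify(traj.z)  # (n_frames, n_molecules)
    last_side = sides[0].copy()  # 0 where not yet definite
    half_box = traj.box_z / 2.0 if traj.box_z is not None else np.inf

    for f in range(1, traj.n_frames):
        cur = sides[f]
        definite = cur != _INSIDE
        wrapped = np.abs(traj.z[f] - traj.z[f - 1]) > half_box
        # wraps reset state to the new region; not a crossing
        reset = wrapped
        crossing = definite & (last_side != _UNKNOWN) & (cur != last_side) & ~reset
        # completing frame f belongs to window (f-1)//frames_per_window
        w = (f - 1) // frames_per_window
        n_down = int(np.sum(crossing & (cur == _BELOW)))
        n_up = int(np.sum(crossing & (cur == _ABOVE)))
        counts[w] += n_down + n_up
        down_total += n_down
        up_total += n_up
        # update last definite side (also for wrapped molecules, without count)
        last_side = np.where(definite, cur, np.where(wrapped, _UNKNOWN, last_side))

    return CrossingCountSeries(
        counts=counts,
        window_ps=window_ps,
        direction_totals=(down_total, up_total),
    )
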