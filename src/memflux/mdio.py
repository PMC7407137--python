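"""Reading standard MD trajectory formats into a :class:`TrajectorySlice`.

Backed by MDAnalysis, so anything it can open works: PDB (including
multi-MODEL files as trajectories), PSF/GRO topologies with DCD/XTC/TRR
coordinates, and so on. Only water z-coordinates (one reference atom per
water, typically the oxygen) and lipid reference-atom z-coordinates
(typically phosphorus) are extracted — the counter needs nothing else.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .counting import TrajectorySlice

__all__ = ["read_standard_trajectory"]


def read_standard_trajectory(
    topology_path,
    coordinates_path=None,
    water_selection: str = "resname TIP3 HOH SOL WAT and name OH2 OW O",
    lipid_selection: str = "resname POPC and name P",
    dt_ps: Optional[float] = None,
):
    """Extract water and lipid z-coordinates from a standard MD trajectory.

    Parameters
    ----------
    topology_path : topology file (PDB, PSF, GRO, ...)
    coordinates_path : coordinate/trajectory file (DCD, XTC, multi-model
        PDB, ...); omit to read frames from the topology file itself
    water_selection, lipid_selection : MDAnalysis selection strings; each
        should select one reference atom per molecule
    dt_ps : override the per-frame time step (useful for formats like PDB
        that carry no time information)

    Returns
    -------
    (TrajectorySlice, lipid_z)
        The water trajectory slice and a (n_frames, n_lipid_atoms) array of
        lipid reference z-coordinates for slab inference.
    """
    import MDAnalysis as mda

    if coordinates_path is not None:
        universe = mda.Universe(str(topology_path), str(coordinates_path))
    else:
        universe = mda.Universe(str(topology_path))

    waters = universe.select_atoms(water_selection)
    if len(waters) == 0:
        raise ValueError(f"water selection matched no atoms: {water_selection!r}")
    lipids = universe.select_atoms(lipid_selection)
    if len(lipids) == 0:
        raise ValueError(f"lipid selection matched no atoms: {lipid_selection!r}")

    n_frames = len(universe.trajectory)
    water_z = np.empty((n_frames, len(waters)))
    lipid_z = np.empty((n_frames, len(lipids)))
    times = np.empty(n_frames)
    box_z = None
    for i, ts in enumerate(universe.trajectory):
        water_z[i] = waters.positions[:, 2]
        lipid_z[i] = lipids.positions[:, 2]
        times[i] = ts.time
        if ts.dimensions is not None and ts.dimensions[2] > 0:
            box_z = float(ts.dimensions[2])
    if dt_ps is not None:
        times = dt_ps * np.arange(n_frames)
    elif n_frames >= 2 and np.all(np.diff(times) <= 0):
        # format carried no usable time axis; fall back to unit spacing
        times = np.arange(n_frames, dtype=float)

    traj = TrajectorySlice(
        frames=np.arange(n_frames),
        times_ps=times,
        z=water_z,
        molecule_ids=[int(ix) for ix in waters.resids] if len(set(waters.resids)) == len(waters) else list(range(len(waters))),
        box_z=box_z,
    )
    return traj, lipid_z
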