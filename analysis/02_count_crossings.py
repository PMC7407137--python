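#!/usr/bin/env python
"""Count water crossings in the toy membrane trajectory.

Replays the three-state (above / inside / below) machine over the fixture
written by 01_simulate_flux_data.py and checks the windowed totals against
the generator's schedule — the periodic-image wraps injected into the
fixture must not appear as crossings.

Writes: results/toy_trajectory_counts.csv.
"""

import json
from pathlib import Path

from memflux.counting import count_crossings
from memflux.io import read_trajectory_tsv, write_count_series

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tpath = RESULTS / "toy_trajectory.tsv"
    traj, slab = read_trajectory_tsv(tpath)
    meta = json.loads((tpath.parent / (tpath.name + ".meta.json")).read_text())
    series = count_crossings(traj, slab, window_ps=10.0)
    down, up = series.direction_totals
    print(
        f"counted {series.total} crossings ({down} down, {up} up) "
        f"over {series.n_windows} windows"
    )
    expected = meta["schedule_events"]
    status = "matches" if series.total == expected else "MISMATCHES"
    print(f"schedule ground truth: {expected} -> counter {status}")
    out = RESULTS / "toy_trajectory_counts.csv"
    write_count_series(series, out)
    print(f"wrote {out.name}")


if __name__ == "__main__":
    main()
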