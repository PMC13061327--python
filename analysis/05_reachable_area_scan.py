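#!/usr/bin/env python
"""Reachable-area scan: how the diffusive signal's range shapes the indices.

Sweeps the Gaussian kernel scale delta (the "reachable area") at fixed
source strength q = 0.3 and differentiation threshold 0.004, runs
replicates per grid point at desk scale, and classifies the four indices
of the central cross-section against the experimental bands.  Writes
results/reachable_area_scan.csv.

Desk-scale note: replicates and stop count are reduced here so the sweep
finishes quickly; see 01_simulate_scenarios.py for the headline runs.
"""

import sys
from pathlib import Path

from tumoroid.cell_agents import FateConfig
from tumoroid.simulator import SimulationConfig, scan

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(stop_count: int = 5000, seeds=(1, 2)) -> None:
    base = SimulationConfig(
        scenario="diffusive",
        stop_count=stop_count,
        max_hours=20_000,
        fate=FateConfig(differentiation_threshold=0.004),
    )
    grid = [{"delta": d} for d in (1.0, 1.5, 2.0, 2.5)]
    out = scan(base, grid, seeds=list(seeds))
    RESULTS.mkdir(exist_ok=True)
    out.to_csv(RESULTS / "reachable_area_scan.csv", index=False)
    print(out.to_string(index=False))


if __name__ == "__main__":
    stop = int(sys.argv[1]) if len(sys.argv) > 1 else 5000
    main(stop)
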