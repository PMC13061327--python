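#!/usr/bin/env python
"""Compute the four spatial indices on every saved cross-section.

Reads the section tables written by 01_simulate_scenarios.py, evaluates
stem percentage, Moran's I (15 um), distance-histogram entropy and the
centrality ratio, classifies each against the experimental bands, and
writes results/spatial_indices.csv.
"""

from pathlib import Path

import pandas as pd

from tumoroid.spatial_stats import compute_report
from tumoroid.synthetic_patterns import read_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = []
    for path in sorted(RESULTS.glob("section_*.csv")):
        _, scenario, seed = path.stem.split("_")
        table = read_table(path)
        rep = compute_report(table)
        rows.append(
            {
                "scenario": scenario,
                "seed": seed,
                "n_cells": len(table),
                **{k: v for k, v in rep.to_dict().items() if k != "classification"},
                **{f"{k}_class": v for k, v in rep.classification.items()},
            }
        )
    if not rows:
        raise SystemExit("no section tables found; run 01_simulate_scenarios.py first")
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "spatial_indices.csv", index=False)
    print(df.to_string(index=False))
    print("\nscenario means:")
    print(df.groupby("scenario")[["percentage", "morans_i", "entropy", "centrality"]]
          .mean().to_string())


if __name__ == "__main__":
    main()
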