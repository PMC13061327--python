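#!/usr/bin/env python
"""De-differentiation rates per scenario from the saved division logs.

A de-differentiation event is a division in which a differentiated mother
produces two stem daughters; the rate is reported as a percentage of all
division events, per seed and pooled, and written to
results/dedifferentiation.csv.
"""

from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = []
    for path in sorted(RESULTS.glob("divisions_*.csv")):
        _, scenario, seed = path.stem.split("_")
        log = pd.read_csv(path)
        rows.append(
            {
                "scenario": scenario,
                "seed": seed,
                "divisions": len(log),
                "dediff_events": int(log["dedifferentiation"].sum()),
                "dediff_pct": 100.0 * log["dedifferentiation"].mean(),
            }
        )
    if not rows:
        raise SystemExit("no division logs found; run 01_simulate_scenarios.py first")
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "dedifferentiation.csv", index=False)
    print(df.to_string(index=False))
    pooled = df.groupby("scenario").apply(
        lambda g: 100.0 * g["dediff_events"].sum() / g["divisions"].sum(),
        include_groups=False,
    )
    print("\npooled de-differentiation % per scenario:")
    print(pooled.to_string())


if __name__ == "__main__":
    main()
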