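#!/usr/bin/env python
"""Group statistics on the quantified experiment.

Mann-Whitney on per-image mean puncta per cell (control vs stress), the
analysis used for localization-style readouts, plus a summary table.
Writes results/stats.csv.
"""

from pathlib import Path

import pandas as pd

import polysumo as ps

RESULTS = Path("results")


def main() -> None:
    df = pd.read_csv(RESULTS / "images.csv")
    rows = []
    control = df[df["condition"] == "control"]["mean_puncta_per_cell"]
    for cond in df["condition"].unique():
        if cond == "control":
            continue
        other = df[df["condition"] == cond]["mean_puncta_per_cell"]
        r = ps.mann_whitney_u(control, other)
        rows.append(
            {
                "comparison": f"control_vs_{cond}",
                "response": "mean_puncta_per_cell",
                "U": r.statistic,
                "p_value": r.p_value,
                "method": r.method,
                "control_mean": control.mean(),
                "other_mean": other.mean(),
            }
        )
    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "stats.csv", index=False)
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
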