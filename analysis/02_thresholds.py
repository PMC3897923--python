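#!/usr/bin/env python
"""Deterministic sensitivity: switch-point (threshold) analyses.

Finds the four parameter values at which the preferred-or-cheapest strategy
flips: the monthly indirect OA cost above which immediate surgery is
cheapest even before counting its QALY advantage; the monthly bridge cost
below which a bridged delay undercuts immediate surgery on direct costs;
the fraction of indirect costs surgery must recover for immediate surgery
to be cost-saving; and the months of symptomatic relief that make the
bridge itself cost-effective against waiting untreated. Writes one tidy CSV.
"""

from pathlib import Path

import pandas as pd

from tkawait import bundled_config_path, bundled_life_table, load_parameters
from tkawait.sensitivity import (
    bridge_cost_threshold,
    bridge_relief_threshold,
    indirect_cost_threshold,
    indirect_recovery_threshold,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params, _ = load_parameters(bundled_config_path())
    lt = bundled_life_table()
    rows = [
        ("indirect_cost", indirect_cost_threshold(params, lt), "$/month",
         "immediate surgery cheaper than untreated delay (indirect costs in)"),
        ("bridge_cost", bridge_cost_threshold(params, lt), "$/month",
         "bridged delay cheaper than immediate surgery (direct costs only)"),
        ("indirect_recovery", indirect_recovery_threshold(params, lt), "fraction",
         "indirect-cost recovery making immediate surgery cost-saving"),
        ("bridge_relief", bridge_relief_threshold(params, lt), "months",
         "relief duration making the bridge cost-effective vs no treatment"),
    ]
    df = pd.DataFrame(rows, columns=["threshold", "value", "unit", "meaning"])
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "thresholds.csv", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
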