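#!/usr/bin/env python
"""Base case: lifetime costs and QALYs of the three strategies.

Runs the 60-year-old cohort under both cost scenarios (A: direct medical
costs only; B: direct + indirect costs of knee OA) and writes the ranked
cost-effectiveness tables to results/. Under the calibrated life table the
immediate-surgery arm gains the most QALYs in both scenarios; delaying
without treatment is cheapest when only direct costs count, while with
indirect costs immediate surgery is both cheaper and more effective than
either delay (strong dominance).
"""

from pathlib import Path

from tkawait import (
    StrategyResult,
    build_cea_table,
    bundled_config_path,
    bundled_life_table,
    load_parameters,
    run_all_strategies,
)
from tkawait.cea import format_cea_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params, _ = load_parameters(bundled_config_path())
    lt = bundled_life_table()
    OUT.mkdir(exist_ok=True)
    for scenario in ("A", "B"):
        runs = run_all_strategies(params.replace(scenario=scenario), lt)
        table, preferred = build_cea_table(
            [StrategyResult.from_run(s, r) for s, r in runs.items()], wtp=50_000
        )
        table.to_csv(OUT / f"base_case_scenario_{scenario}.csv", index=False)
        print(f"--- scenario {scenario} (preferred: {preferred}) ---")
        print(format_cea_table(table).to_string(index=False))
        print()


if __name__ == "__main__":
    main()
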