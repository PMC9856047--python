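#!/usr/bin/env python
"""Stage-wise degree-day requirements from the constant-temperature rearing table.

Converts the built-in Kerguelen-strain rearing medians into per-stage,
inter-stage and total degree-day requirements with a 2 degC lower and
28 degC upper developmental threshold, and reports the mean egg-to-adult
requirement over the thermal gradient.  Writes
results/thermal_requirements.csv.
"""

from pathlib import Path

import pandas as pd

from ddphen import (STAGES, ThermalThresholds, fit_thermal_summary,
                    kerguelen_rearing_table, mean_required_dd)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    thr = ThermalThresholds()
    table = kerguelen_rearing_table()
    summary = fit_thermal_summary(table, thr)

    rows = []
    for name, stages in summary.per_stage.items():
        rec = {"condition": name}
        rec.update({s: round(v, 1) for s, v in stages.items()})
        rows.append(rec)
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "thermal_requirements.csv", index=False)

    print("Cumulative degree days to each stage, per rearing condition:")
    print(df.to_string(index=False))
    mean_dd = mean_required_dd(table, thr)
    print(f"\nMean egg-to-adult requirement over the gradient "
          f"(ambient run included): {mean_dd:.1f} DD")
    print("The warmest treatments need the fewest days but similar heat "
          "sums, as the linear degree-day model predicts; the 8 degC run "
          "needs more heat, consistent with cold-slowed late development.")


if __name__ == "__main__":
    main()
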