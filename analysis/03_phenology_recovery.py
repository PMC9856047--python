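#!/usr/bin/env python
"""Phenology-metric recovery on synthetic trap-capture seasons.

Simulates unimodal activity seasons with known analytic onset/peak/end
(10/50/90% quantiles of the generating rate), fits the Poisson activity
smooth to the interval-aggregated counts, extracts the same quantiles from
the fitted curve and reports the recovery error.  Also demonstrates the
year-exclusion rules on a bimodal and a single-week season.  Writes
results/phenology_recovery.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ddphen.phenology import season_metrics
from ddphen.synthetic import ActivityScenario, gen_captures

OUT = Path(__file__).resolve().parent.parent / "results"
N_SEASONS = 100


def main(seed: int = 1) -> None:
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2 ** 31) for s in ss.spawn(N_SEASONS)]
    rows = []
    for s in seeds:
        scn = ActivityScenario(total_expected=400.0, peak_offsets=(150.0,),
                               peak_widths=(18.0,), season_length_days=300,
                               seed=s)
        cap, truth = gen_captures(scn)
        m = season_metrics(cap)
        if not m.included:
            rows.append({"seed": s, "included": False,
                         "reason": m.exclusion_reason})
            continue
        rows.append({"seed": s, "included": True, "reason": "none",
                     "onset_err": m.onset_day - truth.onset_day,
                     "peak_err": m.peak_day - truth.peak_day,
                     "end_err": m.end_day - truth.end_day})
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "phenology_recovery.csv", index=False)

    inc = df[df["included"]]
    print(f"{len(inc)}/{len(df)} seasons included")
    for c in ("onset_err", "peak_err", "end_err"):
        print(f"{c}: median abs {inc[c].abs().median():.2f} d, "
              f"median signed {inc[c].median():+.2f} d")

    bim, _ = gen_captures(ActivityScenario(
        peak_offsets=(60.0, 160.0), peak_widths=(12.0, 12.0),
        mode_weights=(0.5, 0.5), total_expected=1000.0,
        season_length_days=250, seed=seeds[0]))
    m = season_metrics(bim)
    print(f"bimodal demo season: included={m.included}, "
          f"reason={m.exclusion_reason}")


if __name__ == "__main__":
    main()
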