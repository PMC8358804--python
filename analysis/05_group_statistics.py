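#!/usr/bin/env python
"""The statistical battery over the measured study tables.

Recomputes the study's tests from the tidy tables: Friedman (with
Bonferroni-adjusted rank post hocs vs day 0) per group on thresholds,
Mann-Whitney between groups at the key days, one-way ANOVA with
Games-Howell on normalised OD across conditions, two-way condition x
frequency ANOVA on button area, and the per-condition size-OD correlation
table.  Prints the qualitative pattern the design injects: significant AT
day-13 elevation, no ES_AT day-13 elevation, and a day-26 OD rebound that
is higher under prior stimulation.
"""

import subprocess
import sys
from pathlib import Path

import pandas as pd

HERE = Path(__file__).resolve().parent
RESULTS = HERE.parent / "results"


def main() -> None:
    thr_path = RESULTS / "pipeline" / "thresholds.csv"
    if not thr_path.exists():
        subprocess.run([sys.executable, str(HERE / "01_simulate_study.py")], check=True)
    thr = pd.read_csv(thr_path)
    buttons = pd.read_csv(RESULTS / "pipeline" / "buttons.csv")

    from efferentquant.stats import (
        anova_oneway_posthoc,
        anova_twoway,
        correlation_table,
        friedman_with_posthoc,
        mann_whitney,
    )

    print("Friedman within groups, post hoc vs day 0 (Bonferroni-adjusted):")
    for g, sub in thr.groupby("group"):
        res = friedman_with_posthoc(
            sub, subject="animal", within="timepoint_day", value="threshold_db"
        )
        d13 = res.posthoc.set_index("level_b").loc[13]
        print(f"  {g:6s} chi2={res.statistic:6.2f} p={res.p_value:.4f} | "
              f"day 13 vs 0: adj p={d13['p_adj']:.4f}"
              f"{'  *' if d13['p_adj'] < 0.05 else ''}")

    d13 = thr[thr.timepoint_day == 13]
    mw = mann_whitney(
        d13[d13.group == "AT"]["threshold_db"],
        d13[d13.group == "ES_AT"]["threshold_db"],
    )
    print(f"\nMann-Whitney AT vs ES_AT at day 13: U={mw.statistic:.0f} "
          f"p={mw.p_value:.4f}")

    groups = {c: s["norm_od"].to_numpy() for c, s in buttons.groupby("condition")}
    an = anova_oneway_posthoc(groups, posthoc="games_howell")
    print(f"\none-way ANOVA on normalised OD across conditions: "
          f"F={an.statistic:.2f} p={an.p_value:.2e}")
    ph = an.posthoc.set_index(["group_a", "group_b"])
    pair = ("AT+14d", "ES_AT+14d")
    row = ph.loc[pair] if pair in ph.index else ph.loc[(pair[1], pair[0])]
    print(f"  Games-Howell AT+14d vs ES_AT+14d: diff={row['diff']:+.3f} "
          f"adj p={row['p_adj']:.4f}")

    tw = anova_twoway(buttons, "area_um2", "condition", "frequency_khz")
    pv = tw.extras["p_values"]
    print(f"\ntwo-way ANOVA on area: condition p={pv['condition']:.2e}, "
          f"frequency p={pv['frequency_khz']:.2e}, "
          f"interaction p={pv['interaction']:.2e}")

    corr = correlation_table(buttons, group_col="condition")
    out = RESULTS / "correlation_table.csv"
    corr.round(4).to_csv(out, index=False)
    print("\nsize-OD correlation table by condition:")
    cols = ["group", "n", "mean_od", "sd_od", "mean_area", "sd_area",
            "pearson_r", "pearson_p"]
    print(corr[cols].round(3).to_string(index=False))
    print(f"wrote {out}")


if __name__ == "__main__":
    sys.exit(main())
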