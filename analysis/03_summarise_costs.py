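#!/usr/bin/env python
"""Summarise the costed cohorts: descriptives, skewness, bootstrap CIs, OI mix.

Reads results/breakdowns/ and results/cohorts/, writes
results/cost_summary.csv (component x arm descriptives),
results/oi_frequency_<arm>.csv and results/summary.json (bootstrap CIs,
skewness, mortality), and prints the headline numbers.
"""

import json
from pathlib import Path

import pandas as pd

from microcost.engine import round_half_up
from microcost.summary import bootstrap_mean_ci, mortality_rate, oi_frequency_table, skewness, summarise

BREAKDOWNS = Path("results/breakdowns")
COHORTS = Path("results/cohorts")
OUT = Path("results")
SEED = 42


def main() -> None:
    summary_rows = []
    arm_json = {}
    for path in sorted(BREAKDOWNS.glob("*.csv")):
        arm = path.stem
        frame = pd.read_csv(path)
        for comp in frame.columns.drop("patient_id"):
            s = summarise(frame[comp].tolist())
            summary_rows.append(
                {"arm": arm, "component": comp,
                 "mean": round_half_up(s.mean), "sd": round_half_up(s.sd),
                 "min": round_half_up(s.minimum), "max": round_half_up(s.maximum), "n": s.n}
            )
        totals = frame["total"].tolist()
        boot = bootstrap_mean_ci(totals, n_resamples=10_000, level=0.95, seed=SEED)
        patients = pd.read_csv(COHORTS / arm / "patients.csv", keep_default_na=False)
        deaths = int((patients["death_day"].astype(str) != "").sum())
        arm_json[arm] = {
            "n": len(totals),
            "mean_total": round_half_up(boot.point_estimate),
            "ci95": [round_half_up(boot.ci_low), round_half_up(boot.ci_high)],
            "skewness_total": round_half_up(skewness(totals)),
            "mortality_percent": round_half_up(mortality_rate(deaths, len(patients))),
        }
        hosp = pd.read_csv(COHORTS / arm / "hospitalisations.csv", keep_default_na=False)
        if len(hosp):
            oi = oi_frequency_table(hosp["cause"].tolist())
            oi.to_frame().to_csv(OUT / f"oi_frequency_{arm}.csv", index=False, lineterminator="\n")
        print(
            f"{arm}: mean total ${arm_json[arm]['mean_total']} "
            f"(95% CI {arm_json[arm]['ci95'][0]}-{arm_json[arm]['ci95'][1]}), "
            f"skewness {arm_json[arm]['skewness_total']}, "
            f"mortality {arm_json[arm]['mortality_percent']}%"
        )

    pd.DataFrame(summary_rows).to_csv(OUT / "cost_summary.csv", index=False, lineterminator="\n")
    (OUT / "summary.json").write_text(json.dumps(arm_json, indent=2, sort_keys=True) + "\n")
    print(f"wrote {OUT}/cost_summary.csv and {OUT}/summary.json")


if __name__ == "__main__":
    main()
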