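#!/usr/bin/env python
"""Cost the generated cohorts patient by patient.

Reads results/cohorts/<arm>/, applies the ingredients costing engine
(fixture drug prices, wage schedules, a per-bed-day overhead rate from a
direct allocation of an illustrative hospital ledger, annuitised capital
shares) and writes one breakdown CSV per arm under results/breakdowns/.
"""

from pathlib import Path

import pandas as pd

from microcost.engine import CostingContext, WageSchedule, breakdowns_to_frame, cost_cohort
from microcost.overhead import (
    CapitalAsset,
    OverheadLedger,
    allocate_overhead,
    equivalent_annual_cost,
    per_day_overhead_rate,
)
from microcost.synthetic_crf import frames_to_cohort
from microcost.unit_costs import bundled_price_table

COHORTS = Path("results/cohorts")
OUT = Path("results/breakdowns")

# per-visit labour: cotrimoxazole-era physician $2, ARV-era physician $5, nurse $2
WAGES = {
    "cotrimoxazole": WageSchedule(wages={"physician": (640.0, 160.0), "nurse": (640.0, 160.0)}),
    "arv": WageSchedule(wages={"physician": (1600.0, 160.0), "nurse": (640.0, 160.0)}),
}

LEDGER = OverheadLedger(
    {"administration": 120_000.0, "security": 40_000.0, "laundry": 25_000.0,
     "catering": 60_000.0, "utilities": 55_000.0}
)
# space share 0.25 for admin/security/utilities, patient-load share 0.18 for the rest
WEIGHTS = {"administration": 0.25, "security": 0.25, "utilities": 0.25,
           "laundry": 0.18, "catering": 0.18}
BED_DAYS = 36_500.0

ASSETS = [
    CapitalAsset("paediatric block", 1_200_000.0, 40, "building"),
    CapitalAsset("trial vehicle", 30_000.0, 5, "vehicle"),
    CapitalAsset("CD4 counter", 80_000.0, 5, "lab_equipment"),
]
CAPITAL_WEIGHT = 0.1
HORIZON_YEARS = 96 / 52


def load_cohort(arm_dir: Path):
    frames = {
        name: pd.read_csv(arm_dir / f"{name}.csv", keep_default_na=False)
        for name in ("patients", "visits", "hospitalisations", "dispenses", "lab_tests")
    }
    return frames_to_cohort(frames)


def main() -> None:
    table = bundled_price_table("all")
    per_day = per_day_overhead_rate(
        sum(allocate_overhead(LEDGER, WEIGHTS).values()), BED_DAYS
    )
    annual_capital = sum(equivalent_annual_cost(a) for a in ASSETS)
    print(f"per-bed-day overhead rate: ${per_day:.2f}; annuitised capital ${annual_capital:,.0f}/y")

    OUT.mkdir(parents=True, exist_ok=True)
    for arm_dir in sorted(COHORTS.iterdir()):
        if not (arm_dir / "patients.csv").exists():
            continue
        records = load_cohort(arm_dir)
        ctx = CostingContext(
            unit_table=table,
            wage_schedule=WAGES[arm_dir.name],
            per_day_overhead=per_day,
            capital_share_per_patient=annual_capital * CAPITAL_WEIGHT * HORIZON_YEARS / len(records),
            lab_flat_rate=15.0,
        )
        cohort = cost_cohort(records, ctx)
        frame = breakdowns_to_frame(cohort, rounded=True)
        dest = OUT / f"{arm_dir.name}.csv"
        frame.to_csv(dest, index=False, lineterminator="\n")
        print(
            f"{arm_dir.name}: {len(cohort)} patients costed, "
            f"mean total ${frame['total'].mean():.2f} -> {dest}"
        )


if __name__ == "__main__":
    main()
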