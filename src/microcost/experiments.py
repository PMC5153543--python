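"""Parameter-recovery studies on the synthetic generator.

The headline per-patient cost totals of the underlying trials cannot be
recomputed from published inputs alone (the patient-level data is not
deposited), so the costing pipeline is validated by recovery instead: a
cohort is generated with a known visit process (Poisson rate lambda) and
a known per-visit labour cost w, the full engine is run, and the cohort
mean labour cost is compared with its analytic expectation lambda x w.
"""

from __future__ import annotations

import numpy as np

from .engine import CostingContext, WageSchedule, cost_cohort
from .synthetic_crf import ArmConfig, LosDistribution, generate_cohort
from .unit_costs import bundled_price_table

__all__ = ["labour_recovery_config", "labour_recovery_mean", "recovery_standard_error"]

_CADRE_RATE_FIELD = {"physician": "physician_visit_rate", "nurse": "nursing_visit_rate"}


def labour_recovery_config(
    arm_label: str,
    cadre: str,
    n_patients: int,
    visit_rate: float,
    seed: int,
    followup_days: int = 336,
) -> ArmConfig:
    """An arm whose only resource stream is one cadre's visit process.

    Mortality is zero so censoring does not bias the mean: the recovery
    target is the uncensored expectation lambda x w.
    """
    rates = {"physician_visit_rate": 0.0, "nursing_visit_rate": 0.0}
    rates[_CADRE_RATE_FIELD[cadre]] = visit_rate
    return ArmConfig(
        arm_label=arm_label,
        n_patients=n_patients,
        followup_days=followup_days,
        mortality_prob=0.0,
        hosp_episode_rate=0.0,
        los_distribution=LosDistribution(median_days=4.0, sigma=0.7, cap_days=37),
        oi_frequency_table={"none": 1.0},
        dispense_model=[],
        seed=seed,
        **rates,
    )


def _wage_for_per_visit_cost(per_visit_cost: float, visit_hours: float = 0.5) -> tuple[float, float]:
    # monthly wage / monthly hours x visit hours == per-visit cost
    monthly_hours = 160.0
    return per_visit_cost / visit_hours * monthly_hours, monthly_hours


def labour_recovery_mean(
    arm_label: str,
    cadre: str,
    n_patients: int,
    visit_rate: float,
    per_visit_cost: float,
    n_seeds: int = 20,
    master_seed: int = 0,
) -> float:
    """Cohort mean labour cost for one cadre, averaged over ``n_seeds`` cohorts.

    Each cohort gets an independent generator seed derived from the master
    seed; the expectation is visit_rate x per_visit_cost.
    """
    table = bundled_price_table("all")
    wages = WageSchedule(
        wages={c: _wage_for_per_visit_cost(per_visit_cost) for c in ("physician", "nurse")}
    )
    ctx = CostingContext(
        unit_table=table,
        wage_schedule=wages,
        per_day_overhead=0.0,
        capital_share_per_patient=0.0,
        lab_flat_rate=0.0,
    )
    component = "physician" if cadre == "physician" else "nursing"
    means = []
    for i in range(n_seeds):
        seed = int(np.random.SeedSequence([master_seed, i]).generate_state(1)[0] % (2**31))
        cfg = labour_recovery_config(arm_label, cadre, n_patients, visit_rate, seed)
        cohort = cost_cohort(generate_cohort(cfg), ctx)
        means.append(float(np.mean([getattr(b, component) for b in cohort])))
    return float(np.mean(means))


def recovery_standard_error(
    visit_rate: float, per_visit_cost: float, n_patients: int, n_seeds: int
) -> float:
    """SE of the averaged cohort mean: per-patient cost is w x Poisson(lambda)."""
    var_per_patient = per_visit_cost**2 * visit_rate
    return float(np.sqrt(var_per_patient / (n_patients * n_seeds)))
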