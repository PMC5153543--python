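"""Per-patient costing: the ingredients formula.

A patient's cost under a treatment regimen is the sum of labour costs
over the cadres seen (L_i), an apportioned share of annuitised capital
(K_t), medicines and supplies valued per dose (D_d), and laboratory
diagnostics (L_l):

    cost per patient = sum L_i + sum K_t + sum D_d + sum L_l.

Labour is costed as (monthly wage / monthly hours) x contact hours per
visit x number of visits.  Inpatient episodes cost their in-stay
medications (direct) plus length-of-stay x a per-bed-day overhead rate
that bundles laboratory, catering, administration, security, building
and transport overheads.  Components are kept disjoint so the total is
an exact sum: medications dispensed during a hospital stay are counted
inside the inpatient component only, and the ``outpatient`` component
carries only the apportioned fixed-cost share of ambulatory care (its
labour, drug and laboratory parts have their own columns).

Censoring by death is an input contract: records are truncated before
costing, so events past the death day contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .synthetic_crf import Hospitalisation, PatientRecord, Visit
from .unit_costs import UnitCostTable, course_cost, lab_panel_cost

__all__ = [
    "WageSchedule",
    "CostingContext",
    "CostBreakdown",
    "labour_cost",
    "inpatient_cost",
    "outpatient_cost",
    "patient_total_cost",
    "cost_cohort",
    "impute_missing_visit_costs",
    "breakdowns_to_frame",
    "round_half_up",
]

COMPONENTS = (
    "physician",
    "nursing",
    "medication",
    "laboratory",
    "inpatient",
    "outpatient",
    "capital_share",
)


class CostingError(ValueError):
    """Raised when a price, wage or cadre cannot be resolved."""


@dataclass(frozen=True)
class WageSchedule:
    """Cadre -> (monthly wage, monthly hours) with per-visit contact-hour defaults.

    The hourly rate is monthly_wage / monthly_hours; a visit of cadre c
    costs hourly_rate(c) x duration.
    """

    wages: Mapping[str, tuple[float, float]]
    default_visit_hours: Mapping[str, float] = field(
        default_factory=lambda: {"physician": 0.5, "nurse": 0.5}
    )

    def __post_init__(self) -> None:
        for cadre, (wage, hours) in self.wages.items():
            if wage < 0:
                raise ValueError(f"monthly wage for {cadre!r} must be >= 0")
            if hours <= 0:
                raise ValueError(f"monthly hours for {cadre!r} must be > 0")

    def hourly_rate(self, cadre: str) -> float:
        try:
            wage, hours = self.wages[cadre]
        except KeyError:
            raise CostingError(f"no wage entry for cadre {cadre!r}") from None
        return wage / hours

    def per_visit_cost(self, cadre: str, duration: float | None = None) -> float:
        if duration is None:
            duration = self.default_visit_hours.get(cadre, 0.5)
        return self.hourly_rate(cadre) * duration


@dataclass(frozen=True)
class CostingContext:
    """All prices and shares a costing run resolves against."""

    unit_table: UnitCostTable
    wage_schedule: WageSchedule
    per_day_overhead: float = 0.0
    capital_share_per_patient: float = 0.0
    lab_flat_rate: float = 15.0
    lab_pricing: str = "flat_panel"  # flat_panel | per_test
    lab_price_table: UnitCostTable | None = None
    outpatient_fixed_share: float = 0.0

    def __post_init__(self) -> None:
        if self.lab_pricing not in ("flat_panel", "per_test"):
            raise ValueError(
                f"lab_pricing must be flat_panel|per_test, got {self.lab_pricing!r}"
            )
        if self.lab_pricing == "per_test" and self.lab_price_table is None:
            raise ValueError("per_test lab pricing requires lab_price_table")
        for name in ("per_day_overhead", "capital_share_per_patient", "lab_flat_rate",
                     "outpatient_fixed_share"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CostBreakdown:
    """Per-patient component costs; ``total`` is their exact sum."""

    patient_id: str
    physician: float = 0.0
    nursing: float = 0.0
    medication: float = 0.0
    laboratory: float = 0.0
    inpatient: float = 0.0
    outpatient: float = 0.0
    capital_share: float = 0.0

    @property
    def total(self) -> float:
        return sum(getattr(self, c) for c in COMPONENTS)

    def scaled(self, c: float) -> "CostBreakdown":
        return CostBreakdown(
            self.patient_id, **{k: getattr(self, k) * c for k in COMPONENTS}
        )


def labour_cost(visits: Iterable[Visit], schedule: WageSchedule, cadre: str) -> float:
    """Wage cost of a patient's visits of one cadre: hourly rate x duration, summed."""
    rate = schedule.hourly_rate(cadre)
    return sum(rate * v.duration for v in visits if v.cadre == cadre)


def inpatient_cost(h: Hospitalisation, ctx: CostingContext) -> float:
    """One hospital episode: in-stay medications (direct) + LOS x per-day overhead."""
    direct = course_cost(h.dispenses_during_stay, ctx.unit_table)
    return direct + h.length_of_stay * ctx.per_day_overhead


def _lab_cost(record: PatientRecord, ctx: CostingContext) -> float:
    if ctx.lab_pricing == "flat_panel":
        return ctx.lab_flat_rate
    return lab_panel_cost(record.lab_tests, ctx.lab_price_table)


def outpatient_cost(
    visits: Iterable[Visit],
    dispenses: Iterable,
    labs: Iterable,
    ctx: CostingContext,
) -> float:
    """Full ambulatory aggregate: labour (both cadres, outpatient visits only)
    + outpatient medications + laboratory panel + apportioned fixed-cost share.

    This is the stand-alone outpatient estimate; in a :class:`CostBreakdown`
    its labour/drug/lab parts appear under their own components instead.
    """
    out_visits = [v for v in visits if v.setting == "outpatient"]
    labour = labour_cost(out_visits, ctx.wage_schedule, "physician") + labour_cost(
        out_visits, ctx.wage_schedule, "nurse"
    )
    meds = course_cost(dispenses, ctx.unit_table)
    if ctx.lab_pricing == "flat_panel":
        lab = ctx.lab_flat_rate
    else:
        lab = lab_panel_cost(labs, ctx.lab_price_table)
    return labour + meds + lab + ctx.outpatient_fixed_share


def patient_total_cost(record: PatientRecord, ctx: CostingContext) -> CostBreakdown:
    """Cost one (already censored) patient record into disjoint components."""
    try:
        return CostBreakdown(
            patient_id=record.patient_id,
            physician=labour_cost(record.visits, ctx.wage_schedule, "physician"),
            nursing=labour_cost(record.visits, ctx.wage_schedule, "nurse"),
            medication=course_cost(record.dispenses, ctx.unit_table),
            laboratory=_lab_cost(record, ctx),
            inpatient=sum(inpatient_cost(h, ctx) for h in record.hospitalisations),
            outpatient=ctx.outpatient_fixed_share,
            capital_share=ctx.capital_share_per_patient,
        )
    except (CostingError, ValueError) as exc:
        raise CostingError(f"patient {record.patient_id}: {exc}") from exc


def cost_cohort(
    records: Sequence[PatientRecord], ctx: CostingContext
) -> list[CostBreakdown]:
    return [patient_total_cost(r, ctx) for r in records]


def impute_missing_visit_costs(
    cohort: Sequence[CostBreakdown],
    missing_flags: Mapping[str, Sequence[str]],
) -> list[CostBreakdown]:
    """Replace flagged component values by the arm mean of non-missing values.

    ``missing_flags`` maps patient_id -> component names whose value was not
    observed (the trial's death-censored visit data).  The imputed cohort's
    component mean equals the complete-case mean.
    """
    flagged: dict[str, set[str]] = {
        pid: set(comps) for pid, comps in missing_flags.items()
    }
    means: dict[str, float] = {}
    for comp in COMPONENTS:
        vals = [
            getattr(b, comp)
            for b in cohort
            if comp not in flagged.get(b.patient_id, ())
        ]
        if any(comp in comps for comps in flagged.values()):
            if not vals:
                raise ValueError(
                    f"cannot impute component {comp!r}: every value is flagged missing"
                )
            means[comp] = sum(vals) / len(vals)
    out = []
    for b in cohort:
        comps = flagged.get(b.patient_id)
        if not comps:
            out.append(b)
            continue
        out.append(
            CostBreakdown(
                b.patient_id,
                **{
                    c: (means[c] if c in comps else getattr(b, c))
                    for c in COMPONENTS
                },
            )
        )
    return out


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Report-level rounding: half-up at ``ndigits`` decimals, serialisation only.

    Decimal-based so the tie rule applies to the shortest decimal
    representation, not the binary float below it.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def breakdowns_to_frame(cohort: Sequence[CostBreakdown], rounded: bool = False) -> pd.DataFrame:
    rows = []
    for b in cohort:
        row = {"patient_id": b.patient_id}
        for c in COMPONENTS:
            row[c] = round_half_up(getattr(b, c)) if rounded else getattr(b, c)
        row["total"] = round_half_up(b.total) if rounded else b.total
        rows.append(row)
    return pd.DataFrame(rows, columns=["patient_id", *COMPONENTS, "total"])
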