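"""Cost engine: labour, inpatient/outpatient algebra, censoring, imputation."""

import io
import random

import pytest

from microcost.engine import (
    COMPONENTS,
    CostBreakdown,
    CostingContext,
    CostingError,
    WageSchedule,
    cost_cohort,
    impute_missing_visit_costs,
    inpatient_cost,
    labour_cost,
    outpatient_cost,
    patient_total_cost,
    round_half_up,
)
from microcost.synthetic_crf import (
    Hospitalisation,
    LabTest,
    MedicationDispense,
    PatientRecord,
    Visit,
    apply_death_censoring,
)
from microcost.unit_costs import load_price_table


def make_record(patient_id="t", **kw):
    return PatientRecord(patient_id=patient_id, arm_label="arv", **kw)


class TestLabourCost:
    def test_wage_share_times_visits(self):
        # 1,200/month over 160 h -> 7.50/h; 0.5 h/visit; 4 visits -> 15.00
        schedule = WageSchedule(wages={"physician": (1200.0, 160.0)})
        visits = tuple(Visit(day=d, cadre="physician", duration=0.5) for d in range(4))
        assert labour_cost(visits, schedule, "physician") == pytest.approx(15.0)

    def test_no_visits_no_cost(self, wage_schedule):
        assert labour_cost((), wage_schedule, "physician") == 0.0

    def test_doubling_visits_doubles_cost(self, wage_schedule):
        v = tuple(Visit(day=d, cadre="nurse", duration=0.5) for d in range(3))
        assert labour_cost(v + v, wage_schedule, "nurse") == pytest.approx(
            2 * labour_cost(v, wage_schedule, "nurse")
        )

    def test_unknown_cadre_is_an_error(self, wage_schedule):
        with pytest.raises(CostingError, match="chaplain"):
            labour_cost((), wage_schedule, "chaplain")


class TestInpatientCost:
    def test_zero_stay_without_dispenses_costs_nothing(self, ctx):
        assert inpatient_cost(Hospitalisation(start_day=0, length_of_stay=0), ctx) == 0.0

    def test_direct_plus_overhead(self, ctx):
        # 10 days at 10/day overhead plus 100 doses of Cotrimoxazole at 0.2
        stay = Hospitalisation(
            start_day=0,
            length_of_stay=10,
            dispenses_during_stay=(
                MedicationDispense(drug_name="Cotrimoxazole", doses=100, day=0),
            ),
        )
        assert inpatient_cost(stay, ctx) == pytest.approx(10 * 10 + 20.0)

    def test_decomposes_into_direct_and_overhead_parts(self, ctx, price_table):
        from microcost.unit_costs import course_cost

        stay = Hospitalisation(
            start_day=2,
            length_of_stay=4,
            dispenses_during_stay=(
                MedicationDispense(drug_name="Ceftriaxone", doses=8, day=3),
            ),
        )
        direct = course_cost(stay.dispenses_during_stay, price_table)
        overhead = stay.length_of_stay * ctx.per_day_overhead
        assert inpatient_cost(stay, ctx) == pytest.approx(direct + overhead)


class TestOutpatientCost:
    lab_prices = load_price_table(
        io.StringIO("item_name,dosage,unit_price,category\nhaematology,,3.0,lab_test\n")
    )

    def test_no_activity_is_fixed_share_only(self, price_table, wage_schedule):
        ctx = CostingContext(
            unit_table=price_table,
            wage_schedule=wage_schedule,
            lab_flat_rate=0.0,
            outpatient_fixed_share=0.0,
        )
        assert outpatient_cost((), (), (), ctx) == 0.0

    def test_nurse_visit_plus_lab_panel(self, price_table, wage_schedule):
        # two-term oracle: one nurse visit at $2 + one haematology test at $3
        ctx = CostingContext(
            unit_table=price_table,
            wage_schedule=wage_schedule,
            lab_pricing="per_test",
            lab_price_table=self.lab_prices,
        )
        visits = (Visit(day=0, cadre="nurse", duration=0.5),)
        labs = (LabTest(test_name="haematology", day=0),)
        assert outpatient_cost(visits, (), labs, ctx) == pytest.approx(2.0 + 3.0)

    def test_sums_over_patients(self, ctx):
        recs = [
            make_record("a", visits=(Visit(day=0, cadre="physician", duration=0.5),)),
            make_record("b", visits=(Visit(day=1, cadre="physician", duration=0.5),)),
        ]
        per_patient = [
            outpatient_cost(r.visits, r.dispenses, r.lab_tests, ctx) for r in recs
        ]
        combined = outpatient_cost(
            recs[0].visits + recs[1].visits, (), (), ctx
        )
        # lab flat rate is 0 in ctx, so additivity is exact up to the shared flat terms
        assert combined == pytest.approx(sum(per_patient))


def brute_force_breakdown(record, ctx):
    """Independent event-by-event oracle for patient_total_cost."""
    phys = nurse = meds = inpat = 0.0
    for v in record.visits:
        wage, hours = ctx.wage_schedule.wages[v.cadre]
        if v.cadre == "physician":
            phys += wage / hours * v.duration
        else:
            nurse += wage / hours * v.duration
    for d in record.dispenses:
        meds += d.doses * ctx.unit_table.price(d.drug_name)
    for h in record.hospitalisations:
        inpat += h.length_of_stay * ctx.per_day_overhead
        for d in h.dispenses_during_stay:
            inpat += d.doses * ctx.unit_table.price(d.drug_name)
    lab = ctx.lab_flat_rate
    return (
        phys
        + nurse
        + meds
        + lab
        + inpat
        + ctx.outpatient_fixed_share
        + ctx.capital_share_per_patient
    )


def random_record(rnd, drugs, max_events=10):
    n = rnd.randint(0, max_events)
    visits, hosps, disps = [], [], []
    for _ in range(n):
        kind = rnd.choice(["visit", "hosp", "disp"])
        day = rnd.randint(0, 100)
        if kind == "visit":
            visits.append(
                Visit(day=day, cadre=rnd.choice(["physician", "nurse"]), duration=rnd.choice([0.25, 0.5, 1.0]))
            )
        elif kind == "hosp":
            stay_disp = tuple(
                MedicationDispense(drug_name=rnd.choice(drugs), doses=rnd.randint(0, 30), day=day)
                for _ in range(rnd.randint(0, 2))
            )
            hosps.append(
                Hospitalisation(start_day=day, length_of_stay=rnd.randint(1, 20), dispenses_during_stay=stay_disp)
            )
        else:
            disps.append(MedicationDispense(drug_name=rnd.choice(drugs), doses=rnd.randint(0, 60), day=day))
    return make_record(
        f"r{rnd.random()}", visits=tuple(visits), hospitalisations=tuple(hosps), dispenses=tuple(disps)
    )


class TestPatientTotalCost:
    def test_lab_only_patient_with_zero_shares_costs_the_panel(self, price_table, wage_schedule):
        ctx = CostingContext(
            unit_table=price_table, wage_schedule=wage_schedule, lab_flat_rate=15.0
        )
        b = patient_total_cost(make_record(), ctx)
        assert b.laboratory == 15.0
        assert b.total == pytest.approx(15.0)

    def test_empty_record_with_zero_shares_is_all_zero(self, price_table, wage_schedule):
        ctx = CostingContext(
            unit_table=price_table, wage_schedule=wage_schedule, lab_flat_rate=0.0
        )
        b = patient_total_cost(make_record(), ctx)
        assert all(getattr(b, c) == 0.0 for c in COMPONENTS)
        assert b.total == 0.0

    def test_matches_brute_force_event_loop_on_random_records(self, ctx, price_table):
        rnd = random.Random(42)
        drugs = [e.item_name for e in price_table.entries]
        for _ in range(200):
            rec = random_record(rnd, drugs)
            assert patient_total_cost(rec, ctx).total == pytest.approx(
                brute_force_breakdown(rec, ctx), rel=1e-12, abs=1e-12
            )

    def test_unresolvable_price_carries_patient_id(self, ctx):
        rec = make_record("p99", dispenses=(MedicationDispense("Nonexistium", 1, 0),))
        with pytest.raises(CostingError, match="p99"):
            patient_total_cost(rec, ctx)

    def test_censoring_never_increases_any_component(self, ctx, price_table):
        rnd = random.Random(7)
        drugs = [e.item_name for e in price_table.entries]
        for _ in range(50):
            rec = random_record(rnd, drugs)
            d2 = rnd.randint(0, 120)
            d1 = rnd.randint(0, d2)
            late = patient_total_cost(apply_death_censoring(rec, d2), ctx)
            early = patient_total_cost(apply_death_censoring(rec, d1), ctx)
            for c in COMPONENTS:
                assert getattr(early, c) <= getattr(late, c) + 1e-12

    def test_scale_equivariance(self, price_table):
        # multiplying every price and wage by c multiplies every component by c
        c = 3.5
        rnd = random.Random(1)
        drugs = [e.item_name for e in price_table.entries]
        rec = random_record(rnd, drugs)
        base_ws = WageSchedule(wages={"physician": (1600.0, 160.0), "nurse": (640.0, 160.0)})
        scaled_ws = WageSchedule(
            wages={"physician": (1600.0 * c, 160.0), "nurse": (640.0 * c, 160.0)}
        )
        from microcost.unit_costs import PriceEntry, UnitCostTable

        scaled_table = UnitCostTable(
            entries=[
                PriceEntry(e.item_name, e.unit_price * c, e.dosage, e.category)
                for e in price_table.entries
            ]
        )
        ctx1 = CostingContext(unit_table=price_table, wage_schedule=base_ws,
                              per_day_overhead=10.0, lab_flat_rate=15.0)
        ctx2 = CostingContext(unit_table=scaled_table, wage_schedule=scaled_ws,
                              per_day_overhead=10.0 * c, lab_flat_rate=15.0 * c)
        b1, b2 = patient_total_cost(rec, ctx1), patient_total_cost(rec, ctx2)
        for comp in COMPONENTS:
            assert getattr(b2, comp) == pytest.approx(c * getattr(b1, comp), rel=1e-12)

    def test_cohort_conservation(self, ctx, price_table):
        rnd = random.Random(3)
        drugs = [e.item_name for e in price_table.entries]
        cohort = cost_cohort([random_record(rnd, drugs) for _ in range(30)], ctx)
        grand = sum(b.total for b in cohort)
        by_component = sum(sum(getattr(b, c) for b in cohort) for c in COMPONENTS)
        assert grand == pytest.approx(by_component, rel=1e-9)


class TestImputation:
    cohort = [
        CostBreakdown("a", physician=10.0),
        CostBreakdown("b", physician=20.0),
        CostBreakdown("c", physician=999.0),
    ]

    def test_mean_imputation(self):
        out = impute_missing_visit_costs(self.cohort, {"c": ["physician"]})
        assert out[2].physician == pytest.approx(15.0)
        assert out[0].physician == 10.0

    def test_no_flags_changes_nothing(self):
        out = impute_missing_visit_costs(self.cohort, {})
        assert [b.physician for b in out] == [10.0, 20.0, 999.0]

    def test_imputed_mean_equals_complete_case_mean(self):
        out = impute_missing_visit_costs(self.cohort, {"c": ["physician"]})
        imputed_mean = sum(b.physician for b in out) / 3
        assert imputed_mean == pytest.approx(15.0)

    def test_all_missing_component_is_an_error(self):
        with pytest.raises(ValueError, match="physician"):
            impute_missing_visit_costs(
                self.cohort, {pid: ["physician"] for pid in "abc"}
            )


def test_round_half_up_at_two_decimals():
    assert round_half_up(2.345) == 2.35
    assert round_half_up(2.344) == 2.34
    assert round_half_up(15.005) == 15.01
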