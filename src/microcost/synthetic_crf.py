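"""Synthetic case-report-form cohorts.

No patient-level data from the underlying paediatric HIV trials is
deposited anywhere, so every downstream costing stage is exercised on
synthetic cohorts whose event streams carry the statistical structure
the costing analysis assumes: two arms (cotrimoxazole prophylaxis
vs. antiretroviral therapy), Poisson visit and hospitalisation counts,
heavy-tailed lengths of stay with the arm-specific hard caps the trials
observed (77 days in the cotrimoxazole cohort, 37 in the ARV cohort),
hospitalisation causes drawn from the published opportunistic-infection
frequency table, medication dispenses per event, laboratory panels at
nursing visits, and censoring of the event stream at death.

Days are integer offsets from enrolment (day 0), closed interval.
Randomness flows from one master seed; each patient gets a substream
derived from (seed, patient index), so enlarging a cohort never
reshuffles earlier patients.
"""

from __future__ import annotations

import csv
import io
import json
import hashlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ArmConfig",
    "LosDistribution",
    "DispenseSpec",
    "Visit",
    "Hospitalisation",
    "MedicationDispense",
    "LabTest",
    "PatientRecord",
    "generate_cohort",
    "apply_death_censoring",
    "sample_oi_events",
    "load_oi_table",
    "default_oi_table",
    "chap_preset",
    "chapas_preset",
    "cohort_to_frames",
    "write_cohort",
    "cohort_digest",
]

DEFAULT_LAB_PANEL = ("haematology", "biochemistry", "lymphocyte subsets", "microbiology")


# ---------------------------------------------------------------------------
# configuration


class LosDistribution(BaseModel):
    """Length-of-stay model: lognormal rounded to whole days, hard-capped.

    ``median_days`` is the median of the underlying lognormal;
    ``sigma`` its log-scale spread (larger => heavier right tail);
    ``cap_days`` the arm's maximum admissible stay.
    """

    model_config = ConfigDict(extra="forbid")

    dist: str = "lognormal"
    median_days: float = Field(gt=0)
    sigma: float = Field(ge=0)
    cap_days: int = Field(gt=0)

    @model_validator(mode="after")
    def _check_dist(self) -> "LosDistribution":
        if self.dist != "lognormal":
            raise ValueError(f"los_distribution.dist must be 'lognormal', got {self.dist!r}")
        return self

    def sample(self, rng: np.random.Generator) -> int:
        raw = rng.lognormal(mean=np.log(self.median_days), sigma=self.sigma)
        return int(np.clip(round(raw), 1, self.cap_days))


class DispenseSpec(BaseModel):
    """Per-event medication rule: at each triggering event the drug is
    dispensed with probability ``probability`` and a Poisson dose count.

    ``setting`` selects the trigger: ``outpatient`` specs fire at each
    physician visit, ``inpatient`` specs at each hospitalisation (with
    ``per_day=True`` the Poisson mean scales with the length of stay).
    """

    model_config = ConfigDict(extra="forbid")

    drug_name: str
    mean_doses: float = Field(ge=0)
    probability: float = Field(default=1.0, ge=0, le=1)
    setting: str = "outpatient"
    per_day: bool = False

    @model_validator(mode="after")
    def _check_setting(self) -> "DispenseSpec":
        if self.setting not in ("outpatient", "inpatient"):
            raise ValueError(f"dispense setting must be outpatient|inpatient, got {self.setting!r}")
        return self


class ArmConfig(BaseModel):
    """Everything needed to simulate one trial arm's CRF streams."""

    model_config = ConfigDict(extra="forbid")

    arm_label: str
    n_patients: int = Field(gt=0)
    followup_days: int = Field(gt=0)
    mortality_prob: float = Field(ge=0, le=1)
    physician_visit_rate: float = Field(ge=0)
    nursing_visit_rate: float = Field(ge=0)
    hosp_episode_rate: float = Field(ge=0)
    los_distribution: LosDistribution
    oi_frequency_table: dict[str, float]
    dispense_model: list[DispenseSpec] = Field(default_factory=list)
    seed: int = 0
    physician_visit_hours: float = Field(default=0.5, gt=0)
    nursing_visit_hours: float = Field(default=0.5, gt=0)
    lab_panel: tuple[str, ...] = DEFAULT_LAB_PANEL

    @model_validator(mode="after")
    def _check(self) -> "ArmConfig":
        if self.arm_label not in ("cotrimoxazole", "arv"):
            raise ValueError(f"arm_label must be cotrimoxazole|arv, got {self.arm_label!r}")
        if not self.oi_frequency_table:
            raise ValueError("oi_frequency_table must be non-empty")
        if any(v < 0 for v in self.oi_frequency_table.values()):
            raise ValueError("oi_frequency_table frequencies must be >= 0")
        if sum(self.oi_frequency_table.values()) <= 0:
            raise ValueError("oi_frequency_table must have positive total frequency")
        return self


# ---------------------------------------------------------------------------
# event records


@dataclass(frozen=True)
class Visit:
    day: int
    cadre: str  # physician | nurse
    duration: float  # hours
    setting: str = "outpatient"  # outpatient | inpatient


@dataclass(frozen=True)
class MedicationDispense:
    drug_name: str
    doses: int
    day: int


@dataclass(frozen=True)
class LabTest:
    test_name: str
    day: int


@dataclass(frozen=True)
class Hospitalisation:
    start_day: int
    length_of_stay: int
    cause: str = ""
    dispenses_during_stay: tuple[MedicationDispense, ...] = ()


@dataclass(frozen=True)
class PatientRecord:
    """One child's full CRF event stream — the unit of costing."""

    patient_id: str
    arm_label: str
    death_day: int | None = None
    visits: tuple[Visit, ...] = ()
    hospitalisations: tuple[Hospitalisation, ...] = ()
    dispenses: tuple[MedicationDispense, ...] = ()
    lab_tests: tuple[LabTest, ...] = ()

    def last_event_day(self) -> int | None:
        days = [v.day for v in self.visits]
        days += [h.start_day + h.length_of_stay - 1 for h in self.hospitalisations]
        days += [d.day for d in self.dispenses]
        days += [t.day for t in self.lab_tests]
        return max(days) if days else None


# ---------------------------------------------------------------------------
# opportunistic-infection tables


def load_oi_table(source: str | Path | IO[str]) -> dict[str, float]:
    """Read a condition -> frequency table from CSV (condition, frequency).

    Duplicate condition labels aggregate their frequencies.
    """
    text = source.read() if hasattr(source, "read") else Path(source).read_text("utf-8")
    reader = csv.DictReader(io.StringIO(text))
    if not reader.fieldnames or not {"condition", "frequency"} <= set(reader.fieldnames):
        raise ValueError("OI table CSV needs headers: condition, frequency")
    table: dict[str, float] = {}
    for row in reader:
        table[row["condition"]] = table.get(row["condition"], 0.0) + float(row["frequency"])
    if not table:
        raise ValueError("OI table is empty")
    return table


def default_oi_table() -> dict[str, float]:
    """The bundled clinical-staging condition frequencies (23 conditions)."""
    from importlib import resources

    ref = resources.files("microcost.data").joinpath("oi_conditions_staging.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return load_oi_table(fh)


# ---------------------------------------------------------------------------
# generation


def _patient_rng(master_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master_seed, index]))


def _sample_cause(oi_table: Mapping[str, float], rng: np.random.Generator) -> str:
    names = list(oi_table)
    freqs = np.asarray([oi_table[n] for n in names], dtype=float)
    p = freqs / freqs.sum()
    return names[rng.choice(len(names), p=p)]


def _dispenses_for_event(
    specs: Sequence[DispenseSpec],
    setting: str,
    day: int,
    los: int,
    rng: np.random.Generator,
) -> list[MedicationDispense]:
    out = []
    for spec in specs:
        if spec.setting != setting:
            continue
        if spec.probability < 1 and rng.random() >= spec.probability:
            continue
        mean = spec.mean_doses * (los if (setting == "inpatient" and spec.per_day) else 1)
        doses = int(rng.poisson(mean))
        if doses > 0:
            out.append(MedicationDispense(drug_name=spec.drug_name, doses=doses, day=day))
    return out


def _generate_patient(config: ArmConfig, index: int) -> PatientRecord:
    rng = _patient_rng(config.seed, index)
    F = config.followup_days

    dies = rng.random() < config.mortality_prob
    death_day = int(rng.integers(0, F + 1)) if dies else None

    visits: list[Visit] = []
    dispenses: list[MedicationDispense] = []
    labs: list[LabTest] = []

    n_phys = rng.poisson(config.physician_visit_rate)
    for day in sorted(int(d) for d in rng.integers(0, F + 1, size=n_phys)):
        visits.append(Visit(day=day, cadre="physician", duration=config.physician_visit_hours))
        dispenses.extend(
            _dispenses_for_event(config.dispense_model, "outpatient", day, 0, rng)
        )

    n_nurse = rng.poisson(config.nursing_visit_rate)
    for day in sorted(int(d) for d in rng.integers(0, F + 1, size=n_nurse)):
        visits.append(Visit(day=day, cadre="nurse", duration=config.nursing_visit_hours))
        labs.extend(LabTest(test_name=t, day=day) for t in config.lab_panel)

    hosps: list[Hospitalisation] = []
    n_hosp = rng.poisson(config.hosp_episode_rate)
    for _ in range(n_hosp):
        start = int(rng.integers(0, F + 1))
        los = config.los_distribution.sample(rng)
        cause = _sample_cause(config.oi_frequency_table, rng)
        stay_dispenses = _dispenses_for_event(
            config.dispense_model, "inpatient", start, los, rng
        )
        hosps.append(
            Hospitalisation(
                start_day=start,
                length_of_stay=los,
                cause=cause,
                dispenses_during_stay=tuple(stay_dispenses),
            )
        )
    hosps.sort(key=lambda h: h.start_day)

    record = PatientRecord(
        patient_id=f"{config.arm_label}-{index:05d}",
        arm_label=config.arm_label,
        death_day=None,
        visits=tuple(visits),
        hospitalisations=tuple(hosps),
        dispenses=tuple(dispenses),
        lab_tests=tuple(labs),
    )
    # stays must end inside follow-up even for survivors
    record = _truncate_at(record, F)
    if death_day is not None:
        record = apply_death_censoring(record, death_day)
    return record


def generate_cohort(config: ArmConfig) -> list[PatientRecord]:
    """Simulate one arm: exactly ``n_patients`` records, deterministic in the seed."""
    return [_generate_patient(config, i) for i in range(config.n_patients)]


def _truncate_at(record: PatientRecord, last_day: int) -> PatientRecord:
    """Drop events after ``last_day``; clip straddling hospital stays."""
    hosps = []
    for h in record.hospitalisations:
        if h.start_day > last_day:
            continue
        los = min(h.length_of_stay, last_day - h.start_day + 1)
        stay_disp = tuple(d for d in h.dispenses_during_stay if d.day <= last_day)
        hosps.append(replace(h, length_of_stay=los, dispenses_during_stay=stay_disp))
    return replace(
        record,
        visits=tuple(v for v in record.visits if v.day <= last_day),
        hospitalisations=tuple(hosps),
        dispenses=tuple(d for d in record.dispenses if d.day <= last_day),
        lab_tests=tuple(t for t in record.lab_tests if t.day <= last_day),
    )


def apply_death_censoring(record: PatientRecord, death_day: int) -> PatientRecord:
    """Censor the event stream at death: no resource accrues past ``death_day``.

    Events on or before the death day are unchanged; a hospital stay that
    straddles it is clipped so the stay ends on the death day.
    """
    if death_day < 0:
        raise ValueError(f"death_day must be >= 0, got {death_day}")
    return replace(_truncate_at(record, death_day), death_day=death_day)


def sample_oi_events(
    record: PatientRecord,
    oi_table: Mapping[str, float],
    rng: np.random.Generator,
) -> PatientRecord:
    """Assign each hospitalisation a cause drawn proportionally to table frequency."""
    if not oi_table:
        raise ValueError("oi_table must be non-empty")
    names = list(oi_table)
    freqs = np.asarray([oi_table[n] for n in names], dtype=float)
    draws = rng.choice(len(names), size=len(record.hospitalisations), p=freqs / freqs.sum())
    hosps = tuple(
        replace(h, cause=names[j]) for h, j in zip(record.hospitalisations, draws)
    )
    return replace(record, hospitalisations=hosps)


# ---------------------------------------------------------------------------
# presets: the two trial arms as published


def chap_preset(seed: int = 0, **overrides) -> ArmConfig:
    """Cotrimoxazole-prophylaxis arm: 265 children randomised to cotrimoxazole,
    pooled two-arm mortality 186/534, admissions up to 77 days.

    The trial randomised 265 to cotrimoxazole and 269 to placebo (534 in
    all; the published enrolment counts upstream of randomisation are
    larger and mutually inconsistent, so the randomised total is used).
    Only the cumulative mortality is published, so deaths fall uniformly
    over follow-up.
    """
    params = dict(
        arm_label="cotrimoxazole",
        n_patients=265,
        followup_days=672,
        mortality_prob=186 / 534,
        physician_visit_rate=11.0,
        nursing_visit_rate=0.65,
        hosp_episode_rate=1.5,
        los_distribution=LosDistribution(median_days=7.0, sigma=0.9, cap_days=77),
        oi_frequency_table=default_oi_table(),
        dispense_model=[
            DispenseSpec(drug_name="Cotrimoxazole", mean_doses=30, setting="outpatient"),
            DispenseSpec(
                drug_name="Ceftriaxone", mean_doses=2, setting="inpatient", per_day=True
            ),
            DispenseSpec(
                drug_name="Coartem", mean_doses=6, probability=0.3, setting="inpatient"
            ),
        ],
        seed=seed,
    )
    params.update(overrides)
    return ArmConfig(**params)


def chapas_preset(seed: int = 0, **overrides) -> ArmConfig:
    """ARV arm: 211 children on fixed-dose-combination paediatric ART,
    22 deaths out of 211, admissions up to 37 days."""
    params = dict(
        arm_label="arv",
        n_patients=211,
        followup_days=336,
        mortality_prob=22 / 211,
        physician_visit_rate=14.2,
        nursing_visit_rate=8.0,
        hosp_episode_rate=0.3,
        los_distribution=LosDistribution(median_days=4.0, sigma=0.7, cap_days=37),
        oi_frequency_table=default_oi_table(),
        dispense_model=[
            DispenseSpec(drug_name="Pedimune Baby", mean_doses=56, setting="outpatient"),
            DispenseSpec(
                drug_name="Amoxycillin", mean_doses=3, setting="inpatient", per_day=True
            ),
        ],
        seed=seed,
    )
    params.update(overrides)
    return ArmConfig(**params)


# ---------------------------------------------------------------------------
# serialisation


def cohort_to_frames(records: Sequence[PatientRecord]) -> dict[str, pd.DataFrame]:
    """Five event tables, one row per event, keyed by patient_id."""
    patients, visits, hosps, disps, labs = [], [], [], [], []
    for r in records:
        patients.append(
            {
                "patient_id": r.patient_id,
                "arm_label": r.arm_label,
                "death_day": "" if r.death_day is None else r.death_day,
            }
        )
        for v in r.visits:
            visits.append(
                {
                    "patient_id": r.patient_id,
                    "day": v.day,
                    "cadre": v.cadre,
                    "duration": v.duration,
                    "setting": v.setting,
                }
            )
        for i, h in enumerate(r.hospitalisations):
            hosps.append(
                {
                    "patient_id": r.patient_id,
                    "episode": i,
                    "start_day": h.start_day,
                    "length_of_stay": h.length_of_stay,
                    "cause": h.cause,
                }
            )
            for d in h.dispenses_during_stay:
                disps.append(
                    {
                        "patient_id": r.patient_id,
                        "day": d.day,
                        "drug_name": d.drug_name,
                        "doses": d.doses,
                        "setting": "inpatient",
                        "episode": i,
                    }
                )
        for d in r.dispenses:
            disps.append(
                {
                    "patient_id": r.patient_id,
                    "day": d.day,
                    "drug_name": d.drug_name,
                    "doses": d.doses,
                    "setting": "outpatient",
                    "episode": "",
                }
            )
        for t in r.lab_tests:
            labs.append({"patient_id": r.patient_id, "day": t.day, "test_name": t.test_name})
    return {
        "patients": pd.DataFrame(
            patients, columns=["patient_id", "arm_label", "death_day"]
        ),
        "visits": pd.DataFrame(
            visits, columns=["patient_id", "day", "cadre", "duration", "setting"]
        ),
        "hospitalisations": pd.DataFrame(
            hosps, columns=["patient_id", "episode", "start_day", "length_of_stay", "cause"]
        ),
        "dispenses": pd.DataFrame(
            disps, columns=["patient_id", "day", "drug_name", "doses", "setting", "episode"]
        ),
        "lab_tests": pd.DataFrame(labs, columns=["patient_id", "day", "test_name"]),
    }


def frames_to_cohort(frames: Mapping[str, pd.DataFrame]) -> list[PatientRecord]:
    """Rebuild PatientRecords from the five event tables."""
    records = []
    visits_by = _group(frames["visits"])
    hosps_by = _group(frames["hospitalisations"])
    disps_by = _group(frames["dispenses"])
    labs_by = _group(frames["lab_tests"])
    for row in frames["patients"].itertuples(index=False):
        pid = row.patient_id
        death = row.death_day
        death_day = None if (death == "" or pd.isna(death)) else int(death)
        vrows = visits_by.get(pid, [])
        drows = disps_by.get(pid, [])
        hrows = hosps_by.get(pid, [])
        trows = labs_by.get(pid, [])
        in_stay: dict[int, list[MedicationDispense]] = {}
        out_disp = []
        for d in drows:
            md = MedicationDispense(drug_name=d["drug_name"], doses=int(d["doses"]), day=int(d["day"]))
            if d["setting"] == "inpatient":
                in_stay.setdefault(int(d["episode"]), []).append(md)
            else:
                out_disp.append(md)
        hosps = tuple(
            Hospitalisation(
                start_day=int(h["start_day"]),
                length_of_stay=int(h["length_of_stay"]),
                cause=h["cause"],
                dispenses_during_stay=tuple(in_stay.get(int(h["episode"]), [])),
            )
            for h in hrows
        )
        records.append(
            PatientRecord(
                patient_id=pid,
                arm_label=row.arm_label,
                death_day=death_day,
                visits=tuple(
                    Visit(
                        day=int(v["day"]),
                        cadre=v["cadre"],
                        duration=float(v["duration"]),
                        setting=v["setting"],
                    )
                    for v in vrows
                ),
                hospitalisations=hosps,
                dispenses=tuple(out_disp),
                lab_tests=tuple(
                    LabTest(test_name=t["test_name"], day=int(t["day"])) for t in trows
                ),
            )
        )
    return records


def _group(frame: pd.DataFrame) -> dict[str, list[dict]]:
    out: dict[str, list[dict]] = {}
    for rec in frame.to_dict("records"):
        out.setdefault(rec["patient_id"], []).append(rec)
    return out


def write_cohort(
    records: Sequence[PatientRecord],
    outdir: str | Path,
    config: ArmConfig | None = None,
) -> dict[str, Path]:
    """Write the five event CSVs plus a JSON manifest recording config and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = cohort_to_frames(records)
    paths = {}
    for name, frame in frames.items():
        p = outdir / f"{name}.csv"
        frame.to_csv(p, index=False, lineterminator="\n")
        paths[name] = p
    manifest = {
        "n_patients": len(records),
        "config": None if config is None else json.loads(config.model_dump_json()),
        "seed": None if config is None else config.seed,
        "digest": cohort_digest(records),
    }
    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    paths["manifest"] = mp
    return paths


def cohort_digest(records: Sequence[PatientRecord]) -> str:
    """SHA-256 of the serialised event tables; equal seeds give equal digests."""
    frames = cohort_to_frames(records)
    h = hashlib.sha256()
    for name in sorted(frames):
        h.update(name.encode())
        h.update(frames[name].to_csv(index=False, lineterminator="\n").encode())
    return h.hexdigest()
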