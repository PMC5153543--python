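"""End-to-end orchestration: generate (or load) cohorts, cost them, summarise.

A run is a pure function of (config, master seed): each arm draws its
generator seed from the master seed, every output CSV/JSON is written
deterministically, and a manifest records the config hash and seed so a
rerun can be checked by file checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .engine import (
    CostingContext,
    WageSchedule,
    breakdowns_to_frame,
    cost_cohort,
)
from .overhead import (
    DEFAULT_DISCOUNT_RATE,
    OverheadLedger,
    allocate_overhead,
    equivalent_annual_cost,
    load_asset_register,
    CapitalAsset,
    per_day_overhead_rate,
)
from .summary import bootstrap_mean_ci, oi_frequency_table, skewness, summarise_cohort
from .synthetic_crf import (
    ArmConfig,
    chap_preset,
    chapas_preset,
    cohort_digest,
    generate_cohort,
    write_cohort,
)
from .unit_costs import UnitCostTable, bundled_price_table, load_price_table

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]

_PRESETS = {"chap": chap_preset, "chapas": chapas_preset}


class ConfigError(ValueError):
    """Invalid run configuration; ``violations`` lists every problem found."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {v}" for v in violations))


class WageEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")
    monthly_wage: float = Field(ge=0)
    monthly_hours: float = Field(gt=0)


class ArmSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    preset: str | None = None  # chap | chapas | None (fully explicit config)
    config: dict[str, Any] = Field(default_factory=dict)
    wages: dict[str, WageEntry] = Field(
        default_factory=lambda: {
            "physician": WageEntry(monthly_wage=1600.0, monthly_hours=160.0),
            "nurse": WageEntry(monthly_wage=640.0, monthly_hours=160.0),
        }
    )


class OverheadSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ledger: dict[str, float] | str = Field(default_factory=dict)  # inline lines or CSV path
    weights: dict[str, float] = Field(default_factory=dict)
    bed_days: float = Field(default=3650.0, gt=0)


class CapitalSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    assets: list[dict[str, Any]] | str = Field(default_factory=list)
    discount_rate: float = Field(default=DEFAULT_DISCOUNT_RATE, ge=0)
    allocation_weight: float = Field(default=0.0, ge=0, le=1)
    horizon_weeks: float = Field(default=96.0, gt=0)


class LabSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pricing: str = "flat_panel"
    flat_rate: float = Field(default=15.0, ge=0)


class BootstrapSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_resamples: int = Field(default=10_000, ge=1)
    level: float = Field(default=0.95, gt=0, lt=1)


class RunConfig(BaseModel):
    """Schema for one reproducible pipeline run."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    arms: list[ArmSection] = Field(min_length=1)
    price_tables: list[str] = Field(default_factory=lambda: ["bundled:all"])
    overhead: OverheadSection = Field(default_factory=OverheadSection)
    capital: CapitalSection = Field(default_factory=CapitalSection)
    lab: LabSection = Field(default_factory=LabSection)
    outpatient_fixed_share: float = Field(default=0.0, ge=0)
    bootstrap: BootstrapSection = Field(default_factory=BootstrapSection)
    export_histograms: bool = False


def _format_violation(err: dict) -> str:
    loc = ".".join(str(p) for p in err["loc"]) or "<root>"
    return f"{loc}: {err['msg']}"


def validate_config(path: str | Path) -> RunConfig:
    """Parse and schema-check a YAML/JSON run config; report all violations."""
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError([f"cannot parse {path}: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError([f"config root must be a mapping, got {type(raw).__name__}"])
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError([_format_violation(e) for e in exc.errors()]) from exc
    violations: list[str] = []
    for i, arm in enumerate(cfg.arms):
        try:
            build_arm_config(arm, cfg.seed, i)
        except ConfigError as exc:
            violations.extend(exc.violations)
    if violations:
        raise ConfigError(violations)
    return cfg


def _load_price_tables(specs: Sequence[str], base_dir: Path) -> UnitCostTable:
    table: UnitCostTable | None = None
    for spec in specs:
        if spec.startswith("bundled:"):
            t = bundled_price_table(spec.split(":", 1)[1])
        else:
            p = Path(spec)
            if not p.is_absolute():
                p = base_dir / p
            if not p.exists():
                raise FileNotFoundError(f"price table not found: {p}")
            t = load_price_table(p)
        table = t if table is None else table.merged(t)
    assert table is not None
    return table


def _arm_seed(master_seed: int, arm_index: int) -> int:
    ss = np.random.SeedSequence([master_seed, arm_index])
    return int(ss.generate_state(1)[0] % (2**31))


def build_arm_config(section: ArmSection, master_seed: int, arm_index: int) -> ArmConfig:
    seed = _arm_seed(master_seed, arm_index)
    if section.preset is not None and section.preset not in _PRESETS:
        raise ConfigError([f"arms[{arm_index}].preset: unknown preset {section.preset!r}"])
    try:
        if section.preset is not None:
            return _PRESETS[section.preset](seed=seed, **section.config)
        return ArmConfig(seed=seed, **section.config)
    except ValidationError as exc:
        raise ConfigError(
            [f"arms[{arm_index}].config.{_format_violation(e)}" for e in exc.errors()]
        ) from exc
    except TypeError as exc:  # unknown keyword passed through a preset
        raise ConfigError([f"arms[{arm_index}].config: {exc}"]) from exc


def _capital_assets(section: CapitalSection, base_dir: Path) -> list[CapitalAsset]:
    if isinstance(section.assets, str):
        p = Path(section.assets)
        if not p.is_absolute():
            p = base_dir / p
        if not p.exists():
            raise FileNotFoundError(f"asset register not found: {p}")
        return load_asset_register(p)
    return [CapitalAsset(**a) for a in section.assets]


def build_costing_context(
    config: RunConfig, arm: ArmSection, n_patients: int, base_dir: Path
) -> CostingContext:
    """Resolve a run config into the per-arm price/overhead context."""
    unit_table = _load_price_tables(config.price_tables, base_dir)
    wages = WageSchedule(
        wages={
            cadre: (w.monthly_wage, w.monthly_hours) for cadre, w in arm.wages.items()
        }
    )
    # shared overhead -> per-bed-day rate
    if isinstance(config.overhead.ledger, str):
        p = Path(config.overhead.ledger)
        if not p.is_absolute():
            p = base_dir / p
        ledger = OverheadLedger.from_csv(p)
    else:
        ledger = OverheadLedger(config.overhead.ledger)
    if ledger.lines:
        allocated = allocate_overhead(ledger, config.overhead.weights)
        per_day = per_day_overhead_rate(sum(allocated.values()), config.overhead.bed_days)
    else:
        per_day = 0.0
    # annuitised capital -> per-patient share over the analysis horizon
    assets = _capital_assets(config.capital, base_dir)
    annual_capital = sum(
        equivalent_annual_cost(a, config.capital.discount_rate) for a in assets
    )
    horizon_years = config.capital.horizon_weeks / 52.0
    capital_share = (
        annual_capital * config.capital.allocation_weight * horizon_years / n_patients
        if assets
        else 0.0
    )
    return CostingContext(
        unit_table=unit_table,
        wage_schedule=wages,
        per_day_overhead=per_day,
        capital_share_per_patient=capital_share,
        lab_flat_rate=config.lab.flat_rate,
        lab_pricing=config.lab.pricing,
        outpatient_fixed_share=config.outpatient_fixed_share,
    )


def run_pipeline(config: RunConfig, outdir: str | Path, base_dir: str | Path = ".") -> dict:
    """Execute generate -> cost -> summarise for every arm; write the report bundle.

    Returns the manifest dict (also written to ``outdir/manifest.json``).
    """
    outdir = Path(outdir)
    base_dir = Path(base_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    summaries = []
    arm_entries = []
    for i, arm_section in enumerate(config.arms):
        arm_cfg = build_arm_config(arm_section, config.seed, i)
        records = generate_cohort(arm_cfg)
        ctx = build_costing_context(config, arm_section, arm_cfg.n_patients, base_dir)

        arm_dir = outdir / f"arm_{i}_{arm_cfg.arm_label}"
        write_cohort(records, arm_dir / "cohort", config=arm_cfg)

        cohort_costs = cost_cohort(records, ctx)
        frame = breakdowns_to_frame(cohort_costs, rounded=True)
        frame.to_csv(arm_dir / "breakdowns.csv", index=False, lineterminator="\n")

        summaries.append(summarise_cohort(cohort_costs, arm_label=arm_cfg.arm_label))

        causes = [h.cause for r in records for h in r.hospitalisations]
        if causes:
            oi = oi_frequency_table(causes)
            oi.to_frame().to_csv(arm_dir / "oi_table.csv", index=False, lineterminator="\n")

        totals = [b.total for b in cohort_costs]
        boot = bootstrap_mean_ci(
            totals,
            n_resamples=config.bootstrap.n_resamples,
            level=config.bootstrap.level,
            seed=_arm_seed(config.seed, 1000 + i),
        )
        deaths = sum(1 for r in records if r.death_day is not None)
        arm_json = {
            "arm_label": arm_cfg.arm_label,
            "n_patients": arm_cfg.n_patients,
            "deaths": deaths,
            "mean_total_cost": boot.point_estimate,
            "bootstrap_ci": [boot.ci_low, boot.ci_high],
            "bootstrap_level": boot.level,
            "n_resamples": boot.n_resamples,
            "skewness_total_cost": skewness(totals) if len(set(totals)) > 2 else None,
            "cohort_digest": cohort_digest(records),
        }
        (arm_dir / "summary.json").write_text(
            json.dumps(arm_json, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        arm_entries.append(arm_json)

        if config.export_histograms:
            from .summary import export_cost_histogram

            export_cost_histogram(
                totals,
                arm_dir / "total_cost_hist.png",
                title=f"Per-patient total cost — {arm_cfg.arm_label}",
            )

    table4 = pd.concat(summaries, ignore_index=True)
    table4.to_csv(outdir / "cost_summary.csv", index=False, lineterminator="\n")

    cfg_json = config.model_dump_json()
    manifest = {
        "microcost_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "arms": arm_entries,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
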