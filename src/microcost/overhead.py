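"""Capital annuitisation and direct allocation of shared hospital costs.

Capital outlays (buildings, vehicles, laboratory equipment) are converted
to an equivalent annual cost with the standard annuity factor

    a(r, n) = (1 - (1 + r)^-n) / r        (= n when r = 0),

using a 3% discount rate by default, over 40 years for buildings and
5 years for vehicles and equipment.  Facility-wide overhead lines
(administration, security, laundry, catering, utilities) are apportioned
to the programme in one step — direct allocation — by either the share
of floor space the programme occupies or its share of the inpatient
load.  The per-day overhead ("hotel") rate then spreads the allocated
annual amount over the facility's bed-days.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping

__all__ = [
    "CapitalAsset",
    "OverheadLedger",
    "AllocationBasis",
    "annuity_factor",
    "equivalent_annual_cost",
    "allocation_weight",
    "allocate_overhead",
    "per_day_overhead_rate",
    "DEFAULT_USEFUL_LIFE",
    "DEFAULT_DISCOUNT_RATE",
]

ASSET_CATEGORIES = ("building", "vehicle", "lab_equipment")

#: Default useful lives in years; buildings 40, other assets 5.
DEFAULT_USEFUL_LIFE = {"building": 40, "vehicle": 5, "lab_equipment": 5}

DEFAULT_DISCOUNT_RATE = 0.03


@dataclass(frozen=True)
class CapitalAsset:
    asset_name: str
    replacement_cost: float
    useful_life: int
    category: str = "building"

    def __post_init__(self) -> None:
        if self.replacement_cost < 0:
            raise ValueError(f"replacement_cost of {self.asset_name!r} must be >= 0")
        if self.useful_life < 1:
            raise ValueError(f"useful_life of {self.asset_name!r} must be >= 1 year")
        if self.category not in ASSET_CATEGORIES:
            raise ValueError(
                f"category of {self.asset_name!r} must be one of {ASSET_CATEGORIES}"
            )


@dataclass(frozen=True)
class OverheadLedger:
    """Annual facility-wide amounts per overhead line item."""

    lines: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, amount in self.lines.items():
            if amount < 0:
                raise ValueError(f"ledger line {name!r} must be >= 0, got {amount}")

    def total(self) -> float:
        return sum(self.lines.values())

    @classmethod
    def from_csv(cls, source: str | Path | IO[str]) -> "OverheadLedger":
        text = source.read() if hasattr(source, "read") else Path(source).read_text("utf-8")
        reader = csv.DictReader(io.StringIO(text))
        if not reader.fieldnames or not {"line_item", "annual_amount"} <= set(reader.fieldnames):
            raise ValueError("overhead ledger CSV needs headers: line_item, annual_amount")
        return cls({r["line_item"]: float(r["annual_amount"]) for r in reader})


def load_asset_register(source: str | Path | IO[str]) -> list[CapitalAsset]:
    """Read a capital-asset register CSV (asset_name, replacement_cost, useful_life, category)."""
    text = source.read() if hasattr(source, "read") else Path(source).read_text("utf-8")
    reader = csv.DictReader(io.StringIO(text))
    need = {"asset_name", "replacement_cost", "useful_life", "category"}
    if not reader.fieldnames or not need <= set(reader.fieldnames):
        raise ValueError(f"asset register CSV needs headers: {', '.join(sorted(need))}")
    return [
        CapitalAsset(
            asset_name=r["asset_name"],
            replacement_cost=float(r["replacement_cost"]),
            useful_life=int(r["useful_life"]),
            category=r["category"],
        )
        for r in reader
    ]


@dataclass(frozen=True)
class AllocationBasis:
    """A one-step allocation weight: programme measure over facility total.

    ``space_share`` uses floor area; ``patient_load_share`` uses inpatient
    admissions or bed-days.
    """

    basis_kind: str
    numerator: float
    denominator: float

    def __post_init__(self) -> None:
        if self.basis_kind not in ("space_share", "patient_load_share"):
            raise ValueError(
                f"basis_kind must be space_share or patient_load_share, got {self.basis_kind!r}"
            )
        if self.denominator <= 0:
            raise ValueError("allocation denominator must be > 0")
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("allocation numerator must lie in [0, denominator]")


def annuity_factor(rate: float, years: int) -> float:
    """Present value of a unit annual payment for ``years`` years at ``rate``.

    Continuous at rate -> 0, where the factor tends to ``years``.
    """
    if years < 1:
        raise ValueError(f"years must be >= 1, got {years}")
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if rate == 0:
        return float(years)
    # expm1/log1p form avoids cancellation as rate -> 0 (factor -> years)
    return -math.expm1(-years * math.log1p(rate)) / rate


def equivalent_annual_cost(asset: CapitalAsset, rate: float = DEFAULT_DISCOUNT_RATE) -> float:
    """Annuitised annual cost of a capital asset: replacement cost over the annuity factor."""
    return asset.replacement_cost / annuity_factor(rate, asset.useful_life)


def allocation_weight(basis: AllocationBasis) -> float:
    """The fraction of a shared cost attributable to the programme."""
    return basis.numerator / basis.denominator


def allocate_overhead(
    ledger: OverheadLedger, weights: Mapping[str, float]
) -> dict[str, float]:
    """Apportion each ledger line by its weight (direct allocation).

    Every line must have a weight in [0, 1]; the allocated total never
    exceeds the ledger total, with equality when all weights are 1.
    """
    allocated = {}
    for name, amount in ledger.lines.items():
        if name not in weights:
            raise ValueError(f"no allocation weight supplied for ledger line {name!r}")
        w = weights[name]
        if not 0 <= w <= 1:
            raise ValueError(f"weight for {name!r} must lie in [0, 1], got {w}")
        allocated[name] = amount * w
    return allocated


def per_day_overhead_rate(allocated_total: float, bed_days: float) -> float:
    """Allocated annual overhead spread over annual bed-days: currency per bed-day."""
    if bed_days <= 0:
        raise ValueError(f"bed_days must be > 0, got {bed_days}")
    return allocated_total / bed_days
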