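"""Unit-price tables and price-level adjustment.

The ingredients approach values every resource event at a unit price:
drugs at a price per dispensed dose, laboratory tests at a price per
test, wages per hour of contact time.  This module loads and validates
the price tables (the bundled ones hold the published ARV and
opportunistic-infection drug prices), computes course costs by per-dose
summation, and re-expresses nominal costs in a target year's prices via
a consumer-price-index ratio.

Name matching is case-insensitive and whitespace-normalised; an unknown
item is always an error, never a silent zero.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping

__all__ = [
    "PriceEntry",
    "UnitCostTable",
    "CpiSeries",
    "load_price_table",
    "write_price_table",
    "bundled_price_table",
    "course_cost",
    "cpi_adjust",
    "lab_panel_cost",
]

CATEGORIES = ("arv", "oi_drug", "lab_test", "other")

REQUIRED_HEADERS = ("item_name", "dosage", "unit_price", "category")


class PriceTableError(ValueError):
    """Raised for malformed or inconsistent price tables."""


def _normalise(name: str) -> str:
    return " ".join(name.split()).lower()


@dataclass(frozen=True)
class PriceEntry:
    """One priced item: a drug dose, a lab test, or another unit input.

    ``dosage`` is the printed dose descriptor (e.g. ``"0.6 g"``) when the
    source table states one; the price is per one such dose unit.
    """

    item_name: str
    unit_price: float
    dosage: str | None = None
    category: str = "other"

    def __post_init__(self) -> None:
        if not self.item_name or not self.item_name.strip():
            raise PriceTableError("item_name must be non-empty")
        if self.unit_price < 0:
            raise PriceTableError(
                f"unit_price for {self.item_name!r} is negative ({self.unit_price})"
            )
        if self.category not in CATEGORIES:
            raise PriceTableError(
                f"category for {self.item_name!r} must be one of {CATEGORIES}, "
                f"got {self.category!r}"
            )


@dataclass
class UnitCostTable:
    """Item -> unit-price lookup with case-insensitive matching."""

    entries: list[PriceEntry]
    currency_year: int | None = None
    source_label: str = ""
    _index: dict[str, PriceEntry] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise PriceTableError("a UnitCostTable must contain at least one entry")
        index: dict[str, PriceEntry] = {}
        for entry in self.entries:
            key = _normalise(entry.item_name)
            if key in index:
                raise PriceTableError(f"duplicate item {entry.item_name!r} in price table")
            index[key] = entry
        self._index = index

    def __contains__(self, item_name: str) -> bool:
        return _normalise(item_name) in self._index

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, item_name: str) -> PriceEntry:
        try:
            return self._index[_normalise(item_name)]
        except KeyError:
            raise PriceTableError(
                f"item {item_name!r} not found in price table {self.source_label!r}"
            ) from None

    def price(self, item_name: str) -> float:
        return self.lookup(item_name).unit_price

    def merged(self, other: "UnitCostTable") -> "UnitCostTable":
        """Union of two tables; overlapping item names are an error."""
        return UnitCostTable(
            entries=self.entries + other.entries,
            currency_year=self.currency_year,
            source_label=f"{self.source_label}+{other.source_label}",
        )


def load_price_table(
    source: str | Path | IO[str],
    currency_year: int | None = None,
    source_label: str | None = None,
) -> UnitCostTable:
    """Read a price table from CSV with headers item_name, dosage, unit_price, category.

    An empty dosage cell means the item is priced per unit with no dose
    descriptor.  Duplicate names, negative prices and missing headers all
    raise :class:`PriceTableError`.
    """
    if hasattr(source, "read"):
        text = source.read()
        label = source_label or "<stream>"
    else:
        text = Path(source).read_text(encoding="utf-8")
        label = source_label or str(source)
    reader = csv.DictReader(io.StringIO(text))
    headers = reader.fieldnames or []
    missing = [h for h in REQUIRED_HEADERS if h not in headers]
    if missing:
        raise PriceTableError(f"price table {label!r} missing header(s): {', '.join(missing)}")
    entries = []
    for row in reader:
        dosage = (row["dosage"] or "").strip() or None
        try:
            price = float(row["unit_price"])
        except ValueError:
            raise PriceTableError(
                f"non-numeric unit_price {row['unit_price']!r} for {row['item_name']!r}"
            ) from None
        entries.append(
            PriceEntry(
                item_name=row["item_name"],
                dosage=dosage,
                unit_price=price,
                category=(row["category"] or "other").strip(),
            )
        )
    return UnitCostTable(entries=entries, currency_year=currency_year, source_label=label)


def write_price_table(table: UnitCostTable, dest: str | Path | IO[str]) -> None:
    """Write a table back to the canonical CSV layout (round-trips the bundled fixtures)."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(REQUIRED_HEADERS)
    for e in table.entries:
        writer.writerow([e.item_name, e.dosage or "", repr(e.unit_price), e.category])
    text = buf.getvalue()
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text, encoding="utf-8")


_BUNDLED = {
    "arv": "arv_prices.csv",
    "oi_drug": "oi_drug_prices.csv",
}


def bundled_price_table(which: str) -> UnitCostTable:
    """Load a bundled price table: ``"arv"``, ``"oi_drug"`` or ``"all"`` (their union)."""
    if which == "all":
        return bundled_price_table("arv").merged(bundled_price_table("oi_drug"))
    try:
        fname = _BUNDLED[which]
    except KeyError:
        raise PriceTableError(
            f"unknown bundled table {which!r}; choose from {sorted(_BUNDLED)} or 'all'"
        ) from None
    ref = resources.files("microcost.data").joinpath(fname)
    with ref.open("r", encoding="utf-8") as fh:
        return load_price_table(fh, source_label=fname)


def course_cost(dispenses: Iterable, table: UnitCostTable) -> float:
    """Cost of a medication course: sum of doses x unit price over all dispenses.

    ``dispenses`` are objects with ``drug_name`` and ``doses`` attributes
    (see :class:`microcost.synthetic_crf.MedicationDispense`).
    """
    total = 0.0
    for d in dispenses:
        total += d.doses * table.price(d.drug_name)
    return total


@dataclass(frozen=True)
class CpiSeries:
    """Consumer-price-index values per calendar year, for price-level adjustment.

    No index values are bundled: the CPI is an external statistic the user
    supplies (CSV with columns year, index).
    """

    values: Mapping[int, float]

    def __post_init__(self) -> None:
        for year, idx in self.values.items():
            if idx <= 0:
                raise ValueError(f"CPI index for {year} must be positive, got {idx}")

    @classmethod
    def from_csv(cls, source: str | Path | IO[str]) -> "CpiSeries":
        if hasattr(source, "read"):
            text = source.read()
        else:
            text = Path(source).read_text(encoding="utf-8")
        reader = csv.DictReader(io.StringIO(text))
        if not reader.fieldnames or not {"year", "index"} <= set(reader.fieldnames):
            raise ValueError("CPI CSV needs headers: year, index")
        return cls({int(r["year"]): float(r["index"]) for r in reader})

    def index(self, year: int) -> float:
        try:
            return self.values[year]
        except KeyError:
            raise ValueError(f"year {year} not present in CPI series") from None


def cpi_adjust(cost: float, series: CpiSeries, from_year: int, to_year: int) -> float:
    """Re-express ``cost`` from ``from_year`` prices in ``to_year`` prices.

    Multiplicative and exactly invertible: swapping the years recovers the
    original cost.
    """
    return cost * series.index(to_year) / series.index(from_year)


def lab_panel_cost(tests: Iterable, table: UnitCostTable) -> float:
    """Sum of unit prices over performed lab tests (objects with ``test_name``)."""
    return sum(table.price(t.test_name) for t in tests)
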