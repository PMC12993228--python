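"""Domain types and ledger I/O for annual pharmacy inventory data.

A pharmacy ledger is one row per product covering one analysis period
(normally a calendar year): quantities purchased and dispensed, purchase
value excluding VAT, optional revenue / gross-profit figures and optional
opening and closing inventory balances. Products are split into a
*medical* sector (prescription medicines, OTC medicines, medical devices
— the regulator-registered assortment) and a *non-medical* sector
(everything else: supplements, cosmetics, teas, baby products, ...).

Gross profit is the retail revenue retained by the pharmacy after the
acquisition cost, with reimbursed dispensing-service fees added:

    gross_profit = sales_revenue - purchase_cost + service_fee_revenue

It may be negative for loss-leading items. A ledger may carry a
precomputed (already netted) gross profit; when present it wins over the
derived figure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "ASSORTMENT_CLASSES",
    "MEDICAL_CLASSES",
    "ProductRecord",
    "InventoryDataset",
    "compute_gross_profit",
    "read_ledger",
    "write_ledger",
]

#: Internal assortment classes recognised in the ledger.
ASSORTMENT_CLASSES: tuple[str, ...] = (
    "prescription_medicine",
    "otc_medicine",
    "medical_device",
    "tea",
    "cosmetics",
    "dermocosmetics",
    "baby_food",
    "baby_equipment",
    "dietary_supplement",
    "homeopathic",
    "glasses",
    "footwear",
    "bandaging_material",
    "special_population_food",
    "non_medical_device",
    "other",
)

#: Classes registered with the medicines regulator; these define the medical sector.
MEDICAL_CLASSES: frozenset[str] = frozenset(
    {"prescription_medicine", "otc_medicine", "medical_device"}
)

#: Column order of the on-disk ledger CSV.
LEDGER_COLUMNS: tuple[str, ...] = (
    "product_id",
    "product_name",
    "assortment_class",
    "sector",
    "qty_purchased",
    "qty_dispensed",
    "purchase_value",
    "sales_revenue",
    "service_fee_revenue",
    "gross_profit",
    "opening_balance",
    "closing_balance",
)

MANDATORY_COLUMNS: tuple[str, ...] = (
    "product_id",
    "product_name",
    "assortment_class",
    "qty_purchased",
    "qty_dispensed",
    "purchase_value",
)


def sector_for_class(assortment_class: str) -> str:
    """Sector implied by the assortment class: ``medical`` or ``non_medical``."""
    return "medical" if assortment_class in MEDICAL_CLASSES else "non_medical"


def compute_gross_profit(
    sales_revenue: float, purchase_cost: float, service_fee_revenue: float = 0.0
) -> float:
    """Gross profit: sales revenue minus purchase cost plus reimbursed service fees.

    The result may be negative (loss-making item). VAT does not enter: both
    revenue and cost are taken exclusive of it.
    """
    for name, v in (
        ("sales_revenue", sales_revenue),
        ("purchase_cost", purchase_cost),
        ("service_fee_revenue", service_fee_revenue),
    ):
        if not math.isfinite(v):
            raise ValidationError(f"{name} must be finite, got {v!r}")
    if sales_revenue < 0 or purchase_cost < 0:
        raise ValidationError("revenue and cost must be non-negative")
    return sales_revenue - purchase_cost + service_fee_revenue


@dataclass
class ProductRecord:
    """One product's annual ledger row.

    Optional monetary fields use ``None`` as the absent-marker; quantities
    and values are coerced to float on construction so that datasets
    compare field-by-field after a CSV round trip.
    """

    product_id: str
    product_name: str
    assortment_class: str
    qty_purchased: float
    qty_dispensed: float
    purchase_value: float
    sector: Optional[str] = None
    sales_revenue: Optional[float] = None
    service_fee_revenue: float = 0.0
    gross_profit: Optional[float] = None
    opening_balance: Optional[float] = None
    closing_balance: Optional[float] = None

    def __post_init__(self) -> None:
        if self.assortment_class not in ASSORTMENT_CLASSES:
            raise ValidationError(
                f"unknown assortment_class {self.assortment_class!r} "
                f"for product {self.product_id!r}"
            )
        derived = sector_for_class(self.assortment_class)
        if self.sector is None:
            self.sector = derived
        elif self.sector not in ("medical", "non_medical"):
            raise ValidationError(
                f"sector must be 'medical' or 'non_medical', got {self.sector!r}"
            )
        elif self.sector != derived:
            # Explicit sector wins; the regulator-registration rule implied
            # the other one, so flag it.
            warnings.warn(
                f"product {self.product_id!r}: explicit sector {self.sector!r} "
                f"disagrees with assortment class {self.assortment_class!r} "
                f"(implies {derived!r}); keeping the explicit sector",
                stacklevel=2,
            )
        self.qty_purchased = float(self.qty_purchased)
        self.qty_dispensed = float(self.qty_dispensed)
        self.purchase_value = float(self.purchase_value)
        self.service_fee_revenue = float(self.service_fee_revenue)
        for name in ("sales_revenue", "gross_profit", "opening_balance", "closing_balance"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, float(v))
        for name in (
            "qty_purchased",
            "qty_dispensed",
            "purchase_value",
            "service_fee_revenue",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(
                    f"product {self.product_id!r}: {name} must be non-negative"
                )
        for name in ("sales_revenue", "opening_balance", "closing_balance"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(
                    f"product {self.product_id!r}: {name} must be non-negative"
                )

    def effective_gross_profit(self) -> float:
        """Gross profit to use in classification.

        A precomputed ``gross_profit`` (already netted for discounts and
        promotions at source) is used as-is; otherwise it is derived from
        ``sales_revenue``, ``purchase_value`` and ``service_fee_revenue``.
        """
        if self.gross_profit is not None:
            return self.gross_profit
        if self.sales_revenue is None:
            raise ValidationError(
                f"product {self.product_id!r}: gross profit unavailable — "
                "neither gross_profit nor sales_revenue present"
            )
        return compute_gross_profit(
            self.sales_revenue, self.purchase_value, self.service_fee_revenue
        )

    def has_balances(self) -> bool:
        return self.opening_balance is not None and self.closing_balance is not None


@dataclass
class InventoryDataset:
    """A validated collection of product records plus the analysis period length."""

    records: list[ProductRecord]
    period_days: int = 365
    currency_label: str = "EUR"

    def __post_init__(self) -> None:
        if self.period_days <= 0:
            raise ValidationError(f"period_days must be positive, got {self.period_days}")
        seen: dict[str, int] = {}
        dups: list[str] = []
        for r in self.records:
            seen[r.product_id] = seen.get(r.product_id, 0) + 1
        dups = sorted(pid for pid, n in seen.items() if n > 1)
        if dups:
            raise ValidationError(f"duplicate product_id(s): {', '.join(dups)}")

    def __len__(self) -> int:
        return len(self.records)

    def sector_subset(self, sector: str) -> list[ProductRecord]:
        if sector not in ("medical", "non_medical"):
            raise ValueError(f"unknown sector {sector!r}")
        return [r for r in self.records if r.sector == sector]

    def to_frame(self) -> pd.DataFrame:
        """The ledger as a DataFrame in the on-disk column order."""
        rows = []
        for r in self.records:
            rows.append({c: getattr(r, c) for c in LEDGER_COLUMNS})
        return pd.DataFrame(rows, columns=list(LEDGER_COLUMNS))


def read_ledger(
    path: str | Path,
    *,
    delimiter: str = ",",
    period_days: int = 365,
    currency_label: str = "EUR",
) -> InventoryDataset:
    """Read a delimited ledger file into a validated :class:`InventoryDataset`.

    The file must have a header row naming at least the mandatory columns
    (``product_id``, ``product_name``, ``assortment_class``,
    ``qty_purchased``, ``qty_dispensed``, ``purchase_value``). Optional
    columns absent from the file are treated as absent for every row;
    empty cells in optional columns are absent for that row. Row order is
    preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"ledger {path} is missing mandatory column(s): {', '.join(missing)}")

    def _opt_float(raw: str, column: str, idx: int) -> Optional[float]:
        if raw == "":
            return None
        try:
            return float(raw)
        except ValueError as exc:
            raise ValidationError(
                f"row {idx}: column {column!r} has non-numeric value {raw!r}"
            ) from exc

    records: list[ProductRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        try:
            rec = ProductRecord(
                product_id=row_d["product_id"],
                product_name=row_d["product_name"],
                assortment_class=row_d["assortment_class"],
                sector=(row_d.get("sector") or None),
                qty_purchased=_opt_float(row_d["qty_purchased"], "qty_purchased", idx) or 0.0,
                qty_dispensed=_opt_float(row_d["qty_dispensed"], "qty_dispensed", idx) or 0.0,
                purchase_value=_opt_float(row_d["purchase_value"], "purchase_value", idx) or 0.0,
                sales_revenue=_opt_float(row_d.get("sales_revenue", ""), "sales_revenue", idx),
                service_fee_revenue=_opt_float(
                    row_d.get("service_fee_revenue", ""), "service_fee_revenue", idx
                )
                or 0.0,
                gross_profit=_opt_float(row_d.get("gross_profit", ""), "gross_profit", idx),
                opening_balance=_opt_float(
                    row_d.get("opening_balance", ""), "opening_balance", idx
                ),
                closing_balance=_opt_float(
                    row_d.get("closing_balance", ""), "closing_balance", idx
                ),
            )
        except ValidationError as exc:
            raise ValidationError(f"row {idx}: {exc}") from exc
        records.append(rec)
    return InventoryDataset(records, period_days=period_days, currency_label=currency_label)


def write_ledger(dataset: InventoryDataset, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a dataset as a delimited file losslessly re-readable by :func:`read_ledger`.

    Absent optional values become empty cells; floats use the shortest
    round-trippable decimal representation, so write → read is the
    identity on valid datasets.
    """
    path = Path(path)
    df = dataset.to_frame()
    out = df.copy()
    for c in out.columns:
        out[c] = out[c].map(
            lambda v: ""
            if v is None or (isinstance(v, float) and math.isnan(v))
            else (repr(v) if isinstance(v, float) else str(v))
        )
    out.to_csv(path, sep=delimiter, index=False, encoding="utf-8")
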