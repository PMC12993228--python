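"""Inventory turnover ratio and days inventory held.

The turnover ratio is how many times a year the stock is replenished:

    turnover_ratio = total annual purchased value / average inventory balance
    average inventory balance = (opening balance + closing balance) / 2
    days inventory held = 365 / turnover_ratio

Reports are produced for the overall inventory and separately per ABC
class; class-level figures sum member purchased values and balances
(summing member average balances equals averaging the summed opening and
closing balances, so no aggregation ambiguity arises).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

from .errors import DegenerateInputError, ValidationError
from .model import InventoryDataset

__all__ = [
    "YEAR_DAYS",
    "TurnoverReport",
    "average_inventory_balance",
    "turnover_ratio",
    "days_inventory_held",
    "class_turnover",
]

#: Year length used in the days-held formula (calendar days, no leap switch).
YEAR_DAYS = 365.0


@dataclass(frozen=True)
class TurnoverReport:
    """Turnover metrics for one scope (overall or one ABC class)."""

    scope: str
    n_items: int
    total_purchased_value: float
    average_inventory_balance: float
    turnover_ratio: float
    days_inventory_held: float


def average_inventory_balance(opening: float, closing: float) -> float:
    """Mean of the opening and closing inventory balances."""
    if opening < 0 or closing < 0:
        raise ValidationError("balances must be non-negative")
    return (opening + closing) / 2.0


def turnover_ratio(total_purchased_value: float, average_balance: float) -> float:
    """Annual purchased value over average balance; undefined for zero balance."""
    if average_balance <= 0:
        raise DegenerateInputError(
            "turnover ratio undefined for non-positive average balance"
        )
    return total_purchased_value / average_balance


def days_inventory_held(ratio: float, year_days: float = YEAR_DAYS) -> float:
    """Average duration of one stock cycle in days."""
    if ratio <= 0:
        raise DegenerateInputError("days inventory held undefined for non-positive ratio")
    return year_days / ratio


def class_turnover(
    dataset: InventoryDataset,
    abc_labels: Mapping[str, str],
    *,
    year_days: float = YEAR_DAYS,
) -> list[TurnoverReport]:
    """Turnover reports for the overall inventory and each ABC class.

    A scope is computable only when all its members carry opening and
    closing balances; incomputable scopes are dropped with a warning
    naming them.
    """
    # sum in product_id order so reports are invariant to record order
    ordered = sorted(dataset.records, key=lambda r: r.product_id)
    scopes: dict[str, list] = {"overall": ordered}
    labels_seen = sorted(set(abc_labels.values()))
    for lab in labels_seen:
        scopes[f"class {lab}"] = [r for r in ordered if abc_labels.get(r.product_id) == lab]

    reports: list[TurnoverReport] = []
    skipped: list[str] = []
    for scope, members in scopes.items():
        if not members:
            skipped.append(scope)
            continue
        if not all(r.has_balances() for r in members):
            skipped.append(scope)
            continue
        value = sum(r.purchase_value for r in members)
        balance = sum(
            average_inventory_balance(r.opening_balance, r.closing_balance) for r in members
        )
        if balance <= 0:
            skipped.append(scope)
            continue
        ratio = turnover_ratio(value, balance)
        reports.append(
            TurnoverReport(
                scope=scope,
                n_items=len(members),
                total_purchased_value=value,
                average_inventory_balance=balance,
                turnover_ratio=ratio,
                days_inventory_held=days_inventory_held(ratio, year_days),
            )
        )
    if skipped:
        warnings.warn(
            "turnover not computable for scope(s): " + ", ".join(skipped),
            stacklevel=2,
        )
    return reports
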