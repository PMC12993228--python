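"""Fast / Slow / Non-moving classification from dispensing frequency.

The dispense rate is the annual dispensed *quantity* divided by the
period length in calendar days (the ledger records quantities, not
transaction events). The class intervals follow the stated thresholds
verbatim: more than four dispenses per day is Fast, one to four per day
(closed interval) is Slow, and below one per day is Non-moving — the
pharmacy's dead stock.

    F = (4, inf)        S = [1, 4]        N = [0, 1)
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .model import InventoryDataset

__all__ = ["FsnThresholds", "dispense_rate", "classify_rate", "fsn_classify"]


@dataclass(frozen=True)
class FsnThresholds:
    """Daily-rate bounds: F above ``fast_min_rate`` (exclusive), S down to
    ``slow_min_rate`` (inclusive), N below that."""

    fast_min_rate: float = 4.0
    slow_min_rate: float = 1.0

    def __post_init__(self) -> None:
        if not (self.fast_min_rate >= self.slow_min_rate > 0):
            raise ValueError(
                f"need fast_min_rate >= slow_min_rate > 0, got "
                f"{self.fast_min_rate} / {self.slow_min_rate}"
            )


def dispense_rate(qty_dispensed: float, period_days: int) -> float:
    """Average dispenses per calendar day over the period."""
    if period_days <= 0:
        raise ValidationError(f"period_days must be positive, got {period_days}")
    if qty_dispensed < 0:
        raise ValidationError("qty_dispensed must be non-negative")
    return qty_dispensed / period_days


def classify_rate(rate: float, thresholds: FsnThresholds = FsnThresholds()) -> str:
    """Label a daily dispense rate F, S or N."""
    if rate > thresholds.fast_min_rate:
        return "F"
    if rate >= thresholds.slow_min_rate:
        return "S"
    return "N"


def fsn_classify(
    dataset: InventoryDataset, thresholds: FsnThresholds = FsnThresholds()
) -> dict[str, str]:
    """Classify every product in the dataset; the assignment is total."""
    return {
        r.product_id: classify_rate(
            dispense_rate(r.qty_dispensed, dataset.period_days), thresholds
        )
        for r in dataset.records
    }
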