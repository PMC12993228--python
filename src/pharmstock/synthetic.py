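"""Seeded synthetic pharmacy ledgers with realistic annual structure.

Real community-pharmacy ledgers are proprietary, so testing and
demonstration run on generated data that reproduces the statistical
shape the analysis relies on:

* **Heavy-tailed spend.** Purchase values are lognormal; with the default
  log-sigma of 1.8 roughly the top 10% of items carry about 70% of total
  spend, the Pareto pattern a mixed pharmacy assortment shows.
* **Sparse dispensing.** Only about 3.2% of items move at one or more
  dispenses per day; the rest are the long non-moving tail. Dispensing
  is a two-component mixture: a fixed-size active set (rates >= 1/day,
  sampled with weight toward higher-value items so that the moving
  classes also carry a disproportionate value share) and a low-rate
  component with most mass near zero.
* **Sector split and margins.** About 23.6% of items are medical
  (prescription, OTC, devices) with regulated, lower margins;
  non-medical items carry wider, higher margins. Prescription items earn
  a small reimbursed service fee per dispense.
* **Balances.** Opening/closing balances are noisy fractions of annual
  purchase value, sized so the overall turnover ratio lands in the
  mid-single digits.

One seeded generator is threaded through every draw; a fixed seed gives
a byte-identical ledger.

The module also ships the two reference 3x3 matrices of a published
annual assortment of six community pharmacies (10,541 products), as
aggregate cell counts with synthetic member ids, for exercising the
consolidation stage against known category totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ValidationError
from .matrix import CategoryMatrix
from .model import ASSORTMENT_CLASSES, InventoryDataset, ProductRecord, sector_for_class

__all__ = [
    "SyntheticConfig",
    "generate_ledger",
    "make_fixture_matrices",
    "MEDICAL_MATRIX_COUNTS",
    "NON_MEDICAL_MATRIX_COUNTS",
]

#: Reference ABC x FSN cell counts for the medical sector (2,490 products).
MEDICAL_MATRIX_COUNTS: dict[tuple[str, str], int] = {
    ("A", "F"): 22, ("A", "S"): 74, ("A", "N"): 39,
    ("B", "F"): 3, ("B", "S"): 46, ("B", "N"): 126,
    ("C", "F"): 11, ("C", "S"): 35, ("C", "N"): 2134,
}

#: Reference ABC x HML-P cell counts for the non-medical sector.
NON_MEDICAL_MATRIX_COUNTS: dict[tuple[str, str], int] = {
    ("A", "H"): 201, ("A", "M"): 0, ("A", "L"): 1,
    ("B", "H"): 247, ("B", "M"): 37, ("B", "L"): 3,
    ("C", "H"): 131, ("C", "M"): 1211, ("C", "L"): 6218,
}

_MEDICAL_CLASS_WEIGHTS = {
    "prescription_medicine": 0.55,
    "otc_medicine": 0.33,
    "medical_device": 0.12,
}
_NON_MEDICAL_CLASS_WEIGHTS = {
    "dietary_supplement": 0.22,
    "cosmetics": 0.16,
    "dermocosmetics": 0.14,
    "tea": 0.08,
    "baby_food": 0.06,
    "baby_equipment": 0.05,
    "homeopathic": 0.04,
    "glasses": 0.03,
    "footwear": 0.03,
    "bandaging_material": 0.07,
    "special_population_food": 0.04,
    "non_medical_device": 0.05,
    "other": 0.03,
}

#: Fractional margin (low, high) applied to the purchase value, per class.
#: Medical margins are regulated and capped lower than non-medical ones.
DEFAULT_MARGIN_RANGES: dict[str, tuple[float, float]] = {
    "prescription_medicine": (0.08, 0.18),
    "otc_medicine": (0.12, 0.25),
    "medical_device": (0.12, 0.25),
    "__non_medical__": (0.18, 0.45),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the ledger generator; defaults emulate a mixed annual assortment."""

    n_products: int = 10_000
    medical_fraction: float = 0.236
    #: log-scale sigma of the lognormal purchase-value distribution
    #: (1.8 puts ~70% of spend on the top ~10% of items)
    value_tail_index: float = 1.8
    #: fraction of items dispensed at >= 1/day (the F + S mass)
    active_fraction: float = 0.032
    #: share of the active items that are fast movers (> 4/day)
    fast_given_active: float = 0.19
    margin_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARGIN_RANGES)
    )
    #: reimbursed dispensing-service fee per unit, prescription items only
    service_fee_per_dispense: float = 0.25
    #: average balance as a fraction of annual purchase value
    balance_fraction: float = 0.22
    period_days: int = 365
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_products < 9:
            raise ValidationError("n_products must be >= 9 (one per matrix cell)")
        for name in ("medical_fraction", "active_fraction", "fast_given_active"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        if self.value_tail_index <= 0:
            raise ValidationError("value_tail_index must be positive")
        if not (0.0 < self.balance_fraction < 1.0):
            raise ValidationError("balance_fraction must lie in (0, 1)")
        if self.period_days <= 0:
            raise ValidationError("period_days must be positive")


def _choose_classes(rng: np.random.Generator, weights: dict[str, float], n: int) -> list[str]:
    names = list(weights)
    p = np.array([weights[k] for k in names], dtype=float)
    p /= p.sum()
    return list(rng.choice(names, size=n, p=p))


def generate_ledger(config: SyntheticConfig = SyntheticConfig()) -> InventoryDataset:
    """Generate a validated synthetic annual ledger, deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_products
    n_med = int(round(n * config.medical_fraction))

    classes = _choose_classes(rng, _MEDICAL_CLASS_WEIGHTS, n_med) + _choose_classes(
        rng, _NON_MEDICAL_CLASS_WEIGHTS, n - n_med
    )
    perm = rng.permutation(n)
    classes = [classes[i] for i in perm]

    # annual purchase value, heavy-tailed; the scale (median ~55 EUR) only
    # sets units — all classifications are scale-invariant
    value = np.exp(rng.normal(np.log(55.0), config.value_tail_index, size=n))
    unit_price = np.exp(rng.normal(np.log(5.0), 0.8, size=n))
    qty_purchased = np.maximum(1, np.round(value / unit_price)).astype(float)

    # dispensing: fixed-size active set, value-weighted, so moving items
    # also account for an outsized share of spend
    n_active = int(round(n * config.active_fraction))
    weights = np.sqrt(value)
    active_idx = rng.choice(n, size=n_active, replace=False, p=weights / weights.sum())
    period = config.period_days
    qty_dispensed = np.empty(n)
    low_rate = rng.uniform(0.0, 1.0, size=n) ** 3  # mass piled near zero
    qty_dispensed[:] = np.floor(low_rate * period)  # stays < 1/day
    fast = rng.uniform(0.0, 1.0, size=n_active) < config.fast_given_active
    slow_rates = rng.uniform(1.0, 4.0, size=n_active)
    fast_rates = rng.uniform(4.05, 12.0, size=n_active)
    for j, idx in enumerate(active_idx):
        rate = fast_rates[j] if fast[j] else slow_rates[j]
        qty_dispensed[idx] = max(float(period), float(np.round(rate * period)))

    non_med_range = config.margin_ranges.get("__non_medical__", (0.18, 0.45))
    records: list[ProductRecord] = []
    width = len(str(n))
    for i in range(n):
        cls = classes[i]
        lo, hi = config.margin_ranges.get(cls, non_med_range)
        margin = rng.uniform(lo, hi)
        sales = value[i] * (1.0 + margin)
        fee = (
            config.service_fee_per_dispense * qty_dispensed[i]
            if cls == "prescription_medicine"
            else 0.0
        )
        # high-value items are restocked more often and held shorter, so
        # their balance fraction shrinks mildly with value
        bf = float(
            np.clip(config.balance_fraction * (55.0 / value[i]) ** 0.2, 0.02, 0.95)
        )
        opening = value[i] * bf * np.exp(rng.normal(0.0, 0.3))
        closing = value[i] * bf * np.exp(rng.normal(0.0, 0.3))
        records.append(
            ProductRecord(
                product_id=f"SYN{i + 1:0{width}d}",
                product_name=f"{cls.replace('_', ' ')} item {i + 1}",
                assortment_class=cls,
                qty_purchased=float(qty_purchased[i]),
                qty_dispensed=float(qty_dispensed[i]),
                purchase_value=round(float(value[i]), 2),
                sales_revenue=round(float(sales), 2),
                service_fee_revenue=round(float(fee), 2),
                opening_balance=round(float(opening), 2),
                closing_balance=round(float(closing), 2),
            )
        )
    return InventoryDataset(records, period_days=config.period_days)


def make_fixture_matrices() -> tuple[CategoryMatrix, CategoryMatrix]:
    """The two reference 3x3 matrices (medical ABC x FSN, non-medical ABC x HML-P).

    Cell counts are the published aggregates of the reference assortment;
    member ids are synthetic placeholders (the underlying facility data
    are proprietary).
    """
    medical = CategoryMatrix.from_counts(
        MEDICAL_MATRIX_COUNTS,
        sector="medical",
        col_axis=("F", "S", "N"),
        id_prefix="MED",
    )
    non_medical = CategoryMatrix.from_counts(
        NON_MEDICAL_MATRIX_COUNTS,
        sector="non_medical",
        col_axis=("H", "M", "L"),
        id_prefix="NMED",
    )
    return medical, non_medical
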