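"""Cumulative-share (Pareto) classifier behind both ABC and HML-P.

Both classifications are the same ranking device applied to a different
amount: ABC ranks products by annual purchase value, HML-P by annual
gross profit. Items are sorted by descending amount, the cumulative
share of the total is walked down the list, and the expert cut-offs
70% / 20% / 10% split the list into three classes (A/B/C or H/M/L).

Two details the published procedure leaves open are made explicit here:

* **Boundary rule.** Under the default ``crossing_item_up`` rule the item
  whose inclusion crosses a cut-off joins the *higher* class, so the top
  class is the minimal prefix reaching 70% of the total.
  ``crossing_item_down`` sends the crossing item to the lower class.
* **Non-positive amounts.** Cumulative shares are ill-defined with
  negative terms (possible for loss-leading gross profits). Under the
  default ``force_lowest`` rule such items take the lowest label and are
  excluded from the cumulative denominator; ``include_in_ranking`` keeps
  them in the ranked walk with the signed total as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .errors import DegenerateInputError, EmptyInputError

__all__ = [
    "ParetoConfig",
    "ParetoResult",
    "ABC_CONFIG",
    "HMLP_CONFIG",
    "pareto_classify",
    "cumulative_share_table",
]

_EPS = 1e-12


@dataclass(frozen=True)
class ParetoConfig:
    """Cut-offs, labels and edge-case rules for one cumulative-share classification."""

    cutoffs: tuple[float, float, float] = (0.70, 0.20, 0.10)
    labels: tuple[str, str, str] = ("A", "B", "C")
    boundary_rule: str = "crossing_item_up"
    negative_handling: str = "force_lowest"

    def __post_init__(self) -> None:
        if len(self.cutoffs) != len(self.labels):
            raise ValueError("cutoffs and labels must have equal length")
        if any(c <= 0 for c in self.cutoffs):
            raise ValueError("cutoffs must be strictly positive")
        if abs(sum(self.cutoffs) - 1.0) > 1e-9:
            raise ValueError(f"cutoffs must sum to 1, got {sum(self.cutoffs)}")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be distinct")
        if self.boundary_rule not in ("crossing_item_up", "crossing_item_down"):
            raise ValueError(f"unknown boundary_rule {self.boundary_rule!r}")
        if self.negative_handling not in ("force_lowest", "include_in_ranking"):
            raise ValueError(f"unknown negative_handling {self.negative_handling!r}")

    @property
    def cumulative_cutoffs(self) -> tuple[float, ...]:
        out, acc = [], 0.0
        for c in self.cutoffs:
            acc += c
            out.append(acc)
        return tuple(out)


#: Purchase-value classification (classes A/B/C at 70/20/10).
ABC_CONFIG = ParetoConfig(labels=("A", "B", "C"))
#: Gross-profit classification (classes H/M/L at 70/20/10).
HMLP_CONFIG = ParetoConfig(labels=("H", "M", "L"))


@dataclass
class ParetoResult:
    """Labels plus the ranked bookkeeping table and per-class totals."""

    label_by_id: dict[str, str]
    ranked_table: pd.DataFrame
    class_totals: pd.DataFrame
    config: ParetoConfig = field(default_factory=ParetoConfig)


def _ranked_items(amounts: Mapping[str, float]) -> list[tuple[str, float]]:
    """Items sorted by descending amount, ties broken by ascending id."""
    return sorted(amounts.items(), key=lambda kv: (-kv[1], kv[0]))


def pareto_classify(amounts: Mapping[str, float], config: ParetoConfig = ABC_CONFIG) -> ParetoResult:
    """Assign each item one of the three class labels by cumulative share.

    ``amounts`` maps product id to the classified amount (purchase value
    or gross profit). At least one amount must be positive.
    """
    if not amounts:
        raise EmptyInputError("no amounts to classify")
    for pid, a in amounts.items():
        if not pd.notna(a) or a in (float("inf"), float("-inf")):
            raise DegenerateInputError(f"non-finite amount for {pid!r}")
    items = _ranked_items(amounts)

    if config.negative_handling == "force_lowest":
        walk = [(pid, a) for pid, a in items if a > 0]
        forced = [(pid, a) for pid, a in items if a <= 0]
        total = sum(a for _, a in walk)
    else:
        walk, forced = items, []
        total = sum(a for _, a in walk)
    if total <= 0:
        raise DegenerateInputError("all amounts non-positive; cumulative shares undefined")

    cum_cuts = config.cumulative_cutoffs
    labels: dict[str, str] = {}
    rows: list[dict] = []
    cum = 0.0
    for rank, (pid, a) in enumerate(walk, start=1):
        share = a / total
        cum_before = cum
        cum += share
        if config.boundary_rule == "crossing_item_up":
            # the crossing item joins the higher class: label k applies
            # while the share accumulated *before* the item is below cut k
            label = config.labels[-1]
            for k, cut in enumerate(cum_cuts):
                if cum_before < cut - _EPS:
                    label = config.labels[k]
                    break
        else:
            label = config.labels[-1]
            for k, cut in enumerate(cum_cuts):
                if cum <= cut + _EPS:
                    label = config.labels[k]
                    break
        labels[pid] = label
        rows.append(
            {
                "product_id": pid,
                "rank": rank,
                "amount": a,
                "share": share,
                "cumulative_share": cum,
                "label": label,
            }
        )
    next_rank = len(walk) + 1
    for pid, a in forced:
        labels[pid] = config.labels[-1]
        rows.append(
            {
                "product_id": pid,
                "rank": next_rank,
                "amount": a,
                "share": 0.0,
                "cumulative_share": cum,
                "label": config.labels[-1],
            }
        )
        next_rank += 1

    ranked = pd.DataFrame(
        rows, columns=["product_id", "rank", "amount", "share", "cumulative_share", "label"]
    )
    totals_rows = []
    for lab in config.labels:
        sub = ranked[ranked["label"] == lab]
        totals_rows.append(
            {
                "label": lab,
                "item_count": int(len(sub)),
                "amount_sum": float(sub["amount"].sum()),
                "amount_share": float(sub["share"].sum()),
                "min_amount": float(sub["amount"].min()) if len(sub) else float("nan"),
                "max_amount": float(sub["amount"].max()) if len(sub) else float("nan"),
            }
        )
    totals = pd.DataFrame(totals_rows).set_index("label")
    return ParetoResult(label_by_id=labels, ranked_table=ranked, class_totals=totals, config=config)


def cumulative_share_table(amounts: Mapping[str, float]) -> pd.DataFrame:
    """Deterministic ranked table (descending amount, id tie-break).

    Columns: ``product_id``, ``rank``, ``amount``, ``share``,
    ``cumulative_share``. Shares are over the positive-amount total;
    non-positive items sit at the bottom with share 0.
    """
    res = pareto_classify(amounts)
    return res.ranked_table.drop(columns=["label"])
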