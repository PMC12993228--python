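"""End-to-end analysis pipeline and report tables.

:func:`run_analysis` reads a ledger, runs the three single-dimension
classifications (ABC by purchase value, FSN by dispensing frequency,
HML-P by gross profit), builds the two sector matrices (ABC x FSN for
medical, ABC x HML-P for non-medical), consolidates them into control
Categories I–III, computes turnover metrics when balances are present,
and writes one CSV per table plus a JSON summary, a per-product label
file and a run log.

Data files carry no timestamps, so re-running on identical inputs and
configuration yields byte-identical outputs; only the log records when
the run happened.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import DegenerateInputError, PharmstockError, ValidationError
from .fsn import FsnThresholds, fsn_classify
from .matrix import CategoryMapping, CategoryMatrix, build_matrix, consolidate
from .model import InventoryDataset, read_ledger
from .pareto import ParetoConfig, pareto_classify
from .turnover import class_turnover

__all__ = ["RunConfig", "percent", "run_analysis"]


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """``100 * numerator / denominator`` rounded half-up to ``decimals`` places.

    Half-up (commercial) rounding matches how report tables are usually
    printed; banker's rounding would turn e.g. 0.25% into 0.2%.
    """
    if denominator <= 0:
        raise DegenerateInputError("percent() needs a positive denominator")
    value = Decimal(str(numerator)) * 100 / Decimal(str(denominator))
    q = Decimal(1).scaleb(-decimals)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def _round_half_up(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """Everything a pipeline run needs; defaults mirror the standard analysis."""

    input_path: str | Path = ""
    output_dir: str | Path = "results"
    period_days: int = 365
    abc_cutoffs: tuple[float, float, float] = (0.70, 0.20, 0.10)
    hmlp_cutoffs: tuple[float, float, float] = (0.70, 0.20, 0.10)
    fsn_fast_min_rate: float = 4.0
    fsn_slow_min_rate: float = 1.0
    boundary_rule: str = "crossing_item_up"
    negative_handling: str = "force_lowest"
    #: ``pooled``: class labels computed on the whole inventory, matrices
    #: restrict to each sector; ``sector``: labels recomputed per sector.
    label_scope: str = "pooled"
    #: optional cell -> category override, e.g. {"AF": "I", ...}
    mapping_override: Optional[Mapping[str, str]] = None
    decimals: int = 1

    def __post_init__(self) -> None:
        if self.label_scope not in ("pooled", "sector"):
            raise ValidationError(f"label_scope must be 'pooled' or 'sector', got {self.label_scope!r}")


def _mapping_from_override(
    override: Mapping[str, str], row_axis: Sequence[str], col_axis: Sequence[str]
) -> CategoryMapping:
    assignment = {}
    for r in row_axis:
        for c in col_axis:
            key = f"{r}{c}"
            if key not in override:
                raise ValidationError(f"mapping override not total: cell {key} missing")
            assignment[(r, c)] = override[key]
    return CategoryMapping(assignment)


def _summary_frame(
    labels: Mapping[str, str],
    amounts: Mapping[str, float],
    order: Sequence[str],
    decimals: int,
    amount_name: str,
) -> pd.DataFrame:
    n_total = len(labels)
    amount_total = sum(amounts.values())
    rows = []
    for lab in order:
        ids = [pid for pid, l in labels.items() if l == lab]
        amt = sum(amounts[pid] for pid in ids)
        rows.append(
            {
                "class": lab,
                "n_items": len(ids),
                "pct_items": percent(len(ids), n_total, decimals),
                amount_name: round(amt, 2),
                f"pct_{amount_name}": percent(amt, amount_total, decimals)
                if amount_total > 0
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def run_analysis(config: RunConfig) -> dict:
    """Run the full pipeline and write the report bundle.

    Returns the JSON-serialisable summary dictionary that is also written
    to ``summary.json``. On failure every file already written by this
    run is removed before the error propagates.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_csv(df: pd.DataFrame, name: str) -> None:
        p = out_dir / name
        df.to_csv(p, index=False)
        written.append(p)

    log_lines: list[str] = []
    try:
        dataset = read_ledger(config.input_path, period_days=config.period_days)
        n = len(dataset)
        medical = dataset.sector_subset("medical")
        non_medical = dataset.sector_subset("non_medical")

        abc_cfg = ParetoConfig(
            cutoffs=config.abc_cutoffs,
            labels=("A", "B", "C"),
            boundary_rule=config.boundary_rule,
            negative_handling=config.negative_handling,
        )
        hmlp_cfg = ParetoConfig(
            cutoffs=config.hmlp_cutoffs,
            labels=("H", "M", "L"),
            boundary_rule=config.boundary_rule,
            negative_handling=config.negative_handling,
        )
        thresholds = FsnThresholds(config.fsn_fast_min_rate, config.fsn_slow_min_rate)

        values = {r.product_id: r.purchase_value for r in dataset.records}
        profits: dict[str, float] = {}
        profitless: list[str] = []
        for r in dataset.records:
            try:
                profits[r.product_id] = r.effective_gross_profit()
            except ValidationError:
                profitless.append(r.product_id)
        if any(r.sector == "non_medical" and r.product_id in set(profitless) for r in dataset.records):
            raise ValidationError(
                "gross profit unavailable for non-medical product(s): "
                + ", ".join(sorted(set(profitless))[:10])
            )
        if profitless:
            log_lines.append(
                f"WARNING: {len(profitless)} medical product(s) lack gross-profit "
                "information and are excluded from the pooled HML-P ranking"
            )

        abc_pooled = pareto_classify(values, abc_cfg)
        fsn_labels = fsn_classify(dataset, thresholds)
        hmlp_pooled = pareto_classify(profits, hmlp_cfg) if profits else None

        # Table: ABC / FSN / HML-P one-dimensional summaries
        _write_csv(
            _summary_frame(abc_pooled.label_by_id, values, ("A", "B", "C"),
                           config.decimals, "purchase_value"),
            "abc_summary.csv",
        )
        _write_csv(
            _summary_frame(fsn_labels, values, ("F", "S", "N"),
                           config.decimals, "purchase_value"),
            "fsn_summary.csv",
        )
        if hmlp_pooled is not None:
            _write_csv(
                _summary_frame(hmlp_pooled.label_by_id, profits, ("H", "M", "L"),
                               config.decimals, "gross_profit"),
                "hmlp_summary.csv",
            )

        # matrix labels: pooled labels restricted, or recomputed per sector
        if config.label_scope == "pooled":
            abc_med = abc_nmed = abc_pooled.label_by_id
            hmlp_nmed = hmlp_pooled.label_by_id if hmlp_pooled else {}
        else:
            abc_med = pareto_classify(
                {r.product_id: r.purchase_value for r in medical}, abc_cfg
            ).label_by_id if medical else {}
            abc_nmed = pareto_classify(
                {r.product_id: r.purchase_value for r in non_medical}, abc_cfg
            ).label_by_id if non_medical else {}
            hmlp_nmed = pareto_classify(
                {r.product_id: r.effective_gross_profit() for r in non_medical}, hmlp_cfg
            ).label_by_id if non_medical else {}

        summary: dict = {
            "n_products": n,
            "n_medical": len(medical),
            "n_non_medical": len(non_medical),
            "pct_medical": percent(len(medical), n, config.decimals),
            "pct_non_medical": percent(len(non_medical), n, config.decimals),
            "abc_counts": {
                lab: int(c) for lab, c in
                zip(abc_pooled.class_totals.index, abc_pooled.class_totals["item_count"])
            },
            "fsn_counts": {lab: sum(1 for v in fsn_labels.values() if v == lab)
                           for lab in ("F", "S", "N")},
        }
        if hmlp_pooled is not None:
            summary["hmlp_counts"] = {
                lab: int(c) for lab, c in
                zip(hmlp_pooled.class_totals.index, hmlp_pooled.class_totals["item_count"])
            }

        member_rows: list[dict] = []
        for sector_name, subset, row_labels, col_labels, col_axis in (
            ("medical", medical, abc_med, fsn_labels, ("F", "S", "N")),
            ("non_medical", non_medical, abc_nmed, hmlp_nmed, ("H", "M", "L")),
        ):
            if not subset:
                log_lines.append(f"WARNING: no {sector_name} products; matrix skipped")
                continue
            mat = build_matrix(subset, row_labels, col_labels,
                               sector=sector_name, col_axis=col_axis)
            mapping = (
                _mapping_from_override(config.mapping_override, mat.row_axis, mat.col_axis)
                if config.mapping_override
                else CategoryMapping.default(mat.row_axis, mat.col_axis)
            )
            cats = consolidate(mat, mapping)
            frame = mat.to_frame()
            frame.insert(0, "class", frame.index)
            _write_csv(frame.reset_index(drop=True), f"{sector_name}_matrix.csv")
            _write_csv(
                pd.DataFrame(
                    [{"category": cat, "count": cnt} for cat, (cnt, _) in cats.items()]
                ),
                f"{sector_name}_categories.csv",
            )
            cat_of = {pid: cat for cat, (_, ids) in cats.items() for pid in ids}
            for r in sorted(subset, key=lambda x: x.product_id):
                member_rows.append(
                    {
                        "product_id": r.product_id,
                        "sector": sector_name,
                        "row_label": row_labels[r.product_id],
                        "col_label": col_labels[r.product_id],
                        "category": cat_of[r.product_id],
                    }
                )
            summary[f"{sector_name}_categories"] = {cat: cnt for cat, (cnt, _) in cats.items()}
        _write_csv(pd.DataFrame(member_rows), "members.csv")

        # per-product label file (pooled labels)
        label_rows = [
            {
                "product_id": r.product_id,
                "sector": r.sector,
                "abc": abc_pooled.label_by_id[r.product_id],
                "fsn": fsn_labels[r.product_id],
                "hmlp": hmlp_pooled.label_by_id.get(r.product_id, "")
                if hmlp_pooled
                else "",
            }
            for r in dataset.records
        ]
        _write_csv(pd.DataFrame(label_rows), "labels.csv")

        # turnover: graceful degradation when balances are absent
        if all(r.has_balances() for r in dataset.records):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reports = class_turnover(dataset, abc_pooled.label_by_id)
            total_value = sum(r.purchase_value for r in dataset.records)
            rows = []
            for rep in reports:
                rows.append(
                    {
                        "scope": rep.scope,
                        "n_items": rep.n_items,
                        "pct_items": percent(rep.n_items, n, config.decimals),
                        "pct_value": percent(rep.total_purchased_value, total_value,
                                             config.decimals),
                        "turnover_ratio": _round_half_up(rep.turnover_ratio, config.decimals),
                        "days_inventory_held": _round_half_up(rep.days_inventory_held,
                                                              config.decimals),
                    }
                )
            _write_csv(pd.DataFrame(rows), "turnover.csv")
            summary["turnover"] = {
                rep.scope: {
                    "turnover_ratio": _round_half_up(rep.turnover_ratio, config.decimals),
                    "days_inventory_held": _round_half_up(rep.days_inventory_held,
                                                          config.decimals),
                }
                for rep in reports
            }
        else:
            log_lines.append(
                "WARNING: opening/closing balances missing; turnover table skipped"
            )

        p = out_dir / "summary.json"
        p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        written.append(p)

        cfg_echo = asdict(config)
        cfg_echo["input_path"] = str(cfg_echo["input_path"])
        cfg_echo["output_dir"] = str(cfg_echo["output_dir"])
        log = out_dir / "run.log"
        log.write_text(
            "\n".join(
                [
                    f"run completed {datetime.now(timezone.utc).isoformat()}",
                    "config: " + json.dumps(cfg_echo, sort_keys=True, default=str),
                    *log_lines,
                ]
            )
            + "\n"
        )
        written.append(log)
        return summary
    except Exception:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise
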