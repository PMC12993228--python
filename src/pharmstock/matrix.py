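"""Cross-tabulation of two class axes and consolidation into control categories.

Two 3x3 matrices drive selective inventory control: ABC x FSN for the
medical sector and ABC x HML-P for the non-medical sector. Every product
of the sector lands in exactly one cell. Cells are then consolidated
into three oversight tiers:

* **Category I (strict control)** — every cell in row A plus the rest of
  column F (or H): high budget impact or high movement / profitability.
* **Category II (moderate control)** — cells BS/BM, BN/BL and CS/CM.
* **Category III (minimal control)** — the single cell CN (or CL):
  low-value dead stock, candidates for reduction or elimination.

The cell-to-category mapping is data (a nine-entry table), so a pharmacy
can adapt the control logic without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import MissingLabelError, ValidationError
from .model import ProductRecord

__all__ = ["CategoryMatrix", "CategoryMapping", "build_matrix", "consolidate"]

CATEGORIES = ("I", "II", "III")


@dataclass
class CategoryMatrix:
    """A 3x3 cross-tabulation of one product sector.

    ``cells`` maps (row_label, col_label) to the sorted list of member
    product ids; counts derive from the member lists.
    """

    sector: str
    row_axis: tuple[str, str, str]
    col_axis: tuple[str, str, str]
    cells: dict[tuple[str, str], list[str]]

    def __post_init__(self) -> None:
        for r in self.row_axis:
            for c in self.col_axis:
                self.cells.setdefault((r, c), [])
        extra = set(self.cells) - {(r, c) for r in self.row_axis for c in self.col_axis}
        if extra:
            raise ValidationError(f"cells outside the axes: {sorted(extra)}")
        seen: set[str] = set()
        for members in self.cells.values():
            members.sort()
            for pid in members:
                if pid in seen:
                    raise ValidationError(f"product {pid!r} appears in more than one cell")
                seen.add(pid)

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[tuple[str, str], int],
        *,
        sector: str,
        row_axis: Sequence[str] = ("A", "B", "C"),
        col_axis: Sequence[str] = ("F", "S", "N"),
        id_prefix: str = "P",
    ) -> "CategoryMatrix":
        """Build a matrix from published cell counts, minting synthetic member ids.

        Used when only the aggregate 3x3 counts are available (e.g. printed
        summary tables); member ids are placeholders like ``P-AF-0001``.
        """
        cells: dict[tuple[str, str], list[str]] = {}
        for (r, c), n in counts.items():
            if n < 0:
                raise ValidationError(f"negative count for cell {(r, c)}")
            cells[(r, c)] = [f"{id_prefix}-{r}{c}-{i:05d}" for i in range(1, n + 1)]
        return cls(sector=sector, row_axis=tuple(row_axis), col_axis=tuple(col_axis), cells=cells)

    def count(self, row: str, col: str) -> int:
        return len(self.cells[(row, col)])

    def counts(self) -> dict[tuple[str, str], int]:
        return {cell: len(members) for cell, members in self.cells.items()}

    def total(self) -> int:
        return sum(len(m) for m in self.cells.values())

    def to_frame(self) -> pd.DataFrame:
        """Cell counts as a 3x3 DataFrame (rows = value classes)."""
        return pd.DataFrame(
            [[self.count(r, c) for c in self.col_axis] for r in self.row_axis],
            index=list(self.row_axis),
            columns=list(self.col_axis),
        )


@dataclass(frozen=True)
class CategoryMapping:
    """Total mapping of the nine matrix cells onto Categories I/II/III."""

    assignment: Mapping[tuple[str, str], str]

    def __post_init__(self) -> None:
        bad = [v for v in self.assignment.values() if v not in CATEGORIES]
        if bad:
            raise ValidationError(f"unknown categories in mapping: {sorted(set(bad))}")

    @classmethod
    def default(
        cls,
        row_axis: Sequence[str] = ("A", "B", "C"),
        col_axis: Sequence[str] = ("F", "S", "N"),
    ) -> "CategoryMapping":
        """The standard selective-control mapping.

        Row A entirely and column F/H entirely go to Category I; the
        bottom-corner cell (CN / CL) is Category III; the remaining four
        cells are Category II.
        """
        a, b, c_row = row_axis
        f, s, n = col_axis
        assignment = {}
        for r in row_axis:
            for c in col_axis:
                if r == a or c == f:
                    assignment[(r, c)] = "I"
                elif r == c_row and c == n:
                    assignment[(r, c)] = "III"
                else:
                    assignment[(r, c)] = "II"
        return cls(assignment)

    def category(self, row: str, col: str) -> str:
        try:
            return self.assignment[(row, col)]
        except KeyError as exc:
            raise ValidationError(f"mapping not total: cell {(row, col)} unmapped") from exc


def build_matrix(
    subset: Iterable[ProductRecord],
    row_labels: Mapping[str, str],
    col_labels: Mapping[str, str],
    *,
    sector: str | None = None,
    row_axis: Sequence[str] = ("A", "B", "C"),
    col_axis: Sequence[str] = ("F", "S", "N"),
) -> CategoryMatrix:
    """Cross-tabulate a sector subset by its two per-product label maps.

    Every subset product must be labelled on both axes; an unlabelled id
    raises :class:`MissingLabelError` naming the id and the axis.
    """
    subset = list(subset)
    if sector is None:
        sectors = {r.sector for r in subset}
        sector = sectors.pop() if len(sectors) == 1 else "mixed"
    cells: dict[tuple[str, str], list[str]] = {}
    for rec in subset:
        pid = rec.product_id
        if pid not in row_labels:
            raise MissingLabelError(f"product {pid!r} unlabelled on the row axis")
        if pid not in col_labels:
            raise MissingLabelError(f"product {pid!r} unlabelled on the column axis")
        cells.setdefault((row_labels[pid], col_labels[pid]), []).append(pid)
    return CategoryMatrix(
        sector=sector, row_axis=tuple(row_axis), col_axis=tuple(col_axis), cells=cells
    )


def consolidate(
    matrix: CategoryMatrix, mapping: CategoryMapping | None = None
) -> dict[str, tuple[int, list[str]]]:
    """Fold the nine cells into Categories I–III.

    Returns ``{category: (count, sorted member ids)}``; counts conserve
    the matrix total for any total mapping.
    """
    if not isinstance(matrix, CategoryMatrix):
        raise TypeError("consolidate() accepts a CategoryMatrix, not pre-aggregated counts")
    if mapping is None:
        mapping = CategoryMapping.default(matrix.row_axis, matrix.col_axis)
    members: dict[str, list[str]] = {cat: [] for cat in CATEGORIES}
    for r in matrix.row_axis:
        for c in matrix.col_axis:
            members[mapping.category(r, c)].extend(matrix.cells[(r, c)])
    return {cat: (len(ms), sorted(ms)) for cat, ms in members.items()}
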