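"""Contingency tables: 2x2 fourfold tables and 2x2x2 joint-exposure tables.

The fourfold table (a = exposed cases, b = exposed controls, c = unexposed
cases, d = unexposed controls) is the atom of all odds-ratio arithmetic.
The joint table cross-classifies cases and controls over two binary
exposures with the double-unexposed cell (0,0) as the reference stratum.

Counts are normally integers (crosstabs always produce integers) but the
types accept nonnegative reals so that analytic expected-count tables from
the synthetic-cohort model flow through the same odds-ratio code path.

The published cross-classifications of the hypertension study (family
history against diabetes and five lifestyle exposures) ship as packaged
fixtures together with the odds ratios printed alongside them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .cohort import SubjectRecord
from .errors import DomainError

Cell = tuple[int, int]
CELLS: tuple[Cell, ...] = ((0, 0), (0, 1), (1, 0), (1, 1))
REFERENCE_CELL: Cell = (0, 0)


@dataclass(frozen=True)
class FourfoldTable:
    """2x2 case-control x exposed-unexposed counts."""

    a: float  # exposed cases
    b: float  # exposed controls
    c: float  # unexposed cases
    d: float  # unexposed controls
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DomainError(f"negative count in fourfold table {self.label!r}")
        if self.total == 0:
            raise DomainError(f"all-zero fourfold table {self.label!r}")

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def counts(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def has_zero_cell(self) -> bool:
        return min(self.counts) == 0

    def corrected(self) -> "FourfoldTable":
        """Haldane-Anscombe correction: +0.5 to every cell."""
        return FourfoldTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5, self.label)


@dataclass(frozen=True)
class JointExposureTable:
    """Case/control counts over two binary exposures; reference cell (0,0)."""

    counts: dict[Cell, tuple[float, float]]  # cell -> (cases, controls)
    exposure_names: tuple[str, str] = ("exposure1", "exposure2")
    label: str = ""

    def __post_init__(self) -> None:
        if set(self.counts) != set(CELLS):
            raise DomainError("joint table must have exactly the four (e1,e2) cells")
        for cell, (n_case, n_ctrl) in self.counts.items():
            if n_case < 0 or n_ctrl < 0:
                raise DomainError(f"negative count in cell {cell}")

    def cases(self, cell: Cell) -> float:
        return self.counts[cell][0]

    def controls(self, cell: Cell) -> float:
        return self.counts[cell][1]

    @property
    def n_cases(self) -> float:
        return sum(v[0] for v in self.counts.values())

    @property
    def n_controls(self) -> float:
        return sum(v[1] for v in self.counts.values())

    @property
    def total(self) -> float:
        return self.n_cases + self.n_controls

    def transposed(self) -> "JointExposureTable":
        """Swap the two exposures (cell indices transpose)."""
        return JointExposureTable(
            counts={(e2, e1): v for (e1, e2), v in self.counts.items()},
            exposure_names=(self.exposure_names[1], self.exposure_names[0]),
            label=self.label,
        )


def _binary_value(record: SubjectRecord, variable: str) -> int | None:
    level = record.exposures.get(variable)
    if level is None:
        return None
    if level not in ("0", "1"):
        raise DomainError(
            f"variable {variable!r} is not binary (found level {level!r}); "
            "dichotomize it first"
        )
    return int(level)


def crosstab_single(records: Sequence[SubjectRecord], variable: str) -> FourfoldTable:
    """Fourfold table of one binary exposure against case status.

    Records missing the variable are excluded.
    """
    if not records:
        raise DomainError("empty cohort")
    a = b = c = d = 0
    for rec in records:
        value = _binary_value(rec, variable)
        if value is None:
            continue
        if rec.is_case:
            a += value
            c += 1 - value
        else:
            b += value
            d += 1 - value
    return FourfoldTable(a, b, c, d, label=variable)


def crosstab_joint(
    records: Sequence[SubjectRecord], variable1: str, variable2: str
) -> JointExposureTable:
    """2x2x2 cross-classification of two binary exposures by case status.

    Records missing either variable are excluded; marginalising over either
    exposure reproduces the corresponding single crosstab on the jointly
    observed records.
    """
    if variable1 == variable2:
        raise DomainError("joint table requires two distinct variables")
    if not records:
        raise DomainError("empty cohort")
    counts = {cell: [0, 0] for cell in CELLS}
    for rec in records:
        v1 = _binary_value(rec, variable1)
        v2 = _binary_value(rec, variable2)
        if v1 is None or v2 is None:
            continue
        counts[(v1, v2)][0 if rec.is_case else 1] += 1
    return JointExposureTable(
        counts={cell: (n[0], n[1]) for cell, n in counts.items()},
        exposure_names=(variable1, variable2),
    )


def collapse_to_fourfold(joint: JointExposureTable, cell: Cell) -> FourfoldTable:
    """Fourfold table of one joint-exposure stratum against the (0,0) reference."""
    if cell == REFERENCE_CELL:
        raise DomainError("reference cell (0,0) has odds ratio 1 by definition")
    if cell not in CELLS:
        raise DomainError(f"unknown cell {cell}")
    a, b = joint.counts[cell]
    c, d = joint.counts[REFERENCE_CELL]
    return FourfoldTable(a, b, c, d, label=f"{joint.exposure_names}={cell} vs (0,0)")


# ---------------------------------------------------------------------------
# Packaged fixtures: the study's printed cross-classifications

#: exposure pair per published table id (exposure 1 is always family history)
PUBLISHED_EXPOSURES: dict[int, tuple[str, str]] = {
    2: ("family_history", "diabetes"),
    3: ("family_history", "drinking"),
    4: ("family_history", "sports"),
    5: ("family_history", "taste"),
    6: ("family_history", "smoking"),
    7: ("family_history", "pressure"),
}


@dataclass(frozen=True)
class PublishedTable:
    """One published cross-classification plus its printed OR estimates."""

    table_id: int
    joint: JointExposureTable
    # cell -> (printed OR, printed CI low, printed CI high); no entry for (0,0)
    printed: dict[Cell, tuple[float, float, float]] = field(default_factory=dict)


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("addinter.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_published_tables() -> dict[int, PublishedTable]:
    """The study's printed joint count tables, keyed by published table id.

    Counts and printed odds ratios are stored exactly as printed, including
    the cells whose printed OR is not consistent with the printed counts;
    no correction is applied.
    """
    counts_df = _read_packaged("printed_tables.csv")
    est_df = _read_packaged("printed_estimates.csv")
    tables: dict[int, PublishedTable] = {}
    for table_id, grp in counts_df.groupby("source_table"):
        counts = {
            (int(r.e1), int(r.e2)): (int(r.cases), int(r.controls))
            for r in grp.itertuples()
        }
        printed = {
            (int(r.e1), int(r.e2)): (float(r.odds_ratio), float(r.ci_low), float(r.ci_high))
            for r in est_df[est_df.source_table == table_id].itertuples()
        }
        tables[int(table_id)] = PublishedTable(
            table_id=int(table_id),
            joint=JointExposureTable(
                counts=counts,
                exposure_names=PUBLISHED_EXPOSURES[int(table_id)],
                label=f"published table {table_id}",
            ),
            printed=printed,
        )
    return tables
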