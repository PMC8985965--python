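"""Code casualty injury records into binary Barell-cell indicators.

Each casualty carries one or more injury records (body region, nature of
injury, AIS severity, open/closed flag for fractures).  Records resolve
deterministically to cells of the extended Barell matrix, and a cohort
becomes an N x J binary indicator matrix over the populated cells: entry
(i, j) is 1 exactly when casualty i has at least one injury in cell j.
Only populated cells are kept by default, so J is data-dependent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .barell import (
    BarellCell,
    CodingError,
    all_cells,
    cell,
    cell_id,
)

__all__ = [
    "InjuryRecord",
    "IndicatorMatrix",
    "classify_injury",
    "build_indicator_matrix",
    "records_from_dataframe",
    "records_to_dataframe",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InjuryRecord:
    """One coded injury on one casualty.

    ``open_fracture`` is meaningful only when the nature is a fracture;
    AIS is the Abbreviated Injury Scale severity, 1 (minor) to 6
    (maximal/untreatable).
    """

    casualty_id: str
    region_code: str
    nature_code: str
    ais: int
    open_fracture: bool | None = None

    def __post_init__(self) -> None:
        if not 1 <= int(self.ais) <= 6:
            raise CodingError(f"AIS {self.ais} outside 1..6 for {self.casualty_id}")


def classify_injury(record: InjuryRecord) -> BarellCell:
    """Resolve one record to its Barell cell (pure, deterministic).

    Fracture records route to the open/closed fracture column by the
    record's flag; a fracture without a flag is a coding error.
    """
    return cell(record.region_code, record.nature_code, record.open_fracture)


@dataclass
class IndicatorMatrix:
    """Binary casualty-by-cell indicator matrix.

    Attributes
    ----------
    casualty_ids : list of str
        Row labels, one per casualty, in first-appearance order.
    cell_index : list of BarellCell
        Column labels in Barell row-major order (region 1..36, nature
        1..13); when built with ``populated_only`` every column has at
        least one positive entry.
    values : ndarray of shape (N, J), dtype int8
    """

    casualty_ids: list[str]
    cell_index: list[BarellCell]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.casualty_ids), len(self.cell_index)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.casualty_ids)} casualties x {len(self.cell_index)} cells"
            )
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            raise ValueError("indicator values must be 0/1")

    @property
    def n_casualties(self) -> int:
        return len(self.casualty_ids)

    @property
    def n_items(self) -> int:
        return len(self.cell_index)

    def column_names(self) -> list[str]:
        return [cell_id(c) for c in self.cell_index]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.casualty_ids, name="casualty_id"),
            columns=self.column_names(),
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "IndicatorMatrix":
        from .barell import parse_cell_id

        if "casualty_id" in df.columns:
            df = df.set_index("casualty_id")
        cells = [parse_cell_id(c) for c in df.columns]
        return cls(list(df.index.astype(str)), cells, df.to_numpy())


def build_indicator_matrix(
    records: Iterable[InjuryRecord],
    populated_only: bool = True,
    casualty_ids: Sequence[str] | None = None,
) -> IndicatorMatrix:
    """Code records into the N x J binary indicator matrix.

    A cell indicator is 1 when the casualty has one *or more* records in
    that cell — presence, not a count.  With ``populated_only`` (the
    study's convention) columns with no positive entries are dropped and J
    equals the number of populated cells.  ``casualty_ids`` may supply the
    full roster so casualties without records still contribute all-zero
    rows.
    """
    records = list(records)
    ids: list[str] = list(casualty_ids) if casualty_ids is not None else []
    seen = set(ids)
    for rec in records:
        if rec.casualty_id not in seen:
            seen.add(rec.casualty_id)
            ids.append(rec.casualty_id)
    row_of = {cid: i for i, cid in enumerate(ids)}

    cells = all_cells()
    col_of = {c: j for j, c in enumerate(cells)}
    values = np.zeros((len(ids), len(cells)), dtype=np.int8)
    for rec in records:
        values[row_of[rec.casualty_id], col_of[classify_injury(rec)]] = 1

    if populated_only:
        keep = values.sum(axis=0) > 0
        if not keep.any():
            logger.warning("no populated Barell cells; indicator matrix has 0 columns")
        cells = [c for c, k in zip(cells, keep) if k]
        values = values[:, keep]
    return IndicatorMatrix(ids, cells, values)


def records_from_dataframe(df: pd.DataFrame) -> list[InjuryRecord]:
    """Build records from a dataframe with columns casualty_id,
    region_code, nature_code, ais and optional open_fracture."""
    out = []
    has_flag = "open_fracture" in df.columns
    for row in df.itertuples(index=False):
        flag = getattr(row, "open_fracture", None) if has_flag else None
        if flag is not None and not isinstance(flag, bool):
            flag = None if pd.isna(flag) else bool(flag)
        out.append(
            InjuryRecord(
                casualty_id=str(row.casualty_id),
                region_code=str(row.region_code),
                nature_code=str(row.nature_code),
                ais=int(row.ais),
                open_fracture=flag,
            )
        )
    return out


def records_to_dataframe(records: Iterable[InjuryRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "casualty_id": r.casualty_id,
                "region_code": r.region_code,
                "nature_code": r.nature_code,
                "ais": r.ais,
                "open_fracture": r.open_fracture,
            }
            for r in records
        ],
        columns=["casualty_id", "region_code", "nature_code", "ais", "open_fracture"],
    )
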