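"""Barell Injury Diagnosis Matrix: body regions, natures of injury, and cell lookup.

The Barell matrix is a two-dimensional classification of injuries endorsed
by the CDC: 36 body-region rows by 12 nature-of-injury columns.  This
package uses the extended form in which the "fractures" column is split
into open and closed fractures, giving 13 columns and 36 x 13 = 468 cells.

The row and column definitions, the mapping of each Barell row onto one of
the six ISS body regions, and a small illustrative ICD-9-CM range table are
shipped as versioned CSV files under ``injuryprofiles/data``.  The ICD-9-CM
table is a self-contained coding dialect for round-trip testing, not the
official crosswalk.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "BarellCell",
    "CodingError",
    "N_REGIONS",
    "N_NATURES",
    "region_table",
    "nature_table",
    "icd9_table",
    "cell",
    "cell_from_names",
    "cell_id",
    "all_cells",
    "iss_region_of_row",
    "FRACTURE_OPEN_COL",
    "FRACTURE_CLOSED_COL",
]

N_REGIONS = 36
N_NATURES = 13

FRACTURE_OPEN_COL = 1
FRACTURE_CLOSED_COL = 2


class CodingError(ValueError):
    """Raised when an injury record cannot be resolved to a Barell cell."""


@dataclass(frozen=True, order=True)
class BarellCell:
    """One cell of the extended Barell matrix.

    Parameters
    ----------
    region_row : int
        Body-region row, 1-36.
    nature_col : int
        Nature-of-injury column, 1-13 (open and closed fractures occupy
        columns 1 and 2).
    """

    region_row: int
    nature_col: int

    def __post_init__(self) -> None:
        if not 1 <= self.region_row <= N_REGIONS:
            raise CodingError(f"region row {self.region_row} outside 1..{N_REGIONS}")
        if not 1 <= self.nature_col <= N_NATURES:
            raise CodingError(f"nature column {self.nature_col} outside 1..{N_NATURES}")

    @property
    def region_name(self) -> str:
        return region_table().loc[self.region_row, "name"]

    @property
    def nature_name(self) -> str:
        return nature_table().loc[self.nature_col, "name"]

    @property
    def iss_region(self) -> str:
        return iss_region_of_row(self.region_row)

    def __str__(self) -> str:  # pragma: no cover - display only
        return f"({self.region_name}, {self.nature_name})"


def _read_data(filename: str) -> pd.DataFrame:
    with resources.files("injuryprofiles.data").joinpath(filename).open() as fh:
        return pd.read_csv(fh)


@functools.lru_cache(maxsize=None)
def region_table() -> pd.DataFrame:
    """The 36 Barell body-region rows, indexed by row number."""
    return _read_data("barell_rows.csv").set_index("row")


@functools.lru_cache(maxsize=None)
def nature_table() -> pd.DataFrame:
    """The 13 nature-of-injury columns, indexed by column number."""
    return _read_data("barell_natures.csv").set_index("col")


@functools.lru_cache(maxsize=None)
def icd9_table() -> pd.DataFrame:
    """Illustrative ICD-9-CM three-digit range dialect (not the official map)."""
    return _read_data("icd9_ranges.csv")


@functools.lru_cache(maxsize=None)
def _region_lookup() -> dict[str, int]:
    tab = region_table()
    out: dict[str, int] = {}
    for row, rec in tab.iterrows():
        out[rec["region_code"]] = row
        out[rec["name"].lower()] = row
    return out


@functools.lru_cache(maxsize=None)
def _nature_lookup() -> dict[str, int]:
    tab = nature_table()
    out: dict[str, int] = {}
    for col, rec in tab.iterrows():
        out[rec["nature_code"]] = col
        out[rec["name"].lower()] = col
    return out


def _resolve_region(region_code: str) -> int:
    key = str(region_code).strip().lower()
    row = _region_lookup().get(key)
    if row is None:
        raise CodingError(f"unknown body-region code {region_code!r}")
    return row


def _resolve_nature(nature_code: str, open_fracture: bool | None = None) -> int:
    key = str(nature_code).strip().lower()
    if key in ("fracture", "fractures"):
        if open_fracture is None:
            raise CodingError(
                "fracture record requires an open/closed flag to pick the column"
            )
        return FRACTURE_OPEN_COL if open_fracture else FRACTURE_CLOSED_COL
    col = _nature_lookup().get(key)
    if col is None:
        raise CodingError(f"unknown nature-of-injury code {nature_code!r}")
    return col


def cell(region_code: str, nature_code: str, open_fracture: bool | None = None) -> BarellCell:
    """Resolve region and nature codes (or canonical names) to a matrix cell.

    Fracture records are routed to the open or closed fracture column by
    ``open_fracture``; for any other nature the flag is ignored.
    """
    return BarellCell(_resolve_region(region_code), _resolve_nature(nature_code, open_fracture))


def cell_from_names(region_name: str, nature_name: str) -> BarellCell:
    """Resolve by canonical display names (case-insensitive)."""
    return cell(region_name, nature_name)


def cell_id(c: BarellCell) -> str:
    """Stable machine identifier, e.g. ``r05c06`` for (Face, Open wounds)."""
    return f"r{c.region_row:02d}c{c.nature_col:02d}"


def parse_cell_id(s: str) -> BarellCell:
    if len(s) != 6 or s[0] != "r" or s[3] != "c":
        raise CodingError(f"malformed cell id {s!r}")
    return BarellCell(int(s[1:3]), int(s[4:6]))


def all_cells() -> list[BarellCell]:
    """All 468 cells in row-major (region, then nature) order."""
    return [
        BarellCell(r, c)
        for r in range(1, N_REGIONS + 1)
        for c in range(1, N_NATURES + 1)
    ]


def iss_region_of_row(region_row: int) -> str:
    """Map a Barell row to one of the six ISS body regions.

    The bridge (head_neck / face / chest / abdomen / extremities /
    external) follows standard ISS practice — cervical spine with the
    head, thoracic spine with the chest, lumbar and sacral spine with the
    abdomen, pelvis with the extremities — and is a declared, editable
    convention shipped in ``barell_rows.csv``.
    """
    try:
        return region_table().loc[region_row, "iss_region"]
    except KeyError:
        raise CodingError(f"region row {region_row} outside 1..{N_REGIONS}") from None


def classify_icd9(code: float | int | str) -> tuple[str, str]:
    """Map a numeric ICD-9-CM code to (region_code, nature_code) via the
    bundled illustrative range table."""
    value = float(code)
    tab = icd9_table()
    hit = tab[(tab["start"] <= value) & (value <= tab["end"])]
    if hit.empty:
        raise CodingError(f"ICD-9-CM code {code!r} not covered by the bundled dialect")
    rec = hit.iloc[0]
    return rec["region_code"], rec["nature_code"]
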