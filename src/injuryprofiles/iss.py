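"""Injury Severity Score (ISS): computation, categories, inclusion filter.

The ISS summarises multiple injuries on one casualty: take the highest AIS
severity in each of the six ISS body regions (head/neck, face, chest,
abdomen, extremities including pelvis, external), square the three largest
of those regional maxima, and sum.  Any AIS of 6 sets the ISS to 75 by the
standard convention.  Severity categories are serious (9-15), severe
(16-24) and critical (>= 25); casualties below 9 fall outside the study
definition of serious injury.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .barell import CodingError, iss_region_of_row
from .coding import InjuryRecord, classify_injury

__all__ = [
    "IssResult",
    "compute_iss",
    "compute_iss_table",
    "categorize_iss",
    "filter_cohort",
    "SERIOUS_MIN",
]

logger = logging.getLogger(__name__)

SERIOUS_MIN = 9  # inclusion threshold: "serious or greater"


@dataclass(frozen=True)
class IssResult:
    casualty_id: str
    iss: int
    category: str


def compute_iss(
    records: Iterable[InjuryRecord],
    iss_region_map: Mapping[int, str] | None = None,
) -> int:
    """ISS for one casualty's records.

    Records are grouped into ISS body regions (via the bundled Barell-row
    bridge, or ``iss_region_map`` overriding it), the maximum AIS is taken
    per region, and the three largest regional maxima are squared and
    summed.  Fewer than three injured regions contribute fewer terms.
    Order- and duplicate-invariant.  AIS 6 anywhere gives 75.
    """
    maxima: dict[str, int] = {}
    for rec in records:
        ais = int(rec.ais)
        if not 1 <= ais <= 6:
            raise CodingError(f"AIS {ais} outside 1..6")
        if ais == 6:
            return 75
        row = classify_injury(rec).region_row
        region = iss_region_map[row] if iss_region_map is not None else iss_region_of_row(row)
        maxima[region] = max(maxima.get(region, 0), ais)
    top3 = sorted(maxima.values(), reverse=True)[:3]
    return int(sum(a * a for a in top3))


def categorize_iss(iss: int) -> str:
    """Boundary-inclusive category: serious 9-15, severe 16-24, critical >= 25."""
    iss = int(iss)
    if not 0 <= iss <= 75:
        raise ValueError(f"ISS {iss} outside 0..75")
    if iss < SERIOUS_MIN:
        return "below_serious"
    if iss <= 15:
        return "serious"
    if iss <= 24:
        return "severe"
    return "critical"


def compute_iss_table(
    records: Iterable[InjuryRecord],
    casualty_ids: Sequence[str] | None = None,
) -> list[IssResult]:
    """Per-casualty ISS for a whole cohort, in first-appearance (or roster) order."""
    grouped: dict[str, list[InjuryRecord]] = {}
    order: list[str] = list(casualty_ids) if casualty_ids is not None else []
    for cid in order:
        grouped.setdefault(cid, [])
    for rec in records:
        if rec.casualty_id not in grouped:
            order.append(rec.casualty_id)
        grouped.setdefault(rec.casualty_id, []).append(rec)
    out = []
    for cid in order:
        iss = compute_iss(grouped[cid])
        out.append(IssResult(cid, iss, categorize_iss(iss)))
    return out


def filter_cohort(iss_results: Iterable[IssResult], min_iss: int = SERIOUS_MIN) -> list[str]:
    """Casualty ids meeting the severity inclusion rule (ISS >= min_iss),
    input order preserved; the excluded count is logged."""
    results = list(iss_results)
    included = [r.casualty_id for r in results if r.iss >= min_iss]
    excluded = len(results) - len(included)
    if excluded:
        logger.info("excluded %d of %d casualties below ISS %d", excluded, len(results), min_iss)
    if not included and results:
        logger.warning("no casualties meet the ISS >= %d inclusion rule", min_iss)
    return included


def iss_results_to_dataframe(results: Iterable[IssResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"casualty_id": r.casualty_id, "iss": r.iss, "category": r.category} for r in results],
        columns=["casualty_id", "iss", "category"],
    )
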