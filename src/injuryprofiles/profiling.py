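"""Injury-profile labeling and covariate comparisons across profiles.

A fitted latent class becomes an *injury profile*: the injuries that
define it are the indicators whose conditional item probability is at
least 0.30 (the conventional labeling threshold), listed in descending
probability; naming the profile from that list is the analyst's job.
Profiles are then described by demographic, operational and
injury-specific covariates: an omnibus Pearson chi-square per variable,
followed by two-proportion tests for every pair of classes within each
level, Holm-adjusted to control the family-wise error rate at alpha 0.05.

The Holm family is the set of all C(K,2) pairwise tests of one level of
one variable — one family per table row, matching the row-wise
superscript presentation.  Pairwise tests are Pearson chi-square on the
2x2 table without continuity correction (the square of the two-proportion
z-test), consistent with the omnibus test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ProfileLabel",
    "ComparisonResult",
    "label_profiles",
    "crosstab_by_class",
    "chi_square_test",
    "pairwise_holm",
    "holm_adjust",
    "round_half_up",
    "percentage",
    "characteristics_report",
    "DEFAULT_THRESHOLD",
    "DEFAULT_ALPHA",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.30
DEFAULT_ALPHA = 0.05


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 at the last digit rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, ndigits: int = 1) -> float:
    """Display percentage, rounded half-up (e.g. 981 of 5227 -> 18.8)."""
    if total == 0:
        return float("nan")
    return round_half_up(100.0 * count / total, ndigits)


@dataclass
class ProfileLabel:
    """One labeled injury profile.

    ``defining_items`` holds (item name, conditional probability) pairs at
    or above the threshold, sorted by descending probability; the free-text
    ``display_name`` is supplied by the analyst, not inferred.
    """

    class_id: int
    prevalence: float
    defining_items: list[tuple[str, float]]
    display_name: str = ""

    @property
    def n_defining(self) -> int:
        return len(self.defining_items)


def label_profiles(results, threshold: float = DEFAULT_THRESHOLD) -> list[ProfileLabel]:
    """Defining items per class from a fitted model.

    An item defines a class when its conditional probability is at least
    ``threshold`` ("at least 0.30": the boundary value is retained).
    Prevalence is the share of casualties assigned to the class.  A class
    with no defining item is returned with an empty list and a warning —
    labeling such a class falls entirely to the analyst.
    """
    rho = results.item_probs
    names = results.model.item_names
    sizes = results.class_sizes
    out = []
    for k in range(results.n_classes):
        idx = np.nonzero(rho[:, k] >= threshold)[0]
        items = sorted(
            ((names[j], float(rho[j, k])) for j in idx),
            key=lambda t: (-t[1], t[0]),
        )
        if not items:
            logger.warning("class %d has no item probability >= %.2f", k + 1, threshold)
        out.append(
            ProfileLabel(
                class_id=k + 1,
                prevalence=float(sizes[k] / results.nobs),
                defining_items=items,
            )
        )
    return out


def profiles_report(profiles: list[ProfileLabel], threshold: float = DEFAULT_THRESHOLD) -> str:
    """Plain-text profile report (defining items per class with probabilities)."""
    lines = [f"Defining injuries per profile (conditional item probability >= {threshold})"]
    for p in profiles:
        name = f" — {p.display_name}" if p.display_name else ""
        lines.append(f"class {p.class_id} (prevalence {p.prevalence:.1%}){name}:")
        if not p.defining_items:
            lines.append("    (no item reaches the threshold)")
        for item, prob in p.defining_items:
            lines.append(f"    {item:<40s} {prob:.3f}")
    return "\n".join(lines)


def crosstab_by_class(
    covariates: pd.DataFrame, assignments: np.ndarray, variable: str
) -> pd.DataFrame:
    """Counts of one categorical variable by assigned class, with totals
    and within-class column percentages (half-up, one decimal).

    Returns a frame indexed by level with columns ``total``, ``total_pct``
    and per class ``class_<k>`` / ``class_<k>_pct``.
    """
    if variable not in covariates.columns:
        raise KeyError(f"covariate {variable!r} not present")
    values = covariates[variable].astype(str)
    assignments = np.asarray(assignments)
    classes = list(range(1, int(assignments.max()) + 1)) if len(assignments) else []
    counts = pd.crosstab(values, pd.Series(assignments, index=values.index, name="class"))
    counts = counts.reindex(columns=classes, fill_value=0)
    out = pd.DataFrame(index=counts.index)
    out.index.name = variable
    total = counts.sum(axis=1)
    grand = int(total.sum())
    out["total"] = total
    out["total_pct"] = [percentage(c, grand) for c in total]
    for k in classes:
        n_k = int(counts[k].sum())
        out[f"class_{k}"] = counts[k]
        out[f"class_{k}_pct"] = [percentage(c, n_k) for c in counts[k]]
    return out


def _counts_only(table: pd.DataFrame) -> pd.DataFrame:
    """Strip totals/percentage columns from a crosstab_by_class frame."""
    cols = [c for c in table.columns
            if str(c).startswith("class_") and not str(c).endswith("_pct")]
    if cols:
        return table[cols]
    return table


def chi_square_test(table) -> tuple[float, int, float]:
    """Omnibus Pearson chi-square (no continuity correction) on a counts
    table; zero-margin rows/columns are dropped with a warning, and a
    warning is logged when any expected count is below 5."""
    counts = _counts_only(table) if isinstance(table, pd.DataFrame) else pd.DataFrame(table)
    arr = counts.to_numpy(dtype=float)
    row_ok = arr.sum(axis=1) > 0
    col_ok = arr.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        logger.warning("dropping %d zero rows / %d zero columns from chi-square table",
                       (~row_ok).sum(), (~col_ok).sum())
        arr = arr[row_ok][:, col_ok]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("chi-square needs at least a 2x2 table after dropping zero margins")
    stat, p, dof, expected = sps.chi2_contingency(arr, correction=False)
    if (expected < 5).any():
        logger.warning("%d expected counts below 5 in chi-square table", int((expected < 5).sum()))
    return float(stat), int(dof), float(p)


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (order-invariant, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="holm")[1]


@dataclass
class ComparisonResult:
    """One pairwise proportion comparison within a Holm family."""

    variable: str
    level: str
    class_a: int
    class_b: int
    prop_a: float
    prop_b: float
    raw_p: float
    adjusted_p: float = float("nan")
    significant: bool = False


def pairwise_holm(
    table: pd.DataFrame,
    variable: str,
    alpha: float = DEFAULT_ALPHA,
    exclude_levels: tuple[str, ...] = (),
) -> list[ComparisonResult]:
    """All C(K,2) two-proportion comparisons per level, Holm-adjusted.

    ``table`` is a crosstab_by_class frame (or plain counts with classes
    as columns).  Each level forms one Holm family.  Levels named in
    ``exclude_levels`` (e.g. an explicit "Unknown" category) are shown in
    reports but not tested.  Pairs where the level is absent from both
    classes are skipped and logged.
    """
    counts = _counts_only(table)
    class_cols = list(counts.columns)
    class_ids = [int(str(c).replace("class_", "")) for c in class_cols]
    totals = counts.sum(axis=0)
    results: list[ComparisonResult] = []
    for level in counts.index:
        if str(level) in exclude_levels:
            continue
        family: list[ComparisonResult] = []
        for (ca, col_a), (cb, col_b) in combinations(zip(class_ids, class_cols), 2):
            in_a, n_a = int(counts.loc[level, col_a]), int(totals[col_a])
            in_b, n_b = int(counts.loc[level, col_b]), int(totals[col_b])
            if n_a == 0 or n_b == 0 or (in_a == 0 and in_b == 0) or (
                in_a == n_a and in_b == n_b
            ):
                logger.info("skipping %s=%s classes %d vs %d: degenerate 2x2",
                            variable, level, ca, cb)
                continue
            contingency = np.array(
                [[in_a, n_a - in_a], [in_b, n_b - in_b]], dtype=float
            )
            stat, p, _, _ = sps.chi2_contingency(contingency, correction=False)
            family.append(
                ComparisonResult(
                    variable=variable,
                    level=str(level),
                    class_a=ca,
                    class_b=cb,
                    prop_a=in_a / n_a,
                    prop_b=in_b / n_b,
                    raw_p=float(p),
                )
            )
        if family:
            adjusted = holm_adjust([r.raw_p for r in family])
            for r, ap in zip(family, adjusted):
                r.adjusted_p = float(ap)
                r.significant = ap < alpha
        results.extend(family)
    return results


def significance_marks(comparisons: list[ComparisonResult], n_classes: int) -> dict:
    """Superscript letters per (level, class): letter ``a`` marks a
    significant difference from class 1, ``b`` from class 2, and so on."""
    marks: dict[tuple[str, int], list[str]] = {}
    for r in comparisons:
        if not r.significant:
            continue
        marks.setdefault((r.level, r.class_a), []).append(chr(ord("a") + r.class_b - 1))
        marks.setdefault((r.level, r.class_b), []).append(chr(ord("a") + r.class_a - 1))
    return {key: ",".join(sorted(set(v))) for key, v in marks.items()}


def comparisons_to_dataframe(comparisons: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": r.variable, "level": r.level,
                "class_a": r.class_a, "class_b": r.class_b,
                "prop_a": r.prop_a, "prop_b": r.prop_b,
                "raw_p": r.raw_p, "adjusted_p": r.adjusted_p,
                "significant": r.significant,
            }
            for r in comparisons
        ],
        columns=["variable", "level", "class_a", "class_b", "prop_a",
                 "prop_b", "raw_p", "adjusted_p", "significant"],
    )


@dataclass
class CharacteristicsRow:
    variable: str
    omnibus_p: float
    table: pd.DataFrame
    comparisons: list[ComparisonResult] = field(default_factory=list)


def characteristics_report(
    covariates: pd.DataFrame,
    assignments: np.ndarray,
    variables: list[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    exclude_levels: tuple[str, ...] = ("Unknown", "unknown"),
) -> tuple[pd.DataFrame, str, list[ComparisonResult]]:
    """Characteristics-by-profile report for a set of covariates.

    Returns (tidy dataframe, formatted text, all pairwise comparisons).
    Each variable gets an omnibus chi-square across classes plus
    Holm-adjusted pairwise comparisons per level; significant pairs are
    rendered as superscript letters next to the count (percentage).
    """
    if variables is None:
        variables = list(covariates.columns)
    n_classes = int(np.asarray(assignments).max())
    tidy_rows = []
    text = []
    all_comparisons: list[ComparisonResult] = []
    for var in variables:
        tab = crosstab_by_class(covariates, assignments, var)
        try:
            _, _, omnibus_p = chi_square_test(tab)
        except ValueError:
            omnibus_p = float("nan")
        comps = pairwise_holm(tab, var, alpha=alpha, exclude_levels=exclude_levels)
        all_comparisons.extend(comps)
        marks = significance_marks(comps, n_classes)
        p_text = "<0.001" if omnibus_p < 0.001 else f"{omnibus_p:.2f}"
        text.append(f"{var}  (omnibus chi-square p = {p_text})")
        for level in tab.index:
            cells = [f"{int(tab.loc[level, 'total'])} ({tab.loc[level, 'total_pct']})"]
            for k in range(1, n_classes + 1):
                sup = marks.get((str(level), k), "")
                sup = f"^{sup}" if sup else ""
                cells.append(
                    f"{int(tab.loc[level, f'class_{k}'])} "
                    f"({tab.loc[level, f'class_{k}_pct']}){sup}"
                )
            text.append(f"  {level:<20s} " + "  ".join(cells))
            row = {"variable": var, "level": level, "omnibus_p": omnibus_p,
                   "total": int(tab.loc[level, "total"]),
                   "total_pct": tab.loc[level, "total_pct"]}
            for k in range(1, n_classes + 1):
                row[f"class_{k}"] = int(tab.loc[level, f"class_{k}"])
                row[f"class_{k}_pct"] = tab.loc[level, f"class_{k}_pct"]
                row[f"class_{k}_sig"] = marks.get((str(level), k), "")
            tidy_rows.append(row)
    return pd.DataFrame(tidy_rows), "\n".join(text), all_comparisons
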