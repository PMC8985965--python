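"""Model selection for latent class fits: information criteria, relative
entropy, classification diagnostics, and a scan over the class count K.

Criteria (p = K*J + K - 1 free parameters, N observations):

    BIC   = -2 LL + p ln N
    AIC   = -2 LL + 2 p
    CAIC  = -2 LL + p (ln N + 1)
    SABIC = -2 LL + p ln((N + 2) / 24)

Relative entropy, E = 1 - mean posterior Shannon entropy / ln K, is 1 when
every casualty is classified with certainty and 0 for uninformative
posteriors; values above 0.80 are conventionally read as good
classification, and it is undefined for K = 1 (reported as missing).  The
diagnostics matrix averages, within each assigned class (row), the
posterior probability of membership in every class (column); diagonals
above 0.70 with off-diagonals at or below 0.05 indicate well-separated
classes.  The automatic selection rule across K is the CAIC minimum;
judging coherence and interpretability of the classes remains the
analyst's task, so the scan reports every criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lca import FittingError, LatentClassModel, LatentClassResults

__all__ = [
    "FitStats",
    "DiagnosticsMatrix",
    "count_parameters",
    "information_criteria",
    "relative_entropy",
    "classification_diagnostics",
    "fit_statistics",
    "scan_models",
    "ModelScan",
    "DIAGONAL_THRESHOLD",
    "OFFDIAG_THRESHOLD",
    "ENTROPY_THRESHOLD",
]

logger = logging.getLogger(__name__)

DIAGONAL_THRESHOLD = 0.70  # mean posterior indicating a well-separated class
OFFDIAG_THRESHOLD = 0.05   # acceptably low cross-class mean posterior
ENTROPY_THRESHOLD = 0.80   # "good" overall classification


def count_parameters(n_classes: int, n_items: int) -> int:
    """Free parameters of the K-class independent-Bernoulli mixture:
    K*J item probabilities plus K-1 mixing proportions."""
    if n_classes < 1 or n_items < 1:
        raise ValueError("n_classes and n_items must be >= 1")
    return n_classes * n_items + (n_classes - 1)


@dataclass(frozen=True)
class FitStats:
    """Fit statistics for one fitted class count."""

    n_classes: int
    llf: float
    n_parameters: int
    bic: float
    sabic: float
    aic: float
    caic: float
    entropy: float | None  # None for K=1 (undefined)

    def as_row(self) -> dict:
        return {
            "K": self.n_classes,
            "LL": self.llf,
            "BIC": self.bic,
            "SABIC": self.sabic,
            "AIC": self.aic,
            "CAIC": self.caic,
            "Entropy": np.nan if self.entropy is None else self.entropy,
        }


def information_criteria(
    llf: float, n_classes: int, n_items: int, nobs: int,
    entropy: float | None = None,
) -> FitStats:
    """BIC/SABIC/AIC/CAIC from a log-likelihood and the model dimensions."""
    if nobs < 2:
        raise ValueError("information criteria require N >= 2")
    p = count_parameters(n_classes, n_items)
    neg2ll = -2.0 * llf
    log_n = np.log(nobs)
    return FitStats(
        n_classes=n_classes,
        llf=llf,
        n_parameters=p,
        bic=neg2ll + p * log_n,
        sabic=neg2ll + p * np.log((nobs + 2) / 24.0),
        aic=neg2ll + 2.0 * p,
        caic=neg2ll + p * (log_n + 1.0),
        entropy=entropy,
    )


def relative_entropy(posteriors: np.ndarray, n_classes: int | None = None) -> float | None:
    """Standardised entropy E = 1 - sum_i H(p_i) / (N ln K), with
    0 ln 0 := 0; returns None (undefined) for K = 1."""
    post = np.atleast_2d(np.asarray(posteriors, dtype=float))
    k = n_classes if n_classes is not None else post.shape[1]
    if k <= 1:
        return None
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(post > 0, post * np.log(post), 0.0)
    total_entropy = -plogp.sum()
    return float(1.0 - total_entropy / (post.shape[0] * np.log(k)))


@dataclass
class DiagnosticsMatrix:
    """Mean posterior of membership in class (column) among casualties
    assigned to class (row)."""

    values: np.ndarray          # K x K; rows with no assignees are NaN
    class_sizes: np.ndarray     # assigned count per row class
    empty_classes: list[int]    # 1-based classes with no assignees

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.values)

    def well_separated(
        self,
        diag_threshold: float = DIAGONAL_THRESHOLD,
        offdiag_threshold: float = OFFDIAG_THRESHOLD,
    ) -> np.ndarray:
        """Per-row flag: diagonal >= diag_threshold and every off-diagonal
        <= offdiag_threshold (the conventional reading of separation)."""
        k = self.values.shape[0]
        out = np.zeros(k, dtype=bool)
        for r in range(k):
            if r + 1 in self.empty_classes:
                continue
            off = np.delete(self.values[r], r)
            out[r] = (self.values[r, r] >= diag_threshold) and (
                off.size == 0 or off.max() <= offdiag_threshold
            )
        return out

    def to_dataframe(self) -> pd.DataFrame:
        k = self.values.shape[0]
        df = pd.DataFrame(
            self.values,
            index=pd.Index(range(1, k + 1), name="assigned_class"),
            columns=[str(c) for c in range(1, k + 1)],
        )
        df.insert(0, "n", self.class_sizes)
        return df


def classification_diagnostics(
    posteriors: np.ndarray, assignments: np.ndarray, n_classes: int
) -> DiagnosticsMatrix:
    """Average the posterior rows within each hard-assignment group.

    Entry (r, c) is the mean posterior probability of class c among
    casualties assigned to class r; groups with no assignees yield a NaN
    row and are flagged."""
    post = np.atleast_2d(np.asarray(posteriors, dtype=float))
    assignments = np.asarray(assignments)
    values = np.full((n_classes, n_classes), np.nan)
    sizes = np.zeros(n_classes, dtype=int)
    empty = []
    for r in range(1, n_classes + 1):
        mask = assignments == r
        sizes[r - 1] = mask.sum()
        if sizes[r - 1] == 0:
            empty.append(r)
            logger.warning("no casualties assigned to class %d; diagnostics row undefined", r)
            continue
        values[r - 1] = post[mask].mean(axis=0)
    return DiagnosticsMatrix(values, sizes, empty)


def fit_statistics(results: LatentClassResults) -> FitStats:
    """Full fit-statistics row for one fitted model."""
    return information_criteria(
        results.llf,
        results.n_classes,
        results.model.n_items,
        results.nobs,
        entropy=relative_entropy(results.posteriors, results.n_classes),
    )


class ModelScan:
    """Results of fitting a range of class counts to one cohort.

    ``selected`` is the CAIC-minimising K (the automatic quantitative
    rule); ``table()`` renders all criteria so the qualitative judgement
    — coherent, interpretable classes — can override it.
    """

    def __init__(self, fits, stats, errors):
        self.fits: dict[int, LatentClassResults] = fits
        self.stats: dict[int, FitStats] = stats
        self.errors: dict[int, Exception] = errors
        if not stats:
            raise FittingError("every class count in the scan failed to fit")
        self.selected: int = min(self.stats, key=lambda k: self.stats[k].caic)

    @property
    def best(self) -> LatentClassResults:
        return self.fits[self.selected]

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame([self.stats[k].as_row() for k in sorted(self.stats)])
        return df.set_index("K")

    def format_table(self) -> str:
        """Fit-statistics table with the best value per criterion starred."""
        df = self.table()
        lines = ["K    LL          BIC         SABIC       AIC         CAIC        Entropy"]
        best = {c: df[c].idxmin() for c in ("BIC", "SABIC", "AIC", "CAIC")}
        best["LL"] = df["LL"].idxmax()
        ent = df["Entropy"].dropna()
        best["Entropy"] = ent.idxmax() if len(ent) else None
        for k, row in df.iterrows():
            cells = [f"{k:<4d}"]
            for c in ("LL", "BIC", "SABIC", "AIC", "CAIC"):
                mark = "*" if best[c] == k else " "
                cells.append(f"{row[c]:>10.1f}{mark}")
            if np.isnan(row["Entropy"]):
                cells.append("      -")
            else:
                mark = "*" if best["Entropy"] == k else " "
                cells.append(f"{row['Entropy']:>6.3f}{mark}")
            lines.append(" ".join(cells))
        lines.append(f"selected (smallest CAIC): K = {self.selected}")
        return "\n".join(lines)


def scan_models(
    data,
    k_range=range(1, 11),
    n_starts: int = 20,
    tol: float = 1e-8,
    maxiter: int = 5000,
    seed: int | np.random.SeedSequence | None = None,
    item_names=None,
) -> ModelScan:
    """Fit every K in ``k_range``; per-K failures are recorded, not fatal.

    Each K gets an independent child seed of ``seed`` so the scan is
    reproducible as a whole.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(k_range))
    fits, stats, errors = {}, {}, {}
    for k, child in zip(k_range, children):
        try:
            model = LatentClassModel(data, k, item_names=item_names)
            res = model.fit(n_starts=n_starts, tol=tol, maxiter=maxiter, seed=child)
        except (FittingError, ValueError) as exc:
            logger.warning("fit failed for K=%d: %s", k, exc)
            errors[k] = exc
            continue
        fits[k] = res
        stats[k] = fit_statistics(res)
    return ModelScan(fits, stats, errors)
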