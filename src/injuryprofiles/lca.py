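"""Latent class analysis for binary indicators: a K-component mixture of
independent Bernoulli items fitted by EM.

Model
-----
Casualty i carries J binary indicators x_i.  Each casualty belongs to one
of K unobserved classes; class k has prior probability (mixing proportion)
pi_k and, given the class, the items are independent with conditional item
probabilities rho_jk:

    P(x_i) = sum_k pi_k * prod_j rho_jk^x_ij * (1 - rho_jk)^(1 - x_ij)

EM alternates the E-step (posterior class membership per casualty, computed
in log space) with the M-step (responsibility-weighted proportions and item
frequencies).  The likelihood is multimodal, so the fit runs several random
restarts and keeps the best.  Classes are re-ordered canonically by
descending mixing proportion so that fits are comparable across runs.

The surface mirrors statsmodels: ``LatentClassModel(data, n_classes)`` with
``.fit()`` returning a :class:`LatentClassResults` carrying parameters,
posteriors, hard assignments and diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LCAParams",
    "LatentClassModel",
    "LatentClassResults",
    "log_likelihood",
    "e_step",
    "m_step",
    "assign_classes",
    "DegenerateClassError",
    "FittingError",
    "PROB_EPS",
]

logger = logging.getLogger(__name__)

# Clipping bound on conditional item probabilities: keeps log(0) out of the
# E-step and prevents absorption at the boundary.  Perturbs the LL by far
# less than the convergence tolerance at the cohort sizes used here.
PROB_EPS = 1e-6


class DegenerateClassError(RuntimeError):
    """A class lost essentially all responsibility during EM (restart signal)."""


class FittingError(RuntimeError):
    """No EM restart produced a usable solution."""


@dataclass
class LCAParams:
    """Mixture parameters: mixing proportions (length K, simplex) and
    conditional item probabilities (J x K, clipped to [eps, 1-eps])."""

    mixing: np.ndarray
    item_probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.item_probs = np.atleast_2d(np.asarray(self.item_probs, dtype=float))
        if self.mixing.ndim != 1 or self.item_probs.shape[1] != self.mixing.shape[0]:
            raise ValueError(
                f"item_probs shape {self.item_probs.shape} inconsistent with "
                f"{self.mixing.shape[0]} mixing proportions"
            )
        if abs(self.mixing.sum() - 1.0) > 1e-10:
            raise ValueError(f"mixing proportions sum to {self.mixing.sum()!r}, not 1")
        if (self.mixing < 0).any():
            raise ValueError("negative mixing proportion")
        if (self.item_probs < 0).any() or (self.item_probs > 1).any():
            raise ValueError("item probabilities outside [0, 1]")

    @property
    def n_classes(self) -> int:
        return self.mixing.shape[0]

    @property
    def n_items(self) -> int:
        return self.item_probs.shape[0]

    def canonicalized(self) -> "LCAParams":
        """Classes sorted by descending mixing proportion, ties broken by
        the first item's conditional probability (descending)."""
        order = np.lexsort((-self.item_probs[0], -self.mixing))
        return LCAParams(self.mixing[order], self.item_probs[:, order])


def _validate_data(data: np.ndarray, params: LCAParams | None = None) -> np.ndarray:
    data = np.atleast_2d(np.asarray(data))
    if data.size and not np.isin(data, (0, 1)).all():
        raise ValueError("indicator data must be binary 0/1")
    if params is not None and data.shape[1] != params.n_items:
        raise ValueError(
            f"data has {data.shape[1]} items but params expect {params.n_items}"
        )
    return data.astype(float)


def _log_components(params: LCAParams, data: np.ndarray) -> np.ndarray:
    """N x K matrix of log[pi_k * P(x_i | class k)], computed in log space."""
    rho = np.clip(params.item_probs, PROB_EPS, 1.0 - PROB_EPS)
    log_rho = np.log(rho)
    log_1m = np.log1p(-rho)
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.mixing)
    # x @ (log rho - log(1-rho)) + sum_j log(1-rho): one matmul per E-step
    return data @ (log_rho - log_1m) + log_1m.sum(axis=0) + log_pi


def log_likelihood(params: LCAParams, data: np.ndarray) -> float:
    """Observed-data log-likelihood sum_i log sum_k pi_k P(x_i | k)."""
    from scipy.special import logsumexp

    data = _validate_data(data, params)
    if data.shape[0] == 0:
        return 0.0
    return float(logsumexp(_log_components(params, data), axis=1).sum())


def e_step(params: LCAParams, data: np.ndarray) -> tuple[np.ndarray, float]:
    """Posterior membership probabilities (rows normalised) and the LL."""
    from scipy.special import logsumexp

    data = _validate_data(data, params)
    log_comp = _log_components(params, data)
    norm = logsumexp(log_comp, axis=1, keepdims=True)
    post = np.exp(log_comp - norm)
    return post, float(norm.sum())


def m_step(posteriors: np.ndarray, data: np.ndarray) -> LCAParams:
    """Maximisation update: pi_k = mean responsibility, rho_jk =
    responsibility-weighted item frequency, clipped away from 0/1."""
    posteriors = np.atleast_2d(np.asarray(posteriors, dtype=float))
    data = _validate_data(data)
    resp = posteriors.sum(axis=0)
    if (resp < 10 * np.finfo(float).eps).any():
        raise DegenerateClassError("a class received essentially zero responsibility")
    mixing = resp / resp.sum()
    rho = (data.T @ posteriors) / resp
    rho = np.clip(rho, PROB_EPS, 1.0 - PROB_EPS)
    return LCAParams(mixing, rho)


def assign_classes(posteriors: np.ndarray) -> np.ndarray:
    """Maximum-probability assignment: 1-based argmax per row, ties to the
    lowest class index (numpy argmax convention)."""
    return np.argmax(np.atleast_2d(posteriors), axis=1) + 1


class LatentClassModel:
    """Latent class model for an N x J binary indicator matrix.

    Parameters
    ----------
    endog : array-like or DataFrame of shape (N, J)
        Binary indicators; a DataFrame's columns become item names.
    n_classes : int
        Number of latent classes K (>= 1).
    item_names : sequence of str, optional
        Overrides column labels for reporting.
    """

    def __init__(self, endog, n_classes: int, item_names=None):
        if n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if isinstance(endog, pd.DataFrame):
            if item_names is None:
                item_names = list(endog.columns)
            endog = endog.to_numpy()
        self.endog = _validate_data(np.asarray(endog))
        if self.endog.shape[0] == 0:
            raise ValueError("empty data: at least one casualty is required")
        self.n_classes = int(n_classes)
        self.nobs, self.n_items = self.endog.shape
        self.item_names = (
            list(item_names) if item_names is not None
            else [f"item_{j}" for j in range(self.n_items)]
        )

    @classmethod
    def from_indicator_matrix(cls, matrix, n_classes: int) -> "LatentClassModel":
        """Build from a :class:`~injuryprofiles.coding.IndicatorMatrix`."""
        return cls(matrix.values, n_classes, item_names=matrix.column_names())

    def loglike(self, params: LCAParams) -> float:
        return log_likelihood(params, self.endog)

    def _run_em(self, rng, tol: float, maxiter: int) -> tuple[LCAParams, float, int, bool]:
        n, k = self.nobs, self.n_classes
        post = rng.dirichlet(np.ones(k), size=n)
        params = m_step(post, self.endog)
        ll_old = -np.inf
        for it in range(1, maxiter + 1):
            post, ll = e_step(params, self.endog)
            if ll < ll_old - 1e-8 * max(1.0, abs(ll_old)):
                logger.warning("log-likelihood decreased at iteration %d", it)
            if np.isfinite(ll_old) and (ll - ll_old) <= tol * abs(ll_old):
                return params, ll, it, True
            params = m_step(post, self.endog)
            ll_old = ll
        ll = log_likelihood(params, self.endog)
        return params, ll, maxiter, False

    def fit(
        self,
        n_starts: int = 20,
        tol: float = 1e-8,
        maxiter: int = 5000,
        seed: int | np.random.SeedSequence | None = None,
    ) -> "LatentClassResults":
        """Fit by EM with random restarts; the best final LL wins.

        Each restart draws initial posteriors from a flat Dirichlet and
        starts with an M-step.  Convergence is declared when the relative
        LL improvement drops below ``tol``.  Fully reproducible for a
        fixed ``seed``.
        """
        if self.n_classes == 1:
            # closed-form MLE: the item marginal frequencies
            rho = np.clip(self.endog.mean(axis=0)[:, None], PROB_EPS, 1 - PROB_EPS)
            params = LCAParams(np.ones(1), rho)
            ll = self.loglike(params)
            post = np.ones((self.nobs, 1))
            return LatentClassResults(self, params, ll, post, 1, True, 1, seed)

        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        best = None
        n_degenerate = 0
        for child in ss.spawn(n_starts):
            rng = np.random.default_rng(child)
            try:
                params, ll, n_iter, converged = self._run_em(rng, tol, maxiter)
            except DegenerateClassError:
                n_degenerate += 1
                continue
            if best is None or ll > best[1]:
                best = (params, ll, n_iter, converged)
        if best is None:
            raise FittingError(
                f"all {n_starts} EM restarts degenerated (K={self.n_classes}, "
                f"N={self.nobs}, J={self.n_items})"
            )
        if n_degenerate:
            logger.info("%d of %d restarts degenerated and were discarded",
                        n_degenerate, n_starts)
        params, ll, n_iter, converged = best
        params = params.canonicalized()
        post, ll = e_step(params, self.endog)
        return LatentClassResults(
            self, params, ll, post, n_iter, converged, n_starts - n_degenerate, seed
        )


class LatentClassResults:
    """Fitted latent class model.

    Attributes
    ----------
    params : LCAParams
        Canonically ordered estimates (descending prevalence).
    llf : float
        Log-likelihood at the estimates.
    posteriors : ndarray (N, K)
        Posterior class-membership probabilities (rows sum to 1).
    assignments : ndarray (N,)
        Hard 1-based classes from the maximum-probability rule.
    """

    def __init__(self, model, params, llf, posteriors, n_iter, converged,
                 n_restarts_used, seed):
        self.model = model
        self.params = params
        self.llf = float(llf)
        self.posteriors = posteriors
        self.assignments = assign_classes(posteriors)
        self.n_iter = n_iter
        self.converged = converged
        self.n_restarts_used = n_restarts_used
        self.seed = seed

    @property
    def n_classes(self) -> int:
        return self.params.n_classes

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def mixing(self) -> np.ndarray:
        return self.params.mixing

    @property
    def item_probs(self) -> np.ndarray:
        """J x K conditional item probabilities."""
        return self.params.item_probs

    @property
    def class_sizes(self) -> np.ndarray:
        """Assigned casualties per class (1..K)."""
        return np.bincount(self.assignments, minlength=self.n_classes + 1)[1:]

    def fit_stats(self):
        """Information criteria and relative entropy (see model_selection)."""
        from .selection import fit_statistics

        return fit_statistics(self)

    def diagnostics(self):
        """Mean-posterior classification diagnostics matrix."""
        from .selection import classification_diagnostics

        return classification_diagnostics(self.posteriors, self.assignments, self.n_classes)

    def item_prob_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.item_probs,
            index=self.model.item_names,
            columns=[f"class_{k}" for k in range(1, self.n_classes + 1)],
        )

    def summary(self) -> str:
        """Plain-text summary: sizes, prevalences, fit statistics."""
        stats = self.fit_stats()
        lines = [
            "Latent Class Model Results",
            "=" * 60,
            f"No. observations: {self.nobs:>10d}    No. items: {self.model.n_items}",
            f"No. classes:      {self.n_classes:>10d}    Converged: {self.converged}",
            f"Log-likelihood:   {self.llf:>12.1f}    Parameters: {stats.n_parameters}",
            f"BIC: {stats.bic:.1f}  SABIC: {stats.sabic:.1f}  "
            f"AIC: {stats.aic:.1f}  CAIC: {stats.caic:.1f}",
            f"Relative entropy: "
            + (f"{stats.entropy:.3f}" if stats.entropy is not None else "-"),
            "-" * 60,
            "class  mixing  assigned  share",
        ]
        sizes = self.class_sizes
        for k in range(self.n_classes):
            lines.append(
                f"{k + 1:>5d}  {self.mixing[k]:.3f}  {sizes[k]:>8d}  "
                f"{sizes[k] / self.nobs:.3f}"
            )
        return "\n".join(lines)

    def plot_profiles(self, threshold: float = 0.30, ax=None):
        """Heatmap of conditional item probabilities; defining entries
        (>= threshold) are outlined."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(
                figsize=(4 + 0.6 * self.n_classes, 2 + 0.12 * self.model.n_items)
            )
        im = ax.imshow(self.item_probs, aspect="auto", cmap="viridis", vmin=0, vmax=1)
        ax.set_xticks(range(self.n_classes),
                      [f"class {k}" for k in range(1, self.n_classes + 1)])
        ax.set_xlabel("latent class")
        ax.set_ylabel("injury indicator")
        rows, cols = np.nonzero(self.item_probs >= threshold)
        ax.scatter(cols, rows, marker="s", s=12, facecolors="none",
                   edgecolors="white", linewidths=0.8)
        ax.figure.colorbar(im, ax=ax, label="conditional item probability")
        return ax
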