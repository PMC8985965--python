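"""Synthetic casualty cohorts with known latent-class structure.

The restricted source registry behind the original cohort cannot be
redistributed, so every stage of the pipeline is exercised on synthetic
cohorts drawn from the exact generative model the analysis assumes: each
casualty belongs to one of K latent injury profiles drawn from the mixing
proportions; given the profile, J binary Barell-cell indicators are set
independently with class-specific probabilities; categorical covariates
are drawn from class-conditional distributions.  The default template
encodes the published seven-profile solution: 26 indicators carry class
signal at their reported conditional probabilities, every other indicator
fires at a low background rate, and mixing proportions and covariate
distributions follow the reported class-wise counts.

A master seed drives everything; per-stage child seeds are derived
deterministically, so a cohort is byte-reproducible from its config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _tables
from .barell import (
    CodingError,
    FRACTURE_CLOSED_COL,
    FRACTURE_OPEN_COL,
    all_cells,
    cell,
    cell_id,
    nature_table,
    parse_cell_id,
    region_table,
)
from .coding import IndicatorMatrix, InjuryRecord

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "default_template",
    "sample_cohort",
    "sample_injury_records",
    "DEFAULT_BACKGROUND",
    "DEFAULT_SEVERITY",
]

DEFAULT_BACKGROUND = 0.05
# Default per-cell AIS distribution over severities 1..5: most coded
# injuries in a serious-injury cohort are low AIS, with a tail of severe.
DEFAULT_SEVERITY = (0.20, 0.30, 0.30, 0.15, 0.05)
BLOCK_SIGNAL_PROB = 0.80  # signal strength for non-default block templates


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-cohort generative model.

    ``template`` is the K x J matrix of conditional item probabilities,
    ``cell_ids`` names the J items (Barell cell ids), and
    ``covariate_model`` maps each covariate to per-level class-conditional
    probabilities (level -> length-K list).
    """

    n_classes: int
    n_items: int
    n: int
    mixing: np.ndarray
    template: np.ndarray = field(repr=False)
    cell_ids: list[str] = field(repr=False)
    covariate_model: dict[str, dict[str, list[float]]] = field(default_factory=dict, repr=False)
    background_probability: float = DEFAULT_BACKGROUND
    seed: int = 0

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.template = np.asarray(self.template, dtype=float)
        if self.n_classes < 1 or self.n_items < 1 or self.n < 0:
            raise ValueError("require K >= 1, J >= 1, N >= 0")
        if self.mixing.shape != (self.n_classes,):
            raise ValueError("mixing proportions must have length K")
        if abs(self.mixing.sum() - 1.0) > 1e-12 or (self.mixing < 0).any():
            raise ValueError("mixing proportions must form a simplex (sum 1)")
        if self.template.shape != (self.n_classes, self.n_items):
            raise ValueError(
                f"template shape {self.template.shape} != (K={self.n_classes}, J={self.n_items})"
            )
        if (self.template < 0).any() or (self.template > 1).any():
            raise ValueError("template probabilities outside [0, 1]")
        if not 0 <= self.background_probability <= 1:
            raise ValueError("background probability outside [0, 1]")
        if len(self.cell_ids) != self.n_items:
            raise ValueError("cell_ids must name all J items")
        for var, levels in self.covariate_model.items():
            probs = np.asarray(list(levels.values()), dtype=float)
            if probs.shape[1] != self.n_classes:
                raise ValueError(f"covariate {var!r} probabilities not length K per level")
            if (probs < 0).any() or not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
                raise ValueError(f"covariate {var!r} class-conditional probabilities must sum to 1")

    def expected_item_frequency(self) -> np.ndarray:
        """Marginal P(item j = 1) = sum_k pi_k * rho_kj."""
        return self.mixing @ self.template

    # --- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "n_items": self.n_items,
            "n": self.n,
            "mixing": [float(x) for x in self.mixing],
            "template": [[float(x) for x in row] for row in self.template],
            "cell_ids": list(self.cell_ids),
            "covariate_model": {
                var: {lvl: [float(x) for x in p] for lvl, p in levels.items()}
                for var, levels in self.covariate_model.items()
            },
            "background_probability": float(self.background_probability),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(
            n_classes=int(d["n_classes"]),
            n_items=int(d["n_items"]),
            n=int(d["n"]),
            mixing=np.asarray(d["mixing"], dtype=float),
            template=np.asarray(d["template"], dtype=float),
            cell_ids=list(d["cell_ids"]),
            covariate_model=d.get("covariate_model", {}),
            background_probability=float(d.get("background_probability", DEFAULT_BACKGROUND)),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SyntheticCohort:
    """A generated cohort: indicators, true classes, covariates, records."""

    indicators: IndicatorMatrix
    true_labels: np.ndarray  # 1-based class per casualty
    covariates: pd.DataFrame
    records: list[InjuryRecord] | None = None

    def __post_init__(self) -> None:
        n = self.indicators.n_casualties
        self.true_labels = np.asarray(self.true_labels)
        if len(self.true_labels) != n or len(self.covariates) != n:
            raise ValueError("cohort components disagree on the number of casualties")

    @property
    def n(self) -> int:
        return self.indicators.n_casualties

    def write(self, outdir: str | Path) -> None:
        """Write indicators, covariates and (if present) records as CSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ind = self.indicators.to_dataframe()
        ind.to_csv(outdir / "indicators.csv")
        cov = self.covariates.copy()
        cov.insert(0, "true_class", self.true_labels)
        cov.to_csv(outdir / "covariates.csv", index_label="casualty_id")
        if self.records is not None:
            from .coding import records_to_dataframe

            records_to_dataframe(self.records).to_csv(outdir / "records.csv", index=False)


def _default_cell_ids(n_items: int, signal_cells: list[str]) -> list[str]:
    """Signal cells first, then remaining matrix cells in row-major order."""
    if n_items < len(signal_cells):
        raise ValueError(
            f"J={n_items} smaller than the {len(signal_cells)} template items"
        )
    chosen = list(signal_cells)
    seen = set(chosen)
    for c in all_cells():
        if len(chosen) == n_items:
            break
        cid = cell_id(c)
        if cid not in seen:
            chosen.append(cid)
            seen.add(cid)
    if len(chosen) < n_items:
        raise ValueError(f"J={n_items} exceeds the {36 * 13} cells of the matrix")
    return chosen


def default_template(
    n_classes: int = 7,
    n_items: int = 181,
    n: int = _tables.STUDY_N,
    background_probability: float = DEFAULT_BACKGROUND,
    seed: int = 0,
) -> GeneratorConfig:
    """The default study-condition generator configuration.

    For K = 7 the template reproduces the 26 published signal-item
    conditional probabilities, sets every other item to the background
    rate, takes mixing proportions from the assigned class counts, and
    class-conditional covariate distributions from the reported class-wise
    counts.  For any other K a block-diagonal template is built instead:
    class k fires its own block of items with probability 0.8, uniform
    mixing, no covariates.
    """
    if n_classes == 7:
        signal_cells = [
            cell_id(cell(region, nature)) for nature, region in _tables.SIGNAL_ITEMS
        ]
        cell_ids = _default_cell_ids(n_items, signal_cells)
        template = np.full((7, n_items), background_probability)
        template[:, : len(signal_cells)] = np.asarray(_tables.SIGNAL_PROBS).T
        counts = np.asarray(_tables.CLASS_COUNTS, dtype=float)
        mixing = counts / counts.sum()
        covariate_model = {
            var: {lvl: list(np.asarray(c, dtype=float) / counts) for lvl, c in levels.items()}
            for var, levels in _tables.COVARIATE_COUNTS.items()
        }
        return GeneratorConfig(
            n_classes=7, n_items=n_items, n=n, mixing=mixing, template=template,
            cell_ids=cell_ids, covariate_model=covariate_model,
            background_probability=background_probability, seed=seed,
        )
    # generic well-separated block-diagonal design
    cell_ids = _default_cell_ids(n_items, [])
    template = np.full((n_classes, n_items), background_probability)
    block = max(1, n_items // n_classes)
    for k in range(n_classes):
        lo = k * block
        hi = n_items if k == n_classes - 1 else min(n_items, lo + block)
        template[k, lo:hi] = BLOCK_SIGNAL_PROB
    mixing = np.full(n_classes, 1.0 / n_classes)
    mixing[-1] = 1.0 - mixing[:-1].sum()  # exact simplex
    return GeneratorConfig(
        n_classes=n_classes, n_items=n_items, n=n, mixing=mixing, template=template,
        cell_ids=cell_ids, covariate_model={},
        background_probability=background_probability, seed=seed,
    )


def sample_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a cohort from the generative model (seed-reproducible).

    Classes come from the mixing proportions, indicators independently
    from the class's template row, covariates from the class-conditional
    categorical distributions.
    """
    ss = np.random.SeedSequence(config.seed)
    label_rng, item_rng, cov_rng, _record_seed = ss.spawn(4)
    n, k, j = config.n, config.n_classes, config.n_items

    labels0 = np.random.default_rng(label_rng).choice(k, size=n, p=config.mixing)
    values = (
        np.random.default_rng(item_rng).random((n, j)) < config.template[labels0]
    ).astype(np.int8)
    ids = [f"c{i:06d}" for i in range(n)]
    indicators = IndicatorMatrix(ids, [parse_cell_id(c) for c in config.cell_ids], values)

    cov_gen = np.random.default_rng(cov_rng)
    cov_data: dict[str, np.ndarray] = {}
    for var, levels in config.covariate_model.items():
        names = list(levels.keys())
        probs = np.asarray([levels[lvl] for lvl in names], dtype=float)  # L x K
        out = np.empty(n, dtype=object)
        for cls in range(k):
            mask = labels0 == cls
            if mask.any():
                out[mask] = cov_gen.choice(names, size=mask.sum(), p=probs[:, cls])
        cov_data[var] = out
    covariates = pd.DataFrame(cov_data, index=pd.Index(ids, name="casualty_id"))

    return SyntheticCohort(indicators, labels0 + 1, covariates)


def _severity_probs(severity_model, cid: str, known: set[str]) -> np.ndarray:
    if severity_model is None:
        return np.asarray(DEFAULT_SEVERITY)
    for key in severity_model:
        if key != "default" and key not in known:
            raise CodingError(f"severity model references unknown cell id {key!r}")
    probs = severity_model.get(cid, severity_model.get("default", DEFAULT_SEVERITY))
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (5,) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"severity distribution for {cid!r} must be 5 probabilities summing to 1")
    return probs


def sample_injury_records(
    cohort: SyntheticCohort,
    severity_model: dict[str, list[float]] | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """Emit injury records consistent with the cohort's indicators.

    For every positive indicator one record is generated in that Barell
    cell with an AIS severity (1-5) drawn from ``severity_model`` — a
    mapping of cell id to a 5-probability distribution with an optional
    ``"default"`` entry — so that re-coding the records reproduces the
    indicator matrix exactly.
    """
    rng = np.random.default_rng(seed)
    regions = region_table()
    natures = nature_table()
    known = {cell_id(c) for c in cohort.indicators.cell_index}
    records: list[InjuryRecord] = []
    values = cohort.indicators.values
    for i, cid_ in enumerate(cohort.indicators.casualty_ids):
        for j in np.nonzero(values[i])[0]:
            c = cohort.indicators.cell_index[j]
            probs = _severity_probs(severity_model, cell_id(c), known)
            ais = int(rng.choice(5, p=probs)) + 1
            if c.nature_col in (FRACTURE_OPEN_COL, FRACTURE_CLOSED_COL):
                nature_code = "fracture"
                flag = c.nature_col == FRACTURE_OPEN_COL
            else:
                nature_code = natures.loc[c.nature_col, "nature_code"]
                flag = None
            records.append(
                InjuryRecord(
                    casualty_id=cid_,
                    region_code=regions.loc[c.region_row, "region_code"],
                    nature_code=nature_code,
                    ais=ais,
                    open_fracture=flag,
                )
            )
    return SyntheticCohort(cohort.indicators, cohort.true_labels, cohort.covariates, records)
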