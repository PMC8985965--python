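# Methods

This note documents the statistical model, the numerical choices, what
the synthetic-data generator does and does not emulate, and the known
limitations.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The latent class model

The measurement model is a K-component mixture of independent Bernoulli
items over J binary injury indicators.  Parameters are the mixing
proportions π (a K-simplex) and the conditional item probabilities
ρ (J x K).  Assumptions worth stating explicitly:

- **Local independence**: indicators are independent *given* the class.
  All marginal association between injuries is carried by class
  membership.  Real polytrauma can violate this (e.g. mechanically
  linked injuries within a class), which inflates the apparent number
  of classes; the criterion scan plus the analyst's coherence judgement
  is the guard.
- **One class per casualty**: profiles are mutually exclusive; a
  casualty with features of two profiles is expressed through posterior
  uncertainty, not multiple membership.
- Covariates are *descriptive only*: they do not enter the measurement
  model (no concomitant-variable LCA).

### Estimation

EM in log space.  The E-step computes posterior memberships from one
matmul (`x @ (log ρ − log(1−ρ)) + Σ log(1−ρ) + log π`) and a row-wise
log-sum-exp; the M-step is responsibility-weighted means.  Choices:

- **Initialisation**: posteriors drawn from a flat Dirichlet, followed
  by an M-step; `n_starts=20` restarts by default, best final
  log-likelihood wins.  Restart counts of this order are standard for
  multimodal binary-mixture likelihoods.
- **Convergence**: relative LL improvement below `tol=1e-8`, cap 5,000
  iterations.  Tight enough that information criteria are stable to
  well below their decision margins.
- **Clipping**: ρ is kept in [1e-6, 1−1e-6] to avoid log(0) and
  boundary absorption; the LL perturbation is far below `tol` at the
  cohort sizes used.
- **Degeneracy**: a class whose total responsibility collapses to ~0
  aborts that restart; if every restart degenerates, fitting fails
  loudly.
- **Canonical order**: classes sorted by descending π (ties: first
  item's ρ), so fits are comparable across seeds and runs.  Class
  *numbering* is otherwise arbitrary.
- **K=1** is returned in closed form (item marginal frequencies), not
  via EM.
- **Assignment ties** (exactly equal posteriors) go to the lowest class
  index — a measure-zero event that still needs a fixed rule for
  reproducibility.

### Model selection

With p = K·J + (K−1) free parameters and N casualties:

    BIC   = −2LL + p ln N          AIC  = −2LL + 2p
    CAIC  = −2LL + p (ln N + 1)    SABIC = −2LL + p ln((N+2)/24)

The SABIC and CAIC penalty dialects were confirmed by recomputing the
published fit-statistics table rows from their printed log-likelihoods
(test suite, information-criteria tests; agreement within the printed
rounding of ±0.15).  The automatic selection rule is the CAIC minimum —
the stated quantitative basis of the published selection — but the scan
prints every criterion and the entropy so the qualitative judgement
(coherent, interpretable classes) can override; that judgement is a
human step and is not automated.

Relative entropy is the standardised form
E = 1 − Σ_i H(p_i) / (N ln K) ∈ [0,1], undefined (reported as "-") for
K = 1.  The conventional reading — E > 0.80 "good" classification, mean
posterior diagonals > 0.70 with off-diagonals ≤ 0.05 "well separated" —
is applied in the diagnostics report.

## Injury coding and severity

The extended Barell matrix is shipped as versioned CSVs: 36 region rows,
13 nature columns (fractures split open/closed), 468 cells.  An
indicator is *presence* (≥1 injury in the cell), never a count, and only
populated cells are kept, so J is data-dependent (181 in the study this
emulates).  Column order is Barell row-major for determinism.

The bundled ICD-9-CM range table is an illustrative, self-contained
dialect for round-trip testing; it is *not* the official crosswalk,
which is deliberately out of scope.

ISS uses the six standard body regions.  The Barell-row → ISS-region
bridge is unavoidably a convention (the matrix was not designed for
ISS); the shipped mapping follows standard practice — cervical spine
with head/neck, thoracic spine with chest, lumbar/sacral spine with
abdomen, pelvis with extremities — and lives in an editable column of
`barell_rows.csv`.  AIS 6 forces ISS = 75 (standard convention; rarely
exercised in survivor cohorts).  The top-3 rule is verified against
brute-force subset maximisation, which also shows ties among regional
maxima need no tie rule.

## Profiling and comparisons

Classes become injury profiles via the ρ ≥ 0.30 threshold ("at least",
so the boundary is retained), items listed in descending probability;
display names are analyst-supplied.  Covariate comparisons: omnibus
Pearson chi-square (no continuity correction, expected-count < 5
warnings), then all C(K,2) two-proportion chi-square tests per level of
each variable, Holm-adjusted.  Two conventions the published wording
leaves open, fixed here and surfaced in the reports:

- the Holm family is *one level of one variable* (matching the row-wise
  superscript presentation of the published characteristics table);
- explicit "Unknown" categories are displayed but excluded from
  pairwise testing.

Percentages are displayed half-up to one decimal; tests always use
unrounded counts.

## The synthetic-cohort generator

The generator draws from exactly the model the analysis assumes — class
from π, indicators independently from the class's template row,
covariates from class-conditional categorical distributions — so it is
the ground truth for recovery tests, not merely a fixture.  Defaults
encode the published seven-profile study conditions:

- the 26 supra-threshold conditional item probabilities at their
  reported values (signal items);
- all other items at a uniform **background rate of 0.05** per class —
  the published table reports sub-threshold probabilities only as
  ranging up to 0.28 without listing them, so a single low rate is the
  simplest defensible choice and is *not* claimed to match the source
  registry's marginals;
- mixing proportions from the assigned class counts over N = 5,227
  (exact simplex; the printed one-decimal percentages sum to 100.1 and
  cannot be used verbatim);
- class-conditional covariate distributions from the published
  class-wise counts, with "Unknown" posture an explicit category.  One
  printed count (class 4, injured 2009–2019) is inconsistent with its
  own class size and printed percentage; the count implied by the
  percentage (533 = 66.3% of 804) is used.
- Injury records, when requested, carry one record per positive
  indicator with AIS drawn per cell from a configurable severity
  distribution (default (0.20, 0.30, 0.30, 0.15, 0.05) over AIS 1–5,
  a low-skewed mix plausible for a serious-injury survivor cohort);
  re-coding the records reproduces the indicator matrix exactly.

Seeding: one master seed per config; stage-level child seeds are
spawned deterministically (labels / indicators / covariates / records),
so cohorts are byte-reproducible and stages can be re-drawn
independently.

**What the generator does not emulate**: violation of local
independence, sub-threshold item structure, ICD-code-level realism,
temporal deployment dynamics, repeat casualties.  Passing recovery
tests therefore demonstrates correctness of the estimation machinery
under the assumed model, not fidelity of the model to real registry
data.

## Problem sizes used in the checks

Recovery checks fit K = 7 on one default cohort of N = 5,000 with 20
restarts; selection-recovery runs 20 replicate 3-class cohorts (J = 30,
N = 2,000) scanned over K = 1–6 with 5 restarts; sampling-distribution
checks use one cohort of N = 20,000.  These sizes give the recovery
statistics comfortable margins (binomial/correlation standard errors
well inside the asserted bands) while keeping the whole suite
desk-scale.

## Known limitations

- **Individual-level separability of the default template.**  With only
  26 class-informative items and a class-uniform background, the
  Bayes-optimal classifier under the true generator parameters reaches
  an adjusted Rand index of about 0.60 against the true labels and a
  relative entropy of about 0.73 at N = 5,000 (about 82% accuracy).
  Published-solution-level classification quality (mean posterior
  diagonals > 0.90, entropy 0.857) is therefore not reproducible from
  the published table alone: in the real data the 155 unreported
  sub-threshold items also differ across classes and carry the missing
  separation.  Parameter recovery (MAE ≈ 0.02 on signal items) and the
  > 0.70 diagnostics threshold are unaffected; the two test-suite
  assertions that demand ARI ≥ 0.90 and entropy > 0.80 on this template
  document the gap by failing.
- Standard errors for π and ρ are not estimated (no information-matrix
  or bootstrap machinery); uncertainty is reported only through
  posteriors and diagnostics.
- No bootstrap likelihood-ratio test for K; selection rests on the
  information criteria plus analyst judgement.
- The pairwise two-proportion chi-square is asymptotic; with very small
  classes or rare levels the expected-count warnings should be taken
  seriously.
- Casualty *events* are treated as independent rows; a person injured
  twice appears twice.
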