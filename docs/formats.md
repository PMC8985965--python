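# File formats

All stage boundaries are plain CSV (UTF-8, header row); configs are
YAML; run manifests are JSON.  Any stage of the CLI can be run
standalone on files matching these schemas.

## records.csv — casualty injury records

One row per coded injury.

| column | type | meaning |
|---|---|---|
| casualty_id | str | casualty event identifier |
| region_code | str | Barell body-region code or canonical name (see `injuryprofiles/data/barell_rows.csv`) |
| nature_code | str | nature-of-injury code or name; `fracture` requires `open_fracture` |
| ais | int 1–6 | Abbreviated Injury Scale severity |
| open_fracture | bool or empty | open (true) vs closed (false) fracture; ignored otherwise |

## indicators.csv — binary indicator matrix

Index column `casualty_id`; one 0/1 column per populated Barell cell,
named by cell id `rRRcCC` (region row RR 01–36, nature column CC 01–13),
in row-major order.

## iss.csv

`casualty_id, iss (int 1–75), category (below_serious | serious | severe | critical)`.

## covariates.csv

Index `casualty_id`; one categorical column per covariate.  Synthetic
cohorts include a `true_class` column (1-based generating class).

## generator.yaml

Serialised `GeneratorConfig`: `n_classes`, `n_items`, `n`, `mixing`
(length-K simplex), `template` (K x J probabilities), `cell_ids`
(length-J cell ids), `covariate_model` (variable → level → length-K
class-conditional probabilities), `background_probability`, `seed`.

## Fit artifacts

- `fit_statistics.csv` — one row per K: `K, LL, BIC, SABIC, AIC, CAIC,
  Entropy` (entropy empty for K=1); `fit_statistics.txt` is the same
  table formatted, best value per criterion starred.
- `model.json` — selected K, log-likelihood, seed, `mixing`,
  `item_names`, `item_probs` (J x K).
- `posteriors.csv` — `casualty_id`, `class_1..class_K` posterior
  probabilities, `assignment` (1-based argmax).
- `diagnostics.csv` — K x K mean-posterior matrix by assigned class
  (rows) with assigned sizes.

## Profile and comparison artifacts

- `profiles.csv` — `class, prevalence, item, probability` for every
  defining item (probability ≥ threshold), descending per class.
- `characteristics.csv` — per variable level: counts, half-up
  percentages, omnibus p, per-class superscript letters (`a` = differs
  from class 1, …) from Holm-adjusted pairwise tests.
- `comparisons.csv` — every pairwise test: `variable, level, class_a,
  class_b, prop_a, prop_b, raw_p, adjusted_p, significant`.
- `manifest.json` — package/library versions, config echo, seed,
  per-stage summaries (counts, timings, selected K).
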