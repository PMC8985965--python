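"""Synthetic-cohort generator: template defaults, sampling distributions,
record round-trips, determinism."""

import numpy as np
import pandas as pd
import pytest

from injuryprofiles import (
    GeneratorConfig,
    build_indicator_matrix,
    cell,
    cell_id,
    compute_iss,
    default_template,
    sample_cohort,
    sample_injury_records,
)
from injuryprofiles.barell import CodingError
from injuryprofiles._tables import SIGNAL_ITEMS


def item_index(cfg, nature, region):
    return cfg.cell_ids.index(cell_id(cell(region, nature)))


def test_default_template_reproduces_published_entries():
    cfg = default_template(7, 181)
    assert cfg.template.shape == (7, 181)
    # class 4 Type 2 TBI internal-organ and class 6 unspecified burns
    assert cfg.template[3, item_index(cfg, "internal-organ", "type-2-tbi")] == 0.835
    assert cfg.template[5, item_index(cfg, "burn", "unspecified-site")] == 0.986
    assert cfg.mixing[0] == pytest.approx(981 / 5227)
    assert cfg.mixing.sum() == pytest.approx(1.0, abs=1e-15)
    # unlisted items sit at the background rate
    background = np.isclose(cfg.template, cfg.background_probability)
    assert background[:, len(SIGNAL_ITEMS):].all()


def test_default_covariate_model_matches_published_class_counts():
    cfg = default_template()
    mech = cfg.covariate_model["mechanism"]
    assert mech["Blast"][5] == pytest.approx(368 / 387)      # burns profile
    assert mech["Gunshot wound"][6] == pytest.approx(571 / 924)
    for var, levels in cfg.covariate_model.items():
        probs = np.asarray(list(levels.values()))
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-12)


def test_template_rejects_too_few_items():
    with pytest.raises(ValueError, match="smaller than"):
        default_template(7, 10)


def test_config_validation():
    with pytest.raises(ValueError, match="simplex"):
        GeneratorConfig(2, 2, 5, [0.6, 0.6], [[0.5, 0.5], [0.5, 0.5]],
                        ["r01c01", "r01c02"])
    with pytest.raises(ValueError):
        default_template(3, 12, n=-1)


def test_config_yaml_round_trip(tmp_path):
    cfg = default_template(3, 12, n=50, seed=5)
    cfg.to_yaml(tmp_path / "gen.yaml")
    again = GeneratorConfig.from_yaml(tmp_path / "gen.yaml")
    np.testing.assert_allclose(again.template, cfg.template)
    np.testing.assert_allclose(again.mixing, cfg.mixing)
    assert again.cell_ids == cfg.cell_ids
    assert again.seed == 5


def test_empty_cohort_keeps_schema():
    cfg = default_template(3, 12, n=0)
    cohort = sample_cohort(cfg)
    assert cohort.indicators.values.shape == (0, 12)
    assert cohort.indicators.n_items == 12
    assert len(cohort.true_labels) == 0


def test_degenerate_probabilities_copy_template_rows():
    template = np.array([[1, 0, 1, 0], [0, 1, 0, 1]], dtype=float)
    cfg = GeneratorConfig(2, 4, 40, [0.5, 0.5], template,
                          ["r01c01", "r01c02", "r01c03", "r01c04"], seed=3)
    cohort = sample_cohort(cfg)
    for i, lab in enumerate(cohort.true_labels):
        np.testing.assert_array_equal(cohort.indicators.values[i], template[lab - 1])


def test_sampling_reproducible_byte_identical():
    cfg = default_template(n=300, seed=99)
    a, b = sample_cohort(cfg), sample_cohort(cfg)
    np.testing.assert_array_equal(a.indicators.values, b.indicators.values)
    np.testing.assert_array_equal(a.true_labels, b.true_labels)
    pd.testing.assert_frame_equal(a.covariates, b.covariates)


@pytest.fixture(scope="module")
def big_cohort():
    cfg = default_template(n=20000, seed=1234)
    return cfg, sample_cohort(cfg)


def test_item_frequencies_match_mixture_marginals(big_cohort):
    """Each item's empirical frequency within 3 binomial SEs of
    sum_k pi_k rho_kj (binomial sampling oracle at N=20,000)."""
    cfg, cohort = big_cohort
    expected = cfg.expected_item_frequency()
    observed = cohort.indicators.values.mean(axis=0)
    se = np.sqrt(expected * (1 - expected) / cohort.n)
    assert (np.abs(observed - expected) <= 3 * se + 1e-9).mean() > 0.99
    assert (np.abs(observed - expected) <= 4 * se + 1e-9).all()


def test_class_shares_match_mixing_proportions(big_cohort):
    cfg, cohort = big_cohort
    shares = np.bincount(cohort.true_labels - 1, minlength=7) / cohort.n
    se = np.sqrt(cfg.mixing * (1 - cfg.mixing) / cohort.n)
    assert (np.abs(shares - cfg.mixing) <= 3 * se).all()


def test_items_conditionally_independent_within_class(big_cohort):
    """|within-class correlation| < 0.05 for item pairs at N=20,000."""
    _, cohort = big_cohort
    rng = np.random.default_rng(0)
    pairs = [(int(a), int(b)) for a, b in
             rng.integers(0, cohort.indicators.n_items, size=(40, 2)) if a != b]
    # the two largest classes, so the null sampling error of r (~1/sqrt(n_k))
    # sits well inside the 0.05 band
    for k in (1, 5):
        sub = cohort.indicators.values[cohort.true_labels == k].astype(float)
        for a, b in pairs:
            if sub[:, a].std() < 1e-12 or sub[:, b].std() < 1e-12:
                continue
            r = np.corrcoef(sub[:, a], sub[:, b])[0, 1]
            assert abs(r) < 0.05


def test_covariate_shares_match_class_conditionals(big_cohort):
    cfg, cohort = big_cohort
    for var in ("mechanism", "posture"):
        levels = cfg.covariate_model[var]
        for k in range(7):
            mask = cohort.true_labels == k + 1
            n_k = mask.sum()
            observed = cohort.covariates.loc[mask, var].value_counts(normalize=True)
            for level, probs in levels.items():
                p = probs[k]
                se = np.sqrt(p * (1 - p) / n_k)
                assert abs(observed.get(level, 0.0) - p) <= 3 * se + 1e-9


def test_records_round_trip_reproduces_indicators():
    cfg = default_template(3, 12, n=120, seed=8)
    cohort = sample_injury_records(sample_cohort(cfg), seed=4)
    matrix = build_indicator_matrix(
        cohort.records, populated_only=False,
        casualty_ids=cohort.indicators.casualty_ids,
    )
    recoded = matrix.to_dataframe()[cohort.indicators.column_names()]
    np.testing.assert_array_equal(recoded.to_numpy(), cohort.indicators.values)


def test_all_zero_casualty_yields_no_records():
    template = np.zeros((1, 4))
    cfg = GeneratorConfig(1, 4, 5, [1.0], template,
                          ["r01c01", "r01c02", "r01c03", "r01c04"], seed=0)
    cohort = sample_injury_records(sample_cohort(cfg), seed=0)
    assert cohort.records == []


def test_concentrated_severity_passes_iss_filter():
    """AIS >= 3 in three distinct ISS regions implies ISS >= 27 >= 9."""
    cells = ["r19c06", "r20c06", "r31c06"]  # chest, abdomen, lower leg
    template = np.ones((1, 3))
    cfg = GeneratorConfig(1, 3, 30, [1.0], template, cells, seed=1)
    severity = {"default": [0.0, 0.0, 1.0, 0.0, 0.0]}  # all AIS 3
    cohort = sample_injury_records(sample_cohort(cfg), severity_model=severity, seed=2)
    by_casualty: dict[str, list] = {}
    for rec in cohort.records:
        by_casualty.setdefault(rec.casualty_id, []).append(rec)
    for recs in by_casualty.values():
        assert compute_iss(recs) == 27


def test_unknown_cell_in_severity_model_rejected():
    cfg = default_template(3, 12, n=10, seed=0)
    cohort = sample_cohort(cfg)
    with pytest.raises(CodingError, match="zzz"):
        sample_injury_records(cohort, severity_model={"zzz": [1, 0, 0, 0, 0]}, seed=0)


def test_cohort_write_creates_csv_artifacts(tmp_path):
    cfg = default_template(3, 12, n=25, seed=6)
    cohort = sample_injury_records(sample_cohort(cfg), seed=6)
    cohort.write(tmp_path)
    ind = pd.read_csv(tmp_path / "indicators.csv", index_col=0)
    assert ind.shape == (25, 12)
    cov = pd.read_csv(tmp_path / "covariates.csv")
    assert "true_class" in cov.columns and len(cov) == 25
    assert (tmp_path / "records.csv").exists()
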