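"""EM for the Bernoulli-mixture latent class model, against enumeration
and closed-form oracles."""

import math
from itertools import product

import numpy as np
import pytest

from injuryprofiles import (
    LCAParams,
    LatentClassModel,
    assign_classes,
    default_template,
    e_step,
    log_likelihood,
    m_step,
    sample_cohort,
)

TOY = np.array([[1, 1], [1, 1], [0, 1], [0, 0]], dtype=float)  # freqs 0.5, 0.75


def loglik_enumeration(params: LCAParams, data: np.ndarray) -> float:
    """Oracle: direct product-sum evaluation, no log-space tricks."""
    total = 0.0
    for x in data:
        like = 0.0
        for k in range(params.n_classes):
            term = params.mixing[k]
            for j in range(params.n_items):
                rho = params.item_probs[j, k]
                term *= rho if x[j] == 1 else (1 - rho)
            like += term
        total += math.log(like)
    return total


def test_k1_loglik_matches_closed_form():
    params = LCAParams([1.0], np.array([[0.5], [0.75]]))
    # closed form: 4[.5 ln .5 + .5 ln .5] + [3 ln .75 + ln .25]
    expected = 4 * math.log(0.5) + 3 * math.log(0.75) + math.log(0.25)
    assert expected == pytest.approx(-5.021930, abs=1e-6)
    assert log_likelihood(params, TOY) == pytest.approx(expected, abs=1e-9)


def test_loglik_never_positive(rng):
    data = (rng.random((20, 5)) < 0.5).astype(float)
    mixing = rng.dirichlet(np.ones(3))
    params = LCAParams(mixing, rng.uniform(0.1, 0.9, size=(5, 3)))
    assert log_likelihood(params, data) <= 0


def test_mixture_collapse_symmetry():
    """Two classes with identical item columns give the one-class LL."""
    col = np.array([[0.3], [0.8]])
    k1 = LCAParams([1.0], col)
    k2 = LCAParams([0.4, 0.6], np.hstack([col, col]))
    assert log_likelihood(k2, TOY) == pytest.approx(log_likelihood(k1, TOY), abs=1e-9)


def test_loglik_matches_enumeration_oracle(rng):
    data = (rng.random((12, 3)) < 0.5).astype(float)
    params = LCAParams(rng.dirichlet(np.ones(4)), rng.uniform(0.05, 0.95, size=(3, 4)))
    assert log_likelihood(params, data) == pytest.approx(
        loglik_enumeration(params, data), abs=1e-9
    )


def test_e_step_k1_and_symmetric():
    post, _ = e_step(LCAParams([1.0], np.array([[0.4], [0.6]])), TOY)
    np.testing.assert_array_equal(post, np.ones((4, 1)))
    col = np.array([[0.3], [0.8]])
    sym = LCAParams([0.5, 0.5], np.hstack([col, col]))
    post, _ = e_step(sym, TOY)
    np.testing.assert_allclose(post, 0.5)


def test_e_step_matches_hand_enumeration():
    """One casualty, two items, two classes: posterior by Bayes' rule."""
    params = LCAParams([0.3, 0.7], np.array([[0.9, 0.2], [0.1, 0.8]]))
    x = np.array([[1, 0]])
    joint = np.array([0.3 * 0.9 * 0.9, 0.7 * 0.2 * 0.2])
    post, ll = e_step(params, x)
    np.testing.assert_allclose(post[0], joint / joint.sum(), atol=1e-12)
    assert ll == pytest.approx(math.log(joint.sum()), abs=1e-12)


def test_posterior_rows_sum_to_one(study_cohort_small):
    _, cohort = study_cohort_small
    res = LatentClassModel(cohort.indicators.values, 4).fit(n_starts=3, seed=5)
    np.testing.assert_allclose(res.posteriors.sum(axis=1), 1.0, atol=1e-8)
    np.testing.assert_array_equal(res.assignments, res.posteriors.argmax(axis=1) + 1)


def test_m_step_hard_posteriors_give_stratified_frequencies():
    post = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
    params = m_step(post, TOY)
    np.testing.assert_allclose(params.mixing, [0.5, 0.5])
    np.testing.assert_allclose(params.item_probs[:, 0], [1.0 - 1e-6, 1.0 - 1e-6])
    np.testing.assert_allclose(params.item_probs[:, 1], [1e-6, 0.5], atol=1e-9)


def test_m_step_uniform_posteriors_give_marginals():
    post = np.full((4, 3), 1 / 3)
    params = m_step(post, TOY)
    np.testing.assert_allclose(params.mixing, 1 / 3)
    for k in range(3):
        np.testing.assert_allclose(params.item_probs[:, k], [0.5, 0.75])


def test_m_step_matches_weighted_average_oracle(rng):
    data = (rng.random((15, 4)) < 0.4).astype(float)
    post = rng.dirichlet(np.ones(3), size=15)
    params = m_step(post, data)
    for k in range(3):
        w = post[:, k]
        assert params.mixing[k] == pytest.approx(w.mean(), abs=1e-12)
        for j in range(4):
            expected = np.clip((w * data[:, j]).sum() / w.sum(), 1e-6, 1 - 1e-6)
            assert params.item_probs[j, k] == pytest.approx(expected, abs=1e-12)


def test_em_monotone_loglikelihood(rng):
    """LL never decreases across EM iterations, over 100 random instances."""
    for _ in range(100):
        n, j, k = 25, 4, 3
        data = (rng.random((n, j)) < rng.uniform(0.2, 0.8, size=j)).astype(float)
        post = rng.dirichlet(np.ones(k), size=n)
        params = m_step(post, data)
        ll_prev = -np.inf
        for _ in range(15):
            post, ll = e_step(params, data)
            assert ll >= ll_prev - 1e-9 * max(1.0, abs(ll_prev))
            ll_prev = ll
            params = m_step(post, data)


def test_fit_k1_equals_closed_form_marginals():
    res = LatentClassModel(TOY, 1).fit(seed=0)
    np.testing.assert_allclose(res.item_probs[:, 0], [0.5, 0.75])
    np.testing.assert_allclose(res.mixing, [1.0])
    assert res.converged and res.n_iter == 1


def test_duplicating_every_casualty_doubles_loglik(block_cohort):
    _, cohort = block_cohort
    data = cohort.indicators.values
    res1 = LatentClassModel(data, 3).fit(n_starts=4, seed=9)
    res2 = LatentClassModel(np.vstack([data, data]), 3).fit(n_starts=4, seed=9)
    assert res2.llf == pytest.approx(2 * res1.llf, rel=1e-6)
    np.testing.assert_allclose(res2.item_probs, res1.item_probs, atol=5e-4)
    np.testing.assert_allclose(res2.mixing, res1.mixing, atol=5e-4)


def test_parameter_recovery_well_separated_three_classes(rng):
    """EM recovers rho within 0.05 on data generated at {0.05, 0.95}."""
    k, j, n = 3, 15, 2000
    rho_true = np.where(rng.random((k, j)) < 0.5, 0.05, 0.95)
    labels = rng.integers(0, k, size=n)
    data = (rng.random((n, j)) < rho_true[labels]).astype(float)
    res = LatentClassModel(data, k).fit(n_starts=8, seed=13)
    # match recovered classes to truth by nearest template row
    dist = np.abs(res.item_probs.T[:, None, :] - rho_true[None, :, :]).mean(axis=2)
    from scipy.optimize import linear_sum_assignment

    est_idx, true_idx = linear_sum_assignment(dist)
    assert dist[est_idx, true_idx].max() < 0.05


def test_label_permutation_leaves_loglik_unchanged(rng):
    data = (rng.random((30, 5)) < 0.5).astype(float)
    params = LCAParams(rng.dirichlet(np.ones(3)), rng.uniform(0.1, 0.9, (5, 3)))
    perm = [2, 0, 1]
    permuted = LCAParams(params.mixing[perm], params.item_probs[:, perm])
    assert log_likelihood(params, data) == pytest.approx(
        log_likelihood(permuted, data), abs=1e-9
    )


def test_canonical_order_descending_prevalence(block_cohort):
    _, cohort = block_cohort
    res = LatentClassModel(cohort.indicators.values, 3).fit(n_starts=4, seed=2)
    assert (np.diff(res.mixing) <= 1e-12).all()


def test_assignment_tie_breaks_to_lowest_index():
    assert assign_classes(np.array([[0.5, 0.5]]))[0] == 1
    assert assign_classes(np.array([[0.0, 0.0, 1.0]]))[0] == 3
    row = np.array([[0.91, 0.04, 0.02, 0.01, 0.02, 0.0, 0.0]])
    assert assign_classes(row)[0] == 1


def test_fit_reproducible_for_fixed_seed(block_cohort):
    _, cohort = block_cohort
    data = cohort.indicators.values
    a = LatentClassModel(data, 3).fit(n_starts=3, seed=21)
    b = LatentClassModel(data, 3).fit(n_starts=3, seed=21)
    assert a.llf == b.llf
    np.testing.assert_array_equal(a.assignments, b.assignments)
    np.testing.assert_array_equal(a.item_probs, b.item_probs)


def test_profile_heatmap_renders(block_cohort):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    _, cohort = block_cohort
    res = LatentClassModel(cohort.indicators.values, 3).fit(n_starts=2, seed=1)
    ax = res.plot_profiles(threshold=0.30)
    assert ax.get_xlabel() == "latent class"
    plt.close(ax.figure)


def test_empty_data_rejected():
    with pytest.raises(ValueError):
        LatentClassModel(np.zeros((0, 3)), 2)
    with pytest.raises(ValueError):
        LatentClassModel(TOY, 0)
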