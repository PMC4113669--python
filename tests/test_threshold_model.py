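"""Liability-threshold G-BLUP: closed forms, quadrature oracle, equivalences."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import special, stats

from vigorclass import (
    LOGISTIC_VARIANCE,
    SimConfig,
    classify,
    compute_grm,
    fit_marker_effects_ridge,
    fit_threshold_model,
    heritability,
    likelihood_ratio_test,
    phenotype_vector,
    simulate_dataset,
    variance_from_h2,
)
from vigorclass.grm import GRM
from vigorclass.threshold_model import ConvergenceError, laplace_marginal_loglik


# ---------------------------------------------------------------------------
# heritability maps
# ---------------------------------------------------------------------------

def test_heritability_closed_forms():
    assert round(heritability(11.856), 3) == 0.783
    assert heritability(0.0) == 0.0
    assert heritability(LOGISTIC_VARIANCE) == pytest.approx(0.5)
    assert round(LOGISTIC_VARIANCE, 2) == 3.29


def test_variance_from_h2_values():
    assert variance_from_h2(0.5) == pytest.approx(3.2899, abs=5e-5)
    assert variance_from_h2(0.2) == pytest.approx(0.25 * LOGISTIC_VARIANCE)
    assert variance_from_h2(0.0) == 0.0


@given(st.floats(0.0, 0.99))
def test_heritability_inverts_variance_map(h2):
    assert heritability(variance_from_h2(h2)) == pytest.approx(h2, abs=1e-12)


def test_domain_errors():
    with pytest.raises(ValueError):
        heritability(-0.1)
    with pytest.raises(ValueError):
        variance_from_h2(1.0)


# ---------------------------------------------------------------------------
# classification rule
# ---------------------------------------------------------------------------

def _toy_fit(mu, g, ids):
    from vigorclass.threshold_model import LiabilityFit

    return LiabilityFit(
        mu=mu, g=np.asarray(g, float), sigma_a2=1.0, h2=heritability(1.0),
        h2_se=None, deviance=0.0, null_deviance=0.0, converged=True,
        fixed_h2=None, sample_ids=ids, n_obs=len(ids),
    )


def test_classification_tie_goes_to_low():
    fit = _toy_fit(0.5, [-0.5, 19.5], ["a", "b"])
    out = classify(fit)
    assert out[0].p_high == pytest.approx(0.5) and out[0].predicted_class == 0
    assert out[1].p_high == pytest.approx(1.0, abs=1e-8) and out[1].predicted_class == 1


def test_probabilities_match_logistic_cdf():
    rng = np.random.default_rng(0)
    vals = rng.normal(scale=3, size=100)
    fit = _toy_fit(0.7, vals, [f"s{i}" for i in range(100)])
    out = classify(fit)
    expected = stats.logistic.cdf(0.7 + vals)
    np.testing.assert_allclose([c.p_high for c in out], expected, atol=1e-12)


def test_classify_unknown_sample():
    with pytest.raises(KeyError):
        classify(_toy_fit(0, [0.0], ["a"]), ["nope"])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_identity_grm_collapses_to_intercept():
    rng = np.random.default_rng(5)
    n = 60
    y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
    rng.shuffle(y)
    g = GRM(np.eye(n), [f"s{i}" for i in range(n)], np.array([]), 1.0, 0)
    fit = fit_threshold_model(y, g)
    assert fit.sigma_a2 < 0.1
    assert fit.mu == pytest.approx(special.logit(y.mean()), abs=0.15)


def test_laplace_matches_three_dim_quadrature():
    """At small variance the Laplace marginal agrees with exact integration."""
    rng = np.random.default_rng(7)
    A = rng.normal(size=(3, 5))
    K = A @ A.T / 5 + 0.5 * np.eye(3)
    y = np.array([1.0, 0.0, 1.0])
    mu, sigma_a2 = 0.3, 0.1
    ll_lap = laplace_marginal_loglik(y, K, sigma_a2, mu=mu)
    # oracle: tensor-product Gauss-Hermite integration of the marginal
    L = np.linalg.cholesky(K)
    nodes, weights = np.polynomial.hermite.hermgauss(48)
    sc = np.sqrt(2 * sigma_a2)
    total = 0.0
    for i, ui in enumerate(nodes):
        for j, uj in enumerate(nodes):
            for k, uk in enumerate(nodes):
                gv = sc * (L @ np.array([ui, uj, uk]))
                p = special.expit(mu + gv)
                lik = np.prod(np.where(y == 1, p, 1 - p))
                total += weights[i] * weights[j] * weights[k] * lik
    ll_exact = np.log(total / np.pi**1.5)
    assert abs(ll_lap - ll_exact) < 1e-3


def test_fixed_h2_sets_variance_exactly(beet_dataset, beet_grm):
    y = phenotype_vector(beet_dataset.panel)
    fit = fit_threshold_model(y, beet_grm, mode="fixed_h2", h2_fixed=0.5)
    assert fit.sigma_a2 == pytest.approx(LOGISTIC_VARIANCE)
    assert fit.fixed_h2 == 0.5
    assert fit.h2 == pytest.approx(0.5)


def test_training_separable_at_high_variance(beet_dataset, beet_grm):
    """With ample genetic variance a line-structured trait is fit perfectly."""
    y = phenotype_vector(beet_dataset.panel)
    fit = fit_threshold_model(y, beet_grm, mode="fixed_h2", h2_fixed=0.9)
    pred = [c.predicted_class for c in classify(fit)]
    assert np.mean(np.asarray(pred) != y) == 0.0


def test_estimate_on_heritable_trait(beet_dataset, beet_grm):
    y = phenotype_vector(beet_dataset.panel)
    fit = fit_threshold_model(y, beet_grm, compute_se=True)
    assert fit.converged
    assert fit.h2 > 0.5  # strongly heritable line-level trait
    assert fit.deviance < fit.null_deviance
    assert fit.h2_se is None or fit.h2_se > 0


def test_unphenotyped_get_conditional_mean_blup(beet_dataset, beet_grm):
    """Joint-prior prediction equals G21 G11^-1 g_train for held-out samples."""
    y = phenotype_vector(beet_dataset.panel).copy()
    test = np.arange(0, 20)
    y[test] = np.nan
    fit = fit_threshold_model(y, beet_grm, mode="fixed_h2", h2_fixed=0.7)
    train = np.flatnonzero(~np.isnan(y))
    K = beet_grm.ridged()
    expected = K[np.ix_(test, train)] @ np.linalg.solve(K[np.ix_(train, train)], fit.g[train])
    np.testing.assert_allclose(fit.g[test], expected, atol=1e-5)


def test_requires_both_classes():
    g = GRM(np.eye(4), list("abcd"), np.array([]), 1.0, 0)
    with pytest.raises(ValueError, match="each class"):
        fit_threshold_model(np.array([1.0, 1.0, 1.0, np.nan]), g)


# ---------------------------------------------------------------------------
# likelihood ratio test
# ---------------------------------------------------------------------------

def test_lrt_boundary_mixture_values():
    fit = _toy_fit(0, [0.0], ["a"])
    fit.null_deviance, fit.deviance = 10.0, 10.0
    assert likelihood_ratio_test(fit).p_value == pytest.approx(0.5)
    fit.deviance = 10.0 - 2.706
    assert likelihood_ratio_test(fit).p_value == pytest.approx(0.05, abs=1e-3)


def test_lrt_negative_statistic_raises():
    fit = _toy_fit(0, [0.0], ["a"])
    fit.null_deviance, fit.deviance = 10.0, 10.5
    with pytest.raises(ConvergenceError):
        likelihood_ratio_test(fit)


def test_lrt_refuses_fixed_h2_fit():
    fit = _toy_fit(0, [0.0], ["a"])
    fit.fixed_h2 = 0.5
    with pytest.raises(ValueError):
        likelihood_ratio_test(fit)


# ---------------------------------------------------------------------------
# RR-BLUP equivalence
# ---------------------------------------------------------------------------

def test_gblup_equals_rrblup_on_complete_panel():
    """Same penalty through the GRM denominator => identical genetic values."""
    ds = simulate_dataset(
        SimConfig(
            n_lines_high=14, n_lines_low=8, samples_per_line=1, n_scaffolds=6,
            n_snps=80, within_scaffold_rho=0.5, seed=9,
            line_level_phenotype=False, mu=0.0,
        )
    )
    panel = ds.panel
    p = panel.allele_freqs()
    Z = panel.genotypes.astype(float) - 1.0  # -1/0/1 coding, full-rank ZZ'
    d = float(2 * np.sum(p * (1 - p)))
    grm = GRM(Z @ Z.T / d, list(panel.samples["sample_id"]), p, d, panel.n_markers)
    y = phenotype_vector(panel)
    fit = fit_threshold_model(y, grm, mode="fixed_h2", h2_fixed=0.6, ridge=0.0,
                              inner_tol=1e-11)
    sigma_a2 = variance_from_h2(0.6)
    mu_rr, b, g_rr = fit_marker_effects_ridge(y, Z, sigma_a2 / d, tol=1e-12)
    np.testing.assert_allclose(g_rr, fit.g, atol=1e-6)
    assert mu_rr == pytest.approx(fit.mu, abs=1e-6)
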