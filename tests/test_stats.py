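"""Statistics chain: correlation, PCA diagnostics, regression oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from femurmech.errors import ConfigurationError, UndefinedStatisticError
from femurmech.stats import (
    pca_with_diagnostics,
    pearson_with_p,
    regress_on_pcs,
    run_stats_chain,
)

RNG = np.random.default_rng(99)


# ------------------------------------------------------------------- pearson

def test_perfect_linear_relation_gives_r_one_p_zero():
    x = np.arange(10.0)
    r, p = pearson_with_p(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    assert p == pytest.approx(0.0, abs=1e-12)
    r2, _ = pearson_with_p(x, -3 * x + 4)
    assert r2 == pytest.approx(-1.0)


def test_exactly_orthogonal_vectors_give_r_zero_p_one():
    x = np.arange(10.0) - 4.5        # symmetric about zero
    y = x ** 2                        # even function: zero covariance
    assert abs(np.cov(x, y, ddof=1)[0, 1]) < 1e-12
    r, p = pearson_with_p(x, y)
    assert r == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_t_distribution_p_matches_permutation_test():
    n = 20
    x = RNG.normal(size=n)
    y = 0.5 * x + RNG.normal(size=n)
    r, p = pearson_with_p(x, y)
    perm = 0
    n_perm = 100_000
    rng = np.random.default_rng(5)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    robs = abs(xc @ yc / denom)
    for _ in range(n_perm):
        rp = xc @ rng.permutation(yc) / denom
        if abs(rp) >= robs:
            perm += 1
    p_perm = perm / n_perm
    assert p == pytest.approx(p_perm, abs=3 * math.sqrt(
        max(p_perm * (1 - p_perm), 1e-6) / n_perm) + 2e-3)


def test_pearson_symmetry_and_affine_invariance():
    x = RNG.normal(size=15)
    y = RNG.normal(size=15)
    r1, p1 = pearson_with_p(x, y)
    r2, p2 = pearson_with_p(y, x)
    assert r1 == pytest.approx(r2) and p1 == pytest.approx(p2)
    r3, _ = pearson_with_p(3.0 * x + 7.0, y)
    assert r3 == pytest.approx(r1)
    r4, _ = pearson_with_p(-2.0 * x, y)
    assert r4 == pytest.approx(-r1)


def test_zero_variance_correlation_is_undefined():
    with pytest.raises(UndefinedStatisticError):
        pearson_with_p(np.ones(10), RNG.normal(size=10))


# ----------------------------------------------------------------------- PCA

def test_two_perfectly_correlated_variables_yield_rank_one_pca():
    x = RNG.normal(size=30)
    tab = pd.DataFrame({"a": x, "b": 2 * x + 3})
    block = pca_with_diagnostics(tab, ["a", "b"])
    assert block.eigenvalues[0] == pytest.approx(2.0)
    assert block.eigenvalues[1] == pytest.approx(0.0, abs=1e-12)
    assert block.pct_variance[0] == pytest.approx(100.0)
    assert block.n_retained == 1


def test_identity_correlation_matrix_retains_nothing_under_kaiser():
    n, p = 40, 7
    X = RNG.normal(size=(n, p))
    # orthogonalise columns so the sample correlation is exactly identity
    q, _ = np.linalg.qr(X - X.mean(axis=0))
    tab = pd.DataFrame(q, columns=[f"v{i}" for i in range(p)])
    block = pca_with_diagnostics(tab, list(tab.columns))
    assert np.allclose(block.eigenvalues, 1.0, atol=1e-9)
    # no eigenvalue exceeds the Kaiser threshold beyond round-off
    assert int(np.sum(block.eigenvalues > 1.0 + 1e-9)) == 0
    assert block.n_retained == int(np.sum(block.eigenvalues > 1.0))
    assert block.bartlett_p == pytest.approx(1.0)


def test_pca_matches_svd_and_direct_formula_oracles():
    n, p = 20, 7
    X = RNG.normal(size=(n, p)) @ RNG.normal(size=(p, p))
    tab = pd.DataFrame(X, columns=[f"v{i}" for i in range(p)])
    block = pca_with_diagnostics(tab, list(tab.columns))
    # SVD route on the standardized data as an independent eigen-solver
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    sv = np.linalg.svd(Z, compute_uv=False)
    evals = sv ** 2 / (n - 1)
    assert np.allclose(np.sort(block.eigenvalues), np.sort(evals),
                       atol=1e-10)
    assert block.eigenvalues.sum() == pytest.approx(p)
    assert np.all(np.diff(block.cum_pct_variance) >= -1e-12)
    # loadings reproduce the correlation matrix when all PCs are kept
    full = pca_with_diagnostics(tab, list(tab.columns),
                                eigen_threshold=-1.0)
    R = np.corrcoef(Z, rowvar=False)
    if full.n_retained == p:
        L = full.loadings.to_numpy()
        assert np.allclose(L @ L.T, R, atol=1e-8)
    # KMO against a direct inverse-correlation implementation
    Rinv = np.linalg.inv(R)
    partial = -Rinv / np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    off = ~np.eye(p, dtype=bool)
    kmo = (R[off] ** 2).sum() / ((R[off] ** 2).sum()
                                 + (partial[off] ** 2).sum())
    assert block.kmo == pytest.approx(kmo, abs=1e-12)
    # Bartlett chi-square from the printed formula
    chi2 = -(n - 1 - (2 * p + 5) / 6) * math.log(np.linalg.det(R))
    assert block.bartlett_chi2 == pytest.approx(chi2, rel=1e-12)
    assert block.bartlett_df == p * (p - 1) // 2
    # scores standardized
    assert np.allclose(block.scores.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(block.scores.std(axis=0, ddof=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------- regression

def test_intercept_equals_response_mean_with_standardized_scores():
    n, k = 20, 2
    S = RNG.normal(size=(n, k))
    S = (S - S.mean(axis=0)) / S.std(axis=0, ddof=1)
    y = RNG.normal(loc=5640.0, scale=1400.0, size=n)
    reg = regress_on_pcs(S, y)
    # exact when the scores are centred (standardized and orthogonalized)
    Sc = S - S.mean(axis=0)
    assert np.allclose(S.mean(axis=0), 0, atol=1e-12)
    assert reg.intercept == pytest.approx(y.mean(), rel=1e-12)


def test_constant_response_gives_zero_coefficients_and_see():
    S = RNG.normal(size=(12, 2))
    S = (S - S.mean(axis=0)) / S.std(axis=0, ddof=1)
    reg = regress_on_pcs(S, np.full(12, 7.0))
    assert np.allclose(reg.coef["B"], 0.0, atol=1e-9)
    assert reg.see == pytest.approx(0.0, abs=1e-9)


def test_regression_matches_pseudo_inverse_oracle():
    n, k = 20, 2
    S = RNG.normal(size=(n, k))
    S = (S - S.mean(axis=0)) / S.std(axis=0, ddof=1)
    y = 3.0 * S[:, 0] - 2.0 * S[:, 1] + RNG.normal(size=n)
    reg = regress_on_pcs(S, y)
    X = np.column_stack([np.ones(n), S])
    beta = np.linalg.pinv(X) @ y
    assert np.allclose(np.r_[reg.intercept, reg.coef["B"]], beta, atol=1e-9)
    resid = y - X @ beta
    see = math.sqrt(resid @ resid / (n - k - 1))
    cov = see ** 2 * np.linalg.inv(X.T @ X)
    assert np.allclose(np.r_[reg.intercept_se, reg.coef["SE"]],
                       np.sqrt(np.diag(cov)), atol=1e-9)
    assert reg.see == pytest.approx(see, rel=1e-12)
    r2 = 1 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))
    assert reg.model_r == pytest.approx(math.sqrt(r2), rel=1e-12)


def test_coefficients_independent_of_other_included_components():
    n = 24
    S = RNG.normal(size=(n, 3))
    q, _ = np.linalg.qr(S - S.mean(axis=0))
    S = q / q.std(axis=0, ddof=1)
    y = RNG.normal(size=n)
    full = regress_on_pcs(S, y)
    sub = regress_on_pcs(S[:, :1], y)
    assert full.coef["B"].iloc[0] == pytest.approx(sub.coef["B"].iloc[0],
                                                   rel=1e-9)


def test_rank_deficient_scores_are_rejected():
    S = RNG.normal(size=(15, 1))
    S = np.column_stack([S, S])
    with pytest.raises(ConfigurationError):
        regress_on_pcs(S, RNG.normal(size=15))


# -------------------------------------------------------------------- chain

def make_planted_table(n, rng):
    """Morphology-like table with a planted linear effect on strength."""
    cols = {}
    for i in range(6):
        cols[f"m{i}"] = rng.normal(size=n)
    strength = (400.0 * cols["m0"] - 300.0 * cols["m1"]
                + 150.0 * cols["m2"] + rng.normal(scale=200.0, size=n)
                + 5000.0)
    cols["F_fall"] = strength
    return pd.DataFrame(cols)


def test_full_chain_recovers_planted_effect_signs():
    rng = np.random.default_rng(31)
    tab = make_planted_table(200, rng)
    rep = run_stats_chain(tab, [f"m{i}" for i in range(6)], ["F_fall"])
    corr = rep.correlations["F_fall"]
    assert corr.loc["m0", "r"] > 0 and corr.loc["m0", "p"] < 0.05
    assert corr.loc["m1", "r"] < 0 and corr.loc["m1", "p"] < 0.05
    assert corr.loc["m2", "r"] > 0 and corr.loc["m2", "p"] < 0.05
    assert set(rep.significant["F_fall"]) >= {"m0", "m1", "m2"}
    assert rep.pca["F_fall"] is not None
    assert rep.regression["F_fall"] is not None
    assert rep.regression["F_fall"].intercept == pytest.approx(
        tab["F_fall"].mean(), rel=1e-9)


def test_chain_skips_pca_when_too_few_significant_parameters():
    rng = np.random.default_rng(8)
    n = 20
    tab = pd.DataFrame({f"m{i}": rng.normal(size=n) for i in range(5)})
    # strength driven by a single parameter only
    tab["F_st"] = 800.0 * tab["m0"] + rng.normal(scale=100.0, size=n) + 6000
    rep = run_stats_chain(tab, [f"m{i}" for i in range(5)], ["F_st"])
    if len(rep.significant["F_st"]) < 2:
        assert rep.pca["F_st"] is None
        assert "not appropriate" in rep.pca_skip_reason["F_st"]
    else:  # the noise draw may create a second significant parameter
        assert rep.pca["F_st"] is not None


def test_holm_correction_is_monotone_and_conservative():
    rng = np.random.default_rng(12)
    tab = make_planted_table(50, rng)
    plain = run_stats_chain(tab, [f"m{i}" for i in range(6)], ["F_fall"])
    holm = run_stats_chain(tab, [f"m{i}" for i in range(6)], ["F_fall"],
                           holm=True)
    adj = holm.correlations["F_fall"]["p_adjusted"]
    raw = plain.correlations["F_fall"]["p"]
    assert np.all(adj.to_numpy() >= raw.to_numpy() - 1e-15)
    assert set(holm.significant["F_fall"]) <= set(plain.significant["F_fall"])
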