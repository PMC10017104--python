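"""Moderated-t machinery, rank and contingency tests, clinical regressions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as stn
from scipy import special, stats as sps

from omixfuse.stats import (
    DesignError,
    bh_adjust,
    categorical_test,
    contrast_tests,
    fit_linear_models,
    moderate,
    pairwise_differential,
    rank_tests,
    trigamma_inverse,
    univariate_clinical_regression,
)


def _two_group_design(n_per):
    return pd.DataFrame({
        "group_a": [1.0] * n_per + [0.0] * n_per,
        "group_b": [0.0] * n_per + [1.0] * n_per,
    })


def test_ols_matches_normal_equations(rng):
    X = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=12)},
                     index=range(12))
    y = rng.normal(size=12)
    fit = fit_linear_models(pd.DataFrame({"g": y}), X)
    beta_oracle = np.linalg.inv(X.T @ X) @ X.T.to_numpy() @ y
    np.testing.assert_allclose(fit.coefficients.loc["g"].to_numpy(),
                               beta_oracle, atol=1e-10)
    resid = y - X.to_numpy() @ beta_oracle
    np.testing.assert_allclose(fit.sigma2["g"], resid @ resid / 10, atol=1e-10)


def test_adjusted_model_removes_confounder_bias():
    """y = 2*covariate + group effect: only the adjusted fit is unbiased."""
    n_per = 10
    group = np.array([1.0] * n_per + [0.0] * n_per)
    cov = group + np.linspace(0, 0.5, 2 * n_per)  # correlated with group
    y = 2.0 * cov + 1.0 * group
    design_adj = pd.DataFrame({"group_a": group, "group_b": 1 - group,
                               "cov": cov})
    fit = fit_linear_models(pd.DataFrame({"f": y}), design_adj)
    effect = fit.coefficients.loc["f", "group_a"] - \
        fit.coefficients.loc["f", "group_b"]
    assert abs(effect - 1.0) < 1e-10
    design_raw = pd.DataFrame({"group_a": group, "group_b": 1 - group})
    fit_raw = fit_linear_models(pd.DataFrame({"f": y}), design_raw)
    biased = fit_raw.coefficients.loc["f", "group_a"] - \
        fit_raw.coefficients.loc["f", "group_b"]
    assert abs(biased - 1.0) > 0.5


def test_rank_deficient_design_names_columns():
    X = pd.DataFrame({"a": [1.0, 1, 1, 1], "b": [0.0, 1, 0, 1],
                      "dup": [0.0, 1, 0, 1]})
    with pytest.raises(DesignError, match="dup"):
        fit_linear_models(pd.DataFrame({"f": [1.0, 2, 3, 4]}), X)


def test_trigamma_inverse_round_trip():
    for x in (0.3, 1.0, 4.0, 25.0):
        assert abs(trigamma_inverse(special.polygamma(1, x)) - x) < 1e-6


def test_moderation_limits(rng):
    Y = pd.DataFrame(rng.normal(size=(8, 50)))
    fit = fit_linear_models(Y, _two_group_design(4))
    # identical variances: no shrinkage
    fit_same = fit
    fit_same.sigma2[:] = 2.0
    mod = moderate(fit_same)
    np.testing.assert_allclose(mod.posterior_var, 2.0, rtol=1e-6)
    # forced infinite prior df: complete shrinkage to s0
    fit2 = fit_linear_models(pd.DataFrame(rng.normal(size=(8, 50))),
                             _two_group_design(4))
    mod_inf = moderate(fit2, prior_df=np.inf)
    assert mod_inf.posterior_var.nunique() == 1
    s2 = fit2.sigma2.to_numpy()
    env_lo, env_hi = s2.min(), max(s2.max(), mod_inf.prior_var)
    mod_est = moderate(fit2)
    assert ((mod_est.posterior_var >= env_lo - 1e-12) &
            (mod_est.posterior_var <= env_hi + 1e-12)).all()


def test_moderated_t_null_distribution():
    """Null features: moderated t follows t(d0+d) and type-I error ~= alpha."""
    rng = np.random.default_rng(4)
    G, n_per = 10_000, 6
    Y = pd.DataFrame(rng.normal(size=(2 * n_per, G)))
    fit = fit_linear_models(Y, _two_group_design(n_per))
    mod = moderate(fit)
    res = contrast_tests(mod, np.array([1.0, -1.0]))
    assert sps.kstest(res["t"], "t", args=(mod.total_df,)).pvalue > 0.01
    assert 0.045 <= (res["p"] < 0.05).mean() <= 0.055


def test_bh_step_up_hand_oracle():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])
    np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@given(stn.lists(stn.floats(min_value=0.0, max_value=1.0), min_size=2,
                 max_size=40))
def test_bh_preserves_ranking_and_caps(pvals):
    q = bh_adjust(pvals)
    assert (q <= 1.0 + 1e-12).all()
    order = np.argsort(pvals, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()


def test_pairwise_differential_recovers_planted_features(small_cohort):
    cfg, dataset, truth = small_cohort
    log2 = np.log2(dataset.views["metabolome"].matrix)
    labels = truth.labels.map(lambda c: "HC" if c == 0 else f"SNF-{c}")
    table = pairwise_differential(log2, labels, fdr_threshold=0.05)
    assert set(table.columns) >= {"feature", "contrast", "log2FC", "p", "fdr"}
    # FDR >= p within each contrast
    assert (table["fdr"] >= table["p"] - 1e-12).all()
    planted = truth.differential_features["metabolome"]
    c1_feats = set(planted.loc[planted["cluster"] == 1, "feature"])
    got = table[(table["contrast"].str.contains("SNF-1")) &
                (table["contrast"].str.contains("HC")) & table["significant"]]
    sens = len(c1_feats & set(got["feature"])) / len(c1_feats)
    assert sens >= 0.8


def test_pairwise_differential_orthogonal_covariate_no_change(rng):
    n_per = 12
    Y = pd.DataFrame(rng.normal(size=(2 * n_per, 30)))
    labels = pd.Series(["a"] * n_per + ["b"] * n_per, index=Y.index)
    cov = pd.DataFrame({"z": np.tile([-1.0, 1.0], n_per)}, index=Y.index)
    plain = pairwise_differential(Y, labels)
    adj = pairwise_differential(Y, labels, covariates=cov)
    np.testing.assert_allclose(plain["log2FC"], adj["log2FC"], atol=1e-10)


def test_rank_tests_enumeration_and_ties():
    stat, p = rank_tests([[1, 2, 3], [4, 5, 6]], "mann_whitney")
    assert stat == 0.0 and abs(p - 0.1) < 1e-12
    _, p_same = rank_tests([[2, 2, 2], [2, 2, 2]], "mann_whitney")
    assert p_same == 1.0
    H, p_kw = rank_tests([[1, 1], [1, 1], [1, 1]], "kruskal_wallis")
    assert H == 0.0 and p_kw == 1.0


def test_categorical_test_chi_square_formula_and_routing():
    tab = np.array([[10, 20], [30, 40]])
    chi2, p, method = categorical_test(tab)
    expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
    oracle = ((tab - expected) ** 2 / expected).sum()
    assert method == "chi_square" and abs(chi2 - oracle) < 1e-10
    # proportional table: statistic 0
    chi2, p, _ = categorical_test([[10, 20], [20, 40]])
    assert abs(chi2) < 1e-10 and abs(p - 1.0) < 1e-10
    # small expected counts route to Fisher and match scipy's hypergeometric
    small = np.array([[1, 2], [3, 20]])
    _, p_f, method = categorical_test(small)
    assert method == "fisher_exact"
    assert abs(p_f - sps.fisher_exact(small)[1]) < 1e-12


def test_rxc_fisher_matches_r_oracle():
    # 3x2 with small counts; reference value from the standard exact
    # conditional test implementation
    tab = np.array([[3, 1], [1, 3], [0, 4]])
    _, p, method = categorical_test(tab)
    assert method == "fisher_exact"
    assert abs(p - 0.2) < 1e-8


def test_univariate_regression_slope_recovery_and_binary_identity(rng):
    n = 97
    x = rng.normal(size=n)
    mam = pd.DataFrame({
        "m1": 1.0 * x + rng.normal(scale=0.1, size=n),
        "m2": rng.normal(size=n),
    })
    binary = rng.integers(0, 2, size=n).astype(float)
    clin = pd.DataFrame({"x": x, "b": binary})
    out = univariate_clinical_regression(mam, clin)
    slope = out.query("metabolite=='m1' and parameter=='x'")["slope"].iloc[0]
    assert abs(slope - 1.0) < 0.05
    b_slope = out.query("metabolite=='m2' and parameter=='b'")["slope"].iloc[0]
    diff = mam["m2"][binary == 1].mean() - mam["m2"][binary == 0].mean()
    assert abs(b_slope - diff) < 1e-10
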