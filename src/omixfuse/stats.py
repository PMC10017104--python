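"""Differential abundance and clinical statistics.

The centrepiece is the empirical-Bayes moderated t-statistic: per-feature
ordinary least squares fits whose residual variances are shrunk toward a
pooled prior estimated by moment-matching on the log variances (closed-form
digamma/trigamma equations, the prior df obtained by monotone Newton
inversion of the trigamma function).  Around it sit the supporting tests a
cohort characterization needs: Benjamini-Hochberg adjustment, rank tests,
chi-square/Fisher contingency tests with the classical expected-count-5
routing rule, and univariate clinical regressions for microbiome-associated
metabolites.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LinearFit",
    "ModeratedFit",
    "DesignError",
    "fit_linear_models",
    "moderate",
    "trigamma_inverse",
    "bh_adjust",
    "contrast_tests",
    "pairwise_differential",
    "rank_tests",
    "categorical_test",
    "univariate_clinical_regression",
]


class DesignError(ValueError):
    """The design matrix is unusable (e.g. rank deficient)."""


@dataclass
class LinearFit:
    """Per-feature OLS results for a shared design matrix."""

    coefficients: pd.DataFrame  # features x design columns
    sigma2: pd.Series  # residual variance per feature
    df_residual: int
    xtx_inv: np.ndarray  # unscaled coefficient covariance (p x p)
    design: pd.DataFrame


@dataclass
class ModeratedFit:
    """Empirical-Bayes shrinkage of a :class:`LinearFit`."""

    fit: LinearFit
    prior_df: float  # d0, may be inf
    prior_var: float  # s0^2
    posterior_var: pd.Series  # s~^2 per feature
    total_df: float  # d0 + d per feature (d constant here)


def fit_linear_models(Y, design: pd.DataFrame) -> LinearFit:
    """Ordinary least squares of every feature on one design matrix.

    ``Y`` is samples x features (DataFrame or array); ``design`` is
    samples x p and must be full column rank.
    """
    Ymat = Y.to_numpy(dtype=float) if isinstance(Y, pd.DataFrame) else np.asarray(
        Y, dtype=float)
    features = list(Y.columns) if isinstance(Y, pd.DataFrame) else [
        f"f{i}" for i in range(Ymat.shape[1])]
    X = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(
        design, dtype=float)
    colnames = list(design.columns) if isinstance(design, pd.DataFrame) else [
        f"x{i}" for i in range(X.shape[1])]
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name a minimal set of columns that are linear combinations of earlier ones
        bad = []
        for j in range(1, p):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(colnames[j])
        raise DesignError(f"design is rank deficient; collinear columns: {bad}")
    if n <= rank:
        raise DesignError("need more samples than design rank")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Ymat  # p x G
    resid = Ymat - X @ beta
    df = n - rank
    sigma2 = (resid * resid).sum(axis=0) / df
    return LinearFit(
        coefficients=pd.DataFrame(beta.T, index=features, columns=colnames),
        sigma2=pd.Series(sigma2, index=features, name="sigma2"),
        df_residual=df,
        xtx_inv=xtx_inv,
        design=design if isinstance(design, pd.DataFrame) else pd.DataFrame(
            X, columns=colnames),
    )


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve ``trigamma(x) = y`` for x > 0 by monotone Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def moderate(fit: LinearFit, prior_df: float | None = None) -> ModeratedFit:
    """Empirical-Bayes variance shrinkage (moderated-t machinery).

    The residual variances are modelled as scaled F draws around a prior
    ``(d0, s0^2)`` estimated by moment-matching the mean and variance of
    ``log s^2`` through digamma/trigamma identities.  ``prior_df`` may be
    forced (``np.inf`` pools completely).
    """
    s2 = fit.sigma2.to_numpy(dtype=float)
    G = s2.size
    d = fit.df_residual
    if G < 2:
        warnings.warn("fewer than 2 features: no shrinkage (ordinary t)")
        return ModeratedFit(fit, 0.0, float(s2.mean() if G else np.nan),
                            fit.sigma2.copy(), float(d))
    if G < 10:
        warnings.warn("fewer than 10 features: prior estimate unstable")
    positive = s2[s2 > 0]
    if positive.size < 2:
        raise ValueError("residual variances are all zero")
    e = (np.log(positive) - special.digamma(d / 2.0) + np.log(d / 2.0))
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, d / 2.0)
    if prior_df is not None:
        d0 = float(prior_df)
    elif evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
    else:
        d0 = np.inf
    if np.isinf(d0):
        # no excess dispersion in log s^2: pool completely; the pooled mean
        # keeps the identical-variance case a fixed point (no shrinkage)
        s0 = float(positive.mean())
        post = np.full_like(s2, s0)
    else:
        s0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s0 + d * s2) / (d0 + d)
    return ModeratedFit(
        fit=fit,
        prior_df=d0,
        prior_var=s0,
        posterior_var=pd.Series(post, index=fit.sigma2.index, name="s2_post"),
        total_df=float(d0 + d) if np.isfinite(d0) else np.inf,
    )


def contrast_tests(mod: ModeratedFit, contrast: np.ndarray | pd.Series
                   ) -> pd.DataFrame:
    """Moderated t-test of one contrast ``l' beta`` across all features."""
    l = np.asarray(contrast, dtype=float)
    beta = mod.fit.coefficients.to_numpy()
    effect = beta @ l
    u = float(l @ mod.fit.xtx_inv @ l)
    se = np.sqrt(mod.posterior_var.to_numpy() * u)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    df = mod.total_df
    if np.isinf(df):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {"log2FC": effect, "t": t, "p": p}, index=mod.fit.coefficients.index
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _one_hot_design(groups: pd.Series, covariates: pd.DataFrame | None
                    ) -> tuple[pd.DataFrame, list[str]]:
    levels = list(pd.unique(groups))
    cols = {f"group_{g}": (groups == g).astype(float) for g in levels}
    design = pd.DataFrame(cols, index=groups.index)
    if covariates is not None:
        cov = covariates.apply(pd.to_numeric)
        cov = cov - cov.mean()  # centred so group columns stay interpretable
        design = pd.concat([design, cov], axis=1)
    return design, levels


def pairwise_differential(
    Y: pd.DataFrame,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
    fdr_threshold: float = 0.05,
    fdr_family: str = "per_contrast",
) -> pd.DataFrame:
    """All pairwise group contrasts in one moderated linear model.

    Groups are one-hot encoded (no reference level); covariates, if given,
    are centred and appended ("adjusted" model).  BH adjustment is applied
    within each contrast by default, or globally with
    ``fdr_family='global'``.  Returns the differential table with one row
    per (feature, contrast).
    """
    groups = pd.Series(groups, index=Y.index) if not isinstance(
        groups, pd.Series) else groups.loc[Y.index]
    counts = groups.value_counts()
    usable = [g for g in counts.index if counts[g] >= 2]
    skipped = [g for g in counts.index if counts[g] < 2]
    if skipped:
        warnings.warn(f"groups with <2 samples skipped: {skipped}")
    if len(usable) < 2:
        raise ValueError("need at least two groups with >= 2 samples")
    keep = groups.isin(usable)
    design, levels = _one_hot_design(groups[keep], None if covariates is None
                                     else covariates.loc[keep])
    fit = fit_linear_models(Y.loc[keep], design)
    mod = moderate(fit)
    frames = []
    model = "adjusted" if covariates is not None else "unadjusted"
    for a, b in itertools.combinations(levels, 2):
        l = pd.Series(0.0, index=design.columns)
        l[f"group_{a}"] = 1.0
        l[f"group_{b}"] = -1.0
        res = contrast_tests(mod, l)
        res = res.reset_index(names="feature")
        res["contrast"] = f"{a}_vs_{b}"
        res["model"] = model
        frames.append(res)
    table = pd.concat(frames, ignore_index=True)
    if fdr_family == "global":
        table["fdr"] = bh_adjust(table["p"])
    else:
        table["fdr"] = table.groupby("contrast")["p"].transform(
            lambda s: bh_adjust(s.to_numpy()))
    table["significant"] = table["fdr"] < fdr_threshold
    return table[["feature", "contrast", "log2FC", "t", "p", "fdr",
                  "model", "significant"]]


def rank_tests(groups: list[np.ndarray], test: str = "kruskal_wallis"
               ) -> tuple[float, float]:
    """Mann-Whitney U (two groups) or Kruskal-Wallis H (>= 2 groups).

    Tie-corrected; the Mann-Whitney p is exact when both groups have at most
    8 observations and no ties, otherwise the normal approximation is used.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    if test == "mann_whitney":
        if len(arrays) != 2:
            raise ValueError("mann_whitney requires exactly two groups")
        x, y = arrays
        pooled = np.concatenate([x, y])
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) \
            else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return float(res.statistic), float(min(res.pvalue, 1.0))
    if test == "kruskal_wallis":
        if any(a.size < 2 for a in arrays):
            raise ValueError("kruskal_wallis requires >= 2 samples per group")
        pooled = np.concatenate(arrays)
        if np.all(pooled == pooled[0]):
            return 0.0, 1.0
        res = sps.kruskal(*arrays)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def _rxc_fisher_exact(table: np.ndarray, n_mc: int = 200_000, seed: int = 0
                      ) -> tuple[float, str]:
    """Exact conditional (Fisher) p for an r x c table.

    Full enumeration over tables with the observed margins when the state
    space is small; otherwise a seeded Monte Carlo estimate over random
    tables with fixed margins (as in R's simulate.p.value).
    """
    from math import lgamma

    def log_dhyper(t: np.ndarray, row: np.ndarray, col: np.ndarray, n: int) -> float:
        return (
            sum(lgamma(r + 1) for r in row) + sum(lgamma(c + 1) for c in col)
            - lgamma(n + 1) - sum(lgamma(v + 1) for v in t.ravel())
        )

    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = int(table.sum())
    obs = log_dhyper(table, row, col, n)
    r, c = table.shape

    # rough state-space bound: product over free cells of (min margin + 1)
    bound = 1.0
    for i in range(r - 1):
        for j in range(c - 1):
            bound *= min(row[i], col[j]) + 1
            if bound > 5e5:
                break
    if bound <= 5e5:
        total = 0.0
        hit = 0.0

        def recurse(i: int, j: int, t: np.ndarray, rrem: np.ndarray,
                    crem: np.ndarray) -> None:
            nonlocal total, hit
            if i == r - 1:
                last = crem.copy()
                if (last >= 0).all():
                    t[r - 1] = last
                    lp = log_dhyper(t, row, col, n)
                    pr = np.exp(lp)
                    total += pr
                    if lp <= obs + 1e-10:
                        hit += pr
                return
            if j == c - 1:
                if rrem[i] < 0 or rrem[i] > crem[j]:
                    return
                t[i, j] = rrem[i]
                recurse(i + 1, 0, t, np.r_[rrem[:i], 0, rrem[i + 1:]],
                        crem - np.eye(c, dtype=int)[j] * rrem[i])
                return
            hi = min(rrem[i], crem[j])
            for v in range(int(hi) + 1):
                t[i, j] = v
                recurse(i, j + 1, t,
                        np.r_[rrem[:i], rrem[i] - v, rrem[i + 1:]],
                        np.r_[crem[:j], crem[j] - v, crem[j + 1:]])

        recurse(0, 0, np.zeros((r, c), dtype=int), row.copy(), col.copy())
        return float(min(hit / total, 1.0)), "fisher_exact"

    rng = np.random.default_rng(seed)
    flat = np.repeat(np.arange(r), row)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(flat)
        t = np.zeros((r, c), dtype=int)
        start = 0
        for j in range(c):
            seg = perm[start:start + col[j]]
            start += col[j]
            for i in range(r):
                t[i, j] = int((seg == i).sum())
        if log_dhyper(t, row, col, n) <= obs + 1e-10:
            hits += 1
    return float((hits + 1) / (n_mc + 1)), "fisher_monte_carlo"


def categorical_test(table, seed: int = 0) -> tuple[float, float, str]:
    """Chi-square or Fisher's exact test of independence for an r x c table.

    Pearson chi-square (no continuity correction) when every expected count
    is >= 5; otherwise Fisher's exact test (hypergeometric for 2x2, exact
    conditional enumeration for larger tables when feasible).  Returns
    ``(statistic, p, method)``; the statistic is NaN for exact methods.
    """
    t = np.asarray(table, dtype=float)
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold non-negative integer counts")
    rows = t.sum(axis=1) > 0
    cols = t.sum(axis=0) > 0
    if not rows.all() or not cols.all():
        warnings.warn("dropping zero-margin rows/columns")
        t = t[rows][:, cols]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table needs >= 2 non-empty rows and columns")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected >= 5).all():
        chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
        return float(chi2), float(p), "chi_square"
    if t.shape == (2, 2):
        _, p = sps.fisher_exact(t.astype(int))
        return float("nan"), float(p), "fisher_exact"
    p, method = _rxc_fisher_exact(t.astype(int), seed=seed)
    return float("nan"), p, method


def univariate_clinical_regression(
    mam: pd.DataFrame,
    clinical: pd.DataFrame,
    fdr_threshold: float = 0.05,
    min_samples: int = 10,
) -> pd.DataFrame:
    """Simple linear regression of each metabolite on each clinical parameter.

    Pairwise-complete samples; constant predictors are skipped with a
    warning; BH adjustment across all (metabolite, parameter) pairs.  The
    rows with ``fdr < fdr_threshold`` form the exported bipartite edge list.
    """
    rows = []
    for param in clinical.columns:
        x_all = pd.to_numeric(clinical[param], errors="coerce")
        for met in mam.columns:
            y_all = mam[met]
            ok = x_all.notna() & y_all.notna()
            if ok.sum() < min_samples:
                continue
            x = x_all[ok].to_numpy(dtype=float)
            y = y_all[ok].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                warnings.warn(f"constant predictor {param!r} skipped")
                break
            res = sps.linregress(x, y)
            rows.append({"metabolite": met, "parameter": param,
                         "slope": res.slope, "r": res.rvalue,
                         "p": res.pvalue, "n": int(ok.sum())})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr"] = bh_adjust(out["p"])
    out["significant"] = out["fdr"] < fdr_threshold
    return out
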