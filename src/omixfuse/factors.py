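"""Multi-view linear factor analysis.

A deterministic, alternating-least-squares factor model over several
feature views sharing one sample set: shared per-sample scores Z and
per-view loadings W_v minimizing the inverse-dimension-weighted
reconstruction loss ``sum_v ||X_v - Z W_v'||_F^2 / p_v``.  The weighting
makes each view count equally regardless of how many features it has, so a
view cannot dominate by width alone.

This plays the role a Bayesian multi-omics factor analysis plays in
integrative studies — variance decomposition per view and factor,
factor-covariate association, and top-weight feature selection — with a
closed-form trainer instead of variational inference; the substitution is
stated in the package documentation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.extmath import randomized_svd
from sklearn.utils.validation import check_is_fitted

from .stats import bh_adjust

__all__ = [
    "MultiViewFactorModel",
    "variance_decomposition",
    "correlate_factors_with_covariates",
    "cluster_associated_factors",
    "select_top_weight_features",
    "factor_enrichment",
]


class MultiViewFactorModel(BaseEstimator, TransformerMixin):
    """Weighted-ALS shared factor model across feature views.

    Parameters
    ----------
    n_factors : number of latent factors (default 15).
    tol : relative-loss convergence threshold of the ALS sweeps.
    prune_below : drop factors explaining less than this percentage of
        variance in every view (MOFA-style pruning); 0 disables.
    seed : initialization seed (randomized SVD start).

    Attributes (after ``fit``)
    --------------------------
    scores_ : samples x factors DataFrame (unit-norm, orthogonal columns,
        ordered by total variance explained).
    loadings_ : dict of view -> features x factors DataFrame.
    loss_trace_ : per-sweep weighted reconstruction loss (non-increasing).
    """

    def __init__(self, n_factors: int = 15, max_iter: int = 500,
                 tol: float = 1e-8, prune_below: float = 0.1, seed: int = 0):
        self.n_factors = n_factors
        self.max_iter = max_iter
        self.tol = tol
        self.prune_below = prune_below
        self.seed = seed

    def fit(self, X: dict[str, pd.DataFrame], y=None):
        names = list(X)
        mats = {v: (X[v].to_numpy(dtype=float) if isinstance(X[v], pd.DataFrame)
                    else np.asarray(X[v], dtype=float)) for v in names}
        index = X[names[0]].index if isinstance(X[names[0]], pd.DataFrame) else None
        n = mats[names[0]].shape[0]
        for v in names:
            if mats[v].shape[0] != n:
                raise ValueError(f"view {v!r} sample count differs")
        p = {v: mats[v].shape[1] for v in names}
        total_feats = sum(p.values())
        K = self.n_factors
        if K >= min(n, total_feats):
            raise ValueError(
                f"n_factors={K} must be < min(n_samples={n}, "
                f"total_features={total_feats})")

        concat = np.hstack([mats[v] / np.sqrt(p[v]) for v in names])
        U, s, _ = randomized_svd(concat, n_components=K, random_state=self.seed)
        Z = U  # orthonormal start
        W = {}
        loss_trace: list[float] = []
        prev = np.inf
        for _ in range(self.max_iter):
            G = Z.T @ Z
            Ginv = np.linalg.inv(G)
            for v in names:
                W[v] = mats[v].T @ Z @ Ginv
            loss = sum(
                ((mats[v] - Z @ W[v].T) ** 2).sum() / p[v] for v in names
            )
            loss_trace.append(float(loss))
            if prev - loss <= self.tol * max(prev, 1e-300):
                break
            prev = loss
            A = sum(mats[v] @ W[v] / p[v] for v in names)
            B = sum(W[v].T @ W[v] / p[v] for v in names)
            Z = A @ np.linalg.inv(B)
            Q, _ = np.linalg.qr(Z)
            Z = Q

        # absorb scale into loadings, order by total variance explained
        norms = np.linalg.norm(Z, axis=0)
        norms[norms == 0] = 1.0
        Z = Z / norms
        for v in names:
            W[v] = W[v] * norms

        r2 = np.zeros((len(names), Z.shape[1]))
        for vi, v in enumerate(names):
            denom = (mats[v] ** 2).sum()
            for k in range(Z.shape[1]):
                resid = mats[v] - np.outer(Z[:, k], W[v][:, k])
                r2[vi, k] = max(0.0, 100.0 * (1.0 - (resid ** 2).sum() / denom))
        order = np.argsort(-r2.sum(axis=0), kind="stable")
        Z = Z[:, order]
        r2 = r2[:, order]
        for v in names:
            W[v] = W[v][:, order]
        if self.prune_below > 0:
            keep = (r2 >= self.prune_below).any(axis=0)
            if not keep.any():
                keep[0] = True
            Z = Z[:, keep]
            r2 = r2[:, keep]
            for v in names:
                W[v] = W[v][:, keep]

        factor_ids = [f"factor_{k + 1}" for k in range(Z.shape[1])]
        self.view_names_ = names
        self.scores_ = pd.DataFrame(Z, index=index, columns=factor_ids)
        self.loadings_ = {
            v: pd.DataFrame(
                W[v], columns=factor_ids,
                index=(X[v].columns if isinstance(X[v], pd.DataFrame) else None),
            )
            for v in names
        }
        self.per_factor_r2_ = pd.DataFrame(r2, index=names, columns=factor_ids)
        self.loss_trace_ = loss_trace
        self.n_factors_ = Z.shape[1]
        self._mats = mats
        return self

    def transform(self, X=None) -> pd.DataFrame:
        check_is_fitted(self, "scores_")
        if X is None:
            return self.scores_
        # project new data through the fitted loadings (weighted least squares)
        names = self.view_names_
        p = {v: self.loadings_[v].shape[0] for v in names}
        A = sum(
            np.asarray(X[v], dtype=float) @ self.loadings_[v].to_numpy() / p[v]
            for v in names
        )
        B = sum(
            self.loadings_[v].to_numpy().T @ self.loadings_[v].to_numpy() / p[v]
            for v in names
        )
        return pd.DataFrame(A @ np.linalg.inv(B), columns=self.scores_.columns)


def variance_decomposition(model: MultiViewFactorModel,
                           X: dict[str, pd.DataFrame] | None = None
                           ) -> tuple[pd.DataFrame, pd.Series]:
    """Percent variance explained per (view, factor) and per view in total."""
    check_is_fitted(model, "scores_")
    mats = model._mats if X is None else {
        v: np.asarray(X[v], dtype=float) for v in model.view_names_}
    Z = model.scores_.to_numpy()
    per_factor = model.per_factor_r2_.copy()
    totals = {}
    for v in model.view_names_:
        W = model.loadings_[v].to_numpy()
        resid = mats[v] - Z @ W.T
        totals[v] = max(
            0.0, 100.0 * (1.0 - (resid ** 2).sum() / (mats[v] ** 2).sum()))
    return per_factor, pd.Series(totals, name="r2_total")


def correlate_factors_with_covariates(
    model: MultiViewFactorModel, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of every factor with every numeric covariate.

    Binary covariates coded 0/1 give the point-biserial correlation.  BH
    adjustment runs across the whole (factor x covariate) matrix.
    """
    check_is_fitted(model, "scores_")
    rows = []
    Z = model.scores_
    for cov in covariates.columns:
        x = pd.to_numeric(covariates[cov], errors="coerce")
        if x.nunique(dropna=True) < 2:
            warnings.warn(f"constant covariate {cov!r} skipped")
            continue
        for factor in Z.columns:
            ok = x.notna()
            r, p = sps.pearsonr(Z.loc[ok.to_numpy(), factor], x[ok])
            rows.append({"factor": factor, "covariate": cov,
                         "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = bh_adjust(out["p"])
    return out


def cluster_associated_factors(assoc: pd.DataFrame, cluster_covariate: str,
                               alpha: float = 0.05) -> list[str]:
    """Factors whose BH-adjusted association with the cluster label is < alpha."""
    hit = assoc[(assoc["covariate"] == cluster_covariate) & (assoc["fdr"] < alpha)]
    return list(hit["factor"])


def select_top_weight_features(
    model: MultiViewFactorModel,
    factors: list[str] | None = None,
    quantile: float = 0.10,
    mode: str = "top_quantile",
) -> dict[str, list[str]]:
    """Per-view feature selection by absolute loading.

    ``top_quantile``: rank features by their max absolute loading over the
    chosen factors and keep the top ``quantile`` fraction (zero-loading
    features are never selected).  ``tails``: keep features in the 5%/95%
    loading tails of each chosen factor.
    """
    check_is_fitted(model, "scores_")
    factors = list(model.scores_.columns) if factors is None else list(factors)
    if not factors:
        raise ValueError("factors must be non-empty")
    out: dict[str, list[str]] = {}
    for v in model.view_names_:
        W = model.loadings_[v][factors]
        if mode == "top_quantile":
            score = W.abs().max(axis=1)
            n_keep = int(round(quantile * len(score)))
            ranked = score.sort_values(ascending=False, kind="stable")
            chosen = [f for f in ranked.index[:n_keep] if ranked[f] > 0]
        elif mode == "tails":
            chosen_set: set[str] = set()
            for factor in factors:
                w = W[factor]
                lo, hi = w.quantile(0.05), w.quantile(0.95)
                chosen_set |= set(w.index[(w <= lo) | (w >= hi)])
            chosen = sorted(chosen_set)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if not chosen:
            warnings.warn(f"view {v!r}: empty selection")
        out[v] = chosen
    return out


def factor_enrichment(
    model: MultiViewFactorModel,
    annotations: dict[str, dict[str, list[str]]],
    min_set_size: int = 3,
) -> pd.DataFrame:
    """Competitive parametric set test on loadings, per factor and sign.

    For each annotation set the statistic is the two-sample t between the
    set's loadings and the remaining features' loadings, evaluated on the
    raw loadings (positive direction) and their negation (negative
    direction); BH adjustment runs within each (view, factor, sign) family.
    """
    check_is_fitted(model, "scores_")
    rows = []
    for view, sets in annotations.items():
        W = model.loadings_[view]
        for factor in W.columns:
            w = W[factor]
            for sign, vals in (("positive", w), ("negative", -w)):
                for set_name, members in sets.items():
                    members = [m for m in members if m in w.index]
                    if len(members) < min_set_size:
                        continue
                    inset = vals.loc[members].to_numpy()
                    outset = vals.drop(index=members).to_numpy()
                    if outset.size == 0:
                        stat, p = 0.0, 1.0
                    else:
                        stat, p = sps.ttest_ind(inset, outset, equal_var=False)
                        stat, p = float(stat), float(p)
                        # one-sided: enrichment means larger loadings in-set
                        p = p / 2.0 if stat > 0 else 1.0 - p / 2.0
                    rows.append({"view": view, "factor": factor, "sign": sign,
                                 "set": set_name, "t": float(stat),
                                 "p": float(p)})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr"] = out.groupby(["view", "factor", "sign"])["p"].transform(
        lambda s: bh_adjust(s.to_numpy()))
    return out
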