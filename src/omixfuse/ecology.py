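"""Microbiome community analysis.

Alpha-diversity estimators (the richness panel of the classical R
ecosystem: Observed, ACE with its delta-method standard error, Chao1,
Shannon, Simpson, inverse Simpson, Fisher's alpha), Bray-Curtis
dissimilarity, non-metric multidimensional scaling, PERMANOVA with its
PERMDISP2 dispersion check, and a simplified LDA-effect-size procedure for
class-discriminative features.

PERMANOVA and PERMDISP are implemented directly from their sum-of-squares
definitions so the partition is inspectable; permutations are seeded and
vectorised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from .stats import bh_adjust  # noqa: F401  (re-exported convenience)

__all__ = [
    "alpha_diversity",
    "bray_curtis",
    "nmds",
    "OrdinationResult",
    "permanova",
    "PermanovaResult",
    "permdisp",
    "pairwise_permanova",
    "lefse_discriminative",
    "aggregate_taxonomy",
]


def _ace(counts: np.ndarray) -> tuple[float, float]:
    """Chao & Lee ACE estimator and its delta-method SE (rare cutoff 10).

    The gradient matches the symbolic derivative used by the standard R
    implementation, including its treatment of the sample-coverage term.
    """
    x = counts[counts > 0].astype(int)
    s_obs = x.size
    rare = x[x <= 10]
    s_rare = rare.size
    s_abund = s_obs - s_rare
    n_rare = int(rare.sum())
    i = np.arange(1, 11, dtype=float)
    a = np.array([(x == k).sum() for k in range(1, 11)], dtype=float)
    if n_rare == 0:
        return float(s_obs), 0.0
    if a[0] == n_rare:  # all rare species are singletons: coverage zero
        return float("nan"), float("nan")
    c_ace = 1.0 - a[0] / n_rare
    gamma = (i * (i - 1) * a).sum() * s_rare / (c_ace * n_rare * (n_rare - 1)) - 1.0 \
        if n_rare > 1 else 0.0
    s_ace = s_abund + s_rare / c_ace + max(gamma, 0.0) * a[0] / c_ace

    # symbolic gradient of the estimator w.r.t. the abundance-class counts a
    e4 = (i * a).sum()
    e7 = 1.0 - a[0] / (1.0 - e4)
    e8 = 1.0 / e7
    e10 = a.sum()
    e12 = (i * (i - 1) * a).sum()
    e13 = e10 * e12
    e14 = e7 * e4
    e15 = e4 - 1.0
    e16 = e14 * e15
    e18 = e13 / e16 - 1.0
    e20 = e10 + a[0] * e18
    e23 = (1.0 - e4) ** 2
    e25 = 1.0 / (1.0 - e4) + a[0] / e23
    e26 = e7 ** 2
    e35 = e16 ** 2
    grad = a[0] * i / (e23 * e26) * e20 + e8 * (
        1.0 + a[0] * ((e12 + e10 * i * (i - 1.0)) / e16
                      - e13 * ((e7 * i - (a[0] * i / e23) * e4) * e15
                               + e14 * i) / e35)
    )
    grad[0] = e25 / e26 * e20 + e8 * (
        1.0 + (e18 + a[0] * (e12 / e16
                             - e13 * ((e7 - e25 * e4) * e15 + e14) / e35))
    )
    cov = np.diag(a) - np.outer(a, a) / s_ace
    var = float(grad @ cov @ grad)
    return float(s_ace), float(np.sqrt(max(var, 0.0)))


def _chao1(counts: np.ndarray) -> float:
    x = counts[counts > 0]
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    return float(x.size + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def _fisher_alpha(s: int, n: int) -> float:
    """Solve ``S = alpha * ln(1 + N/alpha)`` for alpha."""
    if s <= 0 or n <= 0 or s >= n:
        return float("nan")
    f = lambda a: a * np.log1p(n / a) - s
    return float(brentq(f, 1e-8, 1e8, xtol=1e-10))


def alpha_diversity(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness and diversity panel from raw integer counts."""
    mat = counts.to_numpy()
    if (mat < 0).any() or not np.allclose(mat, np.round(mat)):
        raise ValueError("alpha diversity requires raw non-negative integer counts")
    rows = []
    for idx in range(mat.shape[0]):
        x = mat[idx].astype(float)
        total = x.sum()
        if total == 0:
            warnings.warn(f"sample {counts.index[idx]!r} is empty")
            rows.append({k: np.nan for k in
                         ("Observed", "ACE", "se.ACE", "Chao1", "Shannon",
                          "Simpson", "InvSimpson", "Fisher")})
            continue
        p = x[x > 0] / total
        shannon = float(-(p * np.log(p)).sum())
        simp = float((p * p).sum())
        ace, se_ace = _ace(x)
        rows.append({
            "Observed": float((x > 0).sum()),
            "ACE": ace,
            "se.ACE": se_ace,
            "Chao1": _chao1(x),
            "Shannon": shannon,
            "Simpson": 1.0 - simp,
            "InvSimpson": 1.0 / simp,
            "Fisher": _fisher_alpha(int((x > 0).sum()), int(total)),
        })
    return pd.DataFrame(rows, index=counts.index)


def bray_curtis(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Bray-Curtis dissimilarity ``sum|x-y| / sum(x+y)`` between all rows."""
    X = np.asarray(matrix, dtype=float)
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        num = np.abs(X[i] - X[i + 1:]).sum(axis=1)
        den = (X[i] + X[i + 1:]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(den > 0, num / den, 0.0)
        if (den == 0).any():
            warnings.warn("all-zero sample pair: distance set to 0")
        D[i, i + 1:] = D[i + 1:, i] = d
    return D


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # n x k, centred
    stress: float  # Kruskal stress-1
    converged: bool
    n_starts: int


def nmds(D: np.ndarray, k: int = 2, n_starts: int = 20, seed: int = 0,
         max_iter: int = 300) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1, best of ``n_starts``."""
    from sklearn.manifold import MDS

    D = np.asarray(D, dtype=float)
    model = MDS(
        n_components=k, metric=False, dissimilarity="precomputed",
        n_init=n_starts, random_state=seed, max_iter=max_iter,
        normalized_stress=True, eps=1e-7,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = model.fit_transform(D)
    coords = coords - coords.mean(axis=0)
    return OrdinationResult(
        coordinates=coords,
        stress=float(model.stress_),
        converged=bool(model.n_iter_ < max_iter),
        n_starts=n_starts,
    )


@dataclass
class PermanovaResult:
    pseudo_F: float
    r2: float
    p: float
    n_perm: int
    ss_total: float
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int


def _ss_within(D2: np.ndarray, labels: np.ndarray, levels: np.ndarray) -> float:
    ss = 0.0
    for g in levels:
        mask = labels == g
        ng = int(mask.sum())
        ss += D2[np.ix_(mask, mask)].sum() / (2.0 * ng)
    return ss


def permanova(D: np.ndarray, labels, n_perm: int = 999, seed: int = 0
              ) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``SS_total = (1/n) sum_{i<j} D_ij^2``; ``SS_within`` sums the analogous
    within-group terms; the permutation p-value uses the (count+1)/(perm+1)
    convention.
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    n = D.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels length must match distance matrix")
    levels = np.unique(labels)
    k = levels.size
    if k < 2:
        raise ValueError("need >= 2 groups")
    D2 = D * D
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = _ss_within(D2, labels, levels)
    ss_between = ss_total - ss_within
    df_b, df_w = k - 1, n - k
    F_obs = (ss_between / df_b) / (ss_within / df_w)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        ssw = _ss_within(D2, perm, levels)
        F = ((ss_total - ssw) / df_b) / (ssw / df_w)
        if F >= F_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermanovaResult(
        pseudo_F=float(F_obs), r2=float(ss_between / ss_total), p=float(p),
        n_perm=n_perm, ss_total=float(ss_total), ss_between=float(ss_between),
        ss_within=float(ss_within), df_between=df_b, df_within=df_w,
    )


def _pcoa_embedding(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates: real-axis and imaginary-axis coordinates."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D * D) @ J
    G = (G + G.T) / 2.0
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-8 * max(abs(vals[0]), 1.0)
    pos = vals > tol
    neg = vals < -tol
    real = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    return real, imag


def _spatial_median(X: np.ndarray, max_iter: int = 200, tol: float = 1e-9
                    ) -> np.ndarray:
    """Geometric (spatial) median by Weiszfeld iteration."""
    m = X.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(X - m, axis=1)
        if (d < 1e-12).any():  # median coincides with a data point
            return X[int(np.argmin(d))]
        w = 1.0 / d
        new = (w[:, None] * X).sum(axis=0) / w.sum()
        if np.linalg.norm(new - m) < tol:
            return new
        m = new
    return m


def permdisp(D: np.ndarray, labels, n_perm: int = 999, seed: int = 0,
             center: str = "median") -> tuple[float, float]:
    """PERMDISP2 homogeneity-of-dispersion test.

    Samples are embedded by principal coordinates; each sample's distance to
    its group's spatial median (default, the reference procedure's default)
    or centroid is corrected for negative eigenvalues (squared
    imaginary-axis distances subtracted); the ANOVA F on those distances is
    compared against permutations of the model residuals.  The median
    variant holds its nominal size better in small balanced designs; the
    centroid variant tends to be liberal.
    """
    if center not in ("median", "centroid"):
        raise ValueError("center must be 'median' or 'centroid'")
    labels = np.asarray(labels)
    real, imag = _pcoa_embedding(D)
    levels = np.unique(labels)
    if levels.size < 2:
        raise ValueError("need >= 2 groups")
    z = np.empty(labels.shape[0])
    for g in levels:
        mask = labels == g
        if center == "centroid":
            cr = real[mask].mean(axis=0)
            ci = imag[mask].mean(axis=0) if imag.size else np.zeros(0)
        else:
            cr = _spatial_median(real[mask])
            ci = _spatial_median(imag[mask]) if imag.size else np.zeros(0)
        d2 = ((real[mask] - cr) ** 2).sum(axis=1)
        if imag.size:
            d2 = d2 - ((imag[mask] - ci) ** 2).sum(axis=1)
        z[mask] = np.sqrt(np.maximum(d2, 0.0))

    def anova_f(vals: np.ndarray) -> float:
        grand = vals.mean()
        ssb = sum(((vals[labels == g].mean() - grand) ** 2) *
                  (labels == g).sum() for g in levels)
        ssw = sum(((vals[labels == g] - vals[labels == g].mean()) ** 2).sum()
                  for g in levels)
        df_b, df_w = levels.size - 1, vals.size - levels.size
        if ssw == 0:
            return np.inf
        return (ssb / df_b) / (ssw / df_w)

    F_obs = anova_f(z)
    # permute the least-squares residuals of distances ~ group, not the raw
    # distances: the group-mean structure is removed before permuting
    resid = z.copy()
    for g in levels:
        resid[labels == g] -= z[labels == g].mean()
    rng = np.random.default_rng(seed)
    count = sum(
        anova_f(resid[rng.permutation(labels.shape[0])]) >= F_obs - 1e-12
        for _ in range(n_perm)
    )
    return float(F_obs), float((count + 1) / (n_perm + 1))


def pairwise_permanova(D: np.ndarray, labels, n_perm: int = 999, seed: int = 0,
                       correction: str = "bonferroni") -> pd.DataFrame:
    """PERMANOVA for every pair of groups with Bonferroni correction."""
    labels = np.asarray(labels)
    D = np.asarray(D, dtype=float)
    levels = np.unique(labels)
    pairs = list(combinations(levels, 2))
    rows = []
    for s_off, (a, b) in enumerate(pairs):
        mask = np.isin(labels, [a, b])
        res = permanova(D[np.ix_(mask, mask)], labels[mask],
                        n_perm=n_perm, seed=seed + s_off)
        rows.append({"group_a": a, "group_b": b, "pseudo_F": res.pseudo_F,
                     "r2": res.r2, "p": res.p})
    out = pd.DataFrame(rows)
    if correction == "bonferroni":
        out["p_adjusted"] = np.minimum(out["p"] * len(pairs), 1.0)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return out


def aggregate_taxonomy(counts: pd.DataFrame, taxonomy: pd.DataFrame,
                       level: str = "family") -> pd.DataFrame:
    """Sum ASV counts within a taxonomic level; unassigned taxa pooled."""
    lab = taxonomy[level].reindex(counts.columns).fillna("Unassigned")
    return counts.T.groupby(lab.to_numpy()).sum().T


def lefse_discriminative(
    counts: pd.DataFrame,
    labels,
    kw_alpha: float = 0.05,
    wilcoxon_alpha: float = 0.05,
    lda_threshold: float = 2.0,
    n_boot: int = 30,
    subsample_frac: float = 2.0 / 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simplified LDA-effect-size scan for class-discriminative features.

    One-against-all scheme on total-sum-scaled data (counts per million):
    a feature must reject the Kruskal-Wallis omnibus test and every pairwise
    Wilcoxon test against its top class, with a consistent direction; its
    effect size is a bootstrapped linear-discriminant score
    ``log10(1 + |mean effect|)``, where the per-bootstrap effect averages
    the scaled discriminant coefficient and the raw class-mean difference.
    This is a documented simplification of the published heuristic (the 2/3
    subsampling and 30 bootstraps are retained).
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    labels = np.asarray(labels)
    levels = np.unique(labels)
    small = [g for g in levels if (labels == g).sum() < 3]
    if small:
        warnings.warn(f"classes with <3 samples skipped: {small}")
        keep = ~np.isin(labels, small)
        counts = counts.loc[keep]
        labels = labels[keep]
        levels = np.unique(labels)
    if levels.size < 2:
        raise ValueError("need >= 2 usable classes")

    totals = counts.sum(axis=1).to_numpy(dtype=float)
    tss = counts.to_numpy(dtype=float) / totals[:, None] * 1e6
    X = pd.DataFrame(tss, index=counts.index, columns=counts.columns)

    survivors: dict[str, list[str]] = {str(g): [] for g in levels}
    for feat in X.columns:
        vals = X[feat].to_numpy()
        groups = [vals[labels == g] for g in levels]
        if np.ptp(vals) == 0:
            continue
        try:
            H, p_kw = sps.kruskal(*groups)
        except ValueError:  # all identical
            continue
        if p_kw >= kw_alpha:
            continue
        means = np.array([g.mean() for g in groups])
        top = levels[int(np.argmax(means))]
        enriched_vals = vals[labels == top]
        ok = True
        for g in levels:
            if g == top:
                continue
            other = vals[labels == g]
            try:
                _, p_w = sps.mannwhitneyu(enriched_vals, other,
                                          alternative="two-sided")
            except ValueError:
                ok = False
                break
            if p_w >= wilcoxon_alpha or enriched_vals.mean() <= other.mean():
                ok = False
                break
        if ok:
            survivors[str(top)].append(feat)

    rng = np.random.default_rng(seed)
    rows = []
    for cls, feats in survivors.items():
        if not feats:
            continue
        y = (labels.astype(str) == cls).astype(int)
        sub = X[feats].to_numpy()
        effects = np.zeros((n_boot, len(feats)))
        for b in range(n_boot):
            idx = []
            for val in (0, 1):
                pool = np.flatnonzero(y == val)
                take = max(2, int(np.floor(subsample_frac * pool.size)))
                idx.append(rng.choice(pool, size=take, replace=False))
            idx = np.concatenate(idx)
            Xb, yb = sub[idx], y[idx]
            if np.unique(yb).size < 2:
                continue
            lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            try:
                lda.fit(Xb, yb)
            except Exception:
                continue
            w = lda.coef_.ravel()
            proj = Xb @ w
            spread = abs(proj[yb == 1].mean() - proj[yb == 0].mean())
            norm = np.linalg.norm(w)
            w_scaled = (w / norm * spread) if norm > 0 else np.zeros_like(w)
            dm = Xb[yb == 1].mean(axis=0) - Xb[yb == 0].mean(axis=0)
            effects[b] = 0.5 * (w_scaled + dm)
        mean_eff = effects.mean(axis=0)
        for f, eff in zip(feats, mean_eff):
            score = float(np.log10(1.0 + abs(eff)))
            rows.append({
                "feature": f, "enriched_class": cls,
                "lda_score": score if eff >= 0 else -score,
                "significant": abs(score) > lda_threshold,
            })
    return pd.DataFrame(rows, columns=["feature", "enriched_class",
                                       "lda_score", "significant"])
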