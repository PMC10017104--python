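"""Association networks over omics features.

Single-view Spearman co-expression networks with FDR-controlled edge calls,
the balanced multi-omic consensus procedure (repeatedly subsample an equal
number of features per view, call significant positive Spearman edges
within each draw, and keep pairs that are significant in more than a
consensus fraction of the draws in which both were sampled), Leiden
community detection with a minimum community size, and induced-subnetwork
extraction.

The consensus frequency denominator is the number of iterations in which
both endpoints were co-sampled — with per-view subsampling a pair is absent
from most iterations, so an all-iterations denominator could never reach
the consensus threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

__all__ = [
    "spearman_matrix",
    "correlation_network",
    "consensus_network",
    "detect_communities",
    "CommunityPartition",
    "extract_subnetwork",
]


def _rank_standardize(X: np.ndarray) -> np.ndarray:
    """Column-wise average ranks, z-scored; constant columns become NaN."""
    ranks = sps.rankdata(X, axis=0)
    mean = ranks.mean(axis=0)
    sd = ranks.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (ranks - mean) / sd
    return Z


def spearman_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho (average-rank ties) and t-approximation p."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need >= 4 samples")
    Z = _rank_standardize(X)
    rho = (Z.T @ Z) / (n - 1)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p[np.isnan(t) & ~np.isnan(rho)] = 0.0  # |rho| == 1 exactly
    return rho, p


def correlation_network(
    matrix: pd.DataFrame,
    fdr_threshold: float = 0.02,
    sign: str = "both",
    view: str | None = None,
) -> pd.DataFrame:
    """Spearman co-expression edge list at a BH-FDR threshold.

    Returns one row per significant pair with ``feature_a < feature_b``
    canonical ordering; isolated features simply do not appear.
    """
    if sign not in ("positive", "negative", "both"):
        raise ValueError("sign must be positive|negative|both")
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        warnings.warn(
            f"constant features skipped: {list(matrix.columns[sd == 0][:10])}")
        matrix = matrix.loc[:, sd > 0]
        X = matrix.to_numpy(dtype=float)
    cols = np.asarray(matrix.columns)
    rho, p = spearman_matrix(X)
    iu = np.triu_indices(len(cols), 1)
    pvec = p[iu]
    fdr = bh_adjust(pvec)
    rvec = rho[iu]
    keep = fdr < fdr_threshold
    if sign == "positive":
        keep &= rvec > 0
    elif sign == "negative":
        keep &= rvec < 0
    out = pd.DataFrame({
        "feature_a": cols[iu[0][keep]],
        "feature_b": cols[iu[1][keep]],
        "rho": rvec[keep],
        "p": pvec[keep],
        "fdr": fdr[keep],
    })
    if view is not None:
        out["view_a"] = view
        out["view_b"] = view
    return out


def consensus_network(
    views: dict[str, pd.DataFrame],
    n_iter: int = 1000,
    n_per_view: int = 241,
    fdr: float = 0.001,
    consensus: float = 0.90,
    seed: int = 0,
) -> pd.DataFrame:
    """Balanced-resampling consensus association network across views.

    Per iteration, ``n_per_view`` features are drawn without replacement
    from each view (the whole view if it is smaller); all pairwise Spearman
    correlations among the drawn union are BH-adjusted within the
    iteration, and significant positive pairs are recorded.  Final edges
    are pairs whose significant fraction, over the iterations in which both
    endpoints were drawn, exceeds ``consensus``.
    """
    if n_iter < 50:
        warnings.warn("n_iter < 50: consensus frequencies will be unstable")
    names = list(views)
    feats: list[str] = []
    tags: list[str] = []
    blocks = []
    n = None
    for v in names:
        df = views[v]
        if n is None:
            n = df.shape[0]
        elif df.shape[0] != n:
            raise ValueError(f"view {v!r} sample count differs")
        feats.extend(df.columns)
        tags.extend([v] * df.shape[1])
        blocks.append(df.to_numpy(dtype=float))
    F = len(feats)
    Zfull = np.hstack([_rank_standardize(b) for b in blocks])
    view_slices = {}
    start = 0
    for v, b in zip(names, blocks):
        view_slices[v] = np.arange(start, start + b.shape[1])
        start += b.shape[1]

    co = np.zeros((F, F), dtype=np.int32)
    sig = np.zeros((F, F), dtype=np.int32)
    rho_sum = np.zeros((F, F), dtype=np.float64)
    rng = np.random.default_rng(seed)
    dof = n - 2
    # BH can only reject pairs whose raw p is below the FDR level, and raw p
    # is monotone in |rho| at fixed dof: screen by the critical |rho| first,
    # then run exact step-up BH on the surviving candidates
    t_crit = sps.t.isf(fdr / 2.0, dof)
    rho_crit = t_crit / np.sqrt(dof + t_crit * t_crit)
    iu_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for _ in range(n_iter):
        sel = np.concatenate([
            np.sort(rng.choice(view_slices[v],
                               size=min(n_per_view, view_slices[v].size),
                               replace=False))
            for v in names
        ])
        Z = Zfull[:, sel]
        valid = ~np.isnan(Z).any(axis=0)
        sel = sel[valid]
        Z = Z[:, valid]
        rho = np.clip((Z.T @ Z) / (n - 1), -1.0, 1.0)
        if sel.size not in iu_cache:
            iu_cache[sel.size] = np.triu_indices(sel.size, 1)
        iu = iu_cache[sel.size]
        rho_vec = rho[iu]
        m = rho_vec.size
        cand = np.flatnonzero(np.abs(rho_vec) >= rho_crit * (1.0 - 1e-12))
        rej = np.empty(0, dtype=np.intp)
        if cand.size:
            r_c = rho_vec[cand]
            with np.errstate(divide="ignore"):
                t_c = np.abs(r_c) * np.sqrt(dof / np.maximum(1.0 - r_c * r_c,
                                                             1e-300))
            p_c = 2.0 * sps.t.sf(t_c, dof)
            order = np.argsort(p_c, kind="stable")
            ps = p_c[order]
            passing = np.flatnonzero(
                ps <= (np.arange(1, ps.size + 1) * fdr / m))
            if passing.size:
                rej = cand[order[: passing[-1] + 1]]
        ia, ib = sel[iu[0]], sel[iu[1]]
        co[ia, ib] += 1
        rho_sum[ia, ib] += rho_vec
        hit = rej[rho_vec[rej] > 0]
        if hit.size:
            sig[sel[iu[0][hit]], sel[iu[1][hit]]] += 1

    ia, ib = np.nonzero(co)
    freq = sig[ia, ib] / co[ia, ib]
    keep = freq > consensus
    feats_arr = np.asarray(feats)
    tags_arr = np.asarray(tags)
    return pd.DataFrame({
        "feature_a": feats_arr[ia[keep]],
        "view_a": tags_arr[ia[keep]],
        "feature_b": feats_arr[ib[keep]],
        "view_b": tags_arr[ib[keep]],
        "consensus_frequency": freq[keep],
        "co_sampled_count": co[ia, ib][keep],
        "mean_rho": rho_sum[ia, ib][keep] / co[ia, ib][keep],
    })


class CommunityPartition:
    """Leiden communities with size and mean-degree summaries."""

    def __init__(self, membership: dict[str, int], summaries: pd.DataFrame,
                 excluded: list[int]):
        self.membership = membership
        self.summaries = summaries  # community, size, mean_degree, reported
        self.excluded = excluded

    def reported(self) -> pd.DataFrame:
        return self.summaries[self.summaries["reported"]]


def detect_communities(
    edges: pd.DataFrame,
    resolution: float = 1.0,
    min_size: int = 30,
    seed: int = 0,
) -> CommunityPartition:
    """Leiden modularity communities on an (unweighted) edge list.

    Communities smaller than ``min_size`` are listed as excluded; mean
    degree is computed from full-graph degrees of the members.
    """
    import igraph as ig
    import leidenalg

    if edges.empty:
        return CommunityPartition({}, pd.DataFrame(
            columns=["community", "size", "mean_degree", "reported"]), [])
    nodes = sorted(set(edges["feature_a"]) | set(edges["feature_b"]))
    idx = {v: i for i, v in enumerate(nodes)}
    g = ig.Graph(
        n=len(nodes),
        edges=[(idx[a], idx[b]) for a, b in
               zip(edges["feature_a"], edges["feature_b"])],
    )
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed,
    )
    membership = {v: int(c) for v, c in zip(nodes, part.membership)}
    degrees = np.asarray(g.degree())
    rows = []
    excluded = []
    for c in sorted(set(part.membership)):
        members = [i for i, m in enumerate(part.membership) if m == c]
        size = len(members)
        mean_deg = float(degrees[members].mean())
        reported = size >= min_size
        if not reported:
            excluded.append(c)
        rows.append({"community": c, "size": size,
                     "mean_degree": mean_deg, "reported": reported})
    return CommunityPartition(membership, pd.DataFrame(rows), excluded)


def extract_subnetwork(edges: pd.DataFrame, feature_set) -> pd.DataFrame:
    """Induced subgraph of the edge list on a feature set."""
    wanted = set(feature_set)
    sub = edges[
        edges["feature_a"].isin(wanted) & edges["feature_b"].isin(wanted)
    ].reset_index(drop=True)
    if sub.empty:
        warnings.warn("feature set has no edges in the network")
    return sub


def cross_view_edge_counts(edges: pd.DataFrame) -> pd.Series:
    """Count edges per (view_a, view_b) pair, order-insensitive."""
    if edges.empty or "view_a" not in edges:
        return pd.Series(dtype=int)
    pairs = [
        " - ".join(sorted([a, b]))
        for a, b in zip(edges["view_a"], edges["view_b"])
    ]
    return pd.Series(pairs).value_counts()
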