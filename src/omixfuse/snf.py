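"""Similarity network fusion (SNF) and spectral clustering from first principles.

SNF builds a patient-similarity graph per omics view and fuses them by
cross-diffusion: each view's full-graph transition matrix is repeatedly
smoothed through its own K-nearest-neighbour kernel while exchanging
information with the other views.  The fused network is clustered with
normalized-cut spectral clustering; the number of clusters is chosen by
maximizing the Laplacian eigengap and minimizing a rotation (embedding
alignment) cost; each view's agreement with the fused partition is scored
with normalized mutual information (NMI).

Default hyperparameters follow the study configuration: K=13 neighbours,
kernel bandwidth multiplier alpha=0.8, T=10 fusion iterations, candidate
cluster counts 2..8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .datasets import AlignmentError

__all__ = [
    "SNFConfig",
    "FusedNetwork",
    "ClusterAssignment",
    "SNFClustering",
    "pairwise_distance",
    "affinity_kernel",
    "snf_fuse",
    "spectral_cluster",
    "spectral_embedding",
    "estimate_num_clusters",
    "nmi",
    "concordance_matrix",
]


@dataclass
class SNFConfig:
    """Hyperparameters for the fusion + clustering stage."""

    K: int = 13
    alpha: float = 0.8
    T: int = 10
    C: int | None = None  # None: select automatically by eigengap
    candidate_C_range: tuple[int, int] = (2, 8)
    seed: int = 0

    def validate(self, n: int) -> None:
        if not 1 <= self.K < n:
            raise ValueError(f"K must satisfy 1 <= K < n={n}")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.C is not None and not 2 <= self.C < n:
            raise ValueError("C must satisfy 2 <= C < n")


@dataclass
class AffinityMatrix:
    """Per-view similarity graph in its three SNF forms."""

    W: np.ndarray  # symmetric kernel similarities
    P: np.ndarray  # full-graph row-stochastic transition matrix
    S: np.ndarray  # KNN-restricted local kernel, row-stochastic on support


@dataclass
class FusedNetwork:
    """Fused patient-similarity matrix plus the per-view final matrices."""

    matrix: np.ndarray
    per_view: dict[str, np.ndarray]
    sample_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids,
                            columns=self.sample_ids)


@dataclass
class ClusterAssignment:
    """Spectral-cluster labels with the model-selection trace."""

    labels: np.ndarray  # values in 1..C
    chosen_C: int
    eigengap_by_C: dict[int, float] = field(default_factory=dict)
    rotation_cost_by_C: dict[int, float] = field(default_factory=dict)


def pairwise_distance(matrix: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Squared Euclidean distance between all sample pairs."""
    X = np.asarray(matrix, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in input matrix")
    sq = (X * X).sum(axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.maximum(D, 0.0, out=D)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def _knn_index(D: np.ndarray, K: int) -> np.ndarray:
    """Indices of the K nearest *other* samples per row (ties by index)."""
    n = D.shape[0]
    masked = D.copy()
    np.fill_diagonal(masked, np.inf)
    return np.argsort(masked, axis=1, kind="stable")[:, :K]


def affinity_kernel(D: np.ndarray, K: int = 13, alpha: float = 0.8) -> AffinityMatrix:
    """Exponential-kernel affinity graph with locally adaptive bandwidth.

    ``W(i,j) = exp(-D(i,j) / (alpha * eps_ij))`` with
    ``eps_ij = (mean_K D(i,.) + mean_K D(j,.) + D(i,j)) / 3``, the mean taken
    over each sample's K nearest other samples.  P is the full-graph
    row-stochastic form with the 1/2 self-weight convention; S keeps only
    each row's KNN entries, renormalized to sum to one.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("D must be square")
    if not 1 <= K < n:
        raise ValueError(f"K must satisfy 1 <= K < n={n}")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    knn = _knn_index(D, K)
    mean_knn = np.take_along_axis(D, knn, axis=1).mean(axis=1)
    eps = (mean_knn[:, None] + mean_knn[None, :] + D) / 3.0
    floor = max(np.finfo(float).eps, 1e-12 * max(D.max(), 1.0))
    if (eps <= 0).any():
        warnings.warn("degenerate (duplicate-point) bandwidth; flooring epsilon")
        eps = np.maximum(eps, floor)
    W = np.exp(-D / (alpha * eps))
    W = (W + W.T) / 2.0

    off = W.copy()
    np.fill_diagonal(off, 0.0)
    row = off.sum(axis=1)
    row[row == 0] = 1.0
    P = off / (2.0 * row[:, None])
    np.fill_diagonal(P, 0.5)

    S = np.zeros_like(W)
    rows = np.repeat(np.arange(n), K)
    S[rows, knn.ravel()] = W[rows, knn.ravel()]
    s_row = S.sum(axis=1)
    s_row[s_row == 0] = 1.0
    S /= s_row[:, None]
    return AffinityMatrix(W=W, P=P, S=S)


def _renormalize(P: np.ndarray) -> np.ndarray:
    """Re-impose the SNF transition convention: off-diagonal mass 1/2 per row."""
    off = P.copy()
    np.fill_diagonal(off, 0.0)
    row = off.sum(axis=1)
    row[row == 0] = 1.0
    out = off / (2.0 * row[:, None])
    np.fill_diagonal(out, 0.5)
    return out


def snf_fuse(
    views: dict[str, AffinityMatrix] | list[AffinityMatrix],
    T: int = 10,
    sample_ids: list[str] | None = None,
) -> FusedNetwork:
    """Cross-diffusion fusion of two or more affinity graphs.

    Each iteration updates every view's transition matrix as
    ``P_v <- S_v @ mean_{u != v}(P_u) @ S_v.T`` followed by renormalization;
    the fused network is the average of the final per-view matrices,
    symmetrized with the 1/2-diagonal convention re-imposed.
    """
    if isinstance(views, dict):
        names = list(views)
        mats = [views[k] for k in names]
    else:
        names = [f"view_{i}" for i in range(len(views))]
        mats = list(views)
    if len(mats) < 2:
        raise ValueError("fusion requires at least two views")
    n = mats[0].P.shape[0]
    for m in mats:
        if m.P.shape[0] != n:
            raise AlignmentError("views disagree on sample count/order")
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]

    P = [m.P.copy() for m in mats]
    S = [m.S for m in mats]
    mcount = len(P)
    for _ in range(T):
        new = []
        for v in range(mcount):
            others = sum(P[u] for u in range(mcount) if u != v) / (mcount - 1)
            new.append(_renormalize(S[v] @ others @ S[v].T))
        P = new
    fused = sum(P) / mcount
    fused = (fused + fused.T) / 2.0
    np.fill_diagonal(fused, 0.5)
    per_view = {
        name: (p + p.T) / 2.0 for name, p in zip(names, P)
    }
    for mat in per_view.values():
        np.fill_diagonal(mat, 0.5)
    return FusedNetwork(matrix=fused, per_view=per_view, sample_ids=list(sample_ids))


def _laplacian_spectrum(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (ascending) and eigenvectors of the normalized Laplacian."""
    W = np.asarray(W, dtype=float)
    deg = W.sum(axis=1)
    deg[deg == 0] = 1.0
    d = 1.0 / np.sqrt(deg)
    L = -(d[:, None] * W * d[None, :])
    L[np.diag_indices_from(L)] += 1.0
    L = (L + L.T) / 2.0
    vals, vecs = eigh(L)
    return vals, vecs


def spectral_embedding(W: np.ndarray, C: int) -> np.ndarray:
    """Row-normalized matrix of the C bottom eigenvectors of L_sym."""
    _, vecs = _laplacian_spectrum(W)
    U = vecs[:, :C]
    norms = np.linalg.norm(U, axis=1)
    norms[norms == 0] = 1.0
    return U / norms[:, None]


def spectral_cluster(
    W: np.ndarray,
    C: int,
    seed: int = 0,
    n_init: int = 20,
) -> np.ndarray:
    """Normalized-cut spectral clustering; labels in 1..C.

    The rows of the bottom-C eigenvector embedding are unit-normalized and
    partitioned by k-means with a fixed seed and ``n_init`` restarts.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if not 2 <= C <= n:
        raise ValueError(f"C must satisfy 2 <= C <= n={n}")
    if (W < 0).any():
        raise ValueError("affinity matrix must be non-negative")
    from scipy.sparse.csgraph import connected_components

    n_comp, _ = connected_components((W > 0).astype(int), directed=False)
    if n_comp > C:
        warnings.warn(
            f"graph has {n_comp} components but C={C}; clustering proceeds on "
            "the spectral embedding"
        )
    U = spectral_embedding(W, C)
    km = KMeans(n_clusters=C, n_init=n_init, random_state=seed)
    return km.fit_predict(U) + 1


def _alignment_rotation(U: np.ndarray, max_iter: int = 30) -> np.ndarray:
    """Best rotation aligning embedding rows with coordinate axes.

    Deterministic alternating scheme: greedy near-orthogonal initialization
    from the data rows, then repeat (discretize rows to their dominant axis;
    Procrustes-refit the rotation) until the assignment stabilizes.
    """
    n, C = U.shape
    R = np.zeros((C, C))
    R[:, 0] = U[0]
    c = np.zeros(n)
    for k in range(1, C):
        c += np.abs(U @ R[:, k - 1])
        R[:, k] = U[int(np.argmin(c))]
    last = None
    for _ in range(max_iter):
        proj = U @ R
        assign = np.argmax(np.abs(proj), axis=1)
        if last is not None and np.array_equal(assign, last):
            break
        last = assign
        F = np.sign(proj[np.arange(n), assign])[:, None] * np.eye(C)[assign]
        Wm, _, Vt = np.linalg.svd(U.T @ F)
        R = Wm @ Vt
    return R


def estimate_num_clusters(
    W: np.ndarray,
    candidate_range: tuple[int, int] = (2, 8),
) -> tuple[int, int, dict[int, float], dict[int, float]]:
    """Scan candidate cluster counts by eigengap and rotation cost.

    ``eigengap(C) = lambda_{C+1} - lambda_C`` of the normalized-Laplacian
    spectrum in ascending order (larger is better).  The rotation cost of a
    candidate C is ``sum_i (1 - max_j |(U_hat R)_ij|)`` over the
    row-normalized C-dimensional embedding U_hat, where R is the rotation
    best aligning the rows with a cluster-indicator structure (smaller is
    better); this is one published variant of the criterion.  Ties break
    toward smaller C.
    """
    lo, hi = candidate_range
    n = np.asarray(W).shape[0]
    if not 2 <= lo <= hi <= n - 1:
        raise ValueError(f"candidate range must lie within [2, n-1]={n - 1}")
    vals, vecs = _laplacian_spectrum(np.asarray(W, dtype=float))
    eigengap: dict[int, float] = {}
    rotation: dict[int, float] = {}
    for C in range(lo, hi + 1):
        eigengap[C] = float(vals[C] - vals[C - 1])
        U = vecs[:, :C]
        norms = np.linalg.norm(U, axis=1)
        norms[norms == 0] = 1.0
        Uhat = U / norms[:, None]
        R = _alignment_rotation(Uhat)
        rotation[C] = float(np.sum(1.0 - np.abs(Uhat @ R).max(axis=1)))
    cands = list(range(lo, hi + 1))
    best_gap = cands[int(np.argmax([eigengap[c] for c in cands]))]
    best_rot = cands[int(np.argmin([rotation[c] for c in cands]))]
    return best_gap, best_rot, eigengap, rotation


def nmi(labels_a, labels_b, normalization: str = "sqrt") -> float:
    """Normalized mutual information of two partitions, in [0, 1].

    ``I(A;B) / sqrt(H(A) * H(B))`` with natural-log entropies from the joint
    contingency table.  Two single-class partitions score 1; if exactly one
    partition is single-class the score is 0.  ``normalization`` may also be
    ``max`` or ``mean``.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise AlignmentError("label vectors differ in length")
    n = a.size
    if n == 0:
        raise ValueError("empty label vectors")
    joint = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy(dtype=float) / n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    ha = -np.sum(pa * np.log(pa, where=pa > 0, out=np.zeros_like(pa)))
    hb = -np.sum(pb * np.log(pb, where=pb > 0, out=np.zeros_like(pb)))
    if ha == 0 and hb == 0:
        return 1.0
    if ha == 0 or hb == 0:
        return 0.0
    outer = pa[:, None] * pb[None, :]
    mask = joint > 0
    mi = float(np.sum(joint[mask] * np.log(joint[mask] / outer[mask])))
    denom = {
        "sqrt": np.sqrt(ha * hb),
        "max": max(ha, hb),
        "mean": (ha + hb) / 2.0,
    }[normalization]
    return float(np.clip(mi / denom, 0.0, 1.0))


def concordance_matrix(
    fused: FusedNetwork, C: int, seed: int = 0
) -> pd.DataFrame:
    """NMI between fused-network clusters and each single-view clustering."""
    parts = {"fused": spectral_cluster(fused.matrix, C, seed=seed)}
    for name, mat in fused.per_view.items():
        parts[name] = spectral_cluster(mat, C, seed=seed)
    names = list(parts)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            val = nmi(parts[a], parts[b])
            out.loc[a, b] = out.loc[b, a] = val
    return out


class SNFClustering(BaseEstimator, ClusterMixin):
    """End-to-end SNF patient stratification as a scikit-learn estimator.

    ``fit`` takes a dict (or list) of normalized samples x features views
    sharing one sample order; it computes per-view squared-Euclidean
    distances and affinity graphs, fuses them by cross-diffusion, selects
    the number of clusters by eigengap (unless ``C`` is given), and runs
    normalized-cut spectral clustering on the fused network.

    Attributes (after fit): ``labels_`` (1..C), ``fused_network_``,
    ``assignment_`` (model-selection trace), ``concordance_``.
    """

    def __init__(self, K: int = 13, alpha: float = 0.8, T: int = 10,
                 C: int | None = None, candidate_C_range: tuple[int, int] = (2, 8),
                 seed: int = 0):
        self.K = K
        self.alpha = alpha
        self.T = T
        self.C = C
        self.candidate_C_range = candidate_C_range
        self.seed = seed

    def fit(self, X, y=None):
        if isinstance(X, dict):
            names = list(X)
            mats = [X[k] for k in names]
        else:
            names = [f"view_{i}" for i in range(len(X))]
            mats = list(X)
        sample_ids = None
        arrays = []
        for name, m in zip(names, mats):
            if isinstance(m, pd.DataFrame):
                ids = list(m.index)
                if sample_ids is None:
                    sample_ids = ids
                elif ids != sample_ids:
                    raise AlignmentError(f"view {name!r} sample order differs")
                arrays.append(m.to_numpy(dtype=float))
            else:
                arrays.append(np.asarray(m, dtype=float))
        n = arrays[0].shape[0]
        if sample_ids is None:
            sample_ids = [f"S{i}" for i in range(n)]
        cfg = SNFConfig(self.K, self.alpha, self.T, self.C,
                        self.candidate_C_range, self.seed)
        cfg.validate(n)
        affinities = {
            name: affinity_kernel(pairwise_distance(a), K=self.K, alpha=self.alpha)
            for name, a in zip(names, arrays)
        }
        self.fused_network_ = snf_fuse(affinities, T=self.T, sample_ids=sample_ids)
        hi = min(self.candidate_C_range[1], n - 1)
        rng = (self.candidate_C_range[0], hi)
        best_gap, best_rot, gaps, costs = estimate_num_clusters(
            self.fused_network_.matrix, rng
        )
        chosen = self.C if self.C is not None else best_gap
        labels = spectral_cluster(self.fused_network_.matrix, chosen, seed=self.seed)
        self.assignment_ = ClusterAssignment(
            labels=labels, chosen_C=chosen,
            eigengap_by_C=gaps, rotation_cost_by_C=costs,
        )
        self.best_C_eigengap_ = best_gap
        self.best_C_rotation_ = best_rot
        self.labels_ = labels
        self.n_clusters_ = chosen
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def concordance(self) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "fused_network_")
        return concordance_matrix(self.fused_network_, self.n_clusters_, self.seed)
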