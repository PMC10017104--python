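"""Co-expression and consensus networks, Leiden communities, subnetworks."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from omixfuse.network import (
    consensus_network,
    correlation_network,
    cross_view_edge_counts,
    detect_communities,
    extract_subnetwork,
    spearman_matrix,
)


def test_spearman_matches_scipy_pairwise(rng):
    X = rng.normal(size=(20, 6))
    X[:, 2] = np.exp(X[:, 0]) + 0.3 * rng.normal(size=20)
    rho, p = spearman_matrix(X)
    for i in range(6):
        for j in range(i + 1, 6):
            ref = sps.spearmanr(X[:, i], X[:, j])
            assert abs(rho[i, j] - ref.statistic) < 1e-12
    # hand-ranked 6-sample toy with a tie
    x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([10.0, 8.0, 9.0, 7.0, 5.0, 6.0])
    rho2, _ = spearman_matrix(np.column_stack([x, y]))
    assert abs(rho2[0, 1] - sps.spearmanr(x, y).statistic) < 1e-12


def test_spearman_invariant_under_monotone_transform(rng):
    X = rng.normal(size=(30, 2))
    rho_a, _ = spearman_matrix(X)
    Y = np.column_stack([np.exp(X[:, 0]), X[:, 1] ** 3])
    rho_b, _ = spearman_matrix(Y)
    assert abs(rho_a[0, 1] - rho_b[0, 1]) < 1e-12


def test_correlation_network_duplicate_feature_and_constant_skip(rng):
    X = pd.DataFrame(rng.normal(size=(30, 5)),
                     columns=["a", "b", "c", "d", "e"])
    X["dup"] = X["a"]
    X["const"] = 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        edges = correlation_network(X, fdr_threshold=0.05)
    pair = edges[(edges["feature_a"] == "a") & (edges["feature_b"] == "dup")]
    assert len(pair) == 1 and pair["rho"].iloc[0] == 1.0
    assert not edges["feature_a"].eq("const").any()
    assert not edges["feature_b"].eq("const").any()


def test_correlation_network_null_fdr_control(rng):
    X = pd.DataFrame(rng.normal(size=(97, 100)))
    X.columns = [f"f{i}" for i in range(100)]
    edges = correlation_network(X, fdr_threshold=0.02)
    assert len(edges) <= 5


def test_consensus_degenerates_to_single_pass(rng):
    base = rng.normal(size=(40, 10))
    X = pd.DataFrame(np.hstack([base, base[:, :5] + 0.4 *
                                rng.normal(size=(40, 5))]),
                     columns=[f"f{i}" for i in range(15)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cn = consensus_network({"a": X.iloc[:, :8], "b": X.iloc[:, 8:]},
                               n_iter=1, n_per_view=99, fdr=0.05,
                               consensus=0.5, seed=0)
        single = correlation_network(X, fdr_threshold=0.05, sign="positive")
    e1 = {tuple(sorted(t)) for t in zip(cn["feature_a"], cn["feature_b"])}
    e2 = {tuple(sorted(t)) for t in zip(single["feature_a"],
                                        single["feature_b"])}
    assert e1 == e2 and len(e1) > 0


def test_consensus_planted_block_recovery_and_null(rng):
    n = 97
    met = rng.normal(size=(n, 60))
    asv = rng.normal(size=(n, 60))
    for i in range(10):
        z = rng.normal(size=n)
        met[:, i] = np.sqrt(0.8) * z + np.sqrt(0.2) * rng.normal(size=n)
        asv[:, i] = np.sqrt(0.8) * z + np.sqrt(0.2) * rng.normal(size=n)
    views = {
        "met": pd.DataFrame(met, columns=[f"met{i}" for i in range(60)]),
        "asv": pd.DataFrame(asv, columns=[f"asv{i}" for i in range(60)]),
    }
    cn = consensus_network(views, n_iter=100, n_per_view=40, fdr=0.001,
                           consensus=0.9, seed=0)
    found = {tuple(sorted(t)) for t in zip(cn["feature_a"], cn["feature_b"])}
    planted = {tuple(sorted((f"met{i}", f"asv{i}"))) for i in range(10)}
    assert len(found & planted) >= 9
    assert (cn["consensus_frequency"] > 0.9).all()
    assert (cn["mean_rho"] > 0).all()
    assert (cn["co_sampled_count"] <= 100).all()


def test_consensus_frequency_concentration(rng):
    """Doubling iterations moves frequencies by at most a few binomial SDs."""
    n = 60
    z = rng.normal(size=(n, 5))
    a = np.sqrt(0.7) * z + np.sqrt(0.3) * rng.normal(size=(n, 5))
    b = np.sqrt(0.7) * z + np.sqrt(0.3) * rng.normal(size=(n, 5))
    views = {
        "a": pd.DataFrame(np.hstack([a, rng.normal(size=(n, 20))]),
                          columns=[f"a{i}" for i in range(25)]),
        "b": pd.DataFrame(np.hstack([b, rng.normal(size=(n, 20))]),
                          columns=[f"b{i}" for i in range(25)]),
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        c1 = consensus_network(views, n_iter=150, n_per_view=15, fdr=0.05,
                               consensus=0.5, seed=1)
        c2 = consensus_network(views, n_iter=300, n_per_view=15, fdr=0.05,
                               consensus=0.5, seed=2)
    merged = c1.merge(c2, on=["feature_a", "feature_b"], suffixes=("_1", "_2"))
    assert len(merged) > 0
    f1 = merged["consensus_frequency_1"]
    f2 = merged["consensus_frequency_2"]
    n1 = merged["co_sampled_count_1"]
    sd = np.sqrt(np.maximum(f1 * (1 - f1), 0.25 / n1) / n1)
    assert (np.abs(f1 - f2) <= 3 * np.maximum(sd, 0.05) + 1e-9).all()


def test_detect_communities_cliques_and_size_rule(rng):
    edges = []
    for offset, size in ((0, 40), (100, 40)):
        for i in range(size):
            for j in range(i + 1, size):
                edges.append({"feature_a": f"n{offset + i}",
                              "feature_b": f"n{offset + j}"})
    part = detect_communities(pd.DataFrame(edges), min_size=30, seed=0)
    rep = part.reported()
    assert len(rep) == 2
    assert set(rep["size"]) == {40}
    assert set(rep["mean_degree"]) == {39.0}
    ring = pd.DataFrame([{"feature_a": f"r{i}", "feature_b": f"r{(i + 1) % 10}"}
                         for i in range(10)])
    small = detect_communities(ring, min_size=30, seed=0)
    assert small.reported().empty and len(small.excluded) >= 1


def test_detect_communities_planted_partition(rng):
    sizes, p_in, p_out = [50, 50, 50], 0.3, 0.01
    labels = np.repeat([0, 1, 2], 50)
    rows = []
    n = 150
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if labels[i] == labels[j] else p_out
            if rng.random() < p:
                rows.append({"feature_a": f"x{i}", "feature_b": f"x{j}"})
    part = detect_communities(pd.DataFrame(rows), min_size=30, seed=0)
    found = np.array([part.membership[f"x{i}"] for i in range(n)])
    assert adjusted_rand_score(labels, found) >= 0.95
    # determinism under fixed seed
    part2 = detect_communities(pd.DataFrame(rows), min_size=30, seed=0)
    assert part.membership == part2.membership


def test_extract_subnetwork_identity_disjoint_and_filter(rng):
    edges = pd.DataFrame({
        "feature_a": ["a", "a", "b"], "feature_b": ["b", "c", "c"],
        "view_a": ["met", "met", "lip"], "view_b": ["lip", "met", "lip"],
    })
    full = extract_subnetwork(edges, {"a", "b", "c"})
    pd.testing.assert_frame_equal(full, edges)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        empty = extract_subnetwork(edges, {"zz"})
    assert empty.empty
    sub = extract_subnetwork(edges, {"a", "b"})
    assert len(sub) == 1 and sub["feature_b"].iloc[0] == "b"
    counts = cross_view_edge_counts(edges)
    assert counts["lip - met"] == 1
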