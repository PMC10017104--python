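"""Diversity estimators, ordination, PERMANOVA/PERMDISP, LEfSe variant."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import bisect
from scipy.spatial.distance import pdist, squareform
from scipy import stats as sps

from omixfuse.ecology import (
    aggregate_taxonomy,
    alpha_diversity,
    bray_curtis,
    lefse_discriminative,
    nmds,
    pairwise_permanova,
    permanova,
    permdisp,
)


def test_alpha_diversity_even_community_closed_forms():
    res = alpha_diversity(pd.DataFrame([[10, 10, 10, 10]])).iloc[0]
    assert res["Observed"] == 4
    assert abs(res["Shannon"] - np.log(4)) < 1e-12
    assert abs(res["Simpson"] - 0.75) < 1e-12
    assert abs(res["InvSimpson"] - 4.0) < 1e-12
    assert res["Chao1"] == 4.0  # no singletons


def test_chao1_hand_oracle():
    res = alpha_diversity(pd.DataFrame([[5, 1, 1]])).iloc[0]
    # F1=2, F2=0: 3 + 2*1/(2*1) = 4
    assert res["Chao1"] == 4.0


def test_alpha_panel_matches_reference_implementation():
    """Frozen values from the standard R richness estimators (vegan)."""
    counts = pd.DataFrame([[5, 1, 1, 0, 12, 3, 2, 1, 1, 25, 7, 10]])
    res = alpha_diversity(counts).iloc[0]
    assert abs(res["ACE"] - 15.905350) < 1e-5
    assert abs(res["se.ACE"] - 2.107746) < 1e-5
    assert abs(res["Chao1"] - 14.0) < 1e-9
    assert abs(res["Shannon"] - 1.871459) < 1e-5
    assert abs(res["Simpson"] - 0.7923875) < 1e-6
    assert abs(res["InvSimpson"] - 4.816667) < 1e-5
    assert abs(res["Fisher"] - 3.716196) < 1e-5


def test_fisher_alpha_matches_bisection_oracle():
    S, N = 10, 1000
    res = alpha_diversity(
        pd.DataFrame([[100] * 9 + [100]])).iloc[0]  # S=10, N=1000
    oracle = bisect(lambda a: a * np.log(1 + N / a) - S, 1e-6, 1e6, xtol=1e-9)
    assert abs(res["Fisher"] - oracle) < 1e-6


def test_alpha_diversity_invariants(small_cohort):
    _, dataset, _ = small_cohort
    res = alpha_diversity(dataset.views["microbiome"].matrix)
    assert (res["Observed"] <= res["Chao1"] + 1e-9).all()
    assert res["Simpson"].between(0, 1).all()
    assert (res["InvSimpson"] >= 1.0 - 1e-9).all()


def test_bray_curtis_hand_values():
    D = bray_curtis(np.array([[2.0, 1, 0], [1, 1, 1], [1, 0, 0], [0, 1, 0]]))
    assert abs(D[0, 1] - 1.0 / 3.0) < 1e-12
    assert D[2, 3] == 1.0  # disjoint supports
    assert D[0, 0] == 0.0
    assert (D >= 0).all() and (D <= 1).all()
    np.testing.assert_allclose(D, D.T)


def test_nmds_embeddable_square_and_rank_agreement(rng):
    pts = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
    D = squareform(pdist(pts))
    res = nmds(D, k=2, n_starts=8, seed=0)
    assert res.stress < 1e-3
    assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-9)
    X = rng.normal(size=(12, 4))
    D2 = squareform(pdist(X))
    res2 = nmds(D2, k=3, n_starts=10, seed=0)
    emb = squareform(pdist(res2.coordinates))
    iu = np.triu_indices(12, 1)
    rho = sps.spearmanr(D2[iu], emb[iu]).statistic
    assert rho > 0.95


def test_permanova_partition_matches_hand_sums():
    pts = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
    D = squareform(pdist(pts))
    lab = np.array([0, 0, 0, 1, 1, 1])
    res = permanova(D, lab, n_perm=99, seed=0)
    n = 6
    D2 = D ** 2
    ss_tot = sum(D2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_w = (sum(D2[i, j] for i in range(3) for j in range(i + 1, 3)) / 3
            + sum(D2[i, j] for i in range(3, 6) for j in range(i + 1, 6)) / 3)
    F_oracle = ((ss_tot - ss_w) / 1) / (ss_w / 4)
    assert abs(res.ss_total - ss_tot) < 1e-10
    assert abs(res.ss_within - ss_w) < 1e-10
    assert abs(res.pseudo_F - F_oracle) < 1e-10
    assert abs(res.ss_total - res.ss_between - res.ss_within) < 1e-9
    # two well-separated clouds, enough samples: minimum attainable p
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 0.1, size=(10, 2)),
                   rng.normal(8, 0.1, size=(10, 2))])
    big = permanova(squareform(pdist(X)), np.repeat([0, 1], 10),
                    n_perm=99, seed=0)
    # near the minimum attainable (a random permutation can rediscover the
    # exact partition, so allow one extra hit)
    assert big.p <= 2 / 100 + 1e-9


def test_permanova_agrees_with_skbio(rng):
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import DistanceMatrix, permanova as sk_permanova

    X = rng.normal(size=(18, 4))
    X[:9] += 1.0
    D = squareform(pdist(X))
    lab = np.repeat(["a", "b"], 9)
    mine = permanova(D, lab, n_perm=99, seed=0)
    ref = sk_permanova(DistanceMatrix(D), lab.tolist(), permutations=99)
    assert abs(mine.pseudo_F - ref["test statistic"]) < 1e-9


def test_permanova_scale_and_relabel_invariance(rng):
    X = rng.normal(size=(15, 3))
    D = squareform(pdist(X))
    lab = np.array([0] * 5 + [1] * 5 + [2] * 5)
    a = permanova(D, lab, n_perm=49, seed=3)
    b = permanova(2.5 * D, lab, n_perm=49, seed=3)
    assert abs(a.pseudo_F - b.pseudo_F) < 1e-9
    relabeled = np.array([7, 7, 7, 7, 7, 2, 2, 2, 2, 2, 9, 9, 9, 9, 9])
    c = permanova(D, relabeled, n_perm=49, seed=3)
    assert abs(a.pseudo_F - c.pseudo_F) < 1e-9


def test_permdisp_distances_match_hand_1d():
    pts = np.array([[0.0], [2.0], [4.0], [10.0], [10.0], [16.0]])
    D = squareform(pdist(pts))
    lab = np.array([0, 0, 0, 1, 1, 1])
    F, p = permdisp(D, lab, n_perm=99, seed=0, center="centroid")
    # 1D geometry: distances to centroids are |x - group mean|
    z0 = np.abs(pts[:3, 0] - 2.0)
    z1 = np.abs(pts[3:, 0] - 12.0)
    z = np.concatenate([z0, z1])
    grand = z.mean()
    ssb = 3 * (z0.mean() - grand) ** 2 + 3 * (z1.mean() - grand) ** 2
    ssw = ((z0 - z0.mean()) ** 2).sum() + ((z1 - z1.mean()) ** 2).sum()
    F_oracle = (ssb / 1) / (ssw / 4)
    assert abs(F - F_oracle) < 1e-8


def test_permdisp_separates_location_from_dispersion(rng):
    # different locations, same scatter: should NOT reject
    X = rng.normal(size=(40, 3))
    X[:20] += 5.0
    lab = np.repeat([0, 1], 20)
    _, p_loc = permdisp(squareform(pdist(X)), lab, n_perm=199, seed=1)
    assert p_loc > 0.05
    # one group scaled x3: should reject
    Y = rng.normal(size=(40, 3))
    Y[:20] *= 3.0
    _, p_disp = permdisp(squareform(pdist(Y)), lab, n_perm=199, seed=1)
    assert p_disp < 0.05


def test_pairwise_permanova_bonferroni():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(30, 3))
    X[:10] += 4.0  # only group 0 separated
    lab = np.repeat([0, 1, 2], 10)
    D = squareform(pdist(X))
    out = pairwise_permanova(D, lab, n_perm=199, seed=0)
    assert len(out) == 3
    np.testing.assert_allclose(out["p_adjusted"],
                               np.minimum(out["p"] * 3, 1.0))
    sig = out[out["p_adjusted"] < 0.05]
    assert set(map(tuple, sig[["group_a", "group_b"]].to_numpy())) == \
        {(0, 1), (0, 2)}


def test_aggregate_taxonomy_sums_families(small_cohort):
    _, dataset, _ = small_cohort
    counts = dataset.views["microbiome"].matrix
    tax_strings = dataset.views["microbiome"].feature_annotations
    taxonomy = pd.DataFrame(
        [dict(zip(("kingdom", "phylum", "family", "genus"), v.split(";")))
         for v in tax_strings.values()], index=list(tax_strings))
    fam = aggregate_taxonomy(counts, taxonomy, "family")
    assert fam.sum().sum() == counts.sum().sum()
    prev_members = taxonomy.index[taxonomy["family"] == "Prevotellaceae"]
    np.testing.assert_array_equal(fam["Prevotellaceae"],
                                  counts[prev_members].sum(axis=1))


def test_lefse_exclusive_feature_detected_and_null_clean(rng):
    n_per, m = 20, 25
    counts = rng.integers(50, 200, size=(3 * n_per, m)).astype(float)
    counts[:n_per, 0] += 2000  # feature 0 enriched in class A only
    counts[n_per:, 0] = rng.integers(0, 5, size=2 * n_per)
    frame = pd.DataFrame(counts, columns=[f"t{i}" for i in range(m)])
    labels = np.repeat(["A", "B", "C"], n_per)
    res = lefse_discriminative(frame, labels, seed=0)
    hit = res[res["feature"] == "t0"]
    assert len(hit) == 1
    assert hit["enriched_class"].iloc[0] == "A"
    assert hit["significant"].iloc[0] and hit["lda_score"].iloc[0] > 2
    # permuted labels: nothing reported at the default thresholds
    perm = rng.permutation(labels)
    null = lefse_discriminative(frame, perm, seed=1)
    assert null["significant"].sum() <= 1
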