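# omixfuse

Multi-omics patient stratification and characterization for cohort studies
that profile the same individuals through several molecular views — here a
plasma metabolome, a plasma lipidome (with a species → lipid-class map), and
a fecal 16S microbiome (ASV counts with taxonomy) — plus clinical metadata.
The motivating setting is a treated-HIV comorbidity cohort (~97 cases, ~20
uninfected controls), where the question is whether patients fall into
data-driven metabolic risk groups that no single view or clinical variable
explains on its own.

## What it does

**Similarity network fusion (SNF).** Each normalized view yields a patient
similarity graph via a locally scaled exponential kernel,
`W(i,j) = exp(−d²(i,j) / (μ ε_ij))` with
`ε_ij = (mean_K d²(i,·) + mean_K d²(j,·) + d²(i,j)) / 3`
(K = 13 neighbours, μ = 0.8). Cross-diffusion
`P⁽ᵛ⁾ ← S⁽ᵛ⁾ · mean_{u≠v}(P⁽ᵘ⁾) · S⁽ᵛ⁾ᵀ` (T = 10 iterations) fuses the
graphs; normalized-cut spectral clustering partitions the fused network, the
number of clusters C chosen by the Laplacian eigengap and an
embedding-alignment (rotation) cost; each view's agreement with the fused
partition is scored with normalized mutual information,
`NMI = I(A;B)/√(H(A)H(B))`.

**Cluster characterization.** Per-cluster clinical tables (median/IQR or
N (%), Kruskal–Wallis or chi-square/Fisher p by expected-count routing);
pairwise differential abundance with empirical-Bayes moderated t-statistics
(`s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)`, prior estimated from the log
residual variances) and Benjamini–Hochberg control; univariate regressions
linking microbiome-associated metabolites to clinical parameters.

**Microbiome ecology.** Observed/ACE(+SE)/Chao1/Shannon/Simpson/InvSimpson/
Fisher-α richness panel, Bray–Curtis dissimilarity, non-metric MDS,
PERMANOVA with pairwise Bonferroni contrasts, the PERMDISP2 dispersion
check, and a simplified LDA-effect-size scan for cluster-discriminative taxa.

**Multi-view factor model.** A weighted alternating-least-squares factor
analysis (`min Σ_v ‖X_v − Z W_vᵀ‖²_F / p_v`) giving per-view/per-factor
variance decomposition, factor–covariate associations, and top-weight
feature selection.

**Consensus co-expression network.** Balanced resampling (241 features per
view per iteration), within-iteration BH-controlled positive Spearman edge
calls, a 90 % consensus rule over co-sampled iterations, and Leiden
communities with a minimum-size filter.

A first-class synthetic-cohort generator plants known clusters, a binary
confounder driving a Prevotella-like/Bacteroides-like gradient, correlated
metabolite–ASV blocks, and per-cluster comorbidity prevalences, so every
stage is testable against ground truth.

## Worked example

```python
from omixfuse import SyntheticConfig, generate_cohort, SNFClustering
from omixfuse.datasets import OmicsView
from omixfuse.preprocess import prepare_for_fusion
from sklearn.metrics import adjusted_rand_score

dataset, truth = generate_cohort(SyntheticConfig(seed=1))
cases = dataset.metadata.index[dataset.metadata["group"] == "case"]
views = {n: OmicsView(v.matrix.loc[cases], n, v.feature_annotations)
         for n, v in dataset.views.items()}
model = SNFClustering(K=13, alpha=0.8, T=10, seed=1).fit(
    prepare_for_fusion(views))
print("chosen C:", model.n_clusters_,
      "(eigengap:", model.best_C_eigengap_,
      "rotation:", model.best_C_rotation_, ")")
print("ARI vs planted clusters:",
      round(adjusted_rand_score(truth.labels.loc[cases], model.labels_), 3))
print(model.concordance().round(2))
```

Output:

```
chosen C: 3 (eigengap: 3 rotation: 3 )
ARI vs planted clusters: 1.0
            fused  metabolome  lipidome  microbiome
fused        1.00        1.00      1.00        0.17
metabolome   1.00        1.00      1.00        0.17
lipidome     1.00        1.00      1.00        0.17
microbiome   0.17        0.17      0.17        1.00
```

The three planted case clusters are recovered exactly; both model-selection
criteria pick C = 3; the intensity views agree fully with the fused
partition while the noisy compositional microbiome agrees least — the
qualitative ordering such cohorts show in practice.

The same pipeline runs from the shell:

```bash
omixfuse simulate --seed 1 --out cohort/
omixfuse run-all --config config.yaml
```

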