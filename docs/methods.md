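# Methods

This note documents the models, the numerical choices, and what the
synthetic validation does and does not demonstrate.

## Similarity network fusion

Each view enters fusion as a samples × features matrix with features
z-scored (intensity views are log2-transformed and variance-filtered at
0.3 on the log2 scale first; the microbiome enters as standard-normalized
relative abundances). Distances are squared Euclidean. The affinity kernel
is the exponential form `W(i,j) = exp(−d(i,j)/(μ ε_ij))` with the locally
adaptive bandwidth `ε_ij = (m_i + m_j + d(i,j))/3`, where `m_i` is the mean
distance from i to its K nearest other samples. Defaults K = 13, μ = 0.8,
T = 10 fusion iterations, candidate cluster counts 2–8. The Gaussian-density
kernel variant used by some implementations is not provided; the exponential
form is the published equation of the fusion method this package follows.

Two matrices are derived per view: the full-graph transition matrix P with
the 1/2 self-weight convention (`P(i,i) = 1/2`, off-diagonal mass 1/2 per
row) and the KNN-restricted kernel S, row-stochastic on its support.
Cross-diffusion updates `P⁽ᵛ⁾ ← S⁽ᵛ⁾ · mean_{u≠v}(P⁽ᵘ⁾) · S⁽ᵛ⁾ᵀ` followed by
re-normalization; after T iterations the fused matrix is the view average,
symmetrized as `(P+Pᵀ)/2` with the diagonal convention re-imposed.
Duplicate samples (zero bandwidth) are handled by flooring ε at machine
scale with a warning.

**Spectral clustering.** Normalized-cut variant: the C bottom eigenvectors
of the symmetric normalized Laplacian, rows unit-normalized, partitioned by
k-means with a fixed seed and 20 restarts. Other spectral variants of the
original fusion software are out of scope.

**Model selection.** Eigengap `λ_{C+1} − λ_C` (ascending spectrum; larger
is better). The rotation cost is `Σ_i (1 − max_j |(ÛR)_ij|)` over the
row-normalized C-eigenvector embedding Û, where R is the rotation best
aligning rows with a cluster-indicator structure, found by a deterministic
alternating scheme (greedy near-orthogonal initialization from data rows,
then discretize/Procrustes refits). The alignment step matters: without R
the cost depends on the arbitrary eigenbasis returned by the solver. This
is one published variant of a criterion the literature names without a
unique definition. Ties in both criteria break toward smaller C.

**Concordance.** Fused and per-view final matrices are clustered at the
same C; agreement is NMI with the geometric-mean normalization
`I/√(H·H)` (max and mean normalizations available). Two single-class
partitions define NMI = 1; if exactly one partition is single-class, 0.

## Moderated differential abundance

Per-feature OLS against a one-hot group design (no reference level; all
pairwise contrasts are coefficient differences), optionally with centred
covariates appended ("adjusted" model). Residual variances are shrunk
toward a prior `(d₀, s₀²)` estimated by moment-matching on `log s²` via
digamma/trigamma identities, the trigamma inverted by monotone Newton
iteration; the moderated t has `d₀ + d` degrees of freedom. In the
degenerate limit where the log-variances show no excess dispersion the
prior df is infinite and the prior variance is the pooled mean of the
residual variances, so identical variances are a fixed point (no
shrinkage). BH adjustment is applied within each contrast by default; a
global family is available because the correct family is a modelling
choice, not a mathematical one.

Contingency tables route to Pearson chi-square (no continuity correction)
when all expected counts are ≥ 5 and to Fisher's exact test otherwise
(hypergeometric for 2×2; exact conditional enumeration for small r×c
tables, a seeded Monte Carlo estimate when the state space is too large).

## Microbiome ecology

The richness panel implements the classical estimators on raw integer
counts: bias-corrected Chao1 `S_obs + F₁(F₁−1)/(2(F₂+1))`; ACE with rare
cutoff 10 and its delta-method standard error, the gradient matching the
symbolic derivative used by the standard R implementation; Shannon,
Simpson, inverse Simpson from relative abundances; Fisher's α as the root
of `S = α ln(1 + N/α)`. NMDS minimizes Kruskal stress-1 by non-metric MDS
with 20 random starts (monotone regression + configuration updates).

PERMANOVA uses the direct sum-of-squares partition
(`SS_total = (1/n)Σ_{i<j}D²`, within-group analogues), pseudo-F with
`(k−1, n−k)` degrees of freedom, and the `(count+1)/(n_perm+1)` permutation
p-value. PERMDISP embeds the distance matrix by principal coordinates
(negative eigenvalues handled by subtracting squared imaginary-axis
distances), measures each sample's distance to its group's **spatial
median** by default, and permutes the least-squares residuals of
`distances ~ group`. The spatial median is the default of the reference
dispersion procedure and holds its nominal size in small balanced designs
(measured here: ≈ 0.03–0.04 at α = 0.05, n = 30, k = 3), whereas the
centroid variant is measurably liberal (≈ 0.08–0.09); the centroid remains
available via `center="centroid"`.

The LDA-effect-size scan is a documented simplification of the published
heuristic: total-sum scaling to counts per million; one-against-all
Kruskal–Wallis at α = 0.05; pairwise Wilcoxon tests against the top class
with consistent direction; then 30 bootstraps of 2/3-subsampled
linear-discriminant fits whose per-feature effect averages the scaled
discriminant coefficient and the raw class-mean difference, reported as a
signed `log10(1+|effect|)` score with |score| > 2 flagged. The exact
Galaxy implementation is a non-goal.

## Multi-view factor model

A deterministic weighted-ALS factor analysis replaces a Bayesian
multi-omics factor analysis: it minimizes
`Σ_v ‖X_v − Z W_vᵀ‖²_F / p_v`, the inverse-dimension weighting making each
view count equally regardless of width (duplicating a view's features
leaves its variance share essentially unchanged). Initialization is a
randomized SVD of the weighted concatenation; scores are re-orthonormalized
each sweep, so the weighted loss is non-increasing; convergence at relative
loss change < 1e-8. Factors are ordered by total variance explained and
pruned when they explain < 0.1 % in every view. This reproduces the
quantities downstream analysis actually consumes — per-view/per-factor R²,
factor–covariate Pearson associations (binary covariates 0/1, i.e.
point-biserial), 5 %/95 % and top-decile loading selection, and a
competitive t-type enrichment on loadings with positive/negative directions
separated — without variational inference; it does not provide ARD-style
automatic factor shrinkage or missing-view handling.

## Consensus co-expression network

Spearman correlations use average ranks and the t approximation for p.
Within each of the (default 1000; 200 in the test suite) iterations, 241
features per view are drawn without replacement, all pairs among the drawn
union form one BH family, and significant positive pairs (default
FDR < 0.001) are recorded. An edge's consensus frequency divides by the
number of iterations in which **both** endpoints were co-sampled — with
per-view subsampling a pair is absent from most iterations, and an
all-iterations denominator could never reach the 90 % consensus rule. The
screening shortcut (only pairs whose raw p is below the FDR level can be
BH-rejected; raw p is monotone in |ρ| at fixed df) makes the inner loop
exact and fast. Communities are Leiden partitions (RB-configuration
objective, resolution 1.0, fixed seed) on the unweighted edge list;
communities under 30 members are reported as excluded; mean degree uses
full-graph degrees.

## Synthetic cohorts

The generator emulates the study conditions: 97 cases split 19/44/34 across
three clusters plus 20 controls. Intensity baselines are log-normal with
mean 20, SD 1 on the log2 scale (typical untargeted-MS dynamic range — the
distributional form is a stand-in, since real acquisition distributions are
instrument-specific); planted shifts default to 2.0 log2 units on 30 %
(metabolome), 40 % (lipidome), and 15 % (microbiome) of features, the
lipidome strongest so the per-view concordance ordering matches what such
cohorts show. Under the full pattern each cluster has an exclusive
signature block plus a shared "amino-acid" block elevated in clusters 1-2;
the cluster-2 lipid block is relabelled into TAG/DAG species so class
aggregation shows the di-/triglyceride elevation. The mixed-signal pattern
gives each view separating power for exactly one cluster, so only fusion
resolves all three. Microbiome counts are Dirichlet-multinomial
(concentration 50, library sizes 20k–50k) with a binary transmission-mode
confounder (per-cluster prevalences 0.47/0.81/0.53) shifting a
Prevotella-like block when positive and a Bacteroides-like block when
negative. A 20-metabolite block is re-drawn through a Gaussian copula on
the partner ASV's CLR normal scores to hit a target Spearman ρ (default
0.6), using `r = 2 sin(πρ/6)`. Binary comorbidities are drawn at
per-cluster prevalences (metabolic syndrome 0.32/0.70/0.17, central obesity
0.42/0.73/0.50, hypertension 0.26/0.52/0.62, controls 0.10). One master
seed spawns fixed per-view child streams, so a view is reproducible even
when other views' parameters change.

View sizes default to 200 metabolites / 200 lipids / 120 ASVs — smaller
than a real untargeted panel — so the full validation suite runs quickly;
the planted structure, not the dimensionality, is what the tests probe.

**What passing tests do not show.** The generator draws complete,
batch-free, Gaussian-noise data with block-structured signals; real
cohorts add missing intensities, batch and instrument effects, heavier
tails, and correlated null features. Calibration and recovery results
transfer to real data only to the extent those violations are mild;
the cohort-level published numbers (view concordances, metabolite counts
at stringent FDR, network sizes, variance shares) depend on the cohort's
raw data and are not reproduced here — only their structural and ordering
properties are asserted.

## Degenerate inputs and tie-breaking

Duplicate samples floor the kernel bandwidth; disconnected affinity graphs
warn and proceed on the embedding; zero-variance features must be filtered
before z-scoring (explicit error); empty microbiome samples yield NaN
diversity rows with a warning; all-zero sample pairs get Bray–Curtis 0 with
a warning; constant predictors/covariates are skipped with warnings; group
levels with fewer than 2 (tests) or 3 (discriminant scan) samples are
skipped. K-means and Leiden run under fixed seeds; argmax/argmin ties in
model selection break toward smaller C; consensus edges use canonical
(min, max) endpoint ordering.
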