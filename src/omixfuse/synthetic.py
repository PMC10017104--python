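"""Synthetic multi-omics cohorts with planted, recoverable structure.

Emulates an HIV-comorbidity style cohort: ~97 cases carrying three latent
patient clusters plus ~20 uninfected controls, observed through three views —

* a metabolome of log-normal intensities with cluster-specific shifts (an
  "amino-acid pathway" block elevated in two of the three case clusters
  relative to controls),
* a lipidome with a species-to-class map over 14 lipid classes, where the
  di-/triacylglycerol species are elevated in the "severe" cluster,
* a 16S microbiome of Dirichlet-multinomial ASV counts in which a binary
  confounder (transmission mode) drives a Prevotella-like versus
  Bacteroides-like gradient, independent of the clusters.

A designated block of "microbiome-associated metabolites" is re-drawn to
correlate with partner ASVs at a chosen Spearman rho (Gaussian copula).
Clinical metadata contains binary comorbidities drawn at per-cluster
prevalences, so contingency-table statistics have known expectations.

Every quantity the generator plants is returned in a :class:`GroundTruth`,
which is what downstream tests score against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import MultiOmicsDataset, OmicsView

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "ConfigurationError",
    "generate_cohort",
    "generate_microbiome",
    "generate_mam_structure",
    "mixed_signal_config",
]


class ConfigurationError(ValueError):
    """A synthetic-cohort configuration field is invalid."""


LIPID_CLASSES = (
    "CER", "CE", "DAG", "DCER", "HCER", "LCER", "LPC",
    "LPE", "MAG", "PC", "PE", "PI", "SM", "TAG",
)
# relative panel sizes; TAG/PC/PE dominate, mirroring complex-lipid panels
_LIPID_CLASS_WEIGHTS = np.array(
    [4, 6, 6, 1, 1, 1, 4, 2, 1, 10, 7, 3, 4, 14], dtype=float
)

_GENUS_POOL = (
    "Faecalibacterium", "Ruminococcus", "Blautia", "Roseburia", "Veillonella",
    "Succinivibrio", "Akkermansia", "Alistipes", "Dialister", "Dorea",
    "Coprococcus", "Oscillibacter", "Parabacteroides", "Streptococcus",
)

# child-stream offsets: view-level reproducibility when other views change
_STREAMS = {"metabolome": 1, "lipidome": 2, "microbiome": 3, "clinical": 4, "mam": 5}


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic cohort.

    Defaults reproduce the study conditions: 97 cases split 19/44/34 across
    three clusters plus 20 controls; comorbidity and transmission-mode
    prevalences follow the cohort's clinical table.  Intensity baselines are
    log-normal with mean 20 and SD 1 on the log2 scale (typical untargeted-MS
    dynamic range); planted shifts are expressed in log2 fold change.
    """

    n_cases: int = 97
    n_controls: int = 20
    cluster_sizes: tuple[int, ...] = (19, 44, 34)
    n_metabolites: int = 200
    n_lipids: int = 200
    n_asvs: int = 120
    effect_log2fc: float = 2.0
    frac_differential: dict[str, float] = field(
        default_factory=lambda: {"metabolome": 0.3, "lipidome": 0.4, "microbiome": 0.15}
    )
    confounder_prevalence: tuple[float, ...] = (0.47, 0.81, 0.53)
    control_confounder_prevalence: float = 0.5
    comorbidity_prevalence: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "mets": (0.32, 0.70, 0.17),
            "central_obesity": (0.42, 0.73, 0.50),
            "hypertension": (0.26, 0.52, 0.62),
        }
    )
    control_comorbidity_prevalence: float = 0.10
    mam_block_size: int = 20
    mam_rho: float = 0.6
    confounder_log2fc: float = 1.0
    dirichlet_concentration: float = 50.0
    library_size_range: tuple[int, int] = (20_000, 50_000)
    noise_sd: float = 1.0
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 1.0
    signal_pattern: str = "full"  # "full" or "mixed"
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0:
            raise ConfigurationError("n_cases must be positive")
        if self.n_controls < 0:
            raise ConfigurationError("n_controls must be non-negative")
        if sum(self.cluster_sizes) != self.n_cases:
            raise ConfigurationError(
                f"cluster_sizes {self.cluster_sizes} must sum to n_cases={self.n_cases}"
            )
        if any(s <= 0 for s in self.cluster_sizes):
            raise ConfigurationError("cluster_sizes entries must be positive")
        for view, frac in self.frac_differential.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"frac_differential[{view!r}] not in [0,1]")
        for p in self.confounder_prevalence:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("confounder_prevalence not in [0,1]")
        if len(self.confounder_prevalence) != len(self.cluster_sizes):
            raise ConfigurationError(
                "confounder_prevalence must have one entry per cluster"
            )
        for name, ps in self.comorbidity_prevalence.items():
            if len(ps) != len(self.cluster_sizes):
                raise ConfigurationError(
                    f"comorbidity_prevalence[{name!r}] needs one entry per cluster"
                )
            if any(not 0.0 <= p <= 1.0 for p in ps):
                raise ConfigurationError(f"comorbidity_prevalence[{name!r}] not in [0,1]")
        if self.dirichlet_concentration <= 0:
            raise ConfigurationError("dirichlet_concentration must be positive")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("library_size_range must satisfy 0 < min <= max")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not abs(self.mam_rho) < 1:
            raise ConfigurationError("mam_rho must satisfy |rho| < 1")
        if self.mam_block_size > min(self.n_metabolites, self.n_asvs):
            raise ConfigurationError("mam_block_size exceeds available features")
        if self.signal_pattern not in ("full", "mixed"):
            raise ConfigurationError("signal_pattern must be 'full' or 'mixed'")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic child stream for one view."""
        return np.random.default_rng([self.seed, _STREAMS[stream]])


@dataclass
class GroundTruth:
    """Everything the generator planted, for scoring downstream stages."""

    labels: pd.Series  # per-sample cluster id, 0 = control
    differential_features: dict[str, pd.DataFrame]  # view -> (feature, cluster, log2fc)
    confounder: pd.Series  # per-sample 0/1
    mam_map: dict[str, str]  # metabolite id -> partner ASV id
    mam_rho: float
    planted_factors: pd.DataFrame  # per-sample latent scores

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": self.labels.astype(int).to_dict(),
            "confounder": self.confounder.astype(int).to_dict(),
            "mam_map": self.mam_map,
            "mam_rho": self.mam_rho,
            "differential_features": {
                view: df.to_dict(orient="records")
                for view, df in self.differential_features.items()
            },
            "planted_factors": self.planted_factors.round(10).to_dict(orient="index"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _group_vector(config: SyntheticConfig) -> np.ndarray:
    """Per-sample group id: 0 for controls, 1..k for case clusters."""
    groups = [0] * config.n_controls
    for c, size in enumerate(config.cluster_sizes, start=1):
        groups.extend([c] * size)
    return np.asarray(groups)


def _signature_blocks(
    config: SyntheticConfig, view: str, n_features: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, list[int]]]:
    """Planted (feature_indices, affected_clusters) blocks for one view.

    ``full`` pattern: each cluster gets an exclusive block, plus a shared
    block elevated in clusters 1 and 2 for the intensity views (the
    amino-acid-pathway motif).  ``mixed`` pattern: each view separates only
    one cluster from the other two, so no single view can resolve all three
    — only the fused network can.
    """
    k = len(config.cluster_sizes)
    n_diff = int(round(config.frac_differential.get(view, 0.0) * n_features))
    if n_diff == 0:
        return []
    idx = rng.choice(n_features, size=n_diff, replace=False)
    if config.signal_pattern == "mixed":
        target = {"metabolome": 1, "lipidome": 2, "microbiome": 3}.get(view, 1)
        return [(idx, [target])]
    # full pattern: k exclusive blocks (+ one shared block in intensity views)
    n_blocks = k + (1 if view in ("metabolome", "lipidome") else 0)
    parts = np.array_split(idx, n_blocks)
    blocks = [(parts[c], [c + 1]) for c in range(k)]
    if n_blocks > k and len(parts[k]) > 0:
        blocks.append((parts[k], [1, 2]))
    return blocks


def _intensity_view(
    config: SyntheticConfig, view: str, n_features: int, groups: np.ndarray
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-normal intensity view with planted per-cluster log2 shifts."""
    rng = config.rng(view)
    n = len(groups)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_features)
    shifts = np.zeros((len(config.cluster_sizes) + 1, n_features))
    records = []
    for feat_idx, clusters in _signature_blocks(config, view, n_features, rng):
        for c in clusters:
            shifts[c, feat_idx] += config.effect_log2fc
            records.extend(
                {"feature": int(f), "cluster": int(c), "log2fc": config.effect_log2fc}
                for f in feat_idx
            )
    log2 = (
        baseline[None, :]
        + shifts[groups, :]
        + rng.normal(0.0, config.noise_sd, (n, n_features))
    )
    matrix = np.exp2(log2)
    prefix = "met" if view == "metabolome" else "lip"
    cols = [f"{prefix}_{i:04d}" for i in range(n_features)]
    diff = pd.DataFrame(records) if records else pd.DataFrame(
        columns=["feature", "cluster", "log2fc"]
    )
    if not diff.empty:
        diff["feature"] = [cols[i] for i in diff["feature"]]
    return pd.DataFrame(matrix, columns=cols), diff


def _lipid_class_map(config: SyntheticConfig, cols: list[str], rng: np.random.Generator
                     ) -> dict[str, str]:
    """Assign each species a class, sizes proportional to the panel weights."""
    w = _LIPID_CLASS_WEIGHTS / _LIPID_CLASS_WEIGHTS.sum()
    counts = np.floor(w * len(cols)).astype(int)
    while counts.sum() < len(cols):
        counts[int(np.argmax(w * len(cols) - counts))] += 1
    classes = np.repeat(list(LIPID_CLASSES), counts)
    return dict(zip(cols, classes))


def generate_microbiome(
    labels: np.ndarray,
    confounder: np.ndarray,
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Dirichlet-multinomial ASV counts with a confounder-driven gradient.

    Returns ``(counts, taxonomy, differential)``.  A Prevotella-like block
    has elevated expected relative abundance in confounder-positive samples
    and a Bacteroides-like block in confounder-negative samples; additional
    per-cluster blocks carry the (weaker) cluster signal.
    """
    if config.dirichlet_concentration <= 0:
        raise ConfigurationError("dirichlet_concentration must be positive")
    labels = np.asarray(labels)
    confounder = np.asarray(confounder)
    if labels.shape != confounder.shape:
        raise ConfigurationError("labels and confounder must have equal length")
    rng = config.rng("microbiome")
    n, m = len(labels), config.n_asvs
    block = max(3, m // 12)
    prevotella = np.arange(0, block)
    bacteroides = np.arange(block, 2 * block)

    base = rng.normal(0.0, 1.5, m)  # skewed baseline composition
    log_ab = np.tile(base, (n, 1))
    conf_shift = config.confounder_log2fc * np.log(2.0)
    log_ab[np.ix_(confounder == 1, prevotella)] += conf_shift
    log_ab[np.ix_(confounder == 0, bacteroides)] += conf_shift

    shift = config.effect_log2fc * np.log(2.0)
    records = []
    avail = np.arange(2 * block, m)
    blocks = _signature_blocks(config, "microbiome", len(avail), rng)
    for rel_idx, clusters in blocks:
        feat = avail[rel_idx]
        for c in clusters:
            log_ab[np.ix_(labels == c, feat)] += shift
            records.extend(
                {"feature": f"asv_{f:04d}", "cluster": int(c),
                 "log2fc": config.effect_log2fc}
                for f in feat
            )

    p = np.exp(log_ab)
    p /= p.sum(axis=1, keepdims=True)
    lo, hi = config.library_size_range
    libs = rng.integers(lo, hi + 1, size=n)
    counts = np.empty((n, m), dtype=np.int64)
    for i in range(n):
        comp = rng.dirichlet(config.dirichlet_concentration * p[i])
        counts[i] = rng.multinomial(libs[i], comp)

    asv_ids = [f"asv_{i:04d}" for i in range(m)]
    genus = np.array([_GENUS_POOL[i % len(_GENUS_POOL)] for i in range(m)], dtype=object)
    genus[prevotella] = "Prevotella"
    genus[bacteroides] = "Bacteroides"
    family = np.where(
        np.isin(genus, ["Prevotella"]), "Prevotellaceae",
        np.where(np.isin(genus, ["Bacteroides", "Parabacteroides"]), "Bacteroidaceae",
                 np.char.add(genus.astype(str), "_family")),
    )
    phylum = np.where(
        np.isin(genus, ["Prevotella", "Bacteroides", "Parabacteroides", "Alistipes"]),
        "Bacteroidetes", "Firmicutes",
    )
    taxonomy = pd.DataFrame(
        {"asv_id": asv_ids, "kingdom": "Bacteria", "phylum": phylum,
         "family": family, "genus": genus}
    ).set_index("asv_id")
    diff = pd.DataFrame(records) if records else pd.DataFrame(
        columns=["feature", "cluster", "log2fc"]
    )
    return pd.DataFrame(counts, columns=asv_ids), taxonomy, diff


def generate_mam_structure(
    asv_matrix: pd.DataFrame,
    metabolite_matrix: pd.DataFrame,
    mam_map: dict[str, str],
    rho: float,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Re-draw mapped metabolite columns to track partner ASVs at Spearman rho.

    Each mapped metabolite is rebuilt from the normal scores of its partner
    ASV's CLR abundance through a Gaussian copula, so the pair's Spearman
    correlation has expectation ``rho``; the column keeps its original mean
    and SD on the log2 scale.  Unmapped columns are untouched.
    """
    if not abs(rho) < 1:
        raise ConfigurationError("rho must satisfy |rho| < 1")
    for met, asv in mam_map.items():
        if met not in metabolite_matrix.columns:
            raise KeyError(f"unknown metabolite id {met!r}")
        if asv not in asv_matrix.columns:
            raise KeyError(f"unknown ASV id {asv!r}")
    rng = np.random.default_rng(0) if rng is None else rng
    out = metabolite_matrix.copy()
    logc = np.log(asv_matrix.to_numpy(dtype=float) + 1.0)
    clr = logc - logc.mean(axis=1, keepdims=True)
    clr_df = pd.DataFrame(clr, index=asv_matrix.index, columns=asv_matrix.columns)
    n = len(metabolite_matrix)
    # bivariate-normal Pearson r that yields the requested Spearman rho
    r = 2.0 * np.sin(np.pi * rho / 6.0)
    from scipy.stats import norm, rankdata

    for met, asv in mam_map.items():
        z = norm.ppf((rankdata(clr_df[asv].to_numpy()) - 0.5) / n)
        mixed = r * z + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
        old_log2 = np.log2(metabolite_matrix[met].to_numpy(dtype=float))
        new_log2 = old_log2.mean() + old_log2.std(ddof=1) * mixed
        out[met] = np.exp2(new_log2)
    return out


def _clinical_table(
    config: SyntheticConfig, groups: np.ndarray, sample_ids: list[str]
) -> tuple[pd.DataFrame, np.ndarray]:
    rng = config.rng("clinical")
    n = len(groups)
    conf_p = np.concatenate(
        [[config.control_confounder_prevalence], config.confounder_prevalence]
    )
    confounder = (rng.random(n) < conf_p[groups]).astype(int)
    meta = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    meta["group"] = np.where(groups == 0, "control", "case")
    meta["cluster"] = groups
    meta["msm"] = confounder
    for name, prevs in config.comorbidity_prevalence.items():
        p = np.concatenate([[config.control_comorbidity_prevalence], prevs])
        meta[name] = (rng.random(n) < p[groups]).astype(int)
    meta["age"] = np.round(rng.normal(55.0, 8.0, n), 1)
    cd4_median = np.array([800.0, 680.0, 762.0, 610.0])
    meta["cd4"] = np.round(cd4_median[groups] * np.exp(rng.normal(0.0, 0.25, n)))
    return meta, confounder


def generate_cohort(config: SyntheticConfig) -> tuple[MultiOmicsDataset, GroundTruth]:
    """Generate one aligned three-view cohort plus its ground truth."""
    config.validate()
    groups = _group_vector(config)
    n = len(groups)
    sample_ids = [f"S{i:03d}" for i in range(n)]

    meta, confounder = _clinical_table(config, groups, sample_ids)

    met_mat, met_diff = _intensity_view(config, "metabolome", config.n_metabolites, groups)
    lip_mat, lip_diff = _intensity_view(config, "lipidome", config.n_lipids, groups)
    lip_map = _lipid_class_map(config, list(lip_mat.columns), config.rng("lipidome"))
    # route the severe-cluster lipid block through DAG/TAG species: relabel the
    # planted cluster-2 features into those classes so class aggregation shows
    # the di-/triglyceride elevation
    c2_feats = lip_diff.loc[lip_diff["cluster"] == 2, "feature"].unique()
    for j, feat in enumerate(c2_feats):
        lip_map[feat] = "TAG" if j % 2 == 0 else "DAG"

    counts, taxonomy, micro_diff = generate_microbiome(groups, confounder, config)

    mam_rng = config.rng("mam")
    non_diff = [c for c in met_mat.columns if c not in set(met_diff["feature"])]
    mam_mets = list(mam_rng.choice(non_diff, size=config.mam_block_size, replace=False))
    mam_asvs = list(mam_rng.choice(counts.columns, size=config.mam_block_size,
                                   replace=False))
    mam_map = dict(zip(mam_mets, mam_asvs))
    met_mat = generate_mam_structure(counts, met_mat, mam_map, config.mam_rho, mam_rng)

    for df in (met_mat, lip_mat, counts):
        df.index = pd.Index(sample_ids, name="sample_id")
    taxonomy_str = taxonomy.apply(
        lambda r: ";".join(r[c] for c in ("kingdom", "phylum", "family", "genus")), axis=1
    )
    views = {
        "metabolome": OmicsView(
            met_mat, "metabolome",
            {c: ("Amino Acid" if c in set(
                met_diff.loc[met_diff["cluster"].isin([1, 2]), "feature"])
             else "Other") for c in met_mat.columns},
        ),
        "lipidome": OmicsView(lip_mat, "lipidome", dict(lip_map)),
        "microbiome": OmicsView(counts, "microbiome", taxonomy_str.to_dict()),
    }
    dataset = MultiOmicsDataset(views=views, metadata=meta)

    factors = pd.DataFrame(index=meta.index)
    factors["severity"] = (groups == 2).astype(float)
    factors["amino_acid"] = np.isin(groups, [1, 2]).astype(float)
    factors["transmission"] = confounder.astype(float)
    factors -= factors.mean()

    truth = GroundTruth(
        labels=pd.Series(groups, index=meta.index, name="cluster"),
        differential_features={
            "metabolome": met_diff, "lipidome": lip_diff, "microbiome": micro_diff
        },
        confounder=pd.Series(confounder, index=meta.index, name="msm"),
        mam_map=mam_map,
        mam_rho=config.mam_rho,
        planted_factors=factors,
    )
    return dataset, truth


def mixed_signal_config(**overrides) -> SyntheticConfig:
    """Configuration in which each view separates only one case cluster.

    No single view can resolve all three clusters; the fused network can.
    """
    defaults = dict(
        signal_pattern="mixed",
        frac_differential={"metabolome": 0.3, "lipidome": 0.3, "microbiome": 0.3},
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def write_taxonomy_tsv(taxonomy: pd.DataFrame, path: str | Path) -> None:
    taxonomy.to_csv(path, sep="\t")


def write_biom(counts: pd.DataFrame, path: str | Path) -> None:
    """Optional BIOM 2.1 export of an ASV count table (samples in rows)."""
    import biom
    from biom.util import biom_open

    table = biom.Table(
        counts.to_numpy().T, observation_ids=list(counts.columns),
        sample_ids=list(counts.index),
    )
    with biom_open(str(path), "w") as fh:
        table.to_hdf5(fh, "omixfuse")
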