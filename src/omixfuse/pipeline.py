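"""End-to-end orchestration: simulate/ingest -> preprocess -> fusion ->
clusters -> clinical characterization -> differential abundance -> ecology
-> factors -> networks, under one YAML-configurable run with deterministic
seeds and a checksummed manifest.

Numeric artifacts are written as TSV rounded to six significant digits so
manifests are reproducible across platforms.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ecology as eco
from . import factors as fm
from . import network as net
from . import preprocess as prep
from . import stats as st
from .datasets import MultiOmicsDataset, OmicsView
from .snf import SNFClustering
from .synthetic import SyntheticConfig, generate_cohort

log = logging.getLogger("omixfuse")

ALL_STAGES = ("simulate", "preprocess", "fuse", "characterize", "diff",
              "ecology", "factors", "network")

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """One run's inputs, stage parameters, and output location."""

    outdir: str = "omixfuse_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    synthetic: dict | None = None  # SyntheticConfig overrides; None -> load paths
    view_paths: dict[str, str] | None = None
    metadata_path: str | None = None
    snf: dict = field(default_factory=dict)  # K, alpha, T, C, candidate_C_range
    diff: dict = field(default_factory=lambda: {"fdr_threshold": 0.05})
    ecology: dict = field(default_factory=lambda: {"level": "family",
                                                   "n_perm": 999})
    factors: dict = field(default_factory=lambda: {"n_factors": 15})
    network: dict = field(default_factory=lambda: {
        "n_iter": 1000, "n_per_view": 241, "fdr": 0.001, "consensus": 0.90})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.synthetic is None:
            if not self.view_paths or not self.metadata_path:
                raise ValueError("either synthetic config or input paths required")
            for name, p in self.view_paths.items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"view {name!r}: {p}")
            if not Path(self.metadata_path).exists():
                raise FileNotFoundError(self.metadata_path)


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, **kw)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def characterize_clusters(metadata: pd.DataFrame, labels: pd.Series,
                          max_levels: int = 6) -> pd.DataFrame:
    """Per-cluster clinical characterization table.

    Continuous variables: per-cluster median (IQR) and a Kruskal-Wallis p;
    binary/categorical variables: N (%) and a chi-square/Fisher p (routed
    by expected counts).
    """
    labels = labels.loc[metadata.index]
    clusters = sorted(pd.unique(labels))
    rows = []
    for var in metadata.columns:
        col = metadata[var]
        if col.isna().all():
            warnings.warn(f"variable {var!r} all missing; dropped")
            continue
        numeric = pd.to_numeric(col, errors="coerce")
        is_cat = (numeric.isna().any() and not col.isna().any()) or \
            col.nunique(dropna=True) <= 2
        cells = {"variable": var}
        if is_cat:
            tab = pd.crosstab(col, labels)
            if tab.shape[0] > max_levels or tab.shape[0] < 2:
                continue
            try:
                _, p, method = st.categorical_test(tab.to_numpy())
            except ValueError:
                p, method = np.nan, "NA"
            top = tab.index[-1] if set(tab.index) == {0, 1} else tab.index[0]
            for c in clusters:
                n_c = int((labels == c).sum())
                n_yes = int(tab.loc[top, c]) if c in tab.columns else 0
                cells[f"cluster_{c}"] = f"{n_yes} ({100 * n_yes / n_c:.0f})"
            cells["overall"] = f"{int(tab.loc[top].sum())}"
            cells["p"] = p
            cells["test"] = method
        else:
            ok = numeric.notna()
            groups = [numeric[ok & (labels == c)].to_numpy() for c in clusters]
            if any(g.size < 2 for g in groups):
                continue
            _, p = st.rank_tests(groups, "kruskal_wallis")
            for c, g in zip(clusters, groups):
                q1, q2, q3 = np.percentile(g, [25, 50, 75])
                cells[f"cluster_{c}"] = f"{q2:.3g} ({q1:.3g}-{q3:.3g})"
            q1, q2, q3 = np.percentile(numeric[ok], [25, 50, 75])
            cells["overall"] = f"{q2:.3g} ({q1:.3g}-{q3:.3g})"
            cells["p"] = p
            cells["test"] = "kruskal_wallis"
        rows.append(cells)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return result objects."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": {
        "seed": config.seed, "stages": list(config.stages),
        "snf": config.snf, "diff": config.diff, "ecology": config.ecology,
        "factors": config.factors, "network": config.network,
        "synthetic": config.synthetic,
    }, "artifacts": {}}
    results: dict = {}

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": path.name, "sha256": _checksum(path)}

    # ---- input acquisition -------------------------------------------------
    truth = None
    if config.synthetic is not None and "simulate" in config.stages:
        syn = SyntheticConfig(**{"seed": config.seed, **config.synthetic})
        dataset, truth = generate_cohort(syn)
        dataset.write(outdir / "views")
        truth.to_json(outdir / "ground_truth.json")
        record("ground_truth", outdir / "ground_truth.json")
    else:
        views = {
            name: OmicsView.from_tsv(path, name)
            for name, path in (config.view_paths or {}).items()
        }
        metadata = pd.read_csv(config.metadata_path, sep="\t", index_col=0)
        dataset = MultiOmicsDataset(views=views, metadata=metadata)
    results["dataset"] = dataset
    results["truth"] = truth

    meta = dataset.metadata
    case_mask = (meta["group"] == "case") if "group" in meta else pd.Series(
        True, index=meta.index)
    case_ids = meta.index[case_mask]

    # ---- preprocess --------------------------------------------------------
    normalized = None
    if "preprocess" in config.stages:
        log.info("preprocess: per-view transform chain")
        case_views = {
            name: OmicsView(v.matrix.loc[case_ids], name, v.feature_annotations)
            for name, v in dataset.views.items()
        }
        normalized = prep.prepare_for_fusion(case_views)
        for name, mat in normalized.items():
            path = outdir / f"normalized_{name}.tsv"
            _write_tsv(mat, path, index_label="sample_id")
            record(f"normalized_{name}", path)
        results["normalized"] = normalized

    # ---- fuse + cluster ----------------------------------------------------
    labels = None
    if "fuse" in config.stages and normalized is not None:
        log.info("fuse: SNF + spectral clustering")
        model = SNFClustering(seed=config.seed, **config.snf)
        model.fit(normalized)
        labels = pd.Series(model.labels_, index=case_ids, name="cluster")
        _write_tsv(model.fused_network_.to_frame(), outdir / "fused.tsv",
                   index_label="sample_id")
        _write_tsv(labels.to_frame(), outdir / "labels.tsv",
                   index_label="sample_id")
        traces = {
            "chosen_C": model.assignment_.chosen_C,
            "best_C_eigengap": model.best_C_eigengap_,
            "best_C_rotation": model.best_C_rotation_,
            "eigengap_by_C": model.assignment_.eigengap_by_C,
            "rotation_cost_by_C": model.assignment_.rotation_cost_by_C,
        }
        (outdir / "model_selection.json").write_text(
            json.dumps(traces, indent=1, default=float))
        for name in ("fused", "labels", "model_selection"):
            suffix = ".json" if name == "model_selection" else ".tsv"
            record(name, outdir / f"{name}{suffix}")
        results["snf"] = model
        results["concordance"] = model.concordance()
        _write_tsv(results["concordance"], outdir / "concordance.tsv")
        record("concordance", outdir / "concordance.tsv")

    # assemble per-sample group label over the full cohort: cluster id for
    # cases, "control" for controls
    if labels is not None:
        full_labels = pd.Series("control", index=meta.index, name="group_label")
        full_labels.loc[labels.index] = [f"SNF-{c}" for c in labels]
    else:
        full_labels = None

    # ---- characterize ------------------------------------------------------
    if "characterize" in config.stages and labels is not None:
        log.info("characterize: per-cluster clinical table")
        drop = [c for c in ("cluster", "group") if c in meta.columns]
        table = characterize_clusters(
            meta.loc[case_ids].drop(columns=drop), labels)
        _write_tsv(table, outdir / "characterization.tsv", index=False)
        record("characterization", outdir / "characterization.tsv")
        results["characterization"] = table

    # ---- differential abundance -------------------------------------------
    if "diff" in config.stages and full_labels is not None:
        log.info("diff: moderated pairwise differential abundance")
        frames = []
        for name in ("metabolome", "lipidome"):
            if name not in dataset.views:
                continue
            logged = prep.log2_transform(dataset.views[name])
            tab = st.pairwise_differential(
                logged.matrix, full_labels,
                fdr_threshold=config.diff.get("fdr_threshold", 0.05))
            tab.insert(0, "view", name)
            frames.append(tab)
        diff_table = pd.concat(frames, ignore_index=True)
        _write_tsv(diff_table, outdir / "differential.tsv", index=False)
        record("differential", outdir / "differential.tsv")
        results["differential"] = diff_table

    # ---- ecology -----------------------------------------------------------
    if "ecology" in config.stages and full_labels is not None \
            and "microbiome" in dataset.views:
        log.info("ecology: alpha diversity, ordination, PERMANOVA")
        counts = dataset.views["microbiome"].matrix.loc[case_ids]
        alpha = eco.alpha_diversity(counts)
        _write_tsv(alpha, outdir / "alpha_diversity.tsv",
                   index_label="sample_id")
        record("alpha_diversity", outdir / "alpha_diversity.tsv")
        rel = counts.div(counts.sum(axis=1), axis=0)
        D = eco.bray_curtis(rel)
        case_labels = full_labels.loc[case_ids].to_numpy()
        n_perm = config.ecology.get("n_perm", 999)
        perm = eco.permanova(D, case_labels, n_perm=n_perm, seed=config.seed)
        disp_F, disp_p = eco.permdisp(D, case_labels, n_perm=n_perm,
                                      seed=config.seed)
        pw = eco.pairwise_permanova(D, case_labels, n_perm=n_perm,
                                    seed=config.seed)
        _write_tsv(pw, outdir / "pairwise_permanova.tsv", index=False)
        record("pairwise_permanova", outdir / "pairwise_permanova.tsv")
        results["ecology"] = {
            "alpha": alpha, "permanova": perm,
            "permdisp": {"F": disp_F, "p": disp_p},
            "pairwise_permanova": pw,
        }

    # ---- factors -----------------------------------------------------------
    if "factors" in config.stages and normalized is not None:
        log.info("factors: weighted-ALS multi-view factor model")
        fac_views = dict(normalized)
        if "microbiome" in dataset.views:
            clr = prep.clr_transform(
                OmicsView(dataset.views["microbiome"].matrix.loc[case_ids],
                          "microbiome"))
            mat = clr.matrix.loc[:, clr.matrix.std(ddof=1) > 0]
            fac_views["microbiome"] = (mat - mat.mean()) / mat.std(ddof=1)
        n_factors = min(config.factors.get("n_factors", 15),
                        len(case_ids) - 1)
        model = fm.MultiViewFactorModel(n_factors=n_factors, seed=config.seed)
        model.fit(fac_views)
        per_factor, totals = fm.variance_decomposition(model)
        _write_tsv(model.scores_, outdir / "factor_scores.tsv",
                   index_label="sample_id")
        _write_tsv(per_factor, outdir / "variance_decomposition.tsv",
                   index_label="view")
        record("factor_scores", outdir / "factor_scores.tsv")
        record("variance_decomposition", outdir / "variance_decomposition.tsv")
        results["factor_model"] = model
        results["variance_decomposition"] = (per_factor, totals)

    # ---- network -----------------------------------------------------------
    if "network" in config.stages and normalized is not None:
        log.info("network: balanced consensus association network")
        cn = net.consensus_network(
            {k: v for k, v in normalized.items()},
            n_iter=config.network.get("n_iter", 1000),
            n_per_view=config.network.get("n_per_view", 241),
            fdr=config.network.get("fdr", 0.001),
            consensus=config.network.get("consensus", 0.90),
            seed=config.seed,
        )
        _write_tsv(cn, outdir / "consensus_network.tsv", index=False)
        record("consensus_network", outdir / "consensus_network.tsv")
        if not cn.empty:
            partition = net.detect_communities(
                cn, min_size=config.network.get("min_size", 30),
                seed=config.seed)
            _write_tsv(partition.summaries, outdir / "communities.tsv",
                       index=False)
            record("communities", outdir / "communities.tsv")
            results["communities"] = partition
        results["consensus_network"] = cn

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    return results
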