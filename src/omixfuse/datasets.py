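"""In-memory containers for aligned multi-omics cohorts.

A cohort is a set of feature tables (views) over one shared, ordered sample
set plus a clinical/demographic metadata table.  Views are pandas DataFrames
with samples in rows (index = sample id) and features in columns, which keeps
all downstream code a thin layer over vectorised numpy/pandas operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

VIEW_NAMES = ("metabolome", "lipidome", "microbiome")


class AlignmentError(ValueError):
    """Raised when views or metadata do not share the same sample order."""


@dataclass
class OmicsView:
    """One feature table (samples x features) with per-feature annotations.

    ``feature_annotations`` maps feature id to a domain label: a metabolic
    pathway for metabolites, a lipid class for lipid species, or a taxonomy
    string for ASVs.  ``transform_log`` records the transformations applied
    so pipeline order can be audited.
    """

    matrix: pd.DataFrame
    view_name: str
    feature_annotations: dict[str, str] = field(default_factory=dict)
    transform_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.matrix.index.duplicated().any():
            raise ValueError(f"{self.view_name}: duplicated sample ids")
        if self.matrix.columns.duplicated().any():
            raise ValueError(f"{self.view_name}: duplicated feature ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def with_matrix(self, matrix: pd.DataFrame, step: str) -> "OmicsView":
        """Return a copy holding ``matrix`` with ``step`` appended to the log."""
        return OmicsView(
            matrix=matrix,
            view_name=self.view_name,
            feature_annotations=dict(self.feature_annotations),
            transform_log=self.transform_log + [step],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path, view_name: str) -> "OmicsView":
        mat = pd.read_csv(path, sep="\t", index_col=0)
        return cls(matrix=mat, view_name=view_name)


@dataclass
class MultiOmicsDataset:
    """Aligned multi-view cohort: named views plus clinical metadata."""

    views: dict[str, OmicsView]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        ids = None
        for name, view in self.views.items():
            if ids is None:
                ids = view.sample_ids
            elif view.sample_ids != ids:
                raise AlignmentError(f"view {name!r} sample order differs")
        if ids is not None and list(self.metadata.index) != ids:
            raise AlignmentError("metadata sample order differs from views")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.metadata.index)

    @property
    def n_samples(self) -> int:
        return len(self.metadata)

    def view_names(self) -> list[str]:
        return list(self.views)

    def write(self, outdir: str | Path) -> None:
        """Write all views and metadata as TSV under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, view in self.views.items():
            view.to_tsv(outdir / f"{name}.tsv")
        self.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index_label="sample_id")
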