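"""Per-view transformations feeding network fusion, factors, and networks.

All transformers are scikit-learn style (``fit``/``transform`` over a
samples x features DataFrame) so views can be prepared with ordinary
pipelines; each also accepts/returns :class:`~omixfuse.datasets.OmicsView`
through the module-level convenience functions, which append to the view's
transform log.

Conventions: intensity views (metabolome, lipidome) are log2 transformed,
variance-filtered, then standard normalized before fusion; lipid-class
aggregation happens on the original concentration scale, before the log.
The microbiome enters fusion as standard-normalized relative abundances,
while the centered log-ratio (CLR) transform is reserved for the factor
model, where approximately Gaussian inputs matter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datasets import OmicsView

__all__ = [
    "Log2Transformer",
    "VarianceFilter",
    "StandardNormalizer",
    "CLRTransformer",
    "log2_transform",
    "variance_filter",
    "standard_normalize",
    "clr_transform",
    "relative_abundance",
    "aggregate_lipid_classes",
    "EmptyViewError",
]


class EmptyViewError(ValueError):
    """All features of a view were removed by a filter."""


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


class Log2Transformer(BaseEstimator, TransformerMixin):
    """Elementwise ``log2(x + pseudocount)``."""

    def __init__(self, pseudocount: float = 0.0):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        X = _as_frame(X)
        bad = (X + self.pseudocount <= 0).any(axis=0)
        if bad.any():
            raise ValueError(
                "non-positive values after pseudocount in features: "
                + ", ".join(map(str, X.columns[bad][:10]))
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self)
        X = _as_frame(X)
        return np.log2(X + self.pseudocount)

    def inverse_transform(self, Y) -> pd.DataFrame:
        return np.exp2(_as_frame(Y)) - self.pseudocount


class VarianceFilter(BaseEstimator, TransformerMixin):
    """Drop features whose sample variance (n-1 denominator) is below a cutoff.

    The cutoff applies on whatever scale the data is on at call time; the
    default pipeline applies 0.3 to log2 intensities before fusion and 0.2 to
    relative abundances before the factor model.
    """

    def __init__(self, min_variance: float = 0.3):
        self.min_variance = min_variance

    def fit(self, X, y=None):
        if self.min_variance < 0:
            raise ValueError("min_variance must be >= 0")
        X = _as_frame(X)
        var = X.var(axis=0, ddof=1)
        self.variances_ = var
        self.keep_ = var >= self.min_variance
        if not self.keep_.any():
            raise EmptyViewError("variance filter removed every feature")
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self)
        X = _as_frame(X)
        return X.loc[:, self.keep_[self.keep_].index]


class StandardNormalizer(BaseEstimator, TransformerMixin):
    """Per-feature z-scoring to mean 0, sample SD 1 (n-1 denominator)."""

    def fit(self, X, y=None):
        X = _as_frame(X)
        sd = X.std(axis=0, ddof=1)
        if (sd <= 0).any():
            bad = list(X.columns[(sd <= 0).to_numpy()][:10])
            raise ValueError(
                f"zero-variance features {bad}; run a variance filter first"
            )
        self.mean_ = X.mean(axis=0)
        self.scale_ = sd
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self)
        return (_as_frame(X) - self.mean_) / self.scale_


class CLRTransformer(BaseEstimator, TransformerMixin):
    """Centered log-ratio transform of a count (or composition) table.

    Per sample i: ``y_if = ln(x_if + pc) - mean_f ln(x_if + pc)``, so every
    output row sums to zero.  With ``pseudocount=0`` the transform is
    invariant to per-sample rescaling (compositional invariance).
    """

    def __init__(self, pseudocount: float = 1.0):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        X = _as_frame(X)
        if (X < 0).any().any():
            raise ValueError("counts must be non-negative")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self)
        X = _as_frame(X)
        logged = np.log(X + self.pseudocount)
        return logged.sub(logged.mean(axis=1), axis=0)


def _apply(view: OmicsView, transformer, step: str) -> OmicsView:
    mat = transformer.fit_transform(view.matrix)
    return view.with_matrix(mat, step)


def log2_transform(view: OmicsView, pseudocount: float = 0.0) -> OmicsView:
    return _apply(view, Log2Transformer(pseudocount), f"log2(+{pseudocount})")


def variance_filter(view: OmicsView, min_variance: float = 0.3) -> OmicsView:
    return _apply(view, VarianceFilter(min_variance), f"variance_filter({min_variance})")


def standard_normalize(view: OmicsView) -> OmicsView:
    return _apply(view, StandardNormalizer(), "standard_normalize")


def clr_transform(view: OmicsView, pseudocount: float = 1.0) -> OmicsView:
    return _apply(view, CLRTransformer(pseudocount), f"clr(+{pseudocount})")


def relative_abundance(view: OmicsView) -> OmicsView:
    """Total-sum scaling: each sample's counts divided by its library size."""
    totals = view.matrix.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("samples with zero total count")
    return view.with_matrix(view.matrix.div(totals, axis=0), "relative_abundance")


def aggregate_lipid_classes(view: OmicsView, class_map: dict[str, str]) -> OmicsView:
    """Sum species concentrations into lipid classes (original scale).

    ``[Class_j] = sum_i [species_i]`` over the member species of class j.
    Must be applied before any log transform.
    """
    if any(step.startswith("log2") for step in view.transform_log):
        raise ValueError("lipid-class aggregation requires the concentration scale")
    missing = [c for c in view.matrix.columns if c not in class_map]
    if missing:
        raise KeyError(f"species absent from class map: {missing[:10]}")
    grouped = view.matrix.T.groupby(
        view.matrix.columns.map(class_map)
    ).sum().T
    out = view.with_matrix(grouped, "aggregate_lipid_classes")
    out.feature_annotations = {c: c for c in grouped.columns}
    return out


def prepare_for_fusion(
    views: dict[str, OmicsView],
    min_variance: float = 0.3,
) -> dict[str, pd.DataFrame]:
    """Standard pre-fusion pipeline for the three canonical views.

    Intensity views: log2 -> variance filter -> z-score.  Microbiome:
    relative abundance -> variance filter at 0 (drop constants) -> z-score.
    """
    out: dict[str, pd.DataFrame] = {}
    for name, view in views.items():
        if name == "microbiome":
            v = relative_abundance(view)
            v = _apply(v, VarianceFilter(0.0 + np.finfo(float).tiny), "drop_constant")
        else:
            v = log2_transform(view)
            v = variance_filter(v, min_variance)
        v = standard_normalize(v)
        out[name] = v.matrix
    return out
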