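import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared across read-only tests."""
    from omixfuse.synthetic import SyntheticConfig, generate_cohort

    config = SyntheticConfig(
        n_cases=45, n_controls=12, cluster_sizes=(15, 15, 15),
        n_metabolites=80, n_lipids=80, n_asvs=60, seed=7,
    )
    dataset, truth = generate_cohort(config)
    return config, dataset, truth


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size default cohort (97 cases + 20 controls)."""
    from omixfuse.synthetic import SyntheticConfig, generate_cohort

    config = SyntheticConfig(seed=11)
    dataset, truth = generate_cohort(config)
    return config, dataset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def case_views(dataset):
    """Helper: restrict every view to case samples."""
    from omixfuse.datasets import OmicsView

    cases = dataset.metadata.index[dataset.metadata["group"] == "case"]
    return {
        name: OmicsView(v.matrix.loc[cases], name, v.feature_annotations)
        for name, v in dataset.views.items()
    }, cases


@pytest.fixture(scope="session")
def fused_small(small_cohort):
    """SNF fit on the small cohort's cases."""
    from omixfuse.preprocess import prepare_for_fusion
    from omixfuse.snf import SNFClustering

    config, dataset, truth = small_cohort
    views, cases = case_views(dataset)
    normalized = prepare_for_fusion(views)
    model = SNFClustering(K=10, seed=0).fit(normalized)
    return model, truth.labels.loc[cases].to_numpy()
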