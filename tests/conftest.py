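import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import gsamultiverse as gm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_study() -> gm.SyntheticStudy:
    """A small correlated-null study data set shared by pipeline tests."""
    spec = gm.SimulationSpec(
        n_genes=400,
        samples_per_group=(8, 8),
        within_block_correlation=0.4,
        correlation_block_size=40,
        seed=1234,
    )
    return gm.make_study_data(
        spec, n_sets=10, set_size_range=(15, 40), n_databases=2, duplicate_fraction=0.1
    )


@pytest.fixture(scope="session")
def toy_counts() -> pd.DataFrame:
    rng = np.random.default_rng(7)
    counts = rng.poisson(50.0, size=(30, 8))
    return pd.DataFrame(
        counts,
        index=[f"g{i:02d}" for i in range(30)],
        columns=[f"s{j}" for j in range(8)],
    )


@pytest.fixture(scope="session")
def toy_labels(toy_counts) -> gm.LabelAssignment:
    return gm.LabelAssignment(
        sample_ids=tuple(toy_counts.columns),
        labels=("a",) * 4 + ("b",) * 4,
        reference="a",
    )


def make_gsa_result(adj_pvals, threshold=0.05, threshold_on="adj_p") -> gm.GSAResult:
    """Construct a GSAResult fixture directly from adjusted p-values."""
    adj = np.asarray(adj_pvals, dtype=float)
    table = pd.DataFrame(
        {
            "size": 10,
            "statistic": np.nan,
            "nes": np.nan,
            "pval": adj,
            "adj_pval": adj,
            "significant": adj < threshold,
        },
        index=pd.Index([f"set{i:04d}" for i in range(1, len(adj) + 1)], name="set"),
    )
    return gm.GSAResult(
        table=table, method="fixture", threshold=threshold, threshold_on=threshold_on
    )
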