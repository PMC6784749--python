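import numpy as np
import pytest

from crtplan import ClusterCountTable, SyntheticConfig, generate_cluster_table


@pytest.fixture
def hand_table():
    """Three equal-exposure clusters whose variance decomposition is hand-checkable.

    rates are 0, 0.002, 0.004; pooled rate 0.002; observed variance 4e-6;
    expected Poisson variance (0.002/3)*(3/5000) = 4e-7; between 3.6e-6.
    """
    return ClusterCountTable(["a", "b", "c"], [0, 10, 20], [5000.0, 5000.0, 5000.0])


@pytest.fixture
def flat_table():
    """Four clusters with identical observed rates: no between-cluster spread."""
    return ClusterCountTable(list("abcd"), [10] * 4, [10000.0] * 4)


@pytest.fixture
def synthetic_table():
    """A modest gamma-Poisson table for bootstrap and round-trip tests."""
    cfg = SyntheticConfig(
        n_clusters=20, true_mean_rate=0.001, true_cv=0.5, exposure_days=20000.0, seed=42
    )
    return generate_cluster_table(cfg)
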