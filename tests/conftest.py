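import numpy as np
import pandas as pd
import pytest

from allercast.network import DiseaseNetwork, build_knn_graph
from allercast.synthetic import SyntheticConfig, default_profiles, generate_dataset


@pytest.fixture(scope="session")
def small_regions():
    rng = np.random.default_rng(42)
    return pd.DataFrame(
        {
            "region_id": [f"R{i}" for i in range(8)],
            "lon": rng.uniform(127.0, 128.5, 8),
            "lat": rng.uniform(35.0, 37.0, 8),
        }
    )


@pytest.fixture(scope="session")
def small_network(small_regions):
    return build_knn_graph(small_regions, k=2)


@pytest.fixture(scope="session")
def single_region_network():
    return DiseaseNetwork(region_ids=["R0"], adjacency=np.zeros((1, 1)), k=0)


@pytest.fixture(scope="session")
def small_dataset():
    config = SyntheticConfig(n_regions=8, n_days=200, seed=5, knn_k=2)
    return generate_dataset(config, default_profiles())


@pytest.fixture(scope="session")
def small_panel(small_dataset):
    return small_dataset[0]
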