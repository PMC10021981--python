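import numpy as np
import pytest

from sors import SORSModel
from sors.synthgen import SyntheticConfig, synthesize_dataset, table1_planar_points


@pytest.fixture(scope="session")
def synthetic_paths(tmp_path_factory):
    """One shared synthetic dataset (clustered POIs + star boundary) on disk."""
    out = tmp_path_factory.mktemp("synth")
    poi_path, boundary_path, truth = synthesize_dataset(SyntheticConfig(seed=3), out)
    return poi_path, boundary_path, truth


@pytest.fixture(scope="session")
def fitted_model(synthetic_paths):
    poi_path, boundary_path, _ = synthetic_paths
    model = SORSModel.from_geojson(poi_path, boundary_path)
    return model, model.fit()


@pytest.fixture
def table1_points():
    return table1_planar_points()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
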