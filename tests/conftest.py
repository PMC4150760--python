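import numpy as np
import pytest

from isoformnet.fixtures import generate_fixtures


@pytest.fixture(scope="session")
def fixture_manifest(tmp_path_factory):
    """Synthetic annotation + expression files for both conditions (seed 0)."""
    outdir = tmp_path_factory.mktemp("fixtures")
    return generate_fixtures(str(outdir), seed=0, n_samples=100, edge_c0=0.6)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
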