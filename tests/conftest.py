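import numpy as np
import pytest

from nucleisplit import SyntheticSpec, clustered_fixture, generate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 2D synthetic scene shared by read-only tests."""
    img, truth, centroids = generate(SyntheticSpec(seed=7))
    return {"image": img, "truth": truth, "centroids": centroids}


@pytest.fixture(scope="session")
def valley_clump():
    return clustered_fixture("intensity_valley_clump")


@pytest.fixture(scope="session")
def dim_pair():
    return clustered_fixture("dim_nucleus_pair")
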