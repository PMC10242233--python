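import numpy as np
import pytest

from choroidkit.synthetic import (AngioPhantomSpec, BScanPhantomSpec,
                                  CohortGenParams, generate_bscan_phantom,
                                  generate_cc_phantom, generate_cohort)


@pytest.fixture(scope="session")
def cohort50():
    table, truth = generate_cohort(CohortGenParams(n=50, seed=7))
    return table, truth


@pytest.fixture(scope="session")
def cohort5000():
    table, truth = generate_cohort(CohortGenParams(n=5000, seed=11))
    return table, truth


@pytest.fixture(scope="session")
def bscan_phantom():
    spec = BScanPhantomSpec(seed=3)
    img, truth = generate_bscan_phantom(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def cc_phantom():
    spec = AngioPhantomSpec(seed=5, deficit_fraction_target=0.15)
    img, truth = generate_cc_phantom(spec)
    return spec, img, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
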