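import numpy as np
import pytest

from mitoloc import (
    CompetenceModel,
    GeneKinetics,
    geometry_from_mvf,
)


@pytest.fixture(scope="session")
def geom_4pct():
    """Default geometry at 4% mitochondrial volume fraction."""
    return geometry_from_mvf(0.04)


@pytest.fixture(scope="session")
def conditional_median():
    """Typical conditional gene (short, fast-elongating)."""
    return GeneKinetics("conditional_median", k_init=0.3253, k_elong=14.5086, L=393)


@pytest.fixture(scope="session")
def constitutive_median():
    """Typical constitutive gene (long, slow-elongating)."""
    return GeneKinetics("constitutive_median", k_init=0.1259, k_elong=7.7468, L=483)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def instantaneous():
    return CompetenceModel.instantaneous()


def mean_and_se(values):
    values = np.asarray(values, dtype=float)
    return values.mean(), values.std(ddof=1) / np.sqrt(values.size)
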