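import numpy as np
import pytest
from hypothesis import settings

from famprs import BinaryParams, ContinuousParams
from famprs.simulate import simulate_binary_trios, simulate_continuous_trios

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

# height-like study conditions: PRS explains 36.7% of trait variance and the
# mid-parental value 44.9%, implying 58.1% under-captured heritability
HEIGHT_ALPHA_SQ = 0.367
HEIGHT_BETA_SQ = 0.581


@pytest.fixture(scope="session")
def height_params() -> ContinuousParams:
    return ContinuousParams.from_variance_fractions(HEIGHT_ALPHA_SQ, HEIGHT_BETA_SQ)


@pytest.fixture(scope="session")
def disease_params() -> BinaryParams:
    return BinaryParams(mu0=-2.0, alpha=0.3, beta=0.7)


@pytest.fixture(scope="session")
def height_trios(height_params):
    """200k continuous trios at the height-like parameters."""
    return simulate_continuous_trios(height_params, 200_000, seed=0).table


@pytest.fixture(scope="session")
def disease_trios(disease_params):
    """200k disease trios at (mu0=-2, alpha=0.3, beta=0.7)."""
    return simulate_binary_trios(disease_params, 200_000, seed=0).table
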