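import numpy as np
import pytest

from mirtraj.montecarlo import null_radius_distribution

# One shared 10,000-walk ensemble per direction count, as in the published
# analysis; session-scoped because each takes ~10 s to build.
NULL_SEED_7 = 20110815
NULL_SEED_6 = 20110816


@pytest.fixture(scope="session")
def null7():
    """Radius null for 7 center-projected directions (sham-sized series)."""
    return null_radius_distribution(7, d=3, n_reps=10000, seed=NULL_SEED_7)


@pytest.fixture(scope="session")
def null6():
    """Radius null for 6 center-projected directions (injury-sized series)."""
    return null_radius_distribution(6, d=3, n_reps=10000, seed=NULL_SEED_6)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
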