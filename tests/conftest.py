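import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from siidanet.io import Roster
from siidanet.synthetic import CommunityConfig, generate_community

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_roster() -> Roster:
    """Six-person, two-siida roster used by the hand-computed examples."""
    return Roster(
        pd.DataFrame(
            {
                "id": ["a", "b", "c", "d", "e", "f"],
                "siida": ["s1", "s1", "s1", "s2", "s2", "s2"],
                "interviewed": [1, 1, 1, 1, 0, 0],
                "licence": [1, 1, 1, 1, 1, 1],
            }
        )
    )


@pytest.fixture(scope="session")
def community():
    """One default synthetic community, generated once per session."""
    return generate_community(CommunityConfig(random_seed=20260101))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
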