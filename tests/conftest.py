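import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from poolscreen import LibrarySpec, ScreenParams, make_library

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def uniform_library() -> LibrarySpec:
    """Small library with a perfectly even plasmid pool."""
    n = 200
    return LibrarySpec(
        shrna_ids=[f"sh{i}" for i in range(n)],
        plasmid_props=np.full(n, 1.0 / n),
    )


@pytest.fixture
def skewed_library() -> LibrarySpec:
    """Realistically skewed 500-member library."""
    return make_library(pool_size=500, skew_sigma=0.35, seed=11)


@pytest.fixture
def seq_library() -> LibrarySpec:
    """Small library carrying hairpin sequences for read simulation."""
    return make_library(pool_size=50, with_sequences=True, seq_len=60, seed=7)


@pytest.fixture
def default_params() -> ScreenParams:
    return ScreenParams(seed=42, reads_per_sample=200_000)
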