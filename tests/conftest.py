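import numpy as np
import pytest

from aavdoe import (
    MixtureBounds,
    fccd_design,
    make_archetype,
    simplex_candidates,
)


@pytest.fixture(scope="session")
def default_bounds():
    return MixtureBounds()


@pytest.fixture(scope="session")
def candidates(default_bounds):
    """Standard 0.05-lattice candidate set over the 10-60% simplex."""
    return simplex_candidates(default_bounds, 0.05)


@pytest.fixture(scope="session")
def coarse_candidates(default_bounds):
    """0.1-lattice candidate set (27 points) — small enough for oracles."""
    return simplex_candidates(default_bounds, 0.1)


@pytest.fixture(scope="session")
def fccd9():
    return fccd_design(n_center=1)


@pytest.fixture(scope="session")
def archetypes():
    return {name: make_archetype(name) for name in ("egfp_like", "msh2_like", "bdnf_like")}


@pytest.fixture
def rng():
    return np.random.default_rng(42)
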