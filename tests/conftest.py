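import numpy as np
import pytest

from conplan import FeatureStack, SynthConfig, gen_region, gen_species_stack


def make_stack(values, weights=None, groups=None, names=None, valid=None):
    """Build a small FeatureStack from an (m, nr, nc) array."""
    values = np.asarray(values, dtype=float)
    m = values.shape[0]
    if valid is None:
        valid = np.ones(values.shape[1:], dtype=bool)
    return FeatureStack(
        values,
        names or [f"f{i}" for i in range(m)],
        groups or ["feature"] * m,
        np.ones(m) if weights is None else np.asarray(weights, float),
        np.asarray(valid, bool),
    )


def random_stack(seed, n_cells_max=100, m_max=10):
    """A seeded random dense instance for oracle comparisons."""
    rng = np.random.default_rng(seed)
    nr = rng.integers(2, 11)
    nc = rng.integers(2, min(11, max(3, n_cells_max // nr + 1)))
    m = rng.integers(1, m_max + 1)
    vals = rng.uniform(size=(m, nr, nc))
    w = rng.uniform(0.2, 1.0, size=m)
    return make_stack(vals, weights=w)


@pytest.fixture
def small_region():
    return gen_region(15, 15, 7, 1.0)


@pytest.fixture
def small_species_stack(small_region):
    return gen_species_stack(small_region, SynthConfig(seed=7, n_species=5))
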