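import numpy as np
import pytest

from ecoassembly import AssemblyParams, PoolParams, SpeciesPool, generate_pool


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_pool():
    """A deterministic hand-built web: basal <- A <- B <- C plus a
    branch D eating A and C, one modifier made by A and needed by D."""
    return build_pool(
        n_species=4,
        n_modifiers=1,
        eat={(1, 0), (2, 1), (3, 2), (4, 1), (4, 3)},
        need={(4, 5)},
        make={(1, 5)},
    )


def build_pool(n_species, n_modifiers, eat=(), need=(), make=()):
    n = 1 + n_species + n_modifiers
    mats = {}
    for name, links in (("eat", eat), ("need", need), ("make", make)):
        m = np.zeros((n, n), dtype=bool)
        for s, t in links:
            m[s, t] = True
        mats[name] = m
    return SpeciesPool(n_species, n_modifiers, mats["eat"], mats["need"], mats["make"])


@pytest.fixture
def default_pool_params():
    return PoolParams(n_species=200, p_e=0.01, eta=0.0)


@pytest.fixture
def default_assembly_params():
    return AssemblyParams()
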