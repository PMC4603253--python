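import numpy as np
import pytest

from cpgnet.experiments import run_experiment
from cpgnet.network import NetworkSpec, PopulationSpec, ProjectionSpec, instantiate


@pytest.fixture(scope="session")
def preset_cache():
    """Session-wide cache so criteria sharing a run compute it once."""
    cache = {}

    def get(name, seed=1, **kw):
        key = (name, seed, tuple(sorted(kw.items())))
        if key not in cache:
            cache[key] = run_experiment(name, seed=seed, **kw)
        return cache[key]

    return get


@pytest.fixture()
def tiny_pair_spec():
    """Two 3-neuron populations with an all-to-all projection."""
    pops = (
        PopulationSpec("l-RG-F", "l", "RG-F", 3, -70.0, 0.0, True, 1.0, True),
        PopulationSpec("l-RG-E", "l", "RG-E", 3, -63.0, 0.0, True, 0.1, True),
    )
    projs = (
        ProjectionSpec("l-RG-F", "l-RG-E", "excitatory", 1.0, 0.1),
    )
    return NetworkSpec(pops, projs)


@pytest.fixture()
def single_pop_connectome():
    pop = PopulationSpec("l-RG-F", "l", "RG-F", 12, -70.0, 1.0, True, 1.0, True)
    proj = ProjectionSpec("l-RG-F", "l-RG-F", "excitatory", 0.4, 0.12, 0.2)
    return instantiate(NetworkSpec((pop,), (proj,)), seed=7)
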