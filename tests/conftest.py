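import numpy as np
import pytest

from aedespop import simdata
from aedespop.simdata import SimConfig


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Three diverged populations, one F1 hybrid, two mito lineages
    crossing the nuclear clusters -- small enough for fast tests."""
    return SimConfig(
        n_populations=3,
        target_F=0.15,
        samples_per_population=[10, 10, 10],
        n_sites=4000,
        missing_rate=0.05,
        n_hybrids=[("pop1", "pop2", 1)],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simdata.simulate(small_config)


@pytest.fixture(scope="session")
def bundle_paths(small_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    return simdata.write_dataset(small_bundle, out)


@pytest.fixture(scope="session")
def populations(small_bundle):
    pops: dict[str, list[str]] = {}
    for s, p in small_bundle.truth.population_of.items():
        pops.setdefault(p, []).append(s)
    return pops
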