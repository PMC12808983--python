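import numpy as np
import pytest

import ploidykit as pk
from ploidykit.calls import build_trio_genotypes
from ploidykit.simulate import ErrorModel


@pytest.fixture(scope="session")
def toy_spec():
    return pk.toy_genome()


@pytest.fixture(scope="session")
def grch37_spec():
    return pk.default_genome()


@pytest.fixture(scope="session")
def noiseless():
    """Error-free observation model (deep, no call or read errors)."""
    return ErrorModel(call_error_rate=0.0, depth_mean=1000.0, read_error=0.0)


@pytest.fixture(scope="session")
def platform_noise():
    """Default platform noise: 0.42 % call errors, 360x depth."""
    return ErrorModel()


@pytest.fixture(scope="session")
def toy_parents(toy_spec):
    """One seeded parent pair over an 800-SNP toy panel."""
    return pk.simulate_parents(toy_spec, 800, seed=101)


def make_trio(spec, scenario, error_model, seed, n_sites=800, parents=None):
    """Simulate and genotype one trio (shared helper)."""
    if parents is None:
        mother, father, _ = pk.simulate_parents(spec, n_sites, seed=seed)
    else:
        mother, father, _ = parents
    sim = pk.simulate_embryo_trio(mother, father, spec, scenario, error_model, seed=seed + 7)
    return build_trio_genotypes(sim, spec)
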