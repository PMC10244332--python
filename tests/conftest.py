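import numpy as np
import pytest

from bh3sim.canonical import canonical_model
from bh3sim.population import TreatmentSpec, run_treatment, sample_population
from bh3sim.synthetic import fixture_line


@pytest.fixture(scope="session")
def canonical():
    return canonical_model()


@pytest.fixture(scope="session")
def bclxl_fixture():
    """BCL-xL-dependent ground-truth line at its shipped seed."""
    return fixture_line("BCLxL_dependent")


@pytest.fixture(scope="session")
def bcl2_fixture():
    """BCL2-dependent ground-truth line at its shipped seed."""
    return fixture_line("BCL2_dependent")


@pytest.fixture(scope="session")
def fixture_treatments(bclxl_fixture, bcl2_fixture):
    """Full-inhibition treatments of both fixtures (shared across tests).

    Maps (fixture archetype, target) -> TreatmentResult for f = 1 of each
    single target on a 50-cell shared population.
    """
    out = {}
    for gt in (bclxl_fixture, bcl2_fixture):
        pop = sample_population(gt.line, n_cells=50, seed=5)
        for target in ("BCL2", "BCLXL", "MCL1"):
            res = run_treatment(pop, TreatmentSpec(targets=[(target, 1.0)]))
            out[(gt.archetype, target)] = res
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
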