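import numpy as np
import pytest

from diploscan import simulate as sim


@pytest.fixture(scope="session")
def genome200():
    """Shared 200 kb TME7-like diploid with genes and SVs."""
    cfg = sim.tme7_preset(200_000, seed=11, n_genes=13)
    return sim.generate_diploid(cfg)


@pytest.fixture(scope="session")
def reads200(genome200):
    return sim.simulate_reads(genome200)


@pytest.fixture(scope="session")
def frag200(genome200):
    return sim.fragment_into_contigs(genome200, 25_000, 0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
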