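import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from circfind import AnalysisConfig, Genome, GenomeRecord, build_index

settings.register_profile(
    "fixed",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")

_LETTERS = np.array(list("ACGT"))


def random_sequence(rng, n):
    return "".join(_LETTERS[rng.integers(0, 4, size=n)])


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def planted():
    """A 5 kb random genome with a designated circular locus at [1041, 1100].

    The fixed seed gives a genome whose 20-mers around the locus are unique,
    so junction reads built by rotating the locus have exactly one
    interpretation.
    """
    rng = np.random.default_rng(4242)
    seq = random_sequence(rng, 5000)
    genome = Genome((GenomeRecord("chr1", seq),))
    locus = (1041, 1100)
    index = build_index(genome, seed_len=20)
    return genome, index, locus
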