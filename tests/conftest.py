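import numpy as np
import pytest
from hypothesis import settings

from crossmir import synthetic_data as syn

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def genome_set():
    """Five small source libraries, one per category, k-mer disjoint."""
    specs = [
        syn.LibrarySpec("aphid", "host_insect", 4000, 0.35),
        syn.LibrarySpec("buchnera", "obligate_symbiont", 3000, 0.30),
        syn.LibrarySpec("plant", "host_plant", 4000, 0.40),
        syn.LibrarySpec("bacteria", "bacterial", 3000, 0.45),
        syn.LibrarySpec("virus", "viral", 1000, 0.45),
    ]
    return syn.generate_genome_set(specs, seed=3)


@pytest.fixture
def hairpin():
    """A clean hairpin: 21-nt arms, 20-nt loop, 18-nt flanks, perfect duplex."""
    return syn.generate_precursor(21, 20, (18, 18), n_mismatches=0, seed=2)
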