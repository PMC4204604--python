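import pytest
from hypothesis import HealthCheck, settings

import methylbias as mb

settings.register_profile(
    "default", deadline=None, max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def gradient_genome():
    """100 kb-scale won't fit every test; 4 kb main contig, 600 bp control."""
    return mb.generate_genome(4, 1000, (0.3, 0.5), 600, seed=7)


@pytest.fixture(scope="session")
def gradient_truth(gradient_genome):
    triples = [(0.9, 0.6, 0.2), (0.6, 0.4, 0.1), (0.3, 0.2, 0.05), (0.0, 0.0, 0.0)]
    return mb.generate_methylome(gradient_genome, triples)


@pytest.fixture(scope="session")
def placed_library(gradient_genome, gradient_truth):
    """A small fully-simulated, placed and piled-up library."""
    pool = mb.simulate_fragments(gradient_genome, 1500, 100, seed=3)
    conv = mb.bisulfite_convert_pool(pool, gradient_truth, 0.005, seed=5)
    lib = mb.amplify_and_sample(conv, mb.ENZYME_PRESETS["kapa-like"], 8,
                                4000, seed=9)
    index = mb.build_converted_index(gradient_genome)
    placements, tally = mb.place_library(lib, index)
    counts = mb.pileup_cytosines(placements, gradient_genome)
    return {"library": lib, "placements": placements, "counts": counts,
            "tally": tally}
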