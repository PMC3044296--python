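import random

import pytest

from pathgroups import Genome
from pathgroups.simulate import apply_rearrangements, random_genome


@pytest.fixture
def make_random_genome():
    def factory(n, chromosomes=1, seed=0, name="R"):
        return random_genome(n, chromosomes, random.Random(seed), name=name)

    return factory


@pytest.fixture
def make_median_instance():
    """Three genomes derived from a common source by random operations."""

    def factory(n=30, chromosomes=2, ops=5, seed=0):
        rng = random.Random(seed)
        source = random_genome(n, chromosomes, rng, name="source")
        leaves = []
        for i in range(3):
            g, _ = apply_rearrangements(source, ops, 0.9, rng)
            leaves.append(g.renamed(f"G{i + 1}"))
        return source, leaves

    return factory


@pytest.fixture
def identity_genome():
    def factory(n, name="I"):
        return Genome(name, [list(range(1, n + 1))], n)

    return factory
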