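import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gmatesim.genome import build_genome_map
from gmatesim.population import FEMALE, MALE, Population

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_map():
    """Two 50 cM chromosomes, 40 markers + 5 QTL each."""
    return build_genome_map(2, 50.0, 40, 5, seed=7)


@pytest.fixture(scope="session")
def tiny_map():
    """One 20 cM chromosome, 12 markers + 3 QTL."""
    return build_genome_map(1, 20.0, 12, 3, seed=3)


def random_population(
    gmap,
    n: int,
    rng: np.random.Generator,
    freq: np.ndarray | None = None,
    generation: int = 0,
) -> Population:
    """Unrelated individuals with haplotypes drawn at given allele frequencies."""
    if freq is None:
        freq = rng.uniform(0.1, 0.9, size=gmap.n_loci)
    haps = (rng.random((n, 2, gmap.n_loci)) < freq).astype(np.int8)
    sex = np.tile(np.array([MALE, FEMALE], dtype=np.int8), (n + 1) // 2)[:n]
    return Population(
        haplotypes=haps,
        sex=sex,
        ids=np.arange(n, dtype=np.int64),
        generation=generation,
    )
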