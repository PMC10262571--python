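"""Historical population simulation and modern founder sampling.

The historical phase stands in for the demographic history of a pig
population: haplotypes start with every locus at allele frequency 0.5 and
are then driven towards mutation-drift equilibrium by many discrete
generations of random mating with recurrent bidirectional allele-flip
mutation (default rate 2.5e-5 per locus per gamete, applied to markers and
QTL alike).  A bottleneck between the two phases (default 2,000 -> 400)
generates realistic linkage disequilibrium.  The modern founders -- by
default 30 boars and 900 sows -- are drawn uniformly from the final
historical generation and become pedigree roots with F_PED = 0.
"""

from __future__ import annotations

import numpy as np

from .genome import GenomeMap
from .meiosis import RecombinationModel, mate_cohort
from .population import FEMALE, MALE, Population
from .rng import as_rng

__all__ = ["simulate_historical", "sample_modern_founders"]


def _balanced_sexes(n: int) -> np.ndarray:
    """Exact 1:1 sex ratio; raises if n is odd."""
    if n % 2:
        raise ValueError(f"population size {n} cannot satisfy a 1:1 sex ratio")
    return np.tile(np.array([MALE, FEMALE], dtype=np.int8), n // 2)


def simulate_historical(
    gmap: GenomeMap,
    n_phase1: int = 2000,
    gens_phase1: int = 1000,
    n_phase2: int = 400,
    gens_phase2: int = 1000,
    mutation_rate: float = 2.5e-5,
    seed: int | np.random.Generator = 0,
) -> Population:
    """Evolve founder haplotypes to mutation-drift equilibrium.

    Mating is random with replacement at a 1:1 sex ratio and constant
    population size within each phase; each offspring draws an independent
    sire and dam, so the nominal one-sire-per-dam structure holds in
    expectation.  Returns the final generation only.
    """
    if n_phase1 <= 0 or n_phase2 <= 0:
        raise ValueError("population sizes must be positive")
    if gens_phase1 < 0 or gens_phase2 < 0:
        raise ValueError("generation counts must be non-negative")
    if not 0 <= mutation_rate < 1:
        raise ValueError("mutation rate must lie in [0, 1)")
    rng = as_rng(seed)
    model = RecombinationModel.from_genome_map(gmap)

    sex = _balanced_sexes(n_phase1)
    haps = rng.integers(0, 2, size=(n_phase1, 2, gmap.n_loci), dtype=np.int8)

    for n_target, gens in ((n_phase1, gens_phase1), (n_phase2, gens_phase2)):
        for _ in range(gens):
            next_sex = _balanced_sexes(n_target)
            males = np.flatnonzero(sex == MALE)
            females = np.flatnonzero(sex == FEMALE)
            sires = rng.choice(males, size=n_target)
            dams = rng.choice(females, size=n_target)
            haps, _ = mate_cohort(haps, sires, dams, 1, model, rng)
            if mutation_rate > 0:
                flips = rng.random(haps.shape) < mutation_rate
                haps ^= flips.astype(np.int8)
            sex = next_sex

    n = haps.shape[0]
    return Population(
        haplotypes=haps,
        sex=sex,
        ids=np.arange(n, dtype=np.int64),
        generation=0,
    )


def sample_modern_founders(
    pop: Population,
    n_males: int,
    n_females: int,
    seed: int | np.random.Generator = 0,
) -> Population:
    """Draw modern founders uniformly without replacement from ``pop``.

    Founders are re-identified 0..n-1 (males first) and become pedigree
    roots (unknown parents, F_PED = 0).  Loci that are monomorphic within
    the founders remain in the genome map; downstream relationship and
    marker-effect code excludes them from allele-frequency sums
    (see :func:`gmatesim.population.monomorphic_mask`).
    """
    rng = as_rng(seed)
    males = pop.males()
    females = pop.females()
    if len(males) < n_males or len(females) < n_females:
        raise ValueError(
            f"requested {n_males} males / {n_females} females but only "
            f"{len(males)} / {len(females)} are available"
        )
    pick_m = np.sort(rng.choice(males, size=n_males, replace=False))
    pick_f = np.sort(rng.choice(females, size=n_females, replace=False))
    chosen = pop.subset(np.concatenate([pick_m, pick_f]))
    n = chosen.n_individuals
    return Population(
        haplotypes=chosen.haplotypes,
        sex=chosen.sex,
        ids=np.arange(n, dtype=np.int64),
        generation=0,
    )
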