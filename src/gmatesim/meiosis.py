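"""Gamete sampling under the Haldane map function.

Offspring genotypes are built locus by locus: the first locus of each
chromosome copies a uniformly chosen parental haplotype, and every
subsequent locus switches its source haplotype independently with the
adjacent-interval recombination fraction r = (1 - exp(-2c)) / 2 from the
genetic distance c in Morgan.  Recombination events in disjoint intervals
are independent (no interference) and chromosomes segregate independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeMap
from .population import MALE
from .rng import as_rng

__all__ = [
    "recomb_fraction",
    "RecombinationModel",
    "sample_gamete",
    "sample_gametes",
    "make_offspring",
    "mate_cohort",
    "litter_sexes",
]


def recomb_fraction(c):
    """Haldane recombination fraction r = (1 - e^{-2c}) / 2 for distance c in Morgan."""
    c = np.asarray(c, dtype=np.float64)
    if np.any(c < 0):
        raise ValueError("genetic distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * c))
    return float(r) if r.ndim == 0 else r


@dataclass(frozen=True)
class RecombinationModel:
    """Per-locus source-switch probabilities for gamete sampling.

    ``switch_prob[i]`` is the probability that locus i copies the opposite
    parental haplotype from locus i-1.  Chromosome-initial loci carry 0.5:
    flipping a fair coin against the previous chromosome's source is the
    same as choosing a haplotype uniformly at random.
    """

    switch_prob: np.ndarray

    @classmethod
    def from_genome_map(cls, gmap: GenomeMap) -> "RecombinationModel":
        prob = np.empty(gmap.n_loci)
        starts = gmap.chrom_starts
        for c in range(gmap.n_chromosomes):
            s, e = starts[c], starts[c + 1]
            prob[s] = 0.5
            if e - s > 1:
                dist_morgan = np.diff(gmap.pos_cM[s:e]) / 100.0
                prob[s + 1 : e] = recomb_fraction(dist_morgan)
        return cls(switch_prob=prob)


def sample_gametes(
    parent_haplotypes: np.ndarray,
    model: RecombinationModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample one gamete per parent from ``parent_haplotypes`` of shape (k, 2, L).

    A draw mu is compared against the switch probability at each locus; the
    source haplotype changes iff mu < r (mu exactly equal to r, a
    measure-zero event, causes no switch).
    """
    haps = np.asarray(parent_haplotypes)
    if haps.ndim != 3 or haps.shape[1] != 2 or haps.shape[2] != len(model.switch_prob):
        raise ValueError("parent haplotypes do not match the recombination model")
    k, _, n_loci = haps.shape
    switches = rng.random((k, n_loci)) < model.switch_prob
    source = np.cumsum(switches, axis=1, dtype=np.int32) & 1
    return np.where(source == 0, haps[:, 0, :], haps[:, 1, :])


def sample_gamete(
    parent_haplotypes: np.ndarray,
    model: RecombinationModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Single-parent convenience wrapper around :func:`sample_gametes`."""
    return sample_gametes(np.asarray(parent_haplotypes)[None], model, rng)[0]


def litter_sexes(litter_sizes: np.ndarray, start: int = MALE) -> np.ndarray:
    """Equal-split sexes per litter (5/5 in a litter of 10); odd litters alternate.

    Sexes alternate within each litter; the starting sex itself alternates
    between consecutive odd-sized litters so surplus sexes balance out.
    """
    out = []
    nxt = start
    for size in np.atleast_1d(litter_sizes):
        seq = (np.arange(size) + nxt) % 2
        out.append(seq)
        if size % 2 == 1:
            nxt = 1 - nxt
    return np.concatenate(out).astype(np.int8) if out else np.empty(0, dtype=np.int8)


def make_offspring(
    sire_haplotypes: np.ndarray,
    dam_haplotypes: np.ndarray,
    n_offspring: int,
    model: RecombinationModel,
    rng: np.random.Generator | int,
    sex_start: int = MALE,
) -> tuple[np.ndarray, np.ndarray]:
    """Construct offspring haplotypes for one mating.

    Each offspring receives one sire gamete (stored as haplotype 0) and one
    dam gamete (haplotype 1).  Returns ``(haplotypes (n, 2, L), sexes (n,))``
    with sexes split equally within the litter.
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be at least 1")
    sire = np.asarray(sire_haplotypes)
    dam = np.asarray(dam_haplotypes)
    if sire.shape != dam.shape or sire.ndim != 2:
        raise ValueError("parent haplotypes must both have shape (2, n_loci)")
    rng = as_rng(rng)
    paternal = sample_gametes(np.repeat(sire[None], n_offspring, axis=0), model, rng)
    maternal = sample_gametes(np.repeat(dam[None], n_offspring, axis=0), model, rng)
    haps = np.stack([paternal, maternal], axis=1)
    return haps, litter_sexes(np.array([n_offspring]), start=sex_start)


def mate_cohort(
    parent_haplotypes: np.ndarray,
    sire_rows: np.ndarray,
    dam_rows: np.ndarray,
    litter_size: int,
    model: RecombinationModel,
    rng: np.random.Generator,
    chunk: int = 4096,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised offspring construction for a whole mating plan.

    ``sire_rows``/``dam_rows`` index ``parent_haplotypes`` once per mating;
    every mating contributes ``litter_size`` offspring.  Gametes are sampled
    in chunks to bound memory.  Returns ``(haplotypes, sexes)`` ordered by
    mating, then within-litter.
    """
    sire_rows = np.repeat(np.asarray(sire_rows), litter_size)
    dam_rows = np.repeat(np.asarray(dam_rows), litter_size)
    total = len(sire_rows)
    n_loci = parent_haplotypes.shape[2]
    haps = np.empty((total, 2, n_loci), dtype=np.int8)
    for lo in range(0, total, chunk):
        hi = min(lo + chunk, total)
        haps[lo:hi, 0] = sample_gametes(parent_haplotypes[sire_rows[lo:hi]], model, rng)
        haps[lo:hi, 1] = sample_gametes(parent_haplotypes[dam_rows[lo:hi]], model, rng)
    sexes = litter_sexes(np.full(total // litter_size, litter_size))
    return haps, sexes
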