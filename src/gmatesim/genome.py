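"""Simulated genome map: chromosomes, marker and QTL coordinates in cM.

The default configuration mirrors a pig-like genome: 18 chromosomes of
100 cM each carrying 1,700 biallelic SNP markers and 17 biallelic QTL per
chromosome (30,600 markers, 306 QTL genome-wide), with locus positions
drawn uniformly at random along each chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .rng import as_rng

__all__ = ["GenomeMap", "build_genome_map"]

#: positions are rounded to this resolution (cM); ties are re-drawn
POSITION_RESOLUTION = 1e-6


@dataclass(frozen=True)
class GenomeMap:
    """Ordered locus coordinates for a set of chromosomes.

    Loci are stored genome-wide in a single ordering: by chromosome, then by
    strictly increasing position.  Each locus is either a marker (observable
    SNP) or a QTL (causal, unobserved in prediction).
    """

    n_chromosomes: int
    chromosome_length: float  # cM, identical for every chromosome
    chrom: np.ndarray = field(repr=False)  # int per locus, 0-based
    pos_cM: np.ndarray = field(repr=False)  # float64 per locus
    is_qtl: np.ndarray = field(repr=False)  # bool per locus

    def __post_init__(self) -> None:
        chrom = np.asarray(self.chrom)
        pos = np.asarray(self.pos_cM, dtype=np.float64)
        qtl = np.asarray(self.is_qtl, dtype=bool)
        if not (len(chrom) == len(pos) == len(qtl)):
            raise ValueError("chrom, pos_cM and is_qtl must have equal length")
        if np.any(np.diff(chrom) < 0):
            raise ValueError("loci must be ordered by chromosome")
        if np.any(pos < 0) or np.any(pos > self.chromosome_length):
            raise ValueError("positions must lie in [0, chromosome_length]")
        for c in range(self.n_chromosomes):
            sl = chrom == c
            if np.any(np.diff(pos[sl]) <= 0):
                raise ValueError(
                    f"positions must be strictly increasing on chromosome {c}"
                )
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos_cM", pos)
        object.__setattr__(self, "is_qtl", qtl)

    @property
    def n_loci(self) -> int:
        return len(self.pos_cM)

    @property
    def n_markers(self) -> int:
        return int((~self.is_qtl).sum())

    @property
    def n_qtl(self) -> int:
        return int(self.is_qtl.sum())

    @cached_property
    def marker_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtl)

    @cached_property
    def qtl_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)

    @cached_property
    def chrom_starts(self) -> np.ndarray:
        """Offsets of each chromosome in the genome-wide locus ordering.

        Length ``n_chromosomes + 1``; chromosome ``c`` occupies
        ``slice(chrom_starts[c], chrom_starts[c + 1])``.
        """
        return np.searchsorted(self.chrom, np.arange(self.n_chromosomes + 1))

    def subset(self, indices: np.ndarray) -> "GenomeMap":
        """Map restricted to the given (sorted) locus indices."""
        idx = np.asarray(indices)
        return GenomeMap(
            n_chromosomes=self.n_chromosomes,
            chromosome_length=self.chromosome_length,
            chrom=self.chrom[idx],
            pos_cM=self.pos_cM[idx],
            is_qtl=self.is_qtl[idx],
        )


def build_genome_map(
    n_chr: int,
    length_cM: float,
    n_markers_per_chr: int,
    n_qtl_per_chr: int,
    seed: int | np.random.Generator,
) -> GenomeMap:
    """Draw a random genome map with uniform marker and QTL positions.

    Positions are drawn uniformly on the open interval (0, length_cM),
    rounded to 1e-6 cM; duplicate positions are resolved by re-drawing.  QTL
    status is assigned to a uniform random subset of the drawn loci, so
    marker and QTL positions follow the same uniform law.  Deterministic for
    a fixed seed.
    """
    if n_chr <= 0 or length_cM <= 0 or n_markers_per_chr <= 0 or n_qtl_per_chr < 0:
        raise ValueError("counts and chromosome length must be positive")
    n_per = n_markers_per_chr + n_qtl_per_chr
    if n_per > 0.5 * length_cM / POSITION_RESOLUTION:
        raise ValueError(
            f"{n_per} loci exceed the position density limit for a "
            f"{length_cM} cM chromosome at {POSITION_RESOLUTION} cM resolution"
        )
    rng = as_rng(seed)
    chrom_col, pos_col, qtl_col = [], [], []
    for c in range(n_chr):
        pos = np.empty(0)
        for _ in range(100):
            need = n_per - len(pos)
            if need == 0:
                break
            draw = np.round(rng.uniform(0.0, length_cM, size=need), 6)
            pos = np.unique(np.concatenate([pos, draw]))
            pos = pos[(pos > 0) & (pos < length_cM)]
        else:  # pragma: no cover - essentially unreachable under the density limit
            raise ValueError(f"could not resolve duplicate positions on chromosome {c}")
        pos.sort()
        qtl = np.zeros(n_per, dtype=bool)
        qtl[rng.choice(n_per, size=n_qtl_per_chr, replace=False)] = True
        chrom_col.append(np.full(n_per, c, dtype=np.int16))
        pos_col.append(pos)
        qtl_col.append(qtl)
    return GenomeMap(
        n_chromosomes=n_chr,
        chromosome_length=float(length_cM),
        chrom=np.concatenate(chrom_col),
        pos_cM=np.concatenate(pos_col),
        is_qtl=np.concatenate(qtl_col),
    )
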