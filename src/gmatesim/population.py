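"""Phased diploid populations.

Alleles are coded {0, 1} internally (an explicit bijection to the 1/2
coding used by PLINK-style text exports).  Haplotype 0 of an individual is
always the paternally inherited gamete and haplotype 1 the maternally
inherited one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Population", "MALE", "FEMALE", "UNKNOWN", "monomorphic_mask"]

MALE = 0
FEMALE = 1
UNKNOWN = -1  # sire/dam code for pedigree roots


@dataclass
class Population:
    """A cohort of phased individuals over a shared genome map.

    ``haplotypes`` has shape (n, 2, n_loci) with alleles in {0, 1};
    axis 1 is (paternal gamete, maternal gamete).
    """

    haplotypes: np.ndarray
    sex: np.ndarray  # int8, MALE/FEMALE
    ids: np.ndarray  # int64, unique
    sire: np.ndarray = field(default=None)  # int64 parent ids, UNKNOWN for roots
    dam: np.ndarray = field(default=None)
    generation: int = 0

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, n_loci)")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("alleles must be coded 0/1")
        n = self.haplotypes.shape[0]
        self.sex = np.asarray(self.sex, dtype=np.int8)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.sire is None:
            self.sire = np.full(n, UNKNOWN, dtype=np.int64)
        if self.dam is None:
            self.dam = np.full(n, UNKNOWN, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        for name in ("sex", "ids", "sire", "dam"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match haplotypes")
        if len(np.unique(self.ids)) != n:
            raise ValueError("individual ids must be unique")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def dosages(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Genotype dosage matrix x = h1 + h2 in {0, 1, 2}, optionally at a locus subset."""
        h = self.haplotypes if loci is None else self.haplotypes[:, :, loci]
        return h.sum(axis=1, dtype=np.int16)

    def allele_frequencies(self, loci: np.ndarray | None = None) -> np.ndarray:
        return self.dosages(loci).mean(axis=0) / 2.0

    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sex == MALE)

    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sex == FEMALE)

    def subset(self, idx: np.ndarray) -> "Population":
        idx = np.asarray(idx)
        return replace(
            self,
            haplotypes=self.haplotypes[idx],
            sex=self.sex[idx],
            ids=self.ids[idx],
            sire=self.sire[idx],
            dam=self.dam[idx],
        )

    def index_of(self, ids: np.ndarray) -> np.ndarray:
        """Row indices of the given ids (raises if any id is absent)."""
        lookup = {int(i): k for k, i in enumerate(self.ids)}
        try:
            return np.array([lookup[int(i)] for i in np.atleast_1d(ids)], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"id {exc} not in population") from exc


def monomorphic_mask(pop: Population) -> np.ndarray:
    """Boolean mask of loci fixed (dosage variance zero) in the population."""
    d = pop.dosages()
    return (d == d[0]).all(axis=0)
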