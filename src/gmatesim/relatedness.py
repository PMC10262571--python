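"""Genomic and pedigree relatedness.

Three relationship constructions are provided:

* ``grm_vanraden`` -- the SNP GRM G = Z Z' / (2 sum p_j (1 - p_j)) with
  columns centred by twice the allele frequency (VanRaden method 1).
* ``segment_kinship`` -- a runs-of-homozygosity / shared-segment kinship:
  for each pair of individuals the four haplotype pairs are scanned for
  maximal identical stretches exceeding length and marker-count thresholds,
  and the shared map length is averaged and normalised by the total map
  length.  G_ROH is twice this kinship, so a fully autozygous individual
  has a diagonal of 2.
* ``f_ped`` -- Wright's pedigree inbreeding coefficient via the tabular
  (recursive additive-relationship) method.

``f_grm`` is the marker-based inbreeding estimate; it supports both the
per-marker-standardised denominator and the VanRaden ratio-of-sums
denominator (the latter makes diag(G) - 1 and F_GRM coincide exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np

from .genome import GenomeMap
from .population import UNKNOWN, Population

__all__ = [
    "RelationshipMatrix",
    "grm_vanraden",
    "segment_kinship",
    "f_grm",
    "f_ped",
    "Pedigree",
]


@dataclass(frozen=True)
class RelationshipMatrix:
    """A symmetric relationship matrix with its provenance."""

    values: np.ndarray  # (n, n) symmetric
    kind: str  # "snp" | "roh" | "pedigree"
    ids: np.ndarray  # subject ids, aligned with rows/columns
    p: np.ndarray | None = field(default=None, repr=False)  # allele freqs (snp only)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relationship matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        if len(self.ids) != v.shape[0]:
            raise ValueError("ids must match matrix order")
        if self.kind in ("roh", "pedigree") and np.any(np.diag(v) < 0):
            raise ValueError(f"{self.kind} matrix diagonal must be non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", np.asarray(self.ids, dtype=np.int64))


def grm_vanraden(M: np.ndarray, ids: np.ndarray | None = None) -> RelationshipMatrix:
    """VanRaden method-1 GRM from a dosage matrix (n x m).

    Allele frequencies are computed from ``M`` itself; monomorphic columns
    are dropped from both numerator and denominator.
    """
    M = np.asarray(M, dtype=np.float64)
    n, m = M.shape
    if m < 1:
        raise ValueError("need at least one marker")
    p = M.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers are monomorphic; GRM undefined")
    Z = M[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)  # enforce exact symmetry against float drift
    if ids is None:
        ids = np.arange(n)
    return RelationshipMatrix(values=G, kind="snp", ids=ids, p=p)


def f_grm(M: np.ndarray, per_marker: bool = True) -> np.ndarray:
    """Marker-based inbreeding estimate from the GRM-diagonal construction.

    ``per_marker=True`` standardises each marker by its own 2 p q before
    averaging (may be negative); ``per_marker=False`` uses the common
    VanRaden denominator 2 sum p q, in which case the result equals
    diag(grm_vanraden(M)) - 1 exactly.  Monomorphic markers are excluded
    either way.
    """
    M = np.asarray(M, dtype=np.float64)
    p = M.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers are monomorphic; F_GRM undefined")
    X = M[:, poly] - 2.0 * p[poly]
    pq2 = 2.0 * p[poly] * (1.0 - p[poly])
    if per_marker:
        return (X**2 / pq2).mean(axis=1) - 1.0
    return (X**2).sum(axis=1) / pq2.sum() - 1.0


@numba.njit(cache=True)
def _shared_segment_lengths(H, starts, pos, min_len, min_markers):
    """Upper-triangular matrix of per-haplotype-pair shared map length."""
    nh = H.shape[0]
    S = np.zeros((nh, nh))
    for ci in range(len(starts) - 1):
        s, e = starts[ci], starts[ci + 1]
        for a in range(nh):
            for b in range(a, nh):
                total = 0.0
                run = -1
                for i in range(s, e):
                    if H[a, i] == H[b, i]:
                        if run < 0:
                            run = i
                    elif run >= 0:
                        ln = pos[i - 1] - pos[run]
                        if ln >= min_len and (i - run) >= min_markers:
                            total += ln
                        run = -1
                if run >= 0:
                    ln = pos[e - 1] - pos[run]
                    if ln >= min_len and (e - run) >= min_markers:
                        total += ln
                S[a, b] += total
    return S


def segment_kinship(
    pop: Population,
    gmap: GenomeMap,
    min_length_cM: float = 1.0,
    min_markers: int = 20,
    loci: str = "markers",
) -> RelationshipMatrix:
    """ROH-segment relationship matrix G_ROH = 2 x segment-based kinship.

    Kinship between i and j averages, over the four ordered haplotype
    pairs, the fraction of the map covered by maximal identical stretches
    that pass both thresholds.  The diagonal uses an individual's own two
    haplotypes including the (trivially identical) self pairs, so entries
    lie in [0, 2] and reach 2 only under full autozygosity.
    """
    if pop.n_loci != gmap.n_loci:
        raise ValueError("population and genome map disagree on locus count")
    if loci == "markers":
        idx = gmap.marker_indices
    elif loci == "all":
        idx = np.arange(gmap.n_loci)
    else:
        raise ValueError("loci must be 'markers' or 'all'")
    sub = gmap.subset(idx)
    H = np.ascontiguousarray(
        pop.haplotypes[:, :, idx].reshape(pop.n_individuals * 2, len(idx))
    )
    starts = sub.chrom_starts.astype(np.int64)
    pos = np.ascontiguousarray(sub.pos_cM)
    total_len = sum(
        pos[starts[c + 1] - 1] - pos[starts[c]]
        for c in range(sub.n_chromosomes)
        if starts[c + 1] - starts[c] > 1
    )
    if total_len <= 0:
        raise ValueError("map too short for segment kinship")
    S = _shared_segment_lengths(H, starts, pos, float(min_length_cM), int(min_markers))
    S = S + S.T - np.diag(np.diag(S))
    n = pop.n_individuals
    f = S.reshape(n, 2, n, 2).sum(axis=(1, 3)) / (4.0 * total_len)
    G = 2.0 * f
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(values=G, kind="roh", ids=pop.ids)


def f_ped(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Pedigree inbreeding coefficients by the tabular method.

    ``sire``/``dam`` hold row indices of each individual's parents within
    the same arrays, or a negative value for unknown.  Parents must precede
    offspring (this also excludes pedigree cycles).  Individuals with at
    least one unknown parent get F = 0, the founder convention.
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    n = len(sire)
    if len(dam) != n:
        raise ValueError("sire and dam arrays must have equal length")
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= i or d >= i:
            raise ValueError(
                f"individual {i} listed before parent; order parents first"
            )
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return np.diag(A) - 1.0


class Pedigree:
    """Append-only pedigree keyed by individual id, with cached inbreeding."""

    def __init__(self) -> None:
        self.ids: list[int] = []
        self.sire: list[int] = []
        self.dam: list[int] = []
        self._row: dict[int, int] = {}
        self._F: np.ndarray = np.empty(0)
        self._f_valid = 0  # number of rows covered by the cached F

    def __len__(self) -> int:
        return len(self.ids)

    def append(self, ids, sires, dams) -> None:
        """Add individuals; parents must already be present (or UNKNOWN)."""
        for i, s, d in zip(np.atleast_1d(ids), np.atleast_1d(sires), np.atleast_1d(dams)):
            i, s, d = int(i), int(s), int(d)
            if i in self._row:
                raise ValueError(f"duplicate id {i} in pedigree")
            for parent in (s, d):
                if parent != UNKNOWN and parent not in self._row:
                    raise ValueError(f"parent {parent} of {i} not in pedigree")
            self._row[i] = len(self.ids)
            self.ids.append(i)
            self.sire.append(self._row.get(s, UNKNOWN))
            self.dam.append(self._row.get(d, UNKNOWN))

    def inbreeding(self) -> np.ndarray:
        """F for every recorded individual, in insertion order."""
        if self._f_valid != len(self.ids):
            self._F = f_ped(np.array(self.sire), np.array(self.dam))
            self._f_valid = len(self.ids)
        return self._F

    def f_of(self, ids) -> np.ndarray:
        F = self.inbreeding()
        return np.array([F[self._row[int(i)]] for i in np.atleast_1d(ids)])
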