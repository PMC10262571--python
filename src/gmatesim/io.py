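"""Readers and writers for PLINK-text, VCF and the package's CSV tables.

PLINK text export uses the 1/2 allele coding (internal 0 -> 1, 1 -> 2) and
writes phased allele pairs in paternal-then-maternal order; base-pair
positions are derived from cM as round(cM * 1e6) for tools that require
them.  Phased VCF input is read through cyvcf2 when available.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd

from .bayesb import MarkerEffects
from .genome import GenomeMap
from .mating import MatingPlan
from .population import FEMALE, MALE, Population
from .relatedness import RelationshipMatrix

__all__ = [
    "write_plink",
    "read_plink",
    "read_vcf",
    "write_founder_metadata",
    "write_cohort_table",
    "write_effects_csv",
    "read_effects_csv",
    "write_matrix_csv",
    "write_plan_csv",
    "read_plan_csv",
]


def _locus_names(gmap: GenomeMap) -> list[str]:
    names = []
    counters = {}
    for c, q in zip(gmap.chrom, gmap.is_qtl):
        kind = "q" if q else "m"
        key = (int(c), kind)
        counters[key] = counters.get(key, 0) + 1
        names.append(f"chr{int(c) + 1}_{kind}{counters[key]}")
    return names


def write_plink(
    pop: Population,
    gmap: GenomeMap,
    prefix: str | pathlib.Path,
    loci: str = "markers",
) -> None:
    """Write ``prefix.map`` and ``prefix.ped`` (phased, 1/2 allele coding)."""
    prefix = pathlib.Path(prefix)
    if loci == "markers":
        idx = gmap.marker_indices
    elif loci == "all":
        idx = np.arange(gmap.n_loci)
    else:
        raise ValueError("loci must be 'markers' or 'all'")
    names = np.array(_locus_names(gmap))[idx]
    with open(prefix.with_suffix(".map"), "w") as fh:
        for name, c, pos in zip(names, gmap.chrom[idx], gmap.pos_cM[idx]):
            fh.write(f"{int(c) + 1}\t{name}\t{pos:.6f}\t{int(round(pos * 1e6))}\n")
    haps = pop.haplotypes[:, :, idx] + 1  # 0/1 -> 1/2
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for k in range(pop.n_individuals):
            sex = 1 if pop.sex[k] == MALE else 2
            sire = int(pop.sire[k]) if pop.sire[k] >= 0 else 0
            dam = int(pop.dam[k]) if pop.dam[k] >= 0 else 0
            fields = [str(pop.generation), str(int(pop.ids[k])), str(sire), str(dam), str(sex), "-9"]
            alleles = haps[k].T.reshape(-1)  # h1 h2 per locus
            fh.write(" ".join(fields) + " " + " ".join(map(str, alleles)) + "\n")


def read_plink(prefix: str | pathlib.Path) -> tuple[Population, GenomeMap]:
    """Read the package's PLINK-text convention back into memory.

    All loci are treated as markers (QTL roles are not represented in the
    format); alleles are mapped 1 -> 0, 2 -> 1.
    """
    prefix = pathlib.Path(prefix)
    map_df = pd.read_csv(
        prefix.with_suffix(".map"),
        sep="\t",
        names=["chrom", "name", "cM", "bp"],
    )
    chrom = map_df["chrom"].to_numpy() - 1
    pos = map_df["cM"].to_numpy(dtype=np.float64)
    gmap = GenomeMap(
        n_chromosomes=int(chrom.max()) + 1,
        chromosome_length=float(np.ceil(pos.max())),
        chrom=chrom,
        pos_cM=pos,
        is_qtl=np.zeros(len(pos), dtype=bool),
    )
    ids, sires, dams, sexes, haps = [], [], [], [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            ids.append(int(parts[1]))
            sires.append(int(parts[2]) if parts[2] != "0" else -1)
            dams.append(int(parts[3]) if parts[3] != "0" else -1)
            sexes.append(MALE if parts[4] == "1" else FEMALE)
            alleles = np.array(parts[6:], dtype=np.int8).reshape(-1, 2) - 1
            haps.append(alleles.T)
    pop = Population(
        haplotypes=np.stack(haps),
        sex=np.array(sexes),
        ids=np.array(ids),
        sire=np.array(sires),
        dam=np.array(dams),
    )
    return pop, gmap


def read_vcf(path: str | pathlib.Path) -> tuple[Population, GenomeMap]:
    """Read phased genotypes from a VCF into a Population and genome map.

    Positions are converted to cM as bp / 1e6 (the inverse of the PLINK
    export convention).  Raises on unphased records.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    chroms, pos_cm, h1, h2 = [], [], [], []
    chrom_index: dict[str, int] = {}
    for rec in vcf:
        gts = np.array(rec.genotypes)
        if not np.all(gts[:, 2]):
            raise ValueError(f"unphased genotype at {rec.CHROM}:{rec.POS}")
        chrom_index.setdefault(rec.CHROM, len(chrom_index))
        chroms.append(chrom_index[rec.CHROM])
        pos_cm.append(rec.POS / 1e6)
        h1.append(gts[:, 0])
        h2.append(gts[:, 1])
    haps = np.stack(
        [np.array(h1, dtype=np.int8).T, np.array(h2, dtype=np.int8).T], axis=1
    )
    chrom = np.array(chroms)
    pos = np.array(pos_cm)
    order = np.lexsort((pos, chrom))
    gmap = GenomeMap(
        n_chromosomes=len(chrom_index),
        chromosome_length=float(np.ceil(pos.max())),
        chrom=chrom[order],
        pos_cM=pos[order],
        is_qtl=np.zeros(len(pos), dtype=bool),
    )
    pop = Population(
        haplotypes=haps[:, :, order],
        sex=np.zeros(len(samples), dtype=np.int8),
        ids=np.arange(len(samples), dtype=np.int64),
    )
    return pop, gmap


def write_founder_metadata(pop: Population, path) -> None:
    pd.DataFrame(
        {
            "id": pop.ids,
            "sex": np.where(pop.sex == MALE, "M", "F"),
            "sire": pop.sire,
            "dam": pop.dam,
            "generation": pop.generation,
        }
    ).to_csv(path, index=False)


def write_cohort_table(pop: Population, g, y, path) -> None:
    """Per-individual trait table: id, generation, sex, pedigree links, g, y."""
    pd.DataFrame(
        {
            "id": pop.ids,
            "generation": pop.generation,
            "sex": np.where(pop.sex == MALE, "M", "F"),
            "sire": pop.sire,
            "dam": pop.dam,
            "g": np.asarray(g),
            "y": np.asarray(y),
        }
    ).to_csv(path, index=False)


def write_effects_csv(effects: MarkerEffects, gmap: GenomeMap, path) -> None:
    """Marker effect profile (for plotting effect landscapes along the genome)."""
    idx = gmap.marker_indices
    names = np.array(_locus_names(gmap))[idx]
    pd.DataFrame(
        {
            "marker": names,
            "chromosome": gmap.chrom[idx] + 1,
            "pos_cM": gmap.pos_cM[idx],
            "effect": effects.a,
            "inclusion_prob": effects.inclusion_prob,
        }
    ).to_csv(path, index=False)


def read_effects_csv(path) -> pd.DataFrame:
    """Marker-effect table entry point for real-data use."""
    df = pd.read_csv(path)
    required = {"marker", "effect"}
    if not required <= set(df.columns):
        raise ValueError(f"effects table must contain columns {sorted(required)}")
    return df


def write_matrix_csv(matrix: RelationshipMatrix, path, long: bool = False) -> None:
    if long:
        n = len(matrix.ids)
        i, j = np.triu_indices(n)
        pd.DataFrame(
            {
                "i": matrix.ids[i],
                "j": matrix.ids[j],
                "value": matrix.values[i, j],
            }
        ).to_csv(path, index=False)
    else:
        pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids).to_csv(path)


def write_plan_csv(plan: MatingPlan, path) -> None:
    pd.DataFrame(
        {
            "mating_index": np.arange(plan.n_matings),
            "sire": plan.sires,
            "dam": plan.dams,
            "n_offspring": plan.n_offspring,
        }
    ).to_csv(path, index=False)


def read_plan_csv(path) -> MatingPlan:
    df = pd.read_csv(path)
    return MatingPlan(
        sires=df["sire"].to_numpy(),
        dams=df["dam"].to_numpy(),
        n_offspring=df["n_offspring"].to_numpy(),
    )
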