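"""Mate allocation: traditional schemes and the genomic-mating optimizer.

A mating plan is a list of (sire, dam, litter size) rows; its incidence
matrix P (matings x parents) carries 1/2 on the sire and dam column of each
row, so P applied to a parental merit vector yields midparent values.

The genomic-mating objectives over a plan P are

    Gain(P)       = 1' P G M a
    Inbreeding(P) = 1' (P G P' + D) 1

where G is a genomic relationship matrix (SNP or ROH based), M a the
parents' genomic merit vector, and D the per-mating Mendelian sampling
dispersion.  Writing u = P' 1 for the half-usage vector of the parents,
Gain = u' G M a rewards loading high-merit parents, and the quadratic
1'PGP'1 = u' G u is the group coancestry of the planned progeny: it is
minimised by spreading contributions across unrelated parents, exactly as
in optimal-contribution selection.  The optimizer searches dam->sire
assignment vectors under a sire capacity bound with a hybrid
genetic-algorithm / simulated-annealing loop and keeps an archive of
nondominated (gain, inbreeding) plans; the archive endpoints are the
maximum-gain and minimum-inbreeding schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bayesb import MarkerEffects
from .genome import GenomeMap
from .population import Population
from .relatedness import RelationshipMatrix
from .rng import as_rng

__all__ = [
    "MatingPlan",
    "ObjectivePair",
    "Frontier",
    "random_mating",
    "positive_assortative",
    "negative_assortative",
    "segregation_load",
    "mendelian_dispersion",
    "evaluate_plan",
    "optimize_mating",
]


@dataclass(frozen=True)
class MatingPlan:
    """An ordered list of sire-dam matings with offspring counts."""

    sires: np.ndarray  # sire id per mating
    dams: np.ndarray  # dam id per mating
    n_offspring: np.ndarray  # litter size per mating

    def __post_init__(self) -> None:
        s = np.asarray(self.sires, dtype=np.int64)
        d = np.asarray(self.dams, dtype=np.int64)
        n = np.asarray(self.n_offspring, dtype=np.int64)
        if not (len(s) == len(d) == len(n)):
            raise ValueError("plan columns must have equal length")
        if len(np.unique(d)) != len(d):
            raise ValueError("every dam must appear in exactly one mating")
        if np.any(n < 1):
            raise ValueError("litter sizes must be at least 1")
        object.__setattr__(self, "sires", s)
        object.__setattr__(self, "dams", d)
        object.__setattr__(self, "n_offspring", n)

    @property
    def n_matings(self) -> int:
        return len(self.sires)

    def sire_usage(self) -> dict[int, int]:
        uniq, counts = np.unique(self.sires, return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))

    def validate_capacity(self, capacity: int) -> None:
        over = {s: c for s, c in self.sire_usage().items() if c > capacity}
        if over:
            raise ValueError(f"sire capacity {capacity} exceeded: {over}")

    def incidence(self, parent_ids: np.ndarray) -> np.ndarray:
        """Incidence matrix P (n_matings x n_parents) with entries in {0, 1/2}."""
        parent_ids = np.asarray(parent_ids)
        col = {int(p): j for j, p in enumerate(parent_ids)}
        P = np.zeros((self.n_matings, len(parent_ids)))
        for k, (s, d) in enumerate(zip(self.sires, self.dams)):
            P[k, col[int(s)]] += 0.5
            P[k, col[int(d)]] += 0.5
        return P


@dataclass(frozen=True)
class ObjectivePair:
    gain: float
    inbreeding: float


@dataclass(frozen=True)
class FrontierEntry:
    plan: MatingPlan
    gain: float
    inbreeding: float


@dataclass
class Frontier:
    """Nondominated set of plans trading gain against expected inbreeding."""

    entries: list[FrontierEntry] = field(default_factory=list)

    def insert(self, entry: FrontierEntry) -> None:
        for e in self.entries:
            if e.gain >= entry.gain and e.inbreeding <= entry.inbreeding:
                if e.gain > entry.gain or e.inbreeding < entry.inbreeding:
                    return  # dominated
                return  # duplicate objectives; keep first
        self.entries = [
            e
            for e in self.entries
            if not (
                entry.gain >= e.gain
                and entry.inbreeding <= e.inbreeding
                and (entry.gain > e.gain or entry.inbreeding < e.inbreeding)
            )
        ]
        self.entries.append(entry)

    @property
    def max_gain(self) -> FrontierEntry:
        return max(self.entries, key=lambda e: (e.gain, -e.inbreeding))

    @property
    def min_inbreeding(self) -> FrontierEntry:
        return min(self.entries, key=lambda e: (e.inbreeding, -e.gain))


def _blocks(ordered_sires, ordered_dams, block: int, litter_size: int) -> MatingPlan:
    sires = np.repeat(ordered_sires, block)
    return MatingPlan(
        sires=sires,
        dams=np.asarray(ordered_dams),
        n_offspring=np.full(len(ordered_dams), litter_size, dtype=np.int64),
    )


def random_mating(
    sire_ids: np.ndarray,
    dam_ids: np.ndarray,
    capacity: int,
    seed: int | np.random.Generator = 0,
    litter_size: int = 1,
) -> MatingPlan:
    """Shuffle dams uniformly and deal them to sires in balanced blocks."""
    rng = as_rng(seed)
    sire_ids = np.asarray(sire_ids)
    dam_ids = np.asarray(dam_ids)
    n_s, n_d = len(sire_ids), len(dam_ids)
    if n_d > n_s * capacity:
        raise ValueError(f"{n_d} dams exceed {n_s} sires x capacity {capacity}")
    dams = rng.permutation(dam_ids)
    sires = rng.permutation(sire_ids)
    base, extra = divmod(n_d, n_s)
    counts = np.full(n_s, base)
    counts[:extra] += 1
    return MatingPlan(
        sires=np.repeat(sires, counts),
        dams=dams,
        n_offspring=np.full(n_d, litter_size, dtype=np.int64),
    )


def _ranked(ids, gebv, descending: bool) -> np.ndarray:
    ids = np.asarray(ids)
    gebv = np.asarray(gebv, dtype=np.float64)
    key = -gebv if descending else gebv
    return ids[np.lexsort((ids, key))]


def positive_assortative(
    sire_ids,
    sire_gebv,
    dam_ids,
    dam_gebv,
    capacity: int,
    litter_size: int = 1,
) -> MatingPlan:
    """Best sire takes the top ``capacity`` dams, second sire the next block, ...

    Requires exactly ``capacity`` dams per sire; GEBV ties are broken by id
    so the plan is deterministic.
    """
    if len(dam_ids) != len(sire_ids) * capacity:
        raise ValueError("dam count must equal sire count x capacity")
    return _blocks(
        _ranked(sire_ids, sire_gebv, descending=True),
        _ranked(dam_ids, dam_gebv, descending=True),
        capacity,
        litter_size,
    )


def negative_assortative(
    sire_ids,
    sire_gebv,
    dam_ids,
    dam_gebv,
    capacity: int,
    litter_size: int = 1,
) -> MatingPlan:
    """Sires ranked low-to-high against dams ranked high-to-low, blockwise."""
    if len(dam_ids) != len(sire_ids) * capacity:
        raise ValueError("dam count must equal sire count x capacity")
    return _blocks(
        _ranked(sire_ids, sire_gebv, descending=False),
        _ranked(dam_ids, dam_gebv, descending=True),
        capacity,
        litter_size,
    )


def segregation_load(
    pop: Population,
    effects: MarkerEffects,
    gmap: GenomeMap,
) -> np.ndarray:
    """Per-parent sum of a_j^2 over heterozygous markers.

    The linkage-free within-cross segregation variance of a mating is
    (load_sire + load_dam) / 4; see :func:`mendelian_dispersion`.
    """
    h = pop.haplotypes[:, :, gmap.marker_indices]
    het = (h[:, 0, :] != h[:, 1, :]).astype(np.float64)
    return het @ (effects.a**2)


def mendelian_dispersion(
    plan: MatingPlan,
    parents: Population,
    effects: MarkerEffects,
    gmap: GenomeMap,
) -> np.ndarray:
    """Diagonal of D: within-cross variance of progeny merit per mating.

    Linkage-free approximation D_kk = sum_j a_j^2 [het_s(j) + het_d(j)] / 4;
    a homozygous-by-homozygous cross segregates nothing and gets 0.
    """
    load = segregation_load(parents, effects, gmap)
    s_rows = parents.index_of(plan.sires)
    d_rows = parents.index_of(plan.dams)
    return 0.25 * (load[s_rows] + load[d_rows])


def evaluate_plan(
    plan: MatingPlan,
    G: RelationshipMatrix,
    merit: np.ndarray,
    D: np.ndarray | None = None,
) -> ObjectivePair:
    """Compute (Gain, Inbreeding) for a plan against a parent GRM and merit vector."""
    merit = np.asarray(merit, dtype=np.float64)
    if len(merit) != len(G.ids):
        raise ValueError("merit vector does not match GRM order")
    col = {int(p): j for j, p in enumerate(G.ids)}
    s = np.array([col[int(i)] for i in plan.sires])
    d = np.array([col[int(i)] for i in plan.dams])
    u = np.zeros(len(G.ids))
    np.add.at(u, s, 0.5)
    np.add.at(u, d, 0.5)
    gain = float(u @ G.values @ merit)
    inb = float(u @ G.values @ u)
    if D is not None:
        D = np.asarray(D, dtype=np.float64)
        if len(D) != plan.n_matings:
            raise ValueError("D must have one entry per mating")
        inb += float(D.sum())
    return ObjectivePair(gain=gain, inbreeding=inb)


def _repair(assign: np.ndarray, n_sires: int, capacity: int, rng) -> np.ndarray:
    """Move dams off over-capacity sires onto sires with free slots."""
    counts = np.bincount(assign, minlength=n_sires)
    over = np.flatnonzero(counts > capacity)
    if len(over) == 0:
        return assign
    for s in over:
        dams_of_s = np.flatnonzero(assign == s)
        excess = counts[s] - capacity
        move = rng.choice(dams_of_s, size=excess, replace=False)
        for dam in move:
            free = np.flatnonzero(counts < capacity)
            target = rng.choice(free)
            assign[dam] = target
            counts[s] -= 1
            counts[target] += 1
    return assign


def optimize_mating(
    sire_ids: np.ndarray,
    dam_ids: np.ndarray,
    G: RelationshipMatrix,
    merit: np.ndarray,
    capacity: int,
    seg_load: np.ndarray | None = None,
    ga_pop_size: int = 200,
    n_iter: int = 800,
    seed: int | np.random.Generator = 0,
    litter_size: int = 1,
) -> Frontier:
    """Search dam->sire assignments for the gain/inbreeding Pareto frontier.

    Hybrid GA/SA: each population slot carries a fixed scalarization weight
    lambda in [0, 1] (sweeping the frontier); children are produced by
    binary-tournament selection, uniform crossover, per-dam reassignment
    mutation at rate 1/n_dams and capacity repair, and replace their slot
    if better under its lambda or by a simulated-annealing acceptance with
    geometric temperature decay (T0 = 1, ratio 0.995).  A plan archive
    keeps every nondominated (gain, inbreeding) pair seen.

    ``seg_load`` is the per-parent segregation load (aligned with
    ``G.ids``); when given, the Mendelian dispersion term enters the
    inbreeding objective.
    """
    if ga_pop_size < 2:
        raise ValueError("ga_pop_size must be at least 2")
    rng = as_rng(seed)
    sire_ids = np.asarray(sire_ids)
    dam_ids = np.asarray(dam_ids)
    n_s, n_d = len(sire_ids), len(dam_ids)
    if n_d > n_s * capacity:
        raise ValueError(f"{n_d} dams infeasible for {n_s} sires x capacity {capacity}")
    col = {int(p): j for j, p in enumerate(G.ids)}
    sidx = np.array([col[int(i)] for i in sire_ids])
    didx = np.array([col[int(i)] for i in dam_ids])
    merit = np.asarray(merit, dtype=np.float64)
    q = G.values @ merit
    q_s = q[sidx]
    dam_gain = float(0.5 * q[didx].sum())
    # inbreeding decomposes over the sire usage counts: with u = P'1,
    # u'Gu = cnt'Gss cnt / 4 + cnt.(Gsd 1)/2 + 1'Gdd 1/4
    Gss = G.values[np.ix_(sidx, sidx)]
    v_s = G.values[np.ix_(sidx, didx)].sum(axis=1)
    c_dd = float(G.values[np.ix_(didx, didx)].sum())
    if seg_load is not None:
        seg_load = np.asarray(seg_load, dtype=np.float64)
        load_s = seg_load[sidx]
        load_d_sum = float(seg_load[didx].sum())

    def objectives(assign: np.ndarray) -> tuple[float, float]:
        gain = dam_gain + 0.5 * q_s[assign].sum()
        cnt = np.bincount(assign, minlength=n_s).astype(np.float64)
        inb = 0.25 * (cnt @ Gss @ cnt) + 0.5 * (cnt @ v_s) + 0.25 * c_dd
        if seg_load is not None:
            inb += 0.25 * (cnt @ load_s + load_d_sum)
        return float(gain), float(inb)

    def to_plan(assign: np.ndarray) -> MatingPlan:
        return MatingPlan(
            sires=sire_ids[assign],
            dams=dam_ids,
            n_offspring=np.full(n_d, litter_size, dtype=np.int64),
        )

    frontier = Frontier()

    def record(assign, gain, inb):
        frontier.insert(FrontierEntry(plan=to_plan(assign.copy()), gain=gain, inbreeding=inb))

    pop = [
        _repair(rng.integers(n_s, size=n_d), n_s, capacity, rng)
        for _ in range(ga_pop_size)
    ]
    objs = [objectives(a) for a in pop]
    for a, (g, i) in zip(pop, objs):
        record(a, g, i)
    lambdas = np.linspace(0.0, 1.0, ga_pop_size)
    lo_g = min(g for g, _ in objs)
    hi_g = max(g for g, _ in objs)
    lo_i = min(i for _, i in objs)
    hi_i = max(i for _, i in objs)

    def scalar(g, i, lam):
        gn = (g - lo_g) / (hi_g - lo_g) if hi_g > lo_g else 0.0
        inn = (i - lo_i) / (hi_i - lo_i) if hi_i > lo_i else 0.0
        return lam * gn - (1.0 - lam) * inn

    temp = 1.0
    mut_rate = 1.0 / n_d
    for _ in range(n_iter):
        for k in range(ga_pop_size):
            lam = lambdas[k]
            parents = []
            for _ in range(2):
                i1, i2 = rng.integers(ga_pop_size, size=2)
                s1 = scalar(*objs[i1], lam)
                s2 = scalar(*objs[i2], lam)
                parents.append(pop[i1] if s1 >= s2 else pop[i2])
            child = np.where(rng.random(n_d) < 0.5, parents[0], parents[1])
            mut = rng.random(n_d) < mut_rate
            if mut.any():
                child[mut] = rng.integers(n_s, size=int(mut.sum()))
            child = _repair(child, n_s, capacity, rng)
            g, i = objectives(child)
            lo_g, hi_g = min(lo_g, g), max(hi_g, g)
            lo_i, hi_i = min(lo_i, i), max(hi_i, i)
            record(child, g, i)
            s_child = scalar(g, i, lam)
            s_cur = scalar(*objs[k], lam)
            if s_child >= s_cur or rng.random() < np.exp((s_child - s_cur) / max(temp, 1e-12)):
                pop[k] = child
                objs[k] = (g, i)
        temp *= 0.995
    return frontier
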