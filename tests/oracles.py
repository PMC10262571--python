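"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: pedigree inbreeding
is computed by Wright's path-counting rule, and mate-allocation objectives
by explicit incidence-matrix algebra over exhaustively enumerated plans.
"""

from __future__ import annotations

import itertools

import numpy as np

from gmatesim.mating import MatingPlan


def wright_inbreeding(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Wright's F by enumerating ancestral path pairs.

    F_i sums (1/2)^(n1+n2+1) (1 + F_A) over every common ancestor A of i's
    sire and dam and every pair of ancestral paths meeting only at A.
    Parents are row indices (negative = unknown); exponential in pedigree
    size, fine for <= ~20 individuals.
    """
    sire = np.asarray(sire)
    dam = np.asarray(dam)

    def paths_up(x):
        """All ancestral paths from x: (ancestor, node set, length in edges)."""
        out = [(x, frozenset([x]), 0)]
        for p in (sire[x], dam[x]):
            if p >= 0:
                for anc, nodes, ln in paths_up(p):
                    out.append((anc, nodes | {x}, ln + 1))
        return out

    memo: dict[int, float] = {}

    def f_of(i):
        if i in memo:
            return memo[i]
        s, d = sire[i], dam[i]
        if s < 0 or d < 0:
            memo[i] = 0.0
            return 0.0
        total = 0.0
        for a1, n1, l1 in paths_up(s):
            for a2, n2, l2 in paths_up(d):
                if a1 == a2 and (n1 & n2) == {a1}:
                    total += 0.5 ** (l1 + l2 + 1) * (1.0 + f_of(a1))
        memo[i] = total
        return total

    return np.array([f_of(i) for i in range(len(sire))])


def plan_objectives_matrix(plan: MatingPlan, G, merit, D=None) -> tuple[float, float]:
    """(gain, inbreeding) through the literal incidence-matrix algebra."""
    P = plan.incidence(G.ids)
    ones = np.ones(plan.n_matings)
    gain = float(ones @ P @ G.values @ np.asarray(merit, dtype=float))
    inb = float(ones @ P @ G.values @ P.T @ ones)
    if D is not None:
        inb += float(np.sum(D))
    return gain, inb


def enumerate_best_plans(sire_ids, dam_ids, G, merit, capacity, seg_load=None):
    """Exhaustive search over capacity-feasible dam->sire assignments.

    Returns ((best_gain, its inbreeding), (gain at best inbreeding,
    best_inbreeding)) with the same tie-breaking as the optimizer's
    frontier endpoints (max gain prefers lower inbreeding, and vice versa).
    """
    sire_ids = np.asarray(sire_ids)
    dam_ids = np.asarray(dam_ids)
    n_s, n_d = len(sire_ids), len(dam_ids)
    best_gain = None
    best_inb = None
    for assign in itertools.product(range(n_s), repeat=n_d):
        counts = np.bincount(assign, minlength=n_s)
        if counts.max() > capacity:
            continue
        plan = MatingPlan(
            sires=sire_ids[list(assign)],
            dams=dam_ids,
            n_offspring=np.ones(n_d, dtype=np.int64),
        )
        D = None
        if seg_load is not None:
            col = {int(p): j for j, p in enumerate(G.ids)}
            s = np.array([col[int(i)] for i in plan.sires])
            d = np.array([col[int(i)] for i in plan.dams])
            D = 0.25 * (np.asarray(seg_load)[s] + np.asarray(seg_load)[d])
        g, i = plan_objectives_matrix(plan, G, merit, D)
        if best_gain is None or (g, -i) > (best_gain[0], -best_gain[1]):
            best_gain = (g, i)
        if best_inb is None or (i, -g) < (best_inb[1], -best_inb[0]):
            best_inb = (g, i)
    return best_gain, best_inb


def random_pedigree(n: int, rng: np.random.Generator, p_known: float = 0.75):
    """A random acyclic pedigree (parents precede offspring)."""
    sire = np.full(n, -1)
    dam = np.full(n, -1)
    for i in range(2, n):
        if rng.random() < p_known:
            sire[i], dam[i] = rng.choice(i, size=2, replace=True)
    return sire, dam
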