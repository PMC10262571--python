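"""Mating plans, objectives and the genomic-mating optimizer."""

import numpy as np
import pytest

from gmatesim.bayesb import MarkerEffects
from gmatesim.mating import (
    MatingPlan,
    evaluate_plan,
    mendelian_dispersion,
    negative_assortative,
    optimize_mating,
    positive_assortative,
    random_mating,
)
from gmatesim.population import Population
from gmatesim.relatedness import RelationshipMatrix
from gmatesim.rng import stream

from oracles import enumerate_best_plans, plan_objectives_matrix


def random_grm(ids, rng):
    """A random positive semidefinite relationship matrix."""
    n = len(ids)
    B = rng.normal(size=(n, 2 * n))
    G = B @ B.T / (2 * n)
    return RelationshipMatrix(values=G + np.eye(n) * 0.5, kind="snp", ids=ids)


class TestPlanStructure:
    def test_duplicate_dam_rejected(self):
        with pytest.raises(ValueError, match="dam"):
            MatingPlan(sires=[1, 2], dams=[5, 5], n_offspring=[1, 1])

    def test_incidence_rows_sum_to_one(self):
        plan = MatingPlan(sires=[1, 1, 2], dams=[10, 11, 12], n_offspring=[2, 2, 2])
        P = plan.incidence(np.array([1, 2, 10, 11, 12]))
        np.testing.assert_allclose(P.sum(axis=1), 1.0)
        assert set(np.unique(P)) == {0.0, 0.5}

    def test_capacity_validation(self):
        plan = MatingPlan(sires=[1, 1, 1], dams=[10, 11, 12], n_offspring=[1, 1, 1])
        plan.validate_capacity(3)
        with pytest.raises(ValueError, match="capacity"):
            plan.validate_capacity(2)


class TestRandomMating:
    def test_balanced_blocks_full_scale(self):
        sires = np.arange(30)
        dams = np.arange(100, 1000)
        plan = random_mating(sires, dams, capacity=30, seed=1)
        usage = plan.sire_usage()
        assert all(v == 30 for v in usage.values()) and len(usage) == 30

    def test_single_sire_takes_all(self):
        plan = random_mating([7], np.arange(10, 20), capacity=10, seed=3)
        assert set(plan.sires) == {7}

    def test_capacity_infeasible(self):
        with pytest.raises(ValueError, match="exceed"):
            random_mating([1, 2], np.arange(10), capacity=4, seed=0)

    def test_pairing_is_uniform_over_seeds(self):
        sires = np.array([0, 1, 2])
        dams = np.array([10, 11, 12, 13, 14, 15])
        counts = np.zeros((3, 6))
        n_seeds = 900
        for s in range(n_seeds):
            plan = random_mating(sires, dams, capacity=2, seed=s)
            for si, di in zip(plan.sires, plan.dams):
                counts[si, di - 10] += 1
        freq = counts / n_seeds
        se = np.sqrt((1 / 3) * (2 / 3) / n_seeds)
        assert np.all(np.abs(freq - 1 / 3) < 4 * se)


class TestAssortative:
    def test_positive_blocks_by_rank(self):
        sires = np.arange(3)
        sire_gebv = np.array([5.0, 9.0, 1.0])  # ranks: 1, 0, 2
        dams = np.arange(10, 16)
        dam_gebv = np.array([1.0, 6.0, 3.0, 2.0, 5.0, 4.0])
        plan = positive_assortative(sires, sire_gebv, dams, dam_gebv, capacity=2)
        pairing = {s: [] for s in sires}
        for s, d in zip(plan.sires, plan.dams):
            pairing[s].append(d)
        assert pairing[1] == [11, 14]  # best sire takes the two best dams
        assert pairing[2] == [13, 10]  # worst sire takes the two worst

    def test_negative_reverses_sire_order(self):
        sires = np.arange(3)
        sire_gebv = np.array([5.0, 9.0, 1.0])
        dams = np.arange(10, 16)
        dam_gebv = np.array([1.0, 6.0, 3.0, 2.0, 5.0, 4.0])
        plan = negative_assortative(sires, sire_gebv, dams, dam_gebv, capacity=2)
        pairing = {s: [] for s in sires}
        for s, d in zip(plan.sires, plan.dams):
            pairing[s].append(d)
        assert pairing[2] == [11, 14]  # worst sire now takes the best dams
        assert pairing[1] == [13, 10]

    def test_tied_gebvs_coincide_up_to_tie_rule(self):
        sires = np.arange(4)
        dams = np.arange(10, 18)
        zeros_s = np.zeros(4)
        zeros_d = np.zeros(8)
        p = positive_assortative(sires, zeros_s, dams, zeros_d, capacity=2)
        n = negative_assortative(sires, zeros_s, dams, zeros_d, capacity=2)
        np.testing.assert_array_equal(p.sires, n.sires)
        np.testing.assert_array_equal(p.dams, n.dams)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="capacity"):
            positive_assortative([1, 2], [0, 1], [3, 4, 5], [0, 1, 2], capacity=2)

    def test_midparent_mean_equals_population_midparent(self):
        rng = stream(5)
        sires = np.arange(4)
        dams = np.arange(10, 22)
        sg = rng.normal(size=4)
        dg = rng.normal(size=12)
        lookup = dict(zip(np.r_[sires, dams], np.r_[sg, dg]))
        for plan in (
            positive_assortative(sires, sg, dams, dg, capacity=3),
            negative_assortative(sires, sg, dams, dg, capacity=3),
        ):
            mid = np.mean(
                [0.5 * (lookup[s] + lookup[d]) for s, d in zip(plan.sires, plan.dams)]
            )
            assert mid == pytest.approx(0.5 * sg.mean() + 0.5 * dg.mean())

    def test_positive_pairs_more_alike_than_random(self):
        rng = stream(6)
        sires = np.arange(5)
        dams = np.arange(10, 25)
        sg = rng.normal(size=5)
        dg = rng.normal(size=15)
        lookup = dict(zip(np.r_[sires, dams], np.r_[sg, dg]))

        def mean_gap(plan):
            return np.mean(
                [abs(lookup[s] - lookup[d]) for s, d in zip(plan.sires, plan.dams)]
            )

        p_gap = mean_gap(positive_assortative(sires, sg, dams, dg, capacity=3))
        r_gaps = [
            mean_gap(random_mating(sires, dams, capacity=3, seed=s)) for s in range(100)
        ]
        assert p_gap <= np.mean(r_gaps)


class TestMendelianDispersion:
    def _toy(self, tiny_map, h_sire, h_dam):
        n_loci = tiny_map.n_loci
        haps = np.stack([h_sire, h_dam])
        pop = Population(haplotypes=haps, sex=np.array([0, 1]), ids=np.array([1, 2]))
        a = np.zeros(tiny_map.n_markers)
        a[3] = 2.0
        eff = MarkerEffects(
            a=a,
            inclusion_prob=np.zeros_like(a),
            intercept=0.0,
            var_e=1.0,
            var_e_sd=0.0,
            pi=0.95,
            nu=4.2,
            s2=1.0,
        )
        plan = MatingPlan(sires=[1], dams=[2], n_offspring=[1])
        return mendelian_dispersion(plan, pop, eff, tiny_map)

    def test_homozygous_parents_give_zero(self, tiny_map):
        L = tiny_map.n_loci
        h = np.stack([np.zeros(L, dtype=np.int8)] * 2)
        assert self._toy(tiny_map, h, np.stack([np.ones(L, dtype=np.int8)] * 2))[0] == 0.0

    def test_single_heterozygous_marker(self, tiny_map):
        L = tiny_map.n_loci
        sire = np.zeros((2, L), dtype=np.int8)
        sire[0, tiny_map.marker_indices[3]] = 1  # het at the marker carrying a=2
        dam = np.zeros((2, L), dtype=np.int8)
        assert self._toy(tiny_map, sire, dam)[0] == pytest.approx(4.0 / 4.0)

    def test_swap_invariance(self, tiny_map):
        rng = stream(8)
        L = tiny_map.n_loci
        h1 = rng.integers(0, 2, (2, L), dtype=np.int8)
        h2 = rng.integers(0, 2, (2, L), dtype=np.int8)
        assert self._toy(tiny_map, h1, h2)[0] == pytest.approx(self._toy(tiny_map, h2, h1)[0])


class TestEvaluatePlan:
    def test_identity_grm_toy(self):
        ids = np.array([1, 2, 10, 11])
        G = RelationshipMatrix(values=np.eye(4), kind="snp", ids=ids)
        merit = np.array([4.0, 2.0, 1.0, 3.0])
        plan = MatingPlan(sires=[1, 2], dams=[10, 11], n_offspring=[1, 1])
        obj = evaluate_plan(plan, G, merit)
        assert obj.gain == pytest.approx(0.5 * (4 + 1) + 0.5 * (2 + 3))
        assert obj.inbreeding == pytest.approx(2 / 2)  # N_c / 2 for G = I

    def test_matches_incidence_matrix_algebra(self):
        rng = stream(9)
        for trial in range(10):
            ids = np.arange(7)
            G = random_grm(ids, rng)
            merit = rng.normal(size=7)
            sires = rng.permutation(3)[:2]
            dams = np.array([3, 4, 5, 6])
            assign = rng.integers(2, size=4)
            plan = MatingPlan(sires=sires[assign], dams=dams, n_offspring=np.ones(4, int))
            D = rng.uniform(0, 1, size=4)
            obj = evaluate_plan(plan, G, merit, D)
            gain, inb = plan_objectives_matrix(plan, G, merit, D)
            assert obj.gain == pytest.approx(gain)
            assert obj.inbreeding == pytest.approx(inb)

    def test_gain_linear_coancestry_superlinear(self):
        # dams 20/21 are genomic clones of 10/11: gain doubles with the
        # mating list, while group coancestry grows faster than linearly
        # because the same sires now cover twice the dams
        ids = np.array([1, 2, 10, 11, 20, 21])
        rng = stream(10)
        base = random_grm(np.array([1, 2, 10, 11]), rng).values
        G = np.zeros((6, 6))
        G[:4, :4] = base
        G[4:, :4] = base[2:4, :]
        G[:4, 4:] = base[:, 2:4]
        G[4:, 4:] = base[2:4, 2:4]
        Gm = RelationshipMatrix(values=G, kind="snp", ids=ids)
        merit = np.array([1.0, -1.0, 2.0, 0.5, 2.0, 0.5])
        single = MatingPlan(sires=[1, 2], dams=[10, 11], n_offspring=[1, 1])
        double = MatingPlan(sires=[1, 2, 1, 2], dams=[10, 11, 20, 21], n_offspring=[1, 1, 1, 1])
        o1 = evaluate_plan(single, Gm, merit)
        o2 = evaluate_plan(double, Gm, merit)
        assert o2.gain == pytest.approx(2 * o1.gain)
        assert o2.inbreeding > 2 * o1.inbreeding

    def test_mating_a_clone_of_the_sire_raises_inbreeding(self):
        # parent 3 is a clone of sire 1 (identical G rows); swapping the dam
        # for the clone raises the within-plan coancestry
        G = np.array(
            [
                [1.2, 0.1, 1.2],
                [0.1, 1.0, 0.1],
                [1.2, 0.1, 1.2],
            ]
        )
        ids = np.array([1, 2, 3])
        Gm = RelationshipMatrix(values=G, kind="snp", ids=ids)
        merit = np.zeros(3)
        unrelated = MatingPlan(sires=[1], dams=[2], n_offspring=[1])
        cloned = MatingPlan(sires=[1], dams=[3], n_offspring=[1])
        assert (
            evaluate_plan(cloned, Gm, merit).inbreeding
            > evaluate_plan(unrelated, Gm, merit).inbreeding
        )


class TestOptimizer:
    def test_matches_exhaustive_enumeration_small_instances(self):
        hits = 0
        trials = 6
        for seed in range(trials):
            rng = stream(200 + seed)
            n_s, n_d = 2 + seed % 2, 4 + seed % 3
            ids = np.arange(n_s + n_d)
            G = random_grm(ids, rng)
            merit = rng.normal(size=n_s + n_d)
            capacity = int(np.ceil(n_d / n_s)) + (seed % 2)
            best_gain, best_inb = enumerate_best_plans(
                ids[:n_s], ids[n_s:], G, merit, capacity
            )
            frontier = optimize_mating(
                ids[:n_s],
                ids[n_s:],
                G,
                merit,
                capacity=capacity,
                ga_pop_size=30,
                n_iter=120,
                seed=seed,
            )
            mg, mi = frontier.max_gain, frontier.min_inbreeding
            if np.isclose(mg.gain, best_gain[0]) and np.isclose(
                mi.inbreeding, best_inb[1]
            ):
                hits += 1
        assert hits == trials

    def test_flat_merit_collapses_gain_dimension(self):
        ids = np.arange(8)
        G = RelationshipMatrix(values=np.eye(8), kind="snp", ids=ids)
        merit = np.full(8, 3.0)
        frontier = optimize_mating(
            ids[:2], ids[2:], G, merit, capacity=4, ga_pop_size=10, n_iter=30, seed=1
        )
        gains = [e.gain for e in frontier.entries]
        assert max(gains) - min(gains) < 1e-9

    def test_plans_feasible_and_frontier_nondominated(self):
        rng = stream(11)
        ids = np.arange(9)
        G = random_grm(ids, rng)
        merit = rng.normal(size=9)
        frontier = optimize_mating(
            ids[:3], ids[3:], G, merit, capacity=3, ga_pop_size=20, n_iter=60, seed=2
        )
        for e in frontier.entries:
            e.plan.validate_capacity(3)
            assert sorted(e.plan.dams.tolist()) == list(range(3, 9))
        for a in frontier.entries:
            for b in frontier.entries:
                if a is b:
                    continue
                assert not (
                    a.gain >= b.gain
                    and a.inbreeding <= b.inbreeding
                    and (a.gain > b.gain or a.inbreeding < b.inbreeding)
                )

    def test_invalid_arguments(self):
        ids = np.arange(4)
        G = RelationshipMatrix(values=np.eye(4), kind="snp", ids=ids)
        with pytest.raises(ValueError, match="infeasible"):
            optimize_mating(ids[:1], ids[1:], G, np.zeros(4), capacity=2, seed=0)
        with pytest.raises(ValueError, match="ga_pop_size"):
            optimize_mating(
                ids[:2], ids[2:], G, np.zeros(4), capacity=2, ga_pop_size=1, seed=0
            )
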