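"""SNP GRM, segment kinship, marker- and pedigree-based inbreeding."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gmatesim.meiosis import RecombinationModel, make_offspring
from gmatesim.population import Population
from gmatesim.relatedness import Pedigree, f_grm, f_ped, grm_vanraden, segment_kinship
from gmatesim.rng import stream

from conftest import random_population
from oracles import random_pedigree, wright_inbreeding


class TestGrmVanraden:
    def test_clone_offdiagonal_equals_diagonal(self):
        rng = stream(1)
        M = rng.binomial(2, 0.5, size=(6, 40))
        M[1] = M[0]
        G = grm_vanraden(M).values
        assert G[0, 1] == pytest.approx(G[0, 0])

    def test_hwe_cohort_mean_diagonal_near_one(self):
        rng = stream(2)
        p = rng.uniform(0.1, 0.9, size=500)
        M = rng.binomial(2, p, size=(1000, 500))
        G = grm_vanraden(M).values
        diag = np.diag(G)
        assert diag.mean() == pytest.approx(1.0, abs=3 * diag.std() / np.sqrt(1000) + 0.01)

    def test_allele_relabeling_invariance(self):
        M = stream(3).binomial(2, 0.4, size=(8, 30))
        G1 = grm_vanraden(M).values
        G2 = grm_vanraden(2 - M).values
        np.testing.assert_allclose(G1, G2, atol=1e-10)

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            grm_vanraden(np.ones((4, 5)) * 2)


class TestFGrm:
    def test_fully_homozygous_at_half_frequency(self):
        # two individuals, opposite homozygotes: p = 0.5 everywhere, F = 1
        M = np.vstack([np.zeros(20), np.full(20, 2.0)])
        np.testing.assert_allclose(f_grm(M), [1.0, 1.0])

    def test_hwe_cohort_mean_near_zero(self):
        rng = stream(4)
        p = rng.uniform(0.2, 0.8, size=400)
        M = rng.binomial(2, p, size=(800, 400))
        F = f_grm(M)
        assert abs(F.mean()) < 3 * F.std() / np.sqrt(800) + 0.01

    @given(
        arrays(np.int8, (6, 15), elements=st.integers(min_value=0, max_value=2))
    )
    def test_relabeling_invariance(self, M):
        p = M.mean(axis=0) / 2
        if not np.any((p > 0) & (p < 1)):
            return
        np.testing.assert_allclose(f_grm(M), f_grm(2 - M), atol=1e-10)

    def test_common_denominator_matches_grm_diagonal(self):
        M = stream(5).binomial(2, stream(6).uniform(0.1, 0.9, 50), size=(30, 50))
        G = grm_vanraden(M).values
        np.testing.assert_allclose(np.diag(G) - 1.0, f_grm(M, per_marker=False), atol=1e-12)


class TestSegmentKinship:
    def test_fully_autozygous_diagonal_is_two(self, small_map):
        h = stream(7).integers(0, 2, size=small_map.n_loci, dtype=np.int8)
        pop = Population(
            haplotypes=np.stack([h, h])[None],
            sex=np.array([0]),
            ids=np.array([0]),
        )
        G = segment_kinship(pop, small_map, min_length_cM=1.0, min_markers=5)
        assert G.values[0, 0] == pytest.approx(2.0)

    def test_opposite_haplotypes_share_nothing(self, small_map):
        L = small_map.n_loci
        a = np.zeros(L, dtype=np.int8)
        b = np.ones(L, dtype=np.int8)
        pop = Population(
            haplotypes=np.stack([np.stack([a, a]), np.stack([b, b])]),
            sex=np.array([0, 1]),
            ids=np.array([0, 1]),
        )
        G = segment_kinship(pop, small_map, min_length_cM=1.0, min_markers=2)
        assert G.values[0, 1] == 0.0
        assert G.values[0, 0] == pytest.approx(2.0)

    def test_threshold_monotonicity(self, small_map):
        pop = random_population(small_map, 8, stream(8), freq=np.full(small_map.n_loci, 0.5))
        loose = segment_kinship(pop, small_map, min_length_cM=0.0, min_markers=1).values
        strict = segment_kinship(pop, small_map, min_length_cM=5.0, min_markers=10).values
        assert np.all(loose >= strict - 1e-12)

    def test_full_sibs_share_more_than_unrelated(self, small_map):
        model = RecombinationModel.from_genome_map(small_map)
        rng = stream(9)
        founders = random_population(small_map, 20, rng, freq=np.full(small_map.n_loci, 0.5))
        sibs, _ = make_offspring(founders.haplotypes[0], founders.haplotypes[1], 6, model, stream(10))
        sib_pop = Population(
            haplotypes=sibs, sex=np.zeros(6, dtype=np.int8), ids=np.arange(6)
        )
        G_unrel = segment_kinship(founders, small_map, min_length_cM=1.0, min_markers=3).values
        G_sib = segment_kinship(sib_pop, small_map, min_length_cM=1.0, min_markers=3).values
        off_u = G_unrel[np.triu_indices(20, k=1)].mean()
        off_s = G_sib[np.triu_indices(6, k=1)].mean()
        assert off_s > off_u


class TestFPed:
    def test_canonical_pedigrees(self):
        # 0,1 founders; 2,3 their full-sib offspring; 4 = 2 x 3
        sire = np.array([-1, -1, 0, 0, 2])
        dam = np.array([-1, -1, 1, 1, 3])
        F = f_ped(sire, dam)
        np.testing.assert_allclose(F, [0, 0, 0, 0, 0.25])
        # half sibs: 3 founders; 3,4 share sire 0; 5 = 3 x 4
        sire = np.array([-1, -1, -1, 0, 0, 3])
        dam = np.array([-1, -1, -1, 1, 2, 4])
        assert f_ped(sire, dam)[5] == pytest.approx(0.125)

    def test_unknown_parent_gives_zero(self):
        sire = np.array([-1, -1, 0])
        dam = np.array([-1, -1, -1])
        assert f_ped(sire, dam)[2] == 0.0

    def test_parent_after_child_rejected(self):
        with pytest.raises(ValueError, match="order"):
            f_ped(np.array([1, -1]), np.array([-1, -1]))

    def test_matches_wright_path_enumeration_on_random_pedigrees(self):
        for seed in range(6):
            sire, dam = random_pedigree(14, stream(100 + seed))
            np.testing.assert_allclose(
                f_ped(sire, dam), wright_inbreeding(sire, dam), atol=1e-12
            )


class TestPedigree:
    def test_append_and_lookup(self):
        ped = Pedigree()
        ped.append([1, 2], [-1, -1], [-1, -1])
        ped.append([3], [1], [2])
        ped.append([4], [1], [2])
        ped.append([5], [3], [4])
        np.testing.assert_allclose(ped.f_of([5, 3, 1]), [0.25, 0.0, 0.0])

    def test_duplicate_and_orphan_rejected(self):
        ped = Pedigree()
        ped.append([1], [-1], [-1])
        with pytest.raises(ValueError, match="duplicate"):
            ped.append([1], [-1], [-1])
        with pytest.raises(ValueError, match="not in pedigree"):
            ped.append([2], [99], [-1])
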