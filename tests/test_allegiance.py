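"""Module allegiance, recruitment/integration, Jaccard, matrix similarity."""

import numpy as np
import pytest

from dynmod.allegiance import (
    AllegianceMatrix,
    NetworkAssignment,
    allegiance_similarity,
    integration,
    interaction,
    jaccard_similarity,
    module_allegiance,
    recruitment,
)
from dynmod.modularity import Partition, PartitionEnsemble


def make_ensemble(rng, n_regions=6, n_layers=4, n_partitions=3, n_modules=3):
    parts = [
        Partition(labels=rng.integers(0, n_modules, (n_layers, n_regions)), quality=0.0)
        for _ in range(n_partitions)
    ]
    return PartitionEnsemble(partitions=parts)


def counting_oracle(ensembles):
    """Triple loop over subjects × partitions × slices."""
    n = ensembles[0].partitions[0].n_regions
    T = np.zeros((n, n))
    C = 0
    for ens in ensembles:
        for p in ens.partitions:
            for l in range(p.n_layers):
                for i in range(n):
                    for j in range(n):
                        T[i, j] += p.labels[l, i] == p.labels[l, j]
                C += 1
    return T / C, T, C


def pmat(P):
    return AllegianceMatrix(P=P, T=P, C=1)


class TestModuleAllegiance:
    def test_constant_partition_gives_block_matrix(self):
        labels = np.tile([0, 0, 1, 1], (3, 1))
        ens = PartitionEnsemble(partitions=[Partition(labels=labels, quality=0.0)])
        A = module_allegiance(ens)
        expected = np.array([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]], float)
        assert np.array_equal(A.P, expected)
        assert A.C == 3

    def test_matches_counting_oracle(self, rng):
        ensembles = [make_ensemble(rng) for _ in range(3)]
        A = module_allegiance(ensembles)
        P_o, T_o, C_o = counting_oracle(ensembles)
        assert np.array_equal(A.P, P_o)
        assert np.array_equal(A.T, T_o)
        assert A.C == C_o

    def test_concatenation_equals_count_weighted_average(self, rng):
        e1, e2 = make_ensemble(rng, n_layers=3), make_ensemble(rng, n_layers=5)
        A1, A2 = module_allegiance(e1), module_allegiance(e2)
        A12 = module_allegiance([e1, e2])
        weighted = (A1.P * A1.C + A2.P * A2.C) / (A1.C + A2.C)
        assert np.allclose(A12.P, weighted)

    def test_mismatched_regions_error(self, rng):
        e1 = make_ensemble(rng, n_regions=6)
        e2 = make_ensemble(rng, n_regions=7)
        with pytest.raises(ValueError, match="mismatch"):
            module_allegiance([e1, e2])

    def test_null_zeroing_keeps_diagonal_and_strong_pairs(self, rng):
        labels = np.tile([0, 0, 1, 1, 2, 2], (4, 1))
        ens = PartitionEnsemble(partitions=[Partition(labels=labels, quality=0.0)] * 3)
        A = module_allegiance(ens, null_zero=True, n_null=500, seed=1)
        assert np.allclose(np.diag(A.P), 1.0)
        assert A.P[0, 1] == 1.0  # always-together pair survives
        assert A.P[0, 2] == 0.0  # never-together pair stays zero

    def test_pair_count_formula(self, rng):
        A = module_allegiance(make_ensemble(rng, n_regions=9))
        assert A.n_pairs == 9 * 8 // 2


class TestInteractionRecruitment:
    def test_all_ones_gives_unit_interaction(self):
        assign = NetworkAssignment(labels=np.array([1, 1, 2, 2]))
        A = pmat(np.ones((4, 4)))
        assert interaction(A, 1, 2, assign) == 1.0
        assert recruitment(A, 1, assign) == 1.0

    def test_identity_p_recruitment_closed_form(self):
        """Off-diagonal co-assignment zero: block mean is m/m² = 1/m."""
        assign = NetworkAssignment(labels=np.array([1, 1, 1, 1]))
        A = pmat(np.eye(4))
        assert recruitment(A, 1, assign) == pytest.approx(0.25)

    def test_matches_summation_oracle(self, rng):
        P = rng.random((8, 8))
        P = 0.5 * (P + P.T)
        labels = rng.integers(1, 4, 8)
        labels[:3] = [1, 2, 3]  # every community nonempty
        assign = NetworkAssignment(labels=labels)
        A = pmat(P)
        for k1 in (1, 2, 3):
            for k2 in (1, 2, 3):
                a = np.flatnonzero(labels == k1)
                b = np.flatnonzero(labels == k2)
                oracle = sum(P[i, j] for i in a for j in b) / (len(a) * len(b))
                assert interaction(A, k1, k2, assign) == pytest.approx(oracle, abs=1e-14)

    def test_empty_community_errors(self):
        assign = NetworkAssignment(labels=np.array([1, 1, 2]))
        with pytest.raises(ValueError, match="empty community"):
            interaction(pmat(np.ones((3, 3))), 1, 5, assign)

    def test_region_reordering_invariance(self, rng):
        P = rng.random((8, 8))
        P = 0.5 * (P + P.T)
        labels = np.array([1, 1, 1, 2, 2, 2, 2, 1])
        perm = rng.permutation(8)
        A, Ap = pmat(P), pmat(P[perm][:, perm])
        r1 = recruitment(A, 1, NetworkAssignment(labels=labels))
        r2 = recruitment(Ap, 1, NetworkAssignment(labels=labels[perm]))
        assert r1 == pytest.approx(r2, abs=1e-14)

    def test_off_diagonal_variant(self):
        assign = NetworkAssignment(labels=np.array([1, 1, 1, 1]))
        A = pmat(np.eye(4))
        assert recruitment(A, 1, assign, include_diagonal=False) == 0.0


class TestIntegration:
    def test_constant_p_normalizes_to_one(self):
        assign = NetworkAssignment(labels=np.array([1, 1, 2, 2]))
        A = pmat(np.full((4, 4), 0.37))
        assert integration(A, 1, 2, assign) == pytest.approx(1.0)

    def test_block_diagonal_gives_zero(self):
        assign = NetworkAssignment(labels=np.array([1, 1, 2, 2]))
        P = np.zeros((4, 4))
        P[:2, :2] = 1
        P[2:, 2:] = 1
        assert integration(pmat(P), 1, 2, assign) == 0.0

    def test_matches_formula_oracle(self, rng):
        P = rng.random((6, 6))
        P = 0.5 * (P + P.T)
        assign = NetworkAssignment(labels=np.array([1, 1, 1, 2, 2, 2]))
        A = pmat(P)
        i12 = interaction(A, 1, 2, assign)
        i11 = interaction(A, 1, 1, assign)
        i22 = interaction(A, 2, 2, assign)
        assert integration(A, 1, 2, assign) == pytest.approx(
            i12 / np.sqrt(i11 * i22), abs=1e-14
        )

    def test_may_exceed_one_without_clamping(self):
        """Strong between-block allegiance with weak within-block
        allegiance drives I' above 1; the value must not be clamped."""
        P = np.full((4, 4), 0.9)
        np.fill_diagonal(P, 1.0)
        P[0, 1] = P[1, 0] = 0.1
        P[2, 3] = P[3, 2] = 0.1
        assign = NetworkAssignment(labels=np.array([1, 1, 2, 2]))
        assert integration(pmat(P), 1, 2, assign) > 1.0

    def test_same_network_errors(self):
        assign = NetworkAssignment(labels=np.array([1, 1, 2, 2]))
        with pytest.raises(ValueError, match="distinct"):
            integration(pmat(np.ones((4, 4))), 1, 1, assign)

    def test_zero_recruitment_errors(self):
        assign = NetworkAssignment(labels=np.array([1, 1, 2, 2]))
        P = np.zeros((4, 4))
        with pytest.raises(ValueError, match="undefined normalization"):
            integration(pmat(P), 1, 2, assign)


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(("a", "b", "c"), ("a", "b", "c"), 100.0),
         (("a", "b"), ("c", "d"), 0.0),
         (("a", "b", "c"), ("b", "c", "d"), 50.0)],
    )
    def test_known_values(self, a, b, expected):
        assert jaccard_similarity(a, b) == expected

    def test_empty_union_errors(self):
        with pytest.raises(ValueError):
            jaccard_similarity([], [])


class TestAllegianceSimilarity:
    def test_identical_matrices_correlate_perfectly(self, rng):
        P = rng.random((6, 6))
        P = 0.5 * (P + P.T)
        assert allegiance_similarity(pmat(P), pmat(P)) == pytest.approx(1.0)

    def test_complement_anticorrelates(self, rng):
        P = rng.random((6, 6))
        P = 0.5 * (P + P.T)
        assert allegiance_similarity(pmat(P), pmat(1 - P)) == pytest.approx(-1.0)

    def test_matches_direct_correlation_oracle(self, rng):
        P1 = rng.random((7, 7)); P1 = 0.5 * (P1 + P1.T)
        P2 = rng.random((7, 7)); P2 = 0.5 * (P2 + P2.T)
        iu = np.triu_indices(7, k=1)
        oracle = np.corrcoef(P1[iu], P2[iu])[0, 1]
        assert allegiance_similarity(pmat(P1), pmat(P2)) == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            allegiance_similarity(pmat(np.ones((4, 4))), pmat(np.eye(4)))


class TestPlantedRecruitment:
    def test_planted_community_beats_random_region_set(self, rng):
        """Recruitment of a genuinely coherent community exceeds that of a
        random equal-size region set in every seeded draw."""
        n = 12
        for seed in range(20):
            r = np.random.default_rng(seed)
            base = np.repeat([0, 1], n // 2)
            parts = []
            for _ in range(3):
                labels = np.tile(base, (4, 1))
                flip = r.random((4, n)) < 0.1  # sparse label noise
                noisy = labels.copy()
                noisy[flip] = r.integers(0, 2, flip.sum())
                parts.append(Partition(labels=noisy, quality=0.0))
            A = module_allegiance(PartitionEnsemble(partitions=parts))
            members = np.flatnonzero(base == 0)
            rand_set = r.choice(n, size=len(members), replace=False)
            lab_planted = np.where(np.isin(np.arange(n), members), 1, 2)
            lab_random = np.where(np.isin(np.arange(n), rand_set), 1, 2)
            rec_planted = recruitment(A, 1, NetworkAssignment(labels=lab_planted))
            rec_random = recruitment(A, 1, NetworkAssignment(labels=lab_random))
            if np.array_equal(np.sort(rand_set), members):
                continue
            assert rec_planted > rec_random
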