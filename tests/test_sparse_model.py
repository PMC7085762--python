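import numpy as np
import pytest
import scipy.sparse as sp

from nlsd.sparse_model import (
    global_influence,
    ksvd_learn,
    omp_encode,
    rarity_scores,
    reconstruct,
    reinforce_dictionary,
)

from .conftest import coherence, low_coherence_dictionary
from .oracles import oracle_global_influence, oracle_rarity, oracle_reinforce


class TestOMP:
    def test_orthonormal_selection(self):
        A = omp_encode(np.array([[0.0], [2.0], [0.0]]), np.eye(3), L=1)
        assert np.array_equal(A.toarray().ravel(), [0.0, 2.0, 0.0])

    def test_zero_signal_gives_zero_code(self):
        A = omp_encode(np.zeros((5, 3)), np.eye(5), L=2)
        assert A.nnz == 0

    def test_planted_sparse_recovery(self, rng):
        # designed well under the mu < 1/(2L-1) exact-recovery regime
        D = low_coherence_dictionary(20, 50, mu=0.2, seed=0, iters=2000)
        assert coherence(D) < 0.3
        support = rng.choice(50, 3, replace=False)
        coefs = rng.uniform(0.5, 2.0, 3) * rng.choice([-1, 1], 3)
        y = D[:, support] @ coefs
        A = omp_encode(y[:, None], D, L=3).toarray().ravel()
        assert set(np.flatnonzero(A)) == set(support)
        assert np.allclose(A[support], coefs, atol=1e-8)

    def test_residual_orthogonal_to_selected_atoms(self, rng):
        D = low_coherence_dictionary(15, 40, mu=0.4, seed=1)
        Y = rng.standard_normal((15, 20))
        A = omp_encode(Y, D, L=4)
        R = Y - D @ A
        Ad = A.toarray()
        for c in range(20):
            for k in np.flatnonzero(np.abs(Ad[:, c]) > 0):
                assert abs(D[:, k] @ R[:, c]) < 1e-8

    def test_L_bounds(self):
        with pytest.raises(ValueError):
            omp_encode(np.ones((3, 1)), np.eye(3), L=4)
        with pytest.raises(ValueError):
            omp_encode(np.ones((3, 1)), np.eye(3), L=0)


class TestKSVD:
    def test_objective_monotone_and_deterministic(self, rng):
        Y = rng.standard_normal((10, 200))
        D1, A1, obj1 = ksvd_learn(Y, K=20, L=3, iters=6, seed=3)
        D2, A2, obj2 = ksvd_learn(Y, K=20, L=3, iters=6, seed=3)
        assert np.array_equal(D1, D2)
        assert (A1 != A2).nnz == 0
        assert obj1 == obj2
        assert all(b <= a * (1 + 1e-12) for a, b in zip(obj1, obj1[1:]))
        assert np.allclose(np.linalg.norm(D1, axis=0), 1.0)

    def test_planted_dictionary_recovery(self, rng):
        """No-noise 3-sparse signals from a planted incoherent dictionary:
        most atoms are recovered up to sign with |cosine| > 0.99."""
        Dtrue = low_coherence_dictionary(16, 24, mu=0.35, seed=7)
        P = 1200
        Y = np.zeros((16, P))
        for c in range(P):
            s = rng.choice(24, 3, replace=False)
            Y[:, c] = Dtrue[:, s] @ (rng.uniform(0.5, 2.0, 3) * rng.choice([-1, 1], 3))
        D, _, _ = ksvd_learn(Y, K=24, L=3, iters=40, seed=11)
        C = np.abs(Dtrue.T @ D)
        hits = sum(1 for k in range(24) if C[k].max() > 0.99)
        assert hits >= 0.9 * 24

    def test_too_few_signals_rejected(self, rng):
        with pytest.raises(ValueError):
            ksvd_learn(rng.standard_normal((5, 10)), K=20, L=2)


class TestInfluenceAndRarity:
    def test_single_atom_usage(self):
        A = sp.csc_matrix(np.vstack([np.ones(4), np.zeros((2, 4))]))
        assert np.array_equal(global_influence(A), [1.0, 0.0, 0.0])

    def test_uniform_usage(self):
        A = sp.csc_matrix(np.eye(4))
        assert np.allclose(global_influence(A), 0.25)

    def test_hand_example(self):
        Ad = np.array([[1.0, 2.0, 0, 0], [0, 0, 3.0, 0], [0, 0, 0, -1.0]])
        gi = global_influence(sp.csc_matrix(Ad))
        assert np.allclose(gi, [0.5, 0.25, 0.25])
        assert np.allclose(gi, oracle_global_influence(Ad))

    def test_all_zero_code_rejected(self):
        with pytest.raises(ValueError):
            global_influence(sp.csc_matrix((3, 4)))

    def test_reinforcement(self):
        D = np.eye(3)
        gi = np.array([0.5, 0.25, 0.25])
        Dp = reinforce_dictionary(D, gi, delta=8.0)
        assert np.allclose(np.linalg.norm(Dp, axis=0), [5.0, 3.0, 3.0])
        assert np.array_equal(reinforce_dictionary(D, gi, 0.0), D)
        assert np.allclose(Dp, oracle_reinforce(D, gi, 8.0))
        with pytest.raises(ValueError):
            reinforce_dictionary(D, gi, delta=-3.0)  # 1 - 1.5 < 0

    def test_rarity_hand_example(self):
        gi = np.array([0.5, 0.25, 0.25])
        A = sp.csc_matrix(np.array([[1.0, 0.0], [0.0, 0.0], [0.3, 0.0]]))
        R = rarity_scores(A, gi)
        assert R[0] == pytest.approx(0.575)
        assert R[1] == 1e-12  # zero code floors at epsilon
        assert np.allclose(rarity_scores(2 * A, gi)[0], 2 * R[0])
        Ad = A.toarray()
        assert np.allclose(R, oracle_rarity(Ad, gi))


class TestReconstruct:
    def test_zero_code(self):
        out = reconstruct(np.eye(4), sp.csc_matrix((4, 6)))
        assert np.array_equal(out, np.zeros((4, 6)))

    def test_matches_dense_product(self, rng):
        D = rng.standard_normal((6, 10))
        Ad = rng.standard_normal((10, 7)) * (rng.random((10, 7)) < 0.3)
        out = reconstruct(D, sp.csc_matrix(Ad), chunk_size=3)
        assert np.allclose(out, D @ Ad, atol=1e-12)

    def test_delta_zero_reinforce_is_noop(self, rng):
        D = rng.standard_normal((5, 8))
        D /= np.linalg.norm(D, axis=0)
        Ad = sp.csc_matrix(rng.standard_normal((8, 4)) * (rng.random((8, 4)) < 0.4))
        gi = np.full(8, 1 / 8)
        assert np.array_equal(
            reconstruct(reinforce_dictionary(D, gi, 0.0), Ad), reconstruct(D, Ad)
        )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            reconstruct(np.eye(3), sp.csc_matrix((4, 2)))
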