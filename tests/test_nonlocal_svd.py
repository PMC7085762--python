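import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from nlsd.nonlocal_svd import (
    SimilarityParams,
    candidate_similar,
    estimate_signal,
    nonlocal_stage,
    similar_signals,
    similarity_threshold,
    svd_denoise_group,
    svd_truncation_rank,
    top_influencer_map,
)

from .oracles import (
    oracle_candidates,
    oracle_estimate,
    oracle_rank,
    oracle_similar,
    oracle_threshold,
    oracle_top_map,
)


def _random_sparse_code(rng, K, P, density=0.25):
    Ad = rng.standard_normal((K, P)) * (rng.random((K, P)) < density)
    return Ad, sp.csc_matrix(Ad)


class TestTopInfluencer:
    def test_abs_max_selected(self):
        A = sp.csc_matrix(np.array([[0.0], [3.0], [-5.0]]))
        assert top_influencer_map(A)[0] == 2

    def test_tie_breaks_to_lowest_row(self):
        A = sp.csc_matrix(np.array([[2.0], [-2.0], [0.0]]))
        assert top_influencer_map(A)[0] == 0

    def test_matches_bruteforce(self, rng):
        Ad, A = _random_sparse_code(rng, 10, 50)
        assert np.array_equal(top_influencer_map(A), oracle_top_map(Ad))


class TestCandidates:
    def test_self_membership(self, rng):
        Ad, A = _random_sparse_code(rng, 8, 30)
        top = top_influencer_map(A)
        for c in range(30):
            assert c in candidate_similar(A, top, c)

    def test_disjoint_atom_groups_never_mix(self):
        Ad = np.zeros((4, 6))
        Ad[0, :3] = 1.0  # group 1 uses atoms {0,1}
        Ad[1, :3] = 0.5
        Ad[2, 3:] = 1.0  # group 2 uses atoms {2,3}
        Ad[3, 3:] = 0.5
        A = sp.csc_matrix(Ad)
        top = top_influencer_map(A)
        for c in range(3):
            assert set(candidate_similar(A, top, c)) <= {0, 1, 2}
        for c in range(3, 6):
            assert set(candidate_similar(A, top, c)) <= {3, 4, 5}

    def test_matches_bruteforce(self, rng):
        Ad, A = _random_sparse_code(rng, 8, 30)
        top = top_influencer_map(A)
        for c in range(30):
            assert set(candidate_similar(A, top, c)) == oracle_candidates(Ad, c)


class TestThreshold:
    def test_interval_endpoints(self):
        p = SimilarityParams(a=0.06, b=0.18, gamma=0.05)
        assert similarity_threshold(0.0, 3, p) == pytest.approx(0.18 * 1.05)
        assert similarity_threshold(3**1.5, 3, p) == pytest.approx(0.12 * 1.05)

    def test_monotone_in_norm_and_gamma(self):
        p0 = SimilarityParams(gamma=0.0)
        p1 = SimilarityParams(gamma=0.2)
        norms = np.linspace(0, 3**1.5, 20)
        T0 = [similarity_threshold(x, 3, p0) for x in norms]
        T1 = [similarity_threshold(x, 3, p1) for x in norms]
        assert np.all(np.diff(T0) < 0)
        assert np.all(np.asarray(T1) > np.asarray(T0))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SimilarityParams(a=0.2, b=0.1)
        with pytest.raises(ValueError):
            SimilarityParams(a=0.0, b=0.1)


class TestSimilarSignals:
    def test_identical_signal_kept_and_degenerate_rule(self):
        Yhat = np.zeros((8, 3))
        Yhat[:, 0] = 1e-9  # near-zero reference
        Yhat[:, 2] = 5.0
        p = SimilarityParams()
        kept = similar_signals(Yhat, np.array([0, 1, 2]), 0, p)
        assert 0 in kept and 1 in kept and 2 not in kept

    def test_matches_bruteforce(self, rng):
        Ad, A = _random_sparse_code(rng, 8, 40)
        Yhat = rng.uniform(0, 1, (8, 40))
        top = top_influencer_map(A)
        p = SimilarityParams(a=0.06, b=0.18, gamma=0.1)
        for c in range(40):
            cand = candidate_similar(A, top, c)
            got = set(similar_signals(Yhat, cand, c, p))
            assert got == oracle_similar(Yhat, Ad, c, 2, 0.06, 0.18, 0.1)


class TestRankRule:
    def test_worked_example(self):
        assert svd_truncation_rank(np.array([10.0, 1.0, 0.1]), 0.5) == 1

    def test_zero_tau_keeps_everything(self):
        assert svd_truncation_rank(np.array([3.0, 2.0, 1.0]), 0.0) == 3

    def test_floor_at_one(self):
        assert svd_truncation_rank(np.array([3.0, 2.0, 1.0]), 100.0) == 1

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(1, 8), st.floats(0, 50), st.integers(0, 10_000))
    def test_matches_enumeration(self, r, tau, seed):
        sv = np.sort(np.random.default_rng(seed).uniform(0, 5, r))[::-1]
        assert svd_truncation_rank(sv, tau) == oracle_rank(sv, tau)


class TestGroupFiltering:
    def test_gamma_zero_identity(self, rng):
        X = rng.standard_normal((27, 12))
        Xhat, k = svd_denoise_group(X, 0.0)
        assert k == 12
        assert np.allclose(Xhat, X, atol=1e-10)

    def test_planted_rank_one_recovered(self, rng):
        u = rng.standard_normal(27)
        v = rng.uniform(1, 2, 40)
        gamma = 0.05
        X = np.outer(u / np.linalg.norm(u) * 20, v)
        X += rng.normal(0, gamma, X.shape)
        Xhat, k = svd_denoise_group(X, gamma, mode="scaled")
        assert k == 1

    def test_eckart_young_identity(self, rng):
        X = rng.standard_normal((10, 7))
        gamma = 0.8
        Xhat, k = svd_denoise_group(X, gamma, mode="literal")
        sv = np.linalg.svd(X, compute_uv=False)
        assert np.linalg.norm(X - Xhat) == pytest.approx(
            np.sqrt(np.sum(sv[k:] ** 2)), abs=1e-9
        )

    def test_estimate_signal(self, rng):
        X = rng.standard_normal((6, 5))
        assert np.allclose(estimate_signal(X), oracle_estimate(X), atol=1e-12)
        x = rng.standard_normal(6)
        assert np.array_equal(estimate_signal(x[:, None]), x)
        assert np.allclose(estimate_signal(np.column_stack([x, -x])), 0.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            svd_denoise_group(np.array([[np.nan, 1.0]]), 0.1)


class TestNonlocalStage:
    def _stage_oracle(self, Yhat, A, gamma, p):
        """Composition of the individually tested operations."""
        top = top_influencer_map(A)
        out = np.empty_like(Yhat)
        n3 = Yhat.shape[0]
        for c in range(Yhat.shape[1]):
            cand = candidate_similar(A, top, c)
            members = similar_signals(Yhat, cand, c, p)
            X = Yhat[:, members]
            tau = gamma**2 * X.size
            Xhat, _ = svd_denoise_group(X, gamma)
            out[:, c] = estimate_signal(Xhat)
        return out

    def test_identical_columns_fixed_point(self, rng):
        y = rng.uniform(0.2, 0.8, 8)
        Yhat = np.tile(y[:, None], (1, 10))
        Ad = np.zeros((4, 10))
        Ad[1] = 1.0
        out = nonlocal_stage(Yhat, sp.csc_matrix(Ad), 0.0,
                             group_cap=None, bucket_cap=None)
        assert np.allclose(out, Yhat, atol=1e-10)

    def test_two_cluster_composition_oracle(self, rng):
        # two well-separated clusters with disjoint atom usage
        base1, base2 = rng.uniform(0.6, 0.9, 8), rng.uniform(0.05, 0.2, 8)
        Yhat = np.column_stack(
            [base1 + rng.normal(0, 0.01, 8) for _ in range(6)]
            + [base2 + rng.normal(0, 0.01, 8) for _ in range(6)]
        )
        Ad = np.zeros((4, 12))
        Ad[0, :6], Ad[1, :6] = 1.0, 0.4
        Ad[2, 6:], Ad[3, 6:] = 1.0, 0.4
        A = sp.csc_matrix(Ad)
        gamma = 0.02
        p = SimilarityParams(gamma=gamma)
        out = nonlocal_stage(Yhat, A, gamma, params=p,
                             group_cap=None, bucket_cap=None)
        expect = self._stage_oracle(Yhat, A, gamma, p)
        assert np.allclose(out, expect, atol=1e-9)
        # sanity: cluster-1 outputs draw only on cluster-1 members
        assert np.all(np.abs(out[:, :6].mean(axis=1) - base1) < 0.1)

    def test_matches_composition_on_random_instance(self, rng):
        Ad, A = _random_sparse_code(rng, 6, 30, density=0.3)
        Yhat = rng.uniform(0, 1, (8, 30))
        gamma = 0.05
        p = SimilarityParams(gamma=gamma)
        out = nonlocal_stage(Yhat, A, gamma, params=p,
                             group_cap=None, bucket_cap=None)
        assert np.allclose(out, self._stage_oracle(Yhat, A, gamma, p), atol=1e-9)

    def test_permutation_equivariance(self, rng):
        Ad, A = _random_sparse_code(rng, 6, 20, density=0.3)
        Yhat = rng.uniform(0, 1, (8, 20))
        gamma = 0.03
        perm = rng.permutation(20)
        out = nonlocal_stage(Yhat, A, gamma, group_cap=None, bucket_cap=None)
        out_p = nonlocal_stage(Yhat[:, perm], sp.csc_matrix(Ad[:, perm]), gamma,
                               group_cap=None, bucket_cap=None)
        assert np.allclose(out_p, out[:, perm], atol=1e-9)

    def test_variance_reduction_on_noisy_copies(self, rng):
        clean = rng.uniform(0.3, 0.7, 27)
        gamma = 0.05
        Yhat = clean[:, None] + rng.normal(0, gamma, (27, 40))
        Ad = np.zeros((3, 40))
        Ad[0] = 1.0
        out = nonlocal_stage(Yhat, sp.csc_matrix(Ad), gamma,
                             group_cap=None, bucket_cap=None)
        mse_in = np.mean((Yhat - clean[:, None]) ** 2)
        mse_out = np.mean((out - clean[:, None]) ** 2)
        assert mse_out < mse_in
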