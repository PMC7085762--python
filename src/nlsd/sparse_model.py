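"""Sparse dictionary model: OMP coding, KSVD learning, atom influence.

The signal matrix Y (n³ × P) is approximated as Y ≈ D A with an overcomplete
dictionary D (n³ × K, unit-norm atoms) and a column-sparse code A (K × P,
at most L nonzeros per column), by minimizing ||Y - DA||_F² subject to the
sparsity constraint (KSVD: alternating OMP coding and per-atom rank-1 SVD
updates).

On top of the plain model sit the atom-weighting operations: the *global
influence* of an atom is the normalized frequency with which it participates
in signal reconstructions; the dictionary is *reinforced* as
D' = D · Diag(1 + δ·GI), amplifying common atoms (edges between tissue
structures) so the subsequent averaging blurs them less; the *rarity score*
of a signal is the dot product of GI with its absolute code, low for unusual
patches, and is used as the aggregation weight.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import scipy.sparse as sp
from sklearn.linear_model import orthogonal_mp_gram

logger = logging.getLogger(__name__)

__all__ = [
    "omp_encode",
    "ksvd_learn",
    "global_influence",
    "reinforce_dictionary",
    "reconstruct",
    "rarity_scores",
]

_NONZERO_TOL = 1e-12  # float noise must not count as atom usage


def omp_encode(Y: np.ndarray, D: np.ndarray, L: int,
               chunk_size: int = 50_000) -> sp.csc_matrix:
    """Sparse-code all columns of Y on dictionary D by batch OMP.

    Greedy orthogonal matching pursuit per column: iteratively select the
    atom with maximal |correlation| with the residual, re-solve least squares
    on the selected support, stop at L atoms (or exact representation).

    Parameters
    ----------
    Y : ndarray, shape (n_features, P)
    D : ndarray, shape (n_features, K), unit-norm atoms
    L : int
        Maximum nonzeros per column; must satisfy 1 <= L <= K.

    Returns
    -------
    scipy.sparse.csc_matrix, shape (K, P)
    """
    K = D.shape[1]
    if not 1 <= L <= K:
        raise ValueError(f"L must be in [1, K={K}], got {L}")
    if Y.shape[0] != D.shape[0]:
        raise ValueError("Y and D row dimensions differ")
    gram = D.T @ D
    blocks = []
    for lo in range(0, Y.shape[1], chunk_size):
        chunk = Y[:, lo : lo + chunk_size]
        Xy = D.T @ chunk
        with warnings.catch_warnings():
            # expected when a signal is exactly representable by < L atoms
            warnings.filterwarnings(
                "ignore", message="Orthogonal matching pursuit ended prematurely"
            )
            coefs = orthogonal_mp_gram(gram, Xy, n_nonzero_coefs=L)
        if coefs.ndim == 1:
            coefs = coefs[:, None]
        blocks.append(sp.csc_matrix(coefs))
    A = sp.hstack(blocks, format="csc") if len(blocks) > 1 else blocks[0]
    A.eliminate_zeros()
    return A


def _init_dictionary(Y: np.ndarray, K: int, rng: np.random.Generator,
                     init: str) -> np.ndarray:
    n_feat, P = Y.shape
    if init == "identity":
        if K != n_feat:
            raise ValueError("identity init requires K == signal dimension")
        return np.eye(n_feat)
    if init != "data":
        raise ValueError(f"unknown dictionary init {init!r}")
    norms = np.linalg.norm(Y, axis=0)
    usable = np.flatnonzero(norms > _NONZERO_TOL)
    if usable.size >= K:
        pick = rng.choice(usable, size=K, replace=False)
    else:  # degenerate input: pad with random directions
        pick = rng.choice(P, size=K, replace=P < K)
    D = Y[:, pick].astype(np.float64, copy=True)
    low = np.linalg.norm(D, axis=0) <= _NONZERO_TOL
    if np.any(low):
        D[:, low] = rng.standard_normal((n_feat, int(low.sum())))
    return D / np.linalg.norm(D, axis=0)


def ksvd_learn(
    Y: np.ndarray,
    K: int,
    L: int,
    iters: int = 10,
    seed: int = 0,
    train_subsample: int | None = None,
    dict_init: str = "data",
    coherence_limit: float = 0.99,
) -> tuple[np.ndarray, sp.csc_matrix, list[float]]:
    """Learn a dictionary by KSVD and return the code of *all* columns of Y.

    Alternates OMP sparse coding with per-atom rank-1 SVD updates computed
    from the restricted residual (atom and its coefficients jointly).  Unused
    atoms and near-duplicate atoms (|cosine| > ``coherence_limit``) are
    replaced by the currently worst-represented training signal each
    iteration.  Training optionally runs on a seeded random subsample of the
    columns; the returned code always covers every column.

    Returns
    -------
    D : ndarray (n_features, K), unit-norm atoms
    A : csc_matrix (K, P), final code of all P columns
    objectives : list of float
        ||Y_train - D A_train||_F² recorded after each sparse-coding step;
        non-increasing by the alternating-minimization construction.
    """
    Y = np.asarray(Y, dtype=np.float64)
    n_feat, P = Y.shape
    if iters < 1:
        raise ValueError("iters must be >= 1")
    if K > P:
        raise ValueError(f"need at least K={K} training signals, got {P}")
    rng = np.random.default_rng(seed)

    if train_subsample is not None and train_subsample < P:
        if train_subsample < K:
            raise ValueError("train_subsample must be >= K")
        train_idx = np.sort(rng.choice(P, size=train_subsample, replace=False))
        Yt = Y[:, train_idx]
        logger.info("KSVD training on %d of %d signals", train_subsample, P)
    else:
        Yt = Y

    D = _init_dictionary(Yt, K, rng, dict_init)
    objectives: list[float] = []
    A = None
    prev_Ad: np.ndarray | None = None
    for _ in range(iters):
        A = omp_encode(Yt, D, L)
        Ad = A.toarray()
        if prev_Ad is not None:
            # Greedy OMP is not an exact minimizer and can occasionally lose
            # to the carried-over code near convergence; keeping the better
            # code per column makes the objective provably non-increasing.
            err_new = np.einsum("ij,ij->j", Yt - D @ Ad, Yt - D @ Ad)
            err_old = np.einsum("ij,ij->j", Yt - D @ prev_Ad, Yt - D @ prev_Ad)
            worse = err_new > err_old
            if np.any(worse):
                Ad[:, worse] = prev_Ad[:, worse]
        res = Yt - D @ Ad
        objectives.append(float(np.einsum("ij,ij->", res, res)))
        pool = iter(np.argsort(-np.einsum("ij,ij->j", res, res)))
        replaced: list[int] = []
        for k in range(K):
            idx = np.flatnonzero(np.abs(Ad[k]) > _NONZERO_TOL)
            if idx.size == 0:
                replaced.append(k)
                continue
            # restricted residual with atom k's contribution restored
            E = Yt[:, idx] - D @ Ad[:, idx] + np.outer(D[:, k], Ad[k, idx])
            U, s, Vt = np.linalg.svd(E, full_matrices=False)
            atom = U[:, 0]
            if atom[np.argmax(np.abs(atom))] < 0:  # deterministic sign
                atom, Vt = -atom, -Vt
            D[:, k] = atom
            Ad[k, idx] = s[0] * Vt[0]
        # replace unused and near-duplicate atoms by poorly represented signals
        G = np.abs(D.T @ D)
        np.fill_diagonal(G, 0.0)
        for k in range(K):
            if k not in replaced and np.any(G[k, :k] > coherence_limit):
                replaced.append(k)
        for k in replaced:
            cand = Yt[:, next(pool)]
            nrm = np.linalg.norm(cand)
            if nrm <= _NONZERO_TOL:
                cand = rng.standard_normal(n_feat)
                nrm = np.linalg.norm(cand)
            D[:, k] = cand / nrm
            Ad[k] = 0.0  # the old coefficients no longer refer to this atom
        prev_Ad = Ad

    A_full = omp_encode(Y, D, L)
    return D, A_full, objectives


def global_influence(A: sp.spmatrix) -> np.ndarray:
    """Per-atom global influence: usage counts of each atom, normalized.

    gi_k = f(d_k) / sum_j f(d_j), where f(d_k) counts the columns of A whose
    coefficient on atom k exceeds the nonzero tolerance.
    """
    A = sp.csr_matrix(A)
    counts = np.asarray(
        (abs(A) > _NONZERO_TOL).sum(axis=1), dtype=np.float64
    ).ravel()
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero code: global influence undefined")
    return counts / total


def reinforce_dictionary(D: np.ndarray, gi: np.ndarray, delta: float = 8.0
                         ) -> np.ndarray:
    """Reinforced dictionary D' = D · Diag(1 + δ·gi).

    The sparse code is *not* recomputed against D'; the reconstruction D'A
    simply amplifies frequently used atoms.  δ may be negative as long as no
    multiplier becomes nonpositive (which would invert or annihilate an atom).
    """
    gi = np.asarray(gi, dtype=np.float64)
    if gi.shape != (D.shape[1],):
        raise ValueError("gi length must equal the atom count")
    mult = 1.0 + delta * gi
    if np.any(mult <= 0):
        raise ValueError("1 + delta*gi must stay positive for every atom")
    return D * mult


def reconstruct(Dprime: np.ndarray, A: sp.spmatrix,
                chunk_size: int = 50_000) -> np.ndarray:
    """Dense reconstruction Ŷ = D'A, computed chunk-wise over columns."""
    if Dprime.shape[1] != A.shape[0]:
        raise ValueError(
            f"shape mismatch: D' has {Dprime.shape[1]} atoms, A has {A.shape[0]} rows"
        )
    A = sp.csc_matrix(A)
    P = A.shape[1]
    out = np.empty((Dprime.shape[0], P))
    for lo in range(0, P, chunk_size):
        hi = min(lo + chunk_size, P)
        out[:, lo:hi] = Dprime @ A[:, lo:hi]
    return out


def rarity_scores(A: sp.spmatrix, gi: np.ndarray, signed: bool = False,
                  floor: float = 1e-12) -> np.ndarray:
    """Rarity score per signal: R_c = <gi, |α_c|>, floored at ``floor``.

    High scores mark frequent signals (built from influential atoms), low
    scores rare ones.  Absolute coefficients are used by default so that
    frequent signals cannot score negative; ``signed=True`` applies the dot
    product to the raw coefficients instead.
    """
    A = sp.csc_matrix(A)
    M = A if signed else abs(A)
    scores = np.asarray(gi @ M).ravel()
    return np.maximum(scores, floor)
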