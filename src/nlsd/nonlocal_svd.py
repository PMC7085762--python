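"""Sparse-code-driven non-local grouping and noise-calibrated SVD filtering.

For each reconstructed signal ŷ_c the *influencer atoms* are the atoms with a
nonzero coefficient in its code α_c.  Candidate similar signals are all
signals whose single most influential atom (largest |coefficient|) is one of
ŷ_c's influencers — similarity is inferred from the sparse code, with no
spatial search window.  Candidates are accepted into the similar-signal set
when their relative distance to the reference falls under a variable
threshold that shrinks for bright references and grows with the noise level:

    ||ŷ_j − ŷ_c|| / ||ŷ_c||  ≤  (b − a·||ŷ_c||/n^{3/2}) · (1 + γ)

(for near-zero references, ||ŷ_c|| ≤ 1e-6, the left side degenerates to
||ŷ_j||).  The group matrix X = [ŷ_c  SS(ŷ_c)] is then low-rank filtered:
the retained rank k is the largest k whose discarded singular-value energy
Σ_{i>k} σ_i² still meets the noise energy τ, and the reference is
re-estimated as the column mean of the truncated reconstruction.

Two calibrations of τ are available: ``literal`` (τ = γ²) and ``scaled``
(τ = γ²·n³·l, the expected Frobenius noise energy of an n³×l matrix with
i.i.d. noise of std γ; default, since the un-scaled threshold is
dimensionally inconsistent with a multi-entry Frobenius norm and truncates
almost nothing on [0,1]-scaled data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityParams",
    "top_influencer_map",
    "candidate_similar",
    "similarity_threshold",
    "similar_signals",
    "svd_truncation_rank",
    "svd_denoise_group",
    "estimate_signal",
    "nonlocal_stage",
]

_ZERO_NORM = 1e-6  # reference-magnitude floor of the degenerate rule
NO_ATOM = -1  # sentinel top-influencer for all-zero codes


@dataclass
class SimilarityParams:
    """Variable-threshold parameters: interval [b-a, b] scaled by (1+gamma)."""

    a: float = 0.06
    b: float = 0.18
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.a < self.b:
            raise ValueError(f"need 0 < a < b, got a={self.a}, b={self.b}")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


def top_influencer_map(A: sp.spmatrix) -> np.ndarray:
    """Row index of the max-|coefficient| entry of each column of A.

    Ties break to the lowest row index; all-zero columns get the sentinel
    ``NO_ATOM`` (-1).
    """
    A = sp.csc_matrix(A)
    P = A.shape[1]
    out = np.full(P, NO_ATOM, dtype=np.int64)
    indptr, indices, data = A.indptr, A.indices, np.abs(A.data)
    for c in range(P):
        lo, hi = indptr[c], indptr[c + 1]
        if hi == lo:
            continue
        vals = data[lo:hi]
        best = vals.max()
        # lowest row index among maxima (csc stores rows sorted per column)
        out[c] = indices[lo + int(np.flatnonzero(vals == best)[0])]
    return out


def influencer_atoms(A: sp.spmatrix, c: int) -> np.ndarray:
    """I(ŷ_c): row indices of nonzero coefficients of column c."""
    A = sp.csc_matrix(A)
    lo, hi = A.indptr[c], A.indptr[c + 1]
    rows = A.indices[lo:hi]
    return rows[np.abs(A.data[lo:hi]) > 0]


def candidate_similar(A: sp.spmatrix, top_map: np.ndarray, c: int) -> np.ndarray:
    """CSS(ŷ_c): signals whose top influencer atom lies in I(ŷ_c).

    A signal with an all-zero code has no influencers; its candidate set is
    just itself.
    """
    I = influencer_atoms(A, c)
    if I.size == 0:
        return np.array([c], dtype=np.int64)
    cand = np.flatnonzero(np.isin(top_map, I))
    if c not in cand:  # c's own top atom is in I(c); guard numeric edge cases
        cand = np.append(cand, c)
    return cand.astype(np.int64)


def similarity_threshold(ref_norm: float, n: int, params: SimilarityParams) -> float:
    """Variable similarity threshold T = (b − a·||ŷ_c||/n^{3/2})·(1+γ).

    ||1_{n³}|| = n^{3/2} is the norm of the all-ones patch, so on intensities
    in [0, 1] the ratio lies in [0, 1] and T in [(b−a), b]·(1+γ); brighter
    references admit less relative difference.  The ratio is clamped at 1 for
    the occasional reconstruction overshoot.
    """
    if ref_norm < 0:
        raise ValueError("ref_norm must be >= 0")
    ratio = min(ref_norm / n**1.5, 1.0)
    return (params.b - params.a * ratio) * (1.0 + params.gamma)


def similar_signals(
    Yhat: np.ndarray,
    candidates: np.ndarray,
    c: int,
    params: SimilarityParams,
    cap: int | None = None,
) -> np.ndarray:
    """SS(ŷ_c): candidates within the variable relative-distance threshold.

    The reference c is always a member.  With ``cap`` set, only the ``cap``
    nearest members (by relative distance, reference first) are kept.
    """
    n3 = Yhat.shape[0]
    yc = Yhat[:, c]
    ref_norm = float(np.linalg.norm(yc))
    T = similarity_threshold(ref_norm, round(n3 ** (1 / 3)), params)
    cand = np.asarray(candidates, dtype=np.int64)
    cand = cand[cand != c]
    diff_norms = np.linalg.norm(Yhat[:, cand] - yc[:, None], axis=0)
    if ref_norm <= _ZERO_NORM:
        rel = np.linalg.norm(Yhat[:, cand], axis=0)
    else:
        rel = diff_norms / ref_norm
    kept = cand[rel <= T]
    if cap is not None and kept.size > cap - 1:
        order = np.argsort(rel[rel <= T], kind="stable")[: cap - 1]
        kept = kept[order]
    return np.concatenate(([c], kept))


def svd_truncation_rank(singular_values: np.ndarray, tau: float) -> int:
    """Largest k whose discarded tail energy Σ_{i>k} σ_i² still reaches τ.

    Values must be sorted descending.  If even the largest possible tail
    (k = 1) falls short of τ, k = 1 is returned (at least one component is
    always kept); k = r means no truncation.
    """
    s = np.asarray(singular_values, dtype=np.float64)
    if s.size == 0:
        raise ValueError("empty singular-value vector")
    sq = s**2
    # tail[k] = sum_{i > k} sigma_i^2 for k = 1..r (tail[r] = 0)
    tails = np.concatenate((np.cumsum(sq[::-1])[::-1][1:], [0.0]))
    ok = np.flatnonzero(tails >= tau)
    return int(ok[-1]) + 1 if ok.size else 1


def svd_denoise_group(
    X: np.ndarray, gamma: float, mode: str = "scaled"
) -> tuple[np.ndarray, int]:
    """Low-rank filter a group matrix X by noise-calibrated SVD truncation.

    τ = γ² in ``literal`` mode, γ²·(rows·cols) in ``scaled`` mode (expected
    Frobenius noise energy).  Returns (X̂ = U Σ_k Vᵀ, k).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be a 2-D matrix with >= 1 column")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    if mode == "literal":
        tau = gamma**2
    elif mode == "scaled":
        tau = gamma**2 * X.size
    else:
        raise ValueError(f"unknown energy-scale mode {mode!r}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = svd_truncation_rank(s, tau)
    Xhat = (U[:, :k] * s[:k]) @ Vt[:k]
    return Xhat, k


def estimate_signal(Xhat: np.ndarray) -> np.ndarray:
    """Re-estimated reference: arithmetic mean of the group's l columns."""
    Xhat = np.asarray(Xhat, dtype=np.float64)
    if Xhat.ndim != 2 or Xhat.shape[1] < 1:
        raise ValueError("Xhat must have at least one column")
    return Xhat.mean(axis=1)


def _bucketize(top_map: np.ndarray, K: int, bucket_cap: int | None,
               rng: np.random.Generator) -> list[np.ndarray]:
    """Candidate bucket per atom: signals with that top influencer.

    Oversized buckets are subsampled (seeded) to ``bucket_cap`` members to
    bound the per-reference candidate pool; with fully overlapped patches a
    uniform background atom can otherwise own most of the volume.
    """
    order = np.argsort(top_map, kind="stable")
    sorted_top = top_map[order]
    buckets: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * K
    starts = np.searchsorted(sorted_top, np.arange(K))
    ends = np.searchsorted(sorted_top, np.arange(K), side="right")
    capped = 0
    for r in range(K):
        b = order[starts[r] : ends[r]]
        if bucket_cap is not None and b.size > bucket_cap:
            b = rng.choice(b, size=bucket_cap, replace=False)
            capped += 1
        buckets[r] = np.sort(b)
    if capped:
        logger.info("subsampled %d oversized candidate buckets", capped)
    return buckets


def nonlocal_stage(
    Yhat: np.ndarray,
    A: sp.spmatrix,
    gamma: float,
    params: SimilarityParams | None = None,
    group_cap: int | None = 96,
    bucket_cap: int | None = 1024,
    mode: str = "scaled",
    seed: int = 0,
) -> np.ndarray:
    """Filter every signal of Ŷ through grouping + SVD truncation + mean.

    Batch (Jacobi-style) semantics: every group is formed against the stage
    input Ŷ, never against already-updated signals, so the result is
    independent of processing order.

    Parameters
    ----------
    Yhat : ndarray (n³, P)
        Reconstructed signals D'A.
    A : sparse (K, P)
        Sparse code driving the grouping.
    gamma : float
        Stabilized noise std on the scale of Yhat.
    group_cap : int or None
        Maximum group size (nearest members kept); None disables.
    bucket_cap : int or None
        Maximum per-atom candidate bucket before seeded subsampling.
    """
    if params is None:
        params = SimilarityParams(gamma=gamma)
    A = sp.csc_matrix(A)
    K, P = A.shape
    if Yhat.shape[1] != P:
        raise ValueError("Yhat and A disagree on the number of signals")
    n3 = Yhat.shape[0]
    n = round(n3 ** (1 / 3))
    rng = np.random.default_rng(seed)

    top_map = top_influencer_map(A)
    buckets = _bucketize(top_map, K, bucket_cap, rng)

    YT = np.ascontiguousarray(Yhat.T)
    sqnorms = np.einsum("ij,ij->i", YT, YT)
    norms = np.sqrt(sqnorms)
    n_pow = n**1.5
    bscale = 1.0 + params.gamma
    out = np.empty_like(Yhat)
    cap_hits = 0
    indptr, indices, data = A.indptr, A.indices, A.data

    for c in range(P):
        lo, hi = indptr[c], indptr[c + 1]
        atoms = indices[lo:hi][np.abs(data[lo:hi]) > 0]
        yc = YT[c]
        if atoms.size == 0:
            out[:, c] = yc
            continue
        if atoms.size == 1:
            cand = buckets[atoms[0]]
        else:
            cand = np.concatenate([buckets[r] for r in atoms])
        cand = cand[cand != c]

        ref_norm = norms[c]
        T = (params.b - params.a * min(ref_norm / n_pow, 1.0)) * bscale
        if cand.size:
            d2 = sqnorms[cand] + sqnorms[c] - 2.0 * (YT[cand] @ yc)
            if ref_norm <= _ZERO_NORM:
                rel = norms[cand]
            else:
                rel = np.sqrt(np.maximum(d2, 0.0)) / ref_norm
            keep = rel <= T
            members = cand[keep]
            if group_cap is not None and members.size > group_cap - 1:
                cap_hits += 1
                sel = np.argpartition(rel[keep], group_cap - 1)[: group_cap - 1]
                members = members[sel]
        else:
            members = cand

        if members.size == 0:
            X = yc[:, None]
        else:
            X = np.empty((n3, members.size + 1))
            X[:, 0] = yc
            X[:, 1:] = YT[members].T

        l = X.shape[1]
        tau = gamma**2 if mode == "literal" else gamma**2 * X.size
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        k = svd_truncation_rank(s, tau)
        # column mean of U Σ_k Vᵀ without forming X̂
        out[:, c] = U[:, :k] @ (s[:k] * Vt[:k].sum(axis=1)) / l

    if cap_hits:
        logger.info("group-size cap hit for %d of %d signals (%.1f%%)",
                    cap_hits, P, 100.0 * cap_hits / P)
    return out
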