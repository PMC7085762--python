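"""Independent brute-force reference implementations used by the tests.

Everything here is written as plain loops straight from the defining
formulas, deliberately ignoring the package's vectorized implementations.
"""

import numpy as np


def oracle_global_influence(Ad: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    K, P = Ad.shape
    f = np.zeros(K)
    for c in range(K):
        for p in range(P):
            if abs(Ad[c, p]) > tol:
                f[c] += 1.0
    return f / f.sum()


def oracle_reinforce(D: np.ndarray, gi: np.ndarray, delta: float) -> np.ndarray:
    out = D.copy()
    for k in range(D.shape[1]):
        out[:, k] = (1.0 + delta * gi[k]) * D[:, k]
    return out


def oracle_rarity(Ad: np.ndarray, gi: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    P = Ad.shape[1]
    return np.array([max(float(gi @ np.abs(Ad[:, c])), floor) for c in range(P)])


def oracle_top_map(Ad: np.ndarray) -> np.ndarray:
    K, P = Ad.shape
    out = np.full(P, -1)
    for c in range(P):
        col = np.abs(Ad[:, c])
        if col.max() == 0:
            continue
        out[c] = int(np.argmax(col))  # argmax takes the lowest index on ties
    return out


def oracle_influencers(Ad: np.ndarray, c: int) -> set[int]:
    return {r for r in range(Ad.shape[0]) if Ad[r, c] != 0}


def oracle_candidates(Ad: np.ndarray, c: int) -> set[int]:
    I = oracle_influencers(Ad, c)
    if not I:
        return {c}
    top = oracle_top_map(Ad)
    return {j for j in range(Ad.shape[1]) if top[j] in I} | {c}


def oracle_threshold(ref_norm: float, n: int, a: float, b: float,
                     gamma: float) -> float:
    ratio = min(ref_norm / n**1.5, 1.0)
    return (b - a * ratio) * (1.0 + gamma)


def oracle_similar(Yhat: np.ndarray, Ad: np.ndarray, c: int, n: int,
                   a: float, b: float, gamma: float) -> set[int]:
    yc = Yhat[:, c]
    nc = float(np.linalg.norm(yc))
    T = oracle_threshold(nc, n, a, b, gamma)
    kept = {c}
    for j in oracle_candidates(Ad, c):
        if j == c:
            continue
        if nc <= 1e-6:
            lhs = float(np.linalg.norm(Yhat[:, j]))
        else:
            lhs = float(np.linalg.norm(Yhat[:, j] - yc)) / nc
        if lhs <= T:
            kept.add(j)
    return kept


def oracle_rank(sv: np.ndarray, tau: float) -> int:
    r = len(sv)
    best = 1
    for k in range(1, r + 1):
        tail = sum(float(s) ** 2 for s in sv[k:])
        if tail >= tau:
            best = k
    return best


def oracle_estimate(Xhat: np.ndarray) -> np.ndarray:
    l = Xhat.shape[1]
    acc = np.zeros(Xhat.shape[0])
    for i in range(l):
        acc += Xhat[:, i]
    return acc / l


def oracle_aggregate(signals_Y: np.ndarray, weights: np.ndarray, n: int,
                     stride: int, shape: tuple[int, int, int]) -> np.ndarray:
    """Per-voxel weighted mean over covering patches, fully looped.

    Columns follow the package convention: corners in C order over the corner
    grid, within-patch voxels first-axis-fastest.
    """
    grid = [(s - n) // stride + 1 for s in shape]
    num = np.zeros(shape)
    den = np.zeros(shape)
    for p in range(signals_Y.shape[1]):
        gi_, gj, gk = np.unravel_index(p, grid)
        ox, oy, oz = gi_ * stride, gj * stride, gk * stride
        for k in range(n):
            for j in range(n):
                for i in range(n):
                    val = signals_Y[i + j * n + k * n * n, p]
                    num[ox + i, oy + j, oz + k] += weights[p] * val
                    den[ox + i, oy + j, oz + k] += weights[p]
    out = np.zeros(shape)
    mask = den > 0
    out[mask] = num[mask] / den[mask]
    return out
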