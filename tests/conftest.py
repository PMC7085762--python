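import numpy as np
import pytest

from nlsd import PhantomSpec, make_phantom


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom32():
    return make_phantom(PhantomSpec(shape=(32, 32, 32), seed=7))


@pytest.fixture(scope="session")
def phantom48():
    return make_phantom(PhantomSpec(shape=(48, 48, 48), seed=7))


def low_coherence_dictionary(n_feat: int, K: int, mu: float = 0.3,
                             seed: int = 0, iters: int = 500) -> np.ndarray:
    """Unit-norm dictionary with mutual coherence <= mu, by alternating
    Gram-clipping and rank-n_feat projection (incoherent frame design)."""
    rng = np.random.default_rng(seed)
    D = rng.standard_normal((n_feat, K))
    D /= np.linalg.norm(D, axis=0)
    target = mu * 0.95
    for _ in range(iters):
        G = D.T @ D
        off = np.abs(G - np.eye(K))
        if off.max() <= mu:
            break
        G = np.clip(G, -target, target)
        np.fill_diagonal(G, 1.0)
        w, V = np.linalg.eigh(G)
        w = np.maximum(w[-n_feat:], 0.0)
        D = (V[:, -n_feat:] * np.sqrt(w)).T
        D /= np.linalg.norm(D, axis=0)
    return D


def coherence(D: np.ndarray) -> float:
    G = np.abs(D.T @ D)
    np.fill_diagonal(G, 0.0)
    return float(G.max())
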