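"""Rician noise simulation, estimation, and variance stabilization.

Magnitude MR data corrupted in the complex domain by zero-mean Gaussian noise
of std sigma follow a Rice distribution whose noise std depends on the
underlying signal.  The variance-stabilizing transform (VST) implemented here
is a monotone mapping f, tabulated numerically from the Rice mean m(u) and
std s(u), such that stabilized samples f(z) have (approximately) constant std
gamma for every underlying magnitude u.  The first-order stabilizer
f'(t) = gamma / s(m^-1(t)) is refined by a fixed-point iteration that
measures the conditional std of f(z) by quadrature over the Rice density and
rescales the slope until the std is flat; gamma is normalized so f(z) ~ z at
high SNR, hence gamma == sigma in input units.

Two inverses are provided: the algebraic inverse f^-1 (exact round-trip
identity on deterministic inputs) and the exact-unbiased inverse that maps
the expected stabilized value E[f(z)|u] back to the clean magnitude u,
removing the Rician bias of denoised estimates.  Everything is tabulated once
in sigma=1 units and rescaled, so no per-sigma tables are needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.integrate import cumulative_trapezoid
from scipy.special import i0e, i1e

from .volume_io import Volume

__all__ = [
    "NoiseParams",
    "add_rician_noise",
    "estimate_noise",
    "vst_forward",
    "vst_inverse",
    "rice_mean",
    "rice_std",
    "rice_pdf",
]


@dataclass
class NoiseParams:
    """Rician noise description: absolute sigma, fractional sigma, VST gamma."""

    sigma: float
    sigma_fraction: float | None = None
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.gamma is not None and self.gamma < 0:
            raise ValueError("gamma must be >= 0")


# ---------------------------------------------------------------------------
# Rice distribution moments and density (sigma = 1 units), via exponentially
# scaled Bessel functions for numerical stability at high SNR.
# ---------------------------------------------------------------------------

def rice_mean(u: np.ndarray | float) -> np.ndarray:
    """E[z] for z ~ Rice(u, 1): sqrt(pi/2) * L_{1/2}(-u^2/2)."""
    u = np.asarray(u, dtype=np.float64)
    t = u**2 / 4.0
    lag = (1.0 + 2.0 * t) * i0e(t) + 2.0 * t * i1e(t)
    return np.sqrt(np.pi / 2.0) * lag


def rice_std(u: np.ndarray | float) -> np.ndarray:
    """std of z ~ Rice(u, 1), from E[z^2] = u^2 + 2."""
    u = np.asarray(u, dtype=np.float64)
    var = u**2 + 2.0 - rice_mean(u) ** 2
    return np.sqrt(np.maximum(var, 0.0))


def rice_pdf(z: np.ndarray, u: np.ndarray | float) -> np.ndarray:
    """Rice(u, 1) density, stable for large z*u: z*exp(-(z-u)^2/2)*i0e(z*u)."""
    z = np.asarray(z, dtype=np.float64)
    return z * np.exp(-0.5 * (z - u) ** 2) * i0e(z * u)


# ---------------------------------------------------------------------------
# Tabulated stabilizer (built once, sigma = 1 units)
# ---------------------------------------------------------------------------

_U_MAX = 40.0
_Z_MAX = 48.0


class _Stabilizer:
    """Numerically tabulated VST for Rice(u, 1) data, gamma = 1."""

    def __init__(self, n_iter: int = 16) -> None:
        u = np.concatenate(
            [np.linspace(0.0, 12.0, 601), np.linspace(12.05, _U_MAX, 560)]
        )
        m, s = rice_mean(u), rice_std(u)
        z = np.linspace(0.0, _Z_MAX, 4801)
        fp = 1.0 / np.interp(z, m, s, left=s[0], right=1.0)
        f = cumulative_trapezoid(fp, z, initial=0.0)
        for _ in range(n_iter):
            _, std_u = self._cond_moments(z, f, u)
            fp = fp / np.interp(z, m, std_u, left=std_u[0], right=1.0)
            fp /= fp[-1]  # asymptotic slope 1 -> gamma = sigma
            f = cumulative_trapezoid(fp, z, initial=0.0)
        self.z_tab, self.f_tab = z, f
        ef, _ = self._cond_moments(z, f, u)
        self.u_tab, self.ef_tab = u, ef

    @staticmethod
    def _cond_moments(z_tab, f_tab, u):
        """E and std of f(z) given u, by quadrature over the Rice density."""
        lo = np.maximum(u - 8.0, 0.0)
        hi = u + 8.0
        t = np.linspace(0.0, 1.0, 801)
        Z = lo[:, None] + (hi - lo)[:, None] * t[None, :]
        pdf = rice_pdf(Z, u[:, None])
        fz = np.interp(Z, z_tab, f_tab)
        norm = np.trapezoid(pdf, Z, axis=1)
        e1 = np.trapezoid(pdf * fz, Z, axis=1) / norm
        e2 = np.trapezoid(pdf * fz**2, Z, axis=1) / norm
        return e1, np.sqrt(np.maximum(e2 - e1**2, 0.0))

    def forward(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=np.float64)
        out = np.interp(z, self.z_tab, self.f_tab)
        high = z > self.z_tab[-1]  # linear continuation, slope 1
        if np.any(high):
            out = np.where(high, self.f_tab[-1] + (z - self.z_tab[-1]), out)
        return out

    def inverse_algebraic(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=np.float64)
        out = np.interp(y, self.f_tab, self.z_tab)
        high = y > self.f_tab[-1]
        if np.any(high):
            out = np.where(high, self.z_tab[-1] + (y - self.f_tab[-1]), out)
        return np.maximum(out, 0.0)

    def inverse_unbiased(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=np.float64)
        out = np.interp(y, self.ef_tab, self.u_tab)
        high = y > self.ef_tab[-1]
        if np.any(high):
            out = np.where(high, self.u_tab[-1] + (y - self.ef_tab[-1]), out)
        return np.maximum(out, 0.0)


_STABILIZER: _Stabilizer | None = None


def get_stabilizer() -> _Stabilizer:
    global _STABILIZER
    if _STABILIZER is None:
        _STABILIZER = _Stabilizer()
    return _STABILIZER


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def add_rician_noise(
    vol: Volume, sigma: float, seed: int | np.random.Generator = 0
) -> Volume:
    """Corrupt a clean magnitude volume with Rician noise of parameter sigma.

    Each voxel u becomes sqrt((u + n1)^2 + n2^2) with n1, n2 independent
    zero-mean Gaussians of std sigma; deterministic for a fixed seed.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return vol.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=vol.shape)
    n2 = rng.normal(0.0, sigma, size=vol.shape)
    return vol.with_data(np.hypot(vol.data + n1, n2))


def estimate_noise(vol: Volume) -> float:
    """Estimate the noise std sigma of a corrupted volume (input units).

    Median absolute deviation of the finest-scale wavelet detail (diagonal
    HHH band) coefficients, scaled by 1/0.6745.  Coefficients are restricted
    to foreground regions (approximation band above its Otsu threshold) where
    the Rician noise std approaches sigma; in background regions the magnitude
    noise is Rayleigh-deflated and would bias the estimate low.  A constant
    volume returns 0.
    """
    data = vol.data
    if data.size < 1000:
        raise ValueError("volume too small for noise estimation (< 1000 voxels)")
    if np.ptp(data) == 0:
        return 0.0
    coeffs = pywt.dwtn(data, "db1")
    detail = coeffs["ddd"].ravel()
    approx = coeffs["aaa"].ravel() / (2.0 ** 1.5)  # back to intensity scale
    from skimage.filters import threshold_otsu

    try:
        thr = threshold_otsu(approx)
        mask = approx > thr
    except ValueError:  # single-valued approximation band
        mask = np.ones_like(approx, dtype=bool)
    if mask.sum() < 500:
        mask = np.ones_like(approx, dtype=bool)
    mad = np.median(np.abs(detail[mask]))
    return float(mad / 0.6745)


def vst_forward(vol: Volume, sigma: float) -> tuple[Volume, float]:
    """Apply the variance-stabilizing transform.

    Returns the stabilized volume and gamma, the (approximately constant) std
    of stabilized noise.  With the high-SNR normalization f(z) ~ z, gamma
    equals sigma in input intensity units.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    stab = get_stabilizer()
    return vol.with_data(sigma * stab.forward(vol.data / sigma)), float(sigma)


def vst_inverse(vol_stab: Volume, sigma: float, unbiased: bool = True) -> Volume:
    """Map a stabilized (denoised) volume back to the magnitude domain.

    With ``unbiased=True`` (default, used by the denoising pipeline) the
    exact-unbiased inverse is applied: the stabilized value is treated as an
    estimate of E[f(z)|u] and mapped to the clean magnitude u, removing the
    Rician bias.  With ``unbiased=False`` the algebraic inverse f^-1 is
    applied, which makes vst_inverse(vst_forward(v)) the identity on
    deterministic input.  Nonpositive stabilized values map to 0.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    stab = get_stabilizer()
    y = vol_stab.data / sigma
    inv = stab.inverse_unbiased(y) if unbiased else stab.inverse_algebraic(y)
    return vol_stab.with_data(sigma * inv)


def resolve_sigma(
    vol: Volume, sigma: float | None = None, sigma_pct: float | None = None
) -> NoiseParams:
    """Resolve an absolute or percent-of-max noise level for a volume."""
    if (sigma is None) == (sigma_pct is None):
        raise ValueError("specify exactly one of sigma, sigma_pct")
    peak = float(vol.data.max())
    if sigma is None:
        sigma = sigma_pct / 100.0 * peak
    return NoiseParams(sigma=float(sigma),
                       sigma_fraction=float(sigma) / peak if peak > 0 else None)
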