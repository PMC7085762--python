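"""PSNR and SSIM quality metrics over 3-D volumes.

PSNR uses the maximum of the clean reference as its peak by default, matching
the convention of specifying noise as a percentage of the maximum intensity.
SSIM is the Gaussian-weighted structural similarity (window std 1.5, 11-voxel
support, Wang constants K1=0.01, K2=0.03) computed directly over 3-D windows;
a slice-wise 2-D mode is available for comparison with 2-D conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume_io import Volume

__all__ = ["QualityReport", "psnr", "ssim", "evaluate"]

_SSIM_SIGMA = 1.5
_SSIM_TRUNCATE = 3.5  # radius 5 -> 11-sample support
_K1, _K2 = 0.01, 0.03


@dataclass
class QualityReport:
    psnr_db: float
    ssim: float
    peak: float
    ssim_params: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _as_array(v) -> np.ndarray:
    return v.data if isinstance(v, Volume) else np.asarray(v, dtype=np.float64)


def psnr(ref, test, peak: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB: 10*log10(peak^2 / MSE).

    ``peak`` defaults to the maximum of ``ref``.  Identical inputs return
    ``inf``.
    """
    ref, test = _as_array(ref), _as_array(test)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    if peak is None:
        peak = float(ref.max())
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak**2 / mse)


def _ssim_nd(x: np.ndarray, y: np.ndarray, data_range: float) -> float:
    filt = lambda a: gaussian_filter(a, _SSIM_SIGMA, truncate=_SSIM_TRUNCATE,
                                     mode="reflect")
    ux, uy = filt(x), filt(y)
    # Gaussian-weighted (population) moments; no sample-covariance correction
    vx = filt(x * x) - ux * ux
    vy = filt(y * y) - uy * uy
    vxy = filt(x * y) - ux * uy
    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux**2 + uy**2 + c1) * (vx + vy + c2)
    )
    pad = int(_SSIM_TRUNCATE * _SSIM_SIGMA + 0.5)
    interior = tuple(slice(pad, max(n - pad, pad + 1)) for n in s.shape)
    return float(s[interior].mean(dtype=np.float64))


def ssim(ref, test, data_range: float | None = None,
         mode: str = "3d") -> float:
    """Mean structural similarity between two volumes.

    Parameters
    ----------
    ref, test : Volume or ndarray
        Same-shape inputs.
    data_range : float, optional
        Dynamic range; defaults to max(ref) - min(ref).
    mode : {'3d', 'slice'}
        Full 3-D windows (default), or 2-D windows averaged across the last
        axis.
    """
    ref, test = _as_array(ref), _as_array(test)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    if data_range is None:
        data_range = float(ref.max() - ref.min())
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    if mode == "3d":
        return _ssim_nd(ref, test, data_range)
    if mode == "slice":
        vals = [_ssim_nd(ref[..., k], test[..., k], data_range)
                for k in range(ref.shape[-1])]
        return float(np.mean(vals))
    raise ValueError(f"unknown mode {mode!r}")


def evaluate(ref, test, peak: float | None = None,
             mode: str = "3d") -> QualityReport:
    """PSNR + SSIM report for a denoised volume against its clean reference."""
    ref_a = _as_array(ref)
    peak_val = float(ref_a.max()) if peak is None else float(peak)
    return QualityReport(
        psnr_db=psnr(ref, test, peak=peak_val),
        ssim=ssim(ref, test, mode=mode),
        peak=peak_val,
        ssim_params={"mode": mode, "sigma": _SSIM_SIGMA, "win": 11,
                     "K1": _K1, "K2": _K2},
    )
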