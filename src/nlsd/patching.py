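"""Overlapped n×n×n sub-volume extraction and weighted re-aggregation.

A volume is decomposed into all fully interior n×n×n sub-volumes on a regular
corner grid (stride 1 by default, i.e. fully overlapped).  Each sub-volume is
vectorized into a column of the signal matrix Y (n³ × P).  Conventions, fixed
so the column ↔ sub-volume mapping is reproducible:

* corners are enumerated in lexicographic order of (i, j, k), first axis
  slowest (C order over the corner grid);
* within a patch, voxels are vectorized first-axis-fastest (Fortran order).

Aggregation inverts the decomposition: every voxel is the rarity-weighted mean
of the values proposed by all patches containing it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .volume_io import Volume

logger = logging.getLogger(__name__)

__all__ = ["PatchGeometry", "SignalMatrix", "extract_patches", "aggregate_patches"]


@dataclass(frozen=True)
class PatchGeometry:
    """Geometry of an overlapped patch decomposition."""

    n: int
    stride: int
    volume_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("patch edge n must be >= 2")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if any(self.n > s for s in self.volume_shape):
            raise ValueError(
                f"patch edge {self.n} exceeds volume shape {self.volume_shape}"
            )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """Patch count per axis: floor((len - n)/stride) + 1."""
        return tuple((s - self.n) // self.stride + 1 for s in self.volume_shape)

    @property
    def n_patches(self) -> int:
        g = self.grid_shape
        return g[0] * g[1] * g[2]

    def corner(self, index: int) -> tuple[int, int, int]:
        """Corner voxel of the ``index``-th patch in lexicographic order."""
        i, j, k = np.unravel_index(index, self.grid_shape)
        return (i * self.stride, j * self.stride, k * self.stride)


@dataclass
class SignalMatrix:
    """n³ × P matrix of vectorized sub-volume signals plus its geometry."""

    Y: np.ndarray
    geometry: PatchGeometry

    def __post_init__(self) -> None:
        n3 = self.geometry.n**3
        if self.Y.shape != (n3, self.geometry.n_patches):
            raise ValueError(
                f"signal matrix shape {self.Y.shape} inconsistent with "
                f"geometry ({n3}, {self.geometry.n_patches})"
            )

    @property
    def n_signals(self) -> int:
        return self.Y.shape[1]


def extract_patches(vol: Volume | np.ndarray, n: int, stride: int = 1) -> SignalMatrix:
    """Decompose a volume into the matrix Y of overlapped sub-volume signals."""
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol, dtype=np.float64)
    geom = PatchGeometry(n=n, stride=stride, volume_shape=data.shape)
    win = sliding_window_view(data, (n, n, n))[::stride, ::stride, ::stride]
    # corner grid in C order; within-patch axes reversed for first-axis-fastest
    cols = win.transpose(0, 1, 2, 5, 4, 3).reshape(geom.n_patches, n**3)
    return SignalMatrix(Y=np.ascontiguousarray(cols.T), geometry=geom)


def aggregate_patches(
    signals: SignalMatrix,
    weights: np.ndarray | None = None,
    geometry: PatchGeometry | None = None,
) -> Volume:
    """Recompose a volume as the per-voxel weighted mean over covering patches.

    Each voxel v is sum_i R_i * v_i / sum_i R_i over the patches i containing
    it, v_i being the value patch i proposes for v.  Voxels whose covering
    patches all carry zero weight fall back to the unweighted mean (logged);
    voxels covered by no patch (possible at stride > 1) are set to 0.
    """
    geom = geometry if geometry is not None else signals.geometry
    P = geom.n_patches
    if weights is None:
        weights = np.ones(P)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (P,):
        raise ValueError(f"weights must have length {P}")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")

    n, stride = geom.n, geom.stride
    gx, gy, gz = geom.grid_shape
    # columns back to per-corner-grid patch stacks: (gx, gy, gz, n, n, n)
    patches = signals.Y.T.reshape(gx, gy, gz, n, n, n).transpose(0, 1, 2, 5, 4, 3)
    wgrid = weights.reshape(gx, gy, gz)

    def offset_slices():
        for a in range(n):
            for b in range(n):
                for c in range(n):
                    sl = tuple(
                        slice(o, o + (g - 1) * stride + 1, stride)
                        for o, g in zip((a, b, c), (gx, gy, gz))
                    )
                    yield sl, patches[:, :, :, a, b, c]

    # Reference proposal per voxel (first covering patch).  Accumulating
    # weighted deviations from it instead of raw values keeps the weighted
    # mean exactly equal to the common value when all proposals agree, so
    # aggregate(extract(V)) reproduces V bit-exactly.
    ref = np.full(geom.volume_shape, np.nan)
    for sl, contrib in offset_slices():
        sub = ref[sl]
        fresh = np.isnan(sub)
        sub[fresh] = contrib[fresh]
        ref[sl] = sub

    num = np.zeros(geom.volume_shape)
    den = np.zeros(geom.volume_shape)
    cnt = np.zeros(geom.volume_shape)
    unum = np.zeros(geom.volume_shape)
    for sl, contrib in offset_slices():
        dev = contrib - ref[sl]
        num[sl] += wgrid * dev
        den[sl] += wgrid
        cnt[sl] += 1.0
        unum[sl] += dev

    out = np.zeros(geom.volume_shape)
    covered = cnt > 0
    ok = den > 0
    out[ok] = ref[ok] + num[ok] / den[ok]
    zero_w = (~ok) & covered
    if np.any(zero_w):
        logger.warning(
            "%d voxels covered only by zero-weight patches; uniform fallback",
            int(zero_w.sum()),
        )
        out[zero_w] = ref[zero_w] + unum[zero_w] / cnt[zero_w]
    return Volume(np.maximum(out, 0.0))
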