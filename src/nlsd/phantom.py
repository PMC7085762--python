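"""Seeded synthetic 3-D phantoms with anatomical-like piecewise structure.

The generator builds nested ellipsoidal "tissue" compartments over a dark
exterior, with Gaussian-tapered boundaries, mimicking the tissue-contrast
plateaus and thin high-contrast interfaces of simulated brain volumes.  Two
congruent satellite ellipsoids are always present so the volume is
self-similar: a patch inside one has a genuinely non-local twin inside the
other, which is the structure non-local grouping exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume_io import Volume

__all__ = ["PhantomSpec", "make_phantom"]


@dataclass
class PhantomSpec:
    """Configuration of the synthetic phantom.

    Attributes
    ----------
    shape : tuple of int
        Volume shape; each axis must be >= 16.
    n_structures : int
        Number of nested ellipsoidal compartments (>= 1); with the background
        this gives at least two distinct intensity levels.
    intensity_levels : list of float, optional
        Plateau intensities in [0, 1], outermost first.  Derived from
        ``n_structures`` if omitted.
    edge_smoothing : float
        Std (voxels) of the Gaussian taper applied to boundaries.
    seed : int
        Seed controlling ellipsoid placement jitter.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    n_structures: int = 4
    intensity_levels: list[float] | None = None
    edge_smoothing: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 16 for s in self.shape):
            raise ValueError(f"shape must be 3 axes, each >= 16, got {self.shape}")
        if self.n_structures < 1:
            raise ValueError("n_structures must be >= 1")
        if self.intensity_levels is None:
            # plateaus spread over [0.35, 0.95]: distinct tissue-like contrasts
            self.intensity_levels = list(
                np.linspace(0.35, 0.95, self.n_structures)
            )
        if len(self.intensity_levels) < self.n_structures:
            raise ValueError("need one intensity level per structure")
        if any(not 0.0 <= v <= 1.0 for v in self.intensity_levels):
            raise ValueError("intensity levels must lie in [0, 1]")
        if self.edge_smoothing < 0:
            raise ValueError("edge_smoothing must be >= 0")


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return q <= 1.0


def make_phantom(spec: PhantomSpec) -> Volume:
    """Generate a deterministic piecewise-smooth phantom volume in [0, 1].

    Returns
    -------
    Volume
        Nested ellipsoids at the configured plateau intensities over a dark
        exterior, plus two congruent satellite ellipsoids, with boundaries
        tapered by a Gaussian of std ``spec.edge_smoothing`` voxels.
    """
    rng = np.random.default_rng(spec.seed)
    shape = np.asarray(spec.shape, dtype=float)
    vol = np.full(spec.shape, 0.02)  # dark exterior, not exactly zero

    center = shape / 2.0
    outer = shape * 0.42
    for i in range(spec.n_structures):
        shrink = 1.0 - 0.8 * i / max(spec.n_structures, 1)
        jitter = rng.uniform(-0.02, 0.02, size=3) * shape
        axes = np.maximum(outer * shrink, 2.0)
        mask = _ellipsoid_mask(spec.shape, center + jitter * (i > 0), axes)
        vol[mask] = spec.intensity_levels[i]

    # Two congruent satellites on opposite sides: distant self-similar
    # structure for the non-local grouping to find.
    sat_axes = np.maximum(shape * 0.08, 2.0)
    bright = max(spec.intensity_levels)
    for sign in (-1.0, 1.0):
        c = center + sign * shape * np.array([0.30, 0.30, 0.0])
        vol[_ellipsoid_mask(spec.shape, c, sat_axes)] = bright

    if spec.edge_smoothing > 0:
        vol = gaussian_filter(vol, spec.edge_smoothing, mode="nearest")
    return Volume(np.clip(vol, 0.0, 1.0))
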