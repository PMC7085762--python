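"""Reading and writing 3-D magnitude volumes.

Supported containers: NIfTI-1 (``.nii`` / ``.nii.gz``, via nibabel) and a raw
fallback (little-endian float64 ``.raw`` plus a JSON sidecar holding shape and
spacing).  All data are held in float64 internally regardless of the on-disk
dtype; magnitude images are nonnegative by definition, so negative intensities
(possible from scanner export pipelines) are clamped to zero with a logged
count.

Indices are 0-based and axes follow file axis order; no reorientation is
performed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["Volume", "read_volume", "write_volume"]


@dataclass
class Volume:
    """A 3-D nonnegative scalar field with optional spatial metadata.

    Parameters
    ----------
    data : ndarray
        3-D array of voxel intensities; cast to float64.
    spacing : tuple of float, optional
        Voxel size along each axis in mm.  Defaults to isotropic 1 mm.
    affine : ndarray, optional
        4x4 voxel-to-world matrix, preserved on round-trip.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected a 3-D volume, got {self.data.ndim} axes "
                f"with shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing,
                      None if self.affine is None else self.affine.copy())

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same metadata, new voxel data."""
        return Volume(np.asarray(data, dtype=np.float64), self.spacing,
                      None if self.affine is None else self.affine.copy())


def _clamp_negative(data: np.ndarray, clamp: bool) -> np.ndarray:
    neg = int(np.count_nonzero(data < 0))
    if neg:
        if not clamp:
            raise ValueError(f"volume contains {neg} negative values")
        logger.warning("clamped %d negative voxels to 0", neg)
        data = np.maximum(data, 0.0)
    return data


def read_volume(path: str | Path, clamp_negative: bool = True) -> Volume:
    """Read a 3-D volume from NIfTI-1 or the raw/JSON fallback container.

    Parameters
    ----------
    path : path-like
        ``.nii`` / ``.nii.gz`` file, or a ``.raw`` file with a ``.json``
        sidecar next to it.
    clamp_negative : bool
        Clamp negative intensities to 0 (with a logged count) instead of
        raising.

    Returns
    -------
    Volume
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix == ".raw":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing JSON sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        data = np.fromfile(path, dtype="<f8").reshape(meta["shape"])
        if data.ndim != 3:
            raise ValueError(f"expected a 3-D image, got {data.ndim} axes")
        data = _clamp_negative(data, clamp_negative)
        return Volume(data, tuple(meta.get("spacing", (1.0, 1.0, 1.0))))

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(
            f"expected a 3-D image, got {data.ndim} axes with shape {data.shape}"
        )
    data = _clamp_negative(data, clamp_negative)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data, spacing, affine=np.asarray(img.affine, dtype=np.float64))


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume so that :func:`read_volume` round-trips it exactly.

    Data are stored as float64; NIfTI spacing and affine are preserved.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"directory {path.parent} does not exist")
    if path.suffix == ".raw":
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps({"shape": list(vol.shape),
                                       "spacing": list(vol.spacing)}))
        vol.data.astype("<f8").tofile(path)
        return
    affine = vol.affine
    if affine is None:
        affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float64), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
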