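"""Volume container and NIfTI-1 I/O.

A :class:`Volume` is one 3D echo-planar (or anatomical) grid together with
its voxel-to-world affine and its 0-based acquisition index in the session.
All pipeline stages operate on float64 data regardless of the on-disk dtype.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "read_volume", "write_volume", "VolumeFormatError"]

# dtypes we round-trip bit-exactly through NIfTI-1
_SUPPORTED_DTYPES = (
    np.uint8, np.int16, np.int32, np.float32, np.float64,
)


class VolumeFormatError(ValueError):
    """Raised for files the streaming pipeline cannot consume (4D, odd dtypes)."""


@dataclass
class Volume:
    """One 3D voxel grid with spatial metadata and a session time index."""

    data: np.ndarray
    affine: np.ndarray
    index: int = -1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D grid, got shape {self.data.shape}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel edge length in mm, from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same metadata, new grid."""
        return Volume(data=data, affine=self.affine.copy(), index=self.index)

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy(), self.index)


def read_volume(path: str | Path, index: int = -1) -> Volume:
    """Read a single 3D NIfTI-1 volume.

    Integer-typed files are promoted to float64 with values preserved.
    4D files are rejected: the streaming model is one file per acquisition.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    elif data.ndim != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3D volume, got shape {data.shape}"
        )
    if not any(np.issubdtype(data.dtype, d) for d in _SUPPORTED_DTYPES):
        raise VolumeFormatError(f"{path}: unsupported dtype {data.dtype}")
    return Volume(data=data, affine=img.affine, index=index)


def write_volume(vol: Volume, path: str | Path, dtype=np.float64) -> Path:
    """Write a :class:`Volume` as NIfTI-1.

    ``write_volume`` then :func:`read_volume` round-trips data and affine
    bit-exactly for the supported dtype set (the default float64 always).
    """
    dtype = np.dtype(dtype)
    if not any(np.issubdtype(dtype, d) for d in _SUPPORTED_DTYPES):
        raise VolumeFormatError(f"unsupported output dtype {dtype}")
    img = nib.Nifti1Image(vol.data.astype(dtype), vol.affine)
    img.header.set_data_dtype(dtype)
    nib.save(img, str(path))
    return Path(path)
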