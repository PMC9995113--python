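"""Common 3-D image container and NIfTI I/O.

Axis convention used throughout the package: 0-based voxel indices with axis
order (sagittal, coronal, axial), i.e. slicing along axis 0 yields sagittal
slices.  Voxel size is carried in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass
class ImageVolume:
    """A 3-D scalar grid with physical voxel size.

    Parameters
    ----------
    data
        3-D array of intensities (a.u.).
    voxel_size
        Voxel edge lengths in mm, one per axis.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size entries must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.voxel_size, dict(self.meta))


def save_nifti(volume: ImageVolume | np.ndarray, path, voxel_size=None) -> None:
    """Write a volume as NIfTI-1 with the voxel size in the header."""
    if isinstance(volume, ImageVolume):
        data, vs = volume.data, volume.voxel_size
    else:
        data = np.asarray(volume)
        vs = voxel_size if voxel_size is not None else (1.0, 1.0, 1.0)
    affine = np.diag(list(vs) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms(tuple(vs)[: data.ndim] + (1.0,) * max(0, data.ndim - 3))
    nib.save(img, str(path))


def load_nifti(path) -> ImageVolume:
    """Read a 3-D NIfTI volume into an :class:`ImageVolume`."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()[:3]
    return ImageVolume(data, tuple(float(z) for z in zooms))
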