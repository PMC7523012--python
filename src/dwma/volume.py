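"""3D image volumes with NIfTI-1 I/O and canonical (RAS+) orientation.

All internal processing assumes a right-handed RAS+ voxel grid with the
third array axis running inferior -> superior, so that "the slice above"
always means a larger index along axis 2. Files in any orientation are
reoriented on load and the applied axis permutation/flips are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: array axis holding the inferior->superior (axial stacking) direction
AXIAL_AXIS = 2


class VolumeError(ValueError):
    """Raised for malformed or unsupported image inputs."""


@dataclass
class Volume:
    """A 3D scalar image with its voxel-to-world affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities (any scalar dtype).
    affine : ndarray, shape (4, 4)
        RAS+ voxel-to-mm affine.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeError(
                f"expected a 3D volume, got {self.data.ndim}D array"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise VolumeError("affine must be 4x4")
        if not np.all(np.isfinite(self.affine)) or np.linalg.det(self.affine[:3, :3]) == 0:
            raise VolumeError("affine carries no valid orientation")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_dims(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same grid/affine, new voxel values."""
        return Volume(np.asarray(data), self.affine.copy())

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy())


def affine_from_voxel_dims(voxel_dims) -> np.ndarray:
    """Diagonal RAS+ affine for an axis-aligned grid with the given spacing."""
    dx, dy, dz = voxel_dims
    aff = np.diag([float(dx), float(dy), float(dz), 1.0])
    return aff


def read_volume(path) -> Volume:
    """Load a 3D NIfTI-1 file, reorienting to canonical RAS+.

    Raises
    ------
    VolumeError
        If the image is not 3D or has no usable orientation.
    """
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise VolumeError(f"{path}: expected 3D image, got shape {img.shape}")
    if img.affine is None:
        raise VolumeError(f"{path}: image stores no orientation (affine missing)")
    orig_ornt = nib.orientations.aff2axcodes(img.affine)
    canon = nib.as_closest_canonical(img)
    if orig_ornt != ("R", "A", "S"):
        logger.info("reoriented %s from %s to RAS", path, "".join(orig_ornt))
    data = np.asarray(canon.dataobj)
    return Volume(data, canon.affine)


def write_volume(volume: Volume, path) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz), preserving dtype."""
    data = volume.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_zooms(volume.voxel_dims)
    nib.save(img, str(path))
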