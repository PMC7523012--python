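"""Probabilistic tissue atlases for atlas-guided neonatal segmentation.

An atlas stores, per voxel, prior probabilities over the four classes
(background, CSF, GM, WM) plus a separate lateral-ventricle prior used to
locate the slices "above the ventricles" that define the centrum semiovale.
The atlas is assumed co-registered to any image it guides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .volume import Volume, VolumeError, affine_from_voxel_dims

CLASS_NAMES = ("background", "csf", "gm", "wm")
BACKGROUND, CSF, GM, WM = 0, 1, 2, 3
#: brain-tissue classes in fixed tie-break order
TISSUE_NAMES = ("csf", "gm", "wm")


@dataclass
class TissueAtlas:
    """Voxelwise tissue priors over (background, CSF, GM, WM).

    Attributes
    ----------
    probs : ndarray, shape (nx, ny, nz, 4)
        Prior probabilities; sums to 1 over the last axis.
    ventricle_prior : ndarray, shape (nx, ny, nz)
        Prior probability that a voxel belongs to a lateral ventricle
        (a subset of the CSF class).
    affine : ndarray, shape (4, 4)
    """

    probs: np.ndarray
    ventricle_prior: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.ventricle_prior = np.asarray(self.ventricle_prior, dtype=float)
        if self.probs.ndim != 4 or self.probs.shape[-1] != len(CLASS_NAMES):
            raise VolumeError("atlas probs must have shape (nx, ny, nz, 4)")
        if self.ventricle_prior.shape != self.probs.shape[:3]:
            raise VolumeError("ventricle prior grid does not match atlas grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.probs.shape[:3]  # type: ignore[return-value]

    @property
    def voxel_dims(self) -> tuple[float, float, float]:
        return tuple(np.linalg.norm(np.asarray(self.affine)[:3, :3], axis=0))  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(np.asarray(self.affine)[:3, :3])))

    def argmax_labels(self) -> np.ndarray:
        """Hard labels 0..3; ties resolve to the lowest class code."""
        return np.argmax(self.probs, axis=-1).astype(np.int8)

    def brain_probability(self) -> np.ndarray:
        """P(CSF) + P(GM) + P(WM) per voxel."""
        return self.probs[..., CSF] + self.probs[..., GM] + self.probs[..., WM]

    def tissue_priors(self) -> np.ndarray:
        """Priors over (CSF, GM, WM) renormalized to sum to 1 where brain."""
        tis = self.probs[..., 1:].copy()
        s = tis.sum(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            tis = np.where(s > 0, tis / s, 1.0 / 3.0)
        return tis

    def save(self, path) -> None:
        """Write as a 4D NIfTI: channels = 4 class priors + ventricle prior."""
        stack = np.concatenate(
            [self.probs, self.ventricle_prior[..., None]], axis=-1
        ).astype(np.float32)
        nib.save(nib.Nifti1Image(stack, self.affine), str(path))

    @classmethod
    def load(cls, path) -> "TissueAtlas":
        img = nib.as_closest_canonical(nib.load(str(path)))
        stack = np.asarray(img.dataobj, dtype=float)
        if stack.ndim != 4 or stack.shape[-1] != len(CLASS_NAMES) + 1:
            raise VolumeError(
                f"{path}: expected 4D atlas with {len(CLASS_NAMES) + 1} channels"
            )
        return cls(stack[..., :4], stack[..., 4], img.affine)


def atlas_like_volume(atlas: TissueAtlas, data: np.ndarray) -> Volume:
    """Wrap an array as a Volume on the atlas grid."""
    return Volume(data, np.asarray(atlas.affine, dtype=float))


def default_affine(voxel_dims=(0.93, 0.93, 1.0)) -> np.ndarray:
    return affine_from_voxel_dims(voxel_dims)
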