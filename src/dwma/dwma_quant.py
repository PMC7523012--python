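"""Objective DWMA detection and volumetry in the centrum semiovale.

A voxel is diffuse white matter abnormality (DWMA) when its signal
intensity exceeds ``mu + alpha * sigma``, where mu and sigma are the mean
and population SD of all cerebral-tissue intensities — voxels whose GM or
WM membership probability is at least tau (default 0.95, the
partial-volume control). Detection is restricted to the centrum semiovale,
operationalized as the central white matter of the two axial slices
immediately above the lateral ventricles, and candidates must themselves be
confident WM. Isolated false positives (typically 2-8 voxels near the
interhemispheric fissure) are removed by a 26-connected minimum
component-size filter plus an optional mid-sagittal exclusion band. The
cut-off alpha defaults to 1.8 SD; 2.0 is available but defines only very
small regions.

DWMA volume is voxel volume times voxel count; normalized DWMA volume
divides by total cerebral white matter volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .tissue_seg import T_GM, T_WM, TissueSegmentation, hard_labels, tissue_volumes
from .atlas import WM, TissueAtlas
from .volume import AXIAL_AXIS, Volume


class QuantError(ValueError):
    """Raised when DWMA quantification preconditions fail."""


@dataclass
class DWMAConfig:
    """Detection parameters.

    alpha : SD multiples above the cerebral mean (default 1.8).
    membership_threshold : minimum tissue membership probability tau.
    min_component_voxels : smallest 26-connected component kept.
    midline_exclusion_voxels : half-width of the excluded mid-sagittal band.
    cs_slices_above : axial slices above the ventricles forming the
        centrum semiovale (default 2).
    cs_erosion_voxels : in-plane erosion depth defining "central" WM.
    min_ventricle_slice_voxels : smallest ventricle cross-section (voxels)
        a slice must show to count as containing the ventricles; guards the
        slice window against single-voxel segmentation stragglers.
    wm_volume_hard : use hard-label instead of soft posterior WM count
        for the normalization denominator.
    """

    alpha: float = 1.8
    membership_threshold: float = 0.95
    min_component_voxels: int = 3
    connectivity: int = 26
    midline_exclusion_voxels: int = 2
    cs_slices_above: int = 2
    cs_erosion_voxels: int = 1
    min_ventricle_slice_voxels: int = 5
    wm_volume_hard: bool = False

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise QuantError("alpha must be > 0")
        if not 0.0 < self.membership_threshold < 1.0:
            raise QuantError("membership threshold must lie in (0, 1)")
        if self.min_component_voxels < 1:
            raise QuantError("min_component_voxels must be >= 1")
        if self.connectivity != 26:
            raise QuantError("only 26-neighbourhood connectivity is supported")
        if self.midline_exclusion_voxels < 0 or self.cs_slices_above < 1:
            raise QuantError("invalid centrum semiovale parameters")


@dataclass
class DWMAResult:
    """Detected DWMA mask and derived volumetry."""

    mask: np.ndarray
    n_voxels: int
    volume_mm3: float
    wm_volume_mm3: float
    normalized_volume: float
    cerebral_mean: float
    cerebral_sd: float
    threshold_used: float
    config: DWMAConfig = field(repr=False, default=None)

    def scalars(self) -> dict:
        return {
            "n_voxels": self.n_voxels,
            "volume_mm3": self.volume_mm3,
            "wm_volume_mm3": self.wm_volume_mm3,
            "normalized_volume": self.normalized_volume,
            "cerebral_mean": self.cerebral_mean,
            "cerebral_sd": self.cerebral_sd,
            "threshold_used": self.threshold_used,
        }


def cerebral_stats(
    volume: Volume, seg: TissueSegmentation, tau: float = 0.95
) -> tuple[float, float]:
    """Mean and population SD over confident cerebral tissue.

    Eligible voxels have P(GM) >= tau or P(WM) >= tau; this is the
    partial-volume control applied before thresholding.
    """
    post = seg.posteriors
    eligible = (post[..., T_GM] >= tau) | (post[..., T_WM] >= tau)
    vals = np.asarray(volume.data, dtype=float)[eligible]
    if vals.size < 2:
        raise QuantError(
            f"only {vals.size} voxels pass the membership filter; need >= 2"
        )
    return float(vals.mean()), float(vals.std(ddof=0))


def top_slice(mask: np.ndarray, min_voxels: int = 5) -> int:
    """Topmost axial slice where the mask covers at least ``min_voxels``.

    Falls back to the topmost non-empty slice when no slice reaches the
    minimum cross-section.
    """
    counts = np.asarray(mask, dtype=bool).sum(axis=(0, 1))
    qualifying = np.nonzero(counts >= min_voxels)[0]
    if qualifying.size == 0:
        qualifying = np.nonzero(counts > 0)[0]
    if qualifying.size == 0:
        raise QuantError("mask is empty")
    return int(qualifying.max())


def centrum_semiovale_mask(
    seg: TissueSegmentation,
    ventricles: np.ndarray,
    config: DWMAConfig | None = None,
) -> np.ndarray:
    """Central WM of the axial slices immediately above the ventricles.

    Let k be the topmost axial slice showing a ventricle cross-section of at
    least ``min_ventricle_slice_voxels`` voxels; the mask is WM-labeled
    voxels on slices k+1 .. k+cs_slices_above, eroded in-plane by
    ``cs_erosion_voxels`` (keeping only "central" white matter) and with a
    band of +/- ``midline_exclusion_voxels`` around the mid-sagittal plane
    removed.
    """
    config = config or DWMAConfig()
    ventricles = np.asarray(ventricles, dtype=bool)
    if not ventricles.any():
        raise QuantError("ventricle mask is empty")
    nz = ventricles.shape[AXIAL_AXIS]
    k = top_slice(ventricles, config.min_ventricle_slice_voxels)
    top = k + config.cs_slices_above
    if top >= nz:
        raise QuantError(
            f"slices above the ventricles (up to {top}) exceed the grid ({nz})"
        )

    wm = hard_labels(seg) == WM
    mask = np.zeros_like(wm)
    structure = ndimage.generate_binary_structure(2, 1)
    for z in range(k + 1, top + 1):
        sl = wm[:, :, z]
        if config.cs_erosion_voxels > 0:
            sl = ndimage.binary_erosion(
                sl, structure=structure, iterations=config.cs_erosion_voxels
            )
        mask[:, :, z] = sl

    if config.midline_exclusion_voxels > 0:
        nx = mask.shape[0]
        mid = (nx - 1) / 2.0
        x = np.arange(nx)
        band = np.abs(x - mid) <= config.midline_exclusion_voxels
        mask[band, :, :] = False

    if not mask.any():
        raise QuantError("centrum semiovale mask is empty")
    return mask


def _remove_small_components(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    if min_voxels <= 1 or not mask.any():
        return mask
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    counts = np.bincount(labeled.ravel())
    keep = counts >= min_voxels
    keep[0] = False
    return keep[labeled]


def detect_dwma(
    volume: Volume,
    seg: TissueSegmentation,
    cs_mask: np.ndarray,
    config: DWMAConfig | None = None,
) -> DWMAResult:
    """Threshold-based DWMA detection within the centrum semiovale.

    Candidates are centrum semiovale voxels with intensity strictly greater
    than mu + alpha*sigma and WM membership >= tau; components smaller than
    ``min_component_voxels`` (26-connectivity) are discarded. An empty
    result is valid (normalized DWMA volume 0).
    """
    config = config or DWMAConfig()
    cs_mask = np.asarray(cs_mask, dtype=bool)
    if not cs_mask.any():
        raise QuantError("centrum semiovale mask is empty")
    mu, sigma = cerebral_stats(volume, seg, config.membership_threshold)
    threshold = mu + config.alpha * sigma

    data = np.asarray(volume.data, dtype=float)
    candidates = (
        cs_mask
        & (data > threshold)
        & (seg.posteriors[..., T_WM] >= config.membership_threshold)
    )
    mask = _remove_small_components(candidates, config.min_component_voxels)

    voxel_volume = float(np.prod(seg.voxel_dims))
    n_vox = int(mask.sum())
    vols = tissue_volumes(seg, hard=config.wm_volume_hard)
    wm_volume = vols["wm"]
    if wm_volume <= 0:
        raise QuantError("white matter volume is zero; cannot normalize")
    return DWMAResult(
        mask=mask,
        n_voxels=n_vox,
        volume_mm3=n_vox * voxel_volume,
        wm_volume_mm3=wm_volume,
        normalized_volume=(n_vox * voxel_volume) / wm_volume,
        cerebral_mean=mu,
        cerebral_sd=sigma,
        threshold_used=threshold,
        config=config,
    )


def normalized_dwma(result: DWMAResult) -> float:
    """Normalized DWMA volume: DWMA volume over cerebral WM volume."""
    if result.wm_volume_mm3 <= 0:
        raise QuantError("white matter volume is zero; cannot normalize")
    return result.volume_mm3 / result.wm_volume_mm3


class DWMADetector(BaseEstimator):
    """Convenience estimator binding ventricle finding, the centrum
    semiovale definition and thresholded detection into one step.

    Attributes (after ``detect``)
    -----------------------------
    cs_mask_, ventricles_, result_
    """

    def __init__(
        self,
        alpha: float = 1.8,
        membership_threshold: float = 0.95,
        min_component_voxels: int = 3,
        midline_exclusion_voxels: int = 2,
        cs_slices_above: int = 2,
        cs_erosion_voxels: int = 1,
        wm_volume_hard: bool = False,
    ):
        self.alpha = alpha
        self.membership_threshold = membership_threshold
        self.min_component_voxels = min_component_voxels
        self.midline_exclusion_voxels = midline_exclusion_voxels
        self.cs_slices_above = cs_slices_above
        self.cs_erosion_voxels = cs_erosion_voxels
        self.wm_volume_hard = wm_volume_hard

    def _config(self) -> DWMAConfig:
        return DWMAConfig(
            alpha=self.alpha,
            membership_threshold=self.membership_threshold,
            min_component_voxels=self.min_component_voxels,
            midline_exclusion_voxels=self.midline_exclusion_voxels,
            cs_slices_above=self.cs_slices_above,
            cs_erosion_voxels=self.cs_erosion_voxels,
            wm_volume_hard=self.wm_volume_hard,
        )

    def detect(
        self, volume: Volume, seg: TissueSegmentation, atlas: TissueAtlas
    ) -> DWMAResult:
        from .tissue_seg import ventricle_mask

        config = self._config()
        self.ventricles_ = ventricle_mask(seg, atlas)
        # localize the slice window on the prior-supported ventricle core,
        # where segmentation and atlas cannot disagree
        loc = self.ventricles_ & (atlas.ventricle_prior >= 0.5)
        self.cs_mask_ = centrum_semiovale_mask(
            seg, loc if loc.any() else self.ventricles_, config
        )
        self.result_ = detect_dwma(volume, seg, self.cs_mask_, config)
        return self.result_
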