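"""Atlas-guided probabilistic tissue segmentation (EM Gaussian mixture).

Each masked voxel is modelled as a draw from one of three Gaussians
(CSF, GM, WM) with voxelwise prior probabilities taken from a co-registered
neonatal probabilistic atlas. EM alternates posterior computation
(E-step: posterior proportional to prior x Gaussian likelihood) with
posterior-weighted re-estimation of the class means and SDs (M-step); the
observed-data log-likelihood is non-decreasing. Initialization is
deterministic (atlas-prior-weighted moments), so segmentation introduces no
random state. Partial-volume voxels are not modelled explicitly: they are
excluded downstream by the high-membership filter (default >= 95%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .atlas import CSF, GM, WM, TISSUE_NAMES, TissueAtlas
from .volume import Volume

#: indices into the 3-class posterior array, fixed tie-break order
T_CSF, T_GM, T_WM = 0, 1, 2
_MIN_CLASS_MASS = 10.0


class SegmentationError(ValueError):
    """Raised when the mixture fit is ill-posed or a class collapses."""


@dataclass
class SegConfig:
    """Tunable parameters of the tissue model."""

    max_iter: int = 100
    tol: float = 1e-5
    prior_weight: float = 1.0
    membership_threshold: float = 0.95

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise SegmentationError("tol must be > 0")
        if not 0.0 <= self.prior_weight <= 1.0:
            raise SegmentationError("prior_weight must lie in [0, 1]")
        if not 0.0 < self.membership_threshold < 1.0:
            raise SegmentationError("membership threshold must lie in (0, 1)")


@dataclass
class TissueSegmentation:
    """Fitted per-voxel tissue posteriors over (CSF, GM, WM).

    ``posteriors`` has shape ``grid + (3,)`` and is zero outside ``mask``;
    inside the mask it sums to 1 per voxel.
    """

    posteriors: np.ndarray
    mask: np.ndarray
    class_means: dict
    class_sds: dict
    n_iterations: int
    converged: bool
    voxel_dims: tuple
    log_likelihoods: np.ndarray


class AtlasGuidedSegmenter(BaseEstimator):
    """EM Gaussian-mixture segmenter guided by voxelwise atlas priors.

    Parameters mirror :class:`SegConfig`. ``prior_weight`` blends the atlas
    prior with a uniform prior (``w*pi + (1-w)/3``); 1.0 is pure atlas
    guidance, 0.0 an unguided mixture.

    Attributes (after ``fit``)
    --------------------------
    posteriors_, means_, sds_, n_iter_, converged_, log_likelihoods_
    """

    def __init__(
        self,
        max_iter: int = 100,
        tol: float = 1e-5,
        prior_weight: float = 1.0,
    ):
        self.max_iter = max_iter
        self.tol = tol
        self.prior_weight = prior_weight

    def fit(self, volume: Volume, atlas: TissueAtlas, mask: np.ndarray):
        config = SegConfig(self.max_iter, self.tol, self.prior_weight)
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise SegmentationError("mask is empty")
        if atlas.shape != volume.data.shape:
            raise SegmentationError("atlas grid does not match volume grid")
        intensities = np.asarray(volume.data, dtype=float)[mask]

        priors = atlas.tissue_priors()[mask]  # (n, 3)
        w = config.prior_weight
        priors = w * priors + (1.0 - w) / 3.0

        # deterministic init: prior-weighted intensity moments
        mass = priors.sum(axis=0)
        means = (priors * intensities[:, None]).sum(axis=0) / mass
        var = (priors * (intensities[:, None] - means) ** 2).sum(axis=0) / mass
        sd_floor = max(1e-3 * intensities.std(), 1e-12)
        sds = np.maximum(np.sqrt(var), sd_floor)

        loglik = []
        converged = False
        post = None
        for it in range(config.max_iter):
            # E-step in log space
            log_lik = (
                -0.5 * ((intensities[:, None] - means) / sds) ** 2
                - np.log(sds)
                - 0.5 * np.log(2.0 * np.pi)
            )
            with np.errstate(divide="ignore"):
                log_num = np.log(priors) + log_lik
            m = log_num.max(axis=1, keepdims=True)
            num = np.exp(log_num - m)
            denom = num.sum(axis=1, keepdims=True)
            post = num / denom
            ll = float(np.sum(m[:, 0] + np.log(denom[:, 0])))
            loglik.append(ll)

            # M-step
            mass = post.sum(axis=0)
            for c, name in enumerate(TISSUE_NAMES):
                if mass[c] < _MIN_CLASS_MASS:
                    raise SegmentationError(
                        f"class {name!r} collapsed (posterior mass {mass[c]:.2f})"
                    )
            means = (post * intensities[:, None]).sum(axis=0) / mass
            var = (post * (intensities[:, None] - means) ** 2).sum(axis=0) / mass
            sds = np.maximum(np.sqrt(var), sd_floor)

            if it > 0 and abs(loglik[-1] - loglik[-2]) <= config.tol * abs(loglik[-2]):
                converged = True
                break
        if not converged:
            warnings.warn(
                "tissue EM did not converge within "
                f"{config.max_iter} iterations", RuntimeWarning,
            )

        full = np.zeros(volume.data.shape + (3,))
        full[mask] = post
        self.posteriors_ = full
        self.mask_ = mask
        self.means_ = dict(zip(TISSUE_NAMES, means))
        self.sds_ = dict(zip(TISSUE_NAMES, sds))
        self.n_iter_ = len(loglik)
        self.converged_ = converged
        self.log_likelihoods_ = np.array(loglik)
        self.voxel_dims_ = volume.voxel_dims
        return self

    @property
    def segmentation(self) -> TissueSegmentation:
        return TissueSegmentation(
            posteriors=self.posteriors_,
            mask=self.mask_,
            class_means=self.means_,
            class_sds=self.sds_,
            n_iterations=self.n_iter_,
            converged=self.converged_,
            voxel_dims=self.voxel_dims_,
            log_likelihoods=self.log_likelihoods_,
        )


def fit_tissue_model(
    volume: Volume,
    atlas: TissueAtlas,
    mask: np.ndarray,
    config: SegConfig | None = None,
) -> TissueSegmentation:
    """Fit the atlas-guided 3-class Gaussian mixture; see module docstring."""
    config = config or SegConfig()
    seg = AtlasGuidedSegmenter(
        max_iter=config.max_iter,
        tol=config.tol,
        prior_weight=config.prior_weight,
    ).fit(volume, atlas, mask)
    return seg.segmentation


def hard_labels(seg: TissueSegmentation) -> np.ndarray:
    """Argmax tissue labels (atlas codes 1=CSF, 2=GM, 3=WM; 0 outside mask).

    Ties break to the lowest class code (CSF < GM < WM).
    """
    labels = np.zeros(seg.mask.shape, dtype=np.int8)
    labels[seg.mask] = np.argmax(seg.posteriors[seg.mask], axis=1) + 1
    return labels


def tissue_volumes(
    seg: TissueSegmentation, voxel_dims=None, hard: bool = False
) -> dict:
    """Per-class volume in mm^3 (posterior-weighted soft count by default)."""
    if voxel_dims is None:
        voxel_dims = seg.voxel_dims
    vv = float(np.prod(voxel_dims))
    if hard:
        labels = hard_labels(seg)
        counts = [(labels == c).sum() for c in (CSF, GM, WM)]
    else:
        counts = seg.posteriors[seg.mask].sum(axis=0)
    return {name: vv * float(c) for name, c in zip(TISSUE_NAMES, counts)}


def ventricle_mask(seg: TissueSegmentation, atlas: TissueAtlas) -> np.ndarray:
    """Lateral ventricles: CSF components dominated by the atlas ventricle prior.

    A 26-connected CSF-labeled component qualifies when its mean atlas
    ventricle prior exceeds 0.5; the union of qualifying components is
    returned. The external CSF rim has (near-)zero ventricle prior and is
    excluded by this rule.
    """
    csf = hard_labels(seg) == CSF
    labeled, n = ndimage.label(csf, structure=np.ones((3, 3, 3), dtype=int))
    out = np.zeros(seg.mask.shape, dtype=bool)
    found = False
    for comp in range(1, n + 1):
        sel = labeled == comp
        if atlas.ventricle_prior[sel].mean() > 0.5:
            out |= sel
            found = True
    if not found:
        raise SegmentationError("ventricles not found")
    return out
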