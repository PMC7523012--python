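"""Bias-field correction and intensity normalization for T2w volumes.

The bias field (smooth multiplicative inhomogeneity, chiefly coil
sensitivity) is estimated by least squares in the log domain: a low-order
3D polynomial is fitted to masked log-intensities and exponentiated. When a
tissue atlas is supplied, the fit target is first centred by the
atlas-expected log-intensity of each voxel (prior-weighted class log-means),
which stops slowly-varying anatomy (the dark cortical ribbon, bright CSF
rim) from leaking into the field estimate. The field is gauge-fixed to mean
1 over the mask so correction preserves global brightness.

Intensity normalization maps masked intensities to fixed anchors
(median -> 1000, IQR -> 100 by default) so downstream statistics are
invariant to positive affine rescalings of the scanner output.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .atlas import TissueAtlas
from .volume import Volume

NORM_CENTER_ANCHOR = 1000.0
NORM_SCALE_ANCHOR = 100.0


class PreprocessError(ValueError):
    """Raised for invalid preprocessing inputs."""


def brain_mask_from_atlas(atlas: TissueAtlas, threshold: float = 0.5) -> np.ndarray:
    """Brain mask: voxels with total tissue prior >= threshold.

    Keeps only the largest 26-connected component of the thresholded set.
    """
    if not 0.0 < threshold < 1.0:
        raise PreprocessError("threshold must lie strictly between 0 and 1")
    raw = atlas.brain_probability() >= threshold
    if not raw.any():
        raise PreprocessError("brain mask is empty at this threshold")
    labeled, n = ndimage.label(raw, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        counts = np.bincount(labeled.ravel())[1:]
        raw = labeled == (1 + int(np.argmax(counts)))
    return raw


def _polynomial_design(shape, order, mask):
    """Monomial design matrix over masked voxels, coords normalized to [-1, 1]."""
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    cols = []
    exps = [
        e for e in product(range(order + 1), repeat=3) if sum(e) <= order
    ]
    coords = [g[mask] for g in grids]
    for ex, ey, ez in exps:
        cols.append(coords[0] ** ex * coords[1] ** ey * coords[2] ** ez)
    return np.column_stack(cols), exps, grids


@dataclass
class BiasField:
    """A fitted multiplicative bias field (dimensionless, mean 1 over mask)."""

    field: np.ndarray
    order: int
    mask_used: np.ndarray


class BiasFieldCorrector(BaseEstimator):
    """Log-domain polynomial bias-field estimator.

    Parameters
    ----------
    order : int
        Polynomial degree of the field model (default 3).

    Attributes
    ----------
    field_ : ndarray
        Estimated multiplicative field over the full grid, mean 1 over mask.
    coef_ : ndarray
        Fitted monomial coefficients (log domain).
    mask_ : ndarray of bool
        Mask the fit used.
    """

    def __init__(self, order: int = 3):
        self.order = order

    def fit(self, volume: Volume, mask: np.ndarray, atlas: TissueAtlas | None = None):
        data = np.asarray(volume.data, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != data.shape:
            raise PreprocessError("mask shape does not match volume shape")
        if not mask.any():
            raise PreprocessError("mask is empty")
        vals = data[mask]
        if np.min(vals) <= 0:
            # noise can push a few voxels non-positive; only an all-bad mask
            # is fatal, otherwise clamp to the smallest positive value
            pos = vals[vals > 0]
            if pos.size == 0:
                raise PreprocessError(
                    "no positive intensities inside mask: log fit undefined"
                )
            vals = np.maximum(vals, pos.min())
        target = np.log(vals)

        if atlas is not None:
            target = target - self._atlas_log_reference(atlas, target, mask)

        X, exps, grids = _polynomial_design(data.shape, self.order, mask)
        coef, *_ = np.linalg.lstsq(X, target, rcond=None)

        log_field = np.zeros(data.shape)
        for (ex, ey, ez), c in zip(exps, coef):
            log_field += c * grids[0] ** ex * grids[1] ** ey * grids[2] ** ez
        field = np.exp(log_field)
        field /= field[mask].mean()

        self.coef_ = coef
        self.mask_ = mask
        self.field_ = field
        return self

    @staticmethod
    def _atlas_log_reference(atlas, log_vals, mask):
        """Expected log intensity per masked voxel from its atlas argmax class.

        A piecewise-constant anatomy model: each voxel is predicted by the
        mean log intensity of its most probable atlas tissue, which keeps
        tissue contrast out of the polynomial field fit.
        """
        labels = atlas.argmax_labels()[mask]
        ref = np.full(log_vals.shape, log_vals.mean())
        for c in np.unique(labels):
            sel = labels == c
            if sel.sum() > 0:
                ref[sel] = log_vals[sel].mean()
        return ref - ref.mean()

    def transform(self, volume: Volume) -> Volume:
        """Divide by the fitted field inside the mask; identity outside."""
        if not hasattr(self, "field_"):
            raise PreprocessError("corrector is not fitted")
        if volume.data.shape != self.field_.shape:
            raise PreprocessError("volume shape does not match fitted field")
        out = np.asarray(volume.data, dtype=float).copy()
        out[self.mask_] = out[self.mask_] / self.field_[self.mask_]
        return volume.with_data(out)

    def fit_transform(self, volume, mask, atlas=None) -> Volume:
        return self.fit(volume, mask, atlas).transform(volume)

    @property
    def bias_field(self) -> BiasField:
        return BiasField(field=self.field_, order=self.order, mask_used=self.mask_)


def estimate_bias_field(
    volume: Volume, mask: np.ndarray, order: int = 3, atlas: TissueAtlas | None = None
) -> BiasField:
    """Fit a degree-``order`` polynomial bias field over the mask."""
    return BiasFieldCorrector(order=order).fit(volume, mask, atlas).bias_field


def correct_bias(volume: Volume, bias: BiasField) -> Volume:
    """Divide the volume by the field inside its mask, unchanged outside."""
    if volume.data.shape != bias.field.shape:
        raise PreprocessError("volume shape does not match bias field shape")
    out = np.asarray(volume.data, dtype=float).copy()
    out[bias.mask_used] /= bias.field[bias.mask_used]
    return volume.with_data(out)


@dataclass
class NormalizationParams:
    """Invertible affine intensity map: out = (in - center)/scale * 100 + 1000."""

    center: np.ndarray
    scale: np.ndarray
    method: str
    per_slice: bool = False

    def inverse(self, volume: Volume) -> Volume:
        data = np.asarray(volume.data, dtype=float)
        if self.per_slice:
            c = np.asarray(self.center)[None, None, :]
            s = np.asarray(self.scale)[None, None, :]
        else:
            c, s = float(self.center), float(self.scale)
        return volume.with_data(
            (data - NORM_CENTER_ANCHOR) / NORM_SCALE_ANCHOR * s + c
        )


class IntensityNormalizer(BaseEstimator):
    """Map masked intensities to fixed anchors (median 1000, IQR 100).

    ``method='median_iqr'`` (robust, default) or ``'zscore'``; with
    ``per_slice=True`` each axial slice is normalized independently, which
    removes slice-to-slice drift but sacrifices volume-wide affine
    equivariance.
    """

    def __init__(self, method: str = "median_iqr", per_slice: bool = False):
        self.method = method
        self.per_slice = per_slice

    def _center_scale(self, vals):
        if self.method == "median_iqr":
            center = np.median(vals)
            q25, q75 = np.percentile(vals, [25.0, 75.0])
            scale = q75 - q25
        elif self.method == "zscore":
            center = vals.mean()
            scale = vals.std()
        else:
            raise PreprocessError(f"unknown normalization method {self.method!r}")
        if scale <= 0:
            raise PreprocessError(
                "degenerate intensity distribution: scale is zero"
            )
        return float(center), float(scale)

    def fit(self, volume: Volume, mask: np.ndarray):
        data = np.asarray(volume.data, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise PreprocessError("mask is empty")
        if self.per_slice:
            nz = data.shape[2]
            centers = np.zeros(nz)
            scales = np.ones(nz)
            for k in range(nz):
                m = mask[:, :, k]
                if m.any():
                    centers[k], scales[k] = self._center_scale(data[:, :, k][m])
                else:
                    centers[k], scales[k] = 0.0, np.nan
            # slices with no brain inherit the global map
            gc, gs = self._center_scale(data[mask])
            bad = ~np.isfinite(scales)
            centers[bad], scales[bad] = gc, gs
            self.params_ = NormalizationParams(centers, scales, self.method, True)
        else:
            c, s = self._center_scale(data[mask])
            self.params_ = NormalizationParams(
                np.float64(c), np.float64(s), self.method, False
            )
        return self

    def transform(self, volume: Volume) -> Volume:
        if not hasattr(self, "params_"):
            raise PreprocessError("normalizer is not fitted")
        data = np.asarray(volume.data, dtype=float)
        p = self.params_
        if p.per_slice:
            c = np.asarray(p.center)[None, None, :]
            s = np.asarray(p.scale)[None, None, :]
        else:
            c, s = float(p.center), float(p.scale)
        return volume.with_data(
            (data - c) / s * NORM_SCALE_ANCHOR + NORM_CENTER_ANCHOR
        )

    def fit_transform(self, volume, mask) -> Volume:
        return self.fit(volume, mask).transform(volume)


def normalize_intensity(
    volume: Volume,
    mask: np.ndarray,
    method: str = "median_iqr",
    per_slice: bool = False,
) -> tuple[Volume, NormalizationParams]:
    """Normalize intensities over the mask; returns the inverse-capable params."""
    norm = IntensityNormalizer(method=method, per_slice=per_slice)
    out = norm.fit_transform(volume, mask)
    return out, norm.params_
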