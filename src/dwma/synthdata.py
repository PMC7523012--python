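"""Synthetic neonatal T2w phantoms, matching atlases, and simulated cohorts.

The phantom emulates the features the quantification pipeline actually
relies on at term-equivalent age: T2 contrast ordering CSF > WM > GM
(white matter is unmyelinated and therefore bright), a smooth multiplicative
bias field, additive scanner noise, two lateral ventricles interior to the
white matter, and focal DWMA hyperintensities of known voxel count injected
into the centrum semiovale. It deliberately omits cortical folding,
myelination gradients and MR sequence physics.

The cohort simulator draws normalized DWMA fractions from a right-skewed
log-normal (median matched to a very-preterm cohort at term-equivalent age)
and generates Bayley-III motor composites and cerebral-palsy status from a
linear, respectively logistic, model in DWMA and perinatal covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import BACKGROUND, CSF, GM, WM, TissueAtlas
from .volume import Volume, affine_from_voxel_dims


class SynthesisError(ValueError):
    """Raised for invalid phantom or cohort specifications."""


# ---------------------------------------------------------------------------
# atlas geometry
# ---------------------------------------------------------------------------

#: fractional (scaled) radii of the nested brain shells
_CSF_RIM_INNER = 0.92
_GM_RIBBON_INNER = 0.80
#: ventricle ellipsoids: (center, semi-axes) as fractions of the brain semi-axes
_VENTRICLE_CENTERS = ((-0.28, -0.05, -0.10), (0.28, -0.05, -0.10))
_VENTRICLE_RADII = (0.12, 0.30, 0.22)
#: brain semi-axis as a fraction of the half grid extent
_BRAIN_FRACTION = 0.90

MIN_GRID = 32


def _scaled_radius(shape, voxel_dims, semi_axes_mm):
    """Per-voxel ellipsoidal radius rho (rho=1 on the brain surface)."""
    coords = []
    for n, d, a in zip(shape, voxel_dims, semi_axes_mm):
        x = (np.arange(n) - (n - 1) / 2.0) * d
        coords.append(x / a)
    cx, cy, cz = np.meshgrid(*coords, indexing="ij")
    return np.sqrt(cx**2 + cy**2 + cz**2), (cx, cy, cz)


def make_atlas(
    grid_shape=(96, 96, 96),
    voxel_dims=(0.93, 0.93, 1.0),
    smoothing_mm=1.5,
    seed=0,
    quantize_levels: int = 255,
) -> TissueAtlas:
    """Build a nested-ellipsoid probabilistic atlas with two ventricles.

    The geometric model is background outside the brain ellipsoid, a CSF rim,
    a cortical GM ribbon, a WM core, and two ellipsoidal lateral ventricles
    (CSF) strictly interior to the WM. Class indicator maps are blurred with
    an anisotropic Gaussian of width ``smoothing_mm`` and renormalized,
    giving soft priors at tissue interfaces; ``smoothing_mm=0`` returns the
    0/1 indicators. Priors are then quantized to ``quantize_levels`` steps
    (as real atlases stored in 8-bit are), so a class prior far from that
    tissue is exactly zero rather than an infinitesimal Gaussian tail.
    ``seed`` jitters the ellipsoid semi-axes by a few percent so replicate
    atlases are not identical.

    Raises
    ------
    SynthesisError
        If any grid axis has fewer than 32 voxels.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if min(grid_shape) < MIN_GRID:
        raise SynthesisError(
            f"grid {grid_shape} too small: need >= {MIN_GRID} voxels per axis "
            "to contain the brain ellipsoid"
        )
    voxel_dims = tuple(float(d) for d in voxel_dims)
    if min(voxel_dims) <= 0:
        raise SynthesisError("voxel dimensions must be positive")
    rng = np.random.default_rng(seed)
    jitter = 1.0 + 0.03 * rng.uniform(-1.0, 1.0, size=3)
    semi_axes = [
        _BRAIN_FRACTION * (n * d / 2.0) * j
        for n, d, j in zip(grid_shape, voxel_dims, jitter)
    ]

    rho, _ = _scaled_radius(grid_shape, voxel_dims, semi_axes)
    labels = np.full(grid_shape, BACKGROUND, dtype=np.int8)
    labels[rho <= 1.0] = CSF
    labels[rho <= _CSF_RIM_INNER] = GM
    labels[rho <= _GM_RIBBON_INNER] = WM

    vent = np.zeros(grid_shape, dtype=bool)
    for center in _VENTRICLE_CENTERS:
        vc = [c * a for c, a in zip(center, semi_axes)]
        vr = [r * a for r, a in zip(_VENTRICLE_RADII, semi_axes)]
        coords = []
        for n, d, c0, a in zip(grid_shape, voxel_dims, vc, vr):
            x = (np.arange(n) - (n - 1) / 2.0) * d
            coords.append((x - c0) / a)
        cx, cy, cz = np.meshgrid(*coords, indexing="ij")
        vent |= cx**2 + cy**2 + cz**2 <= 1.0
    labels[vent] = CSF

    onehot = np.stack(
        [(labels == c).astype(float) for c in range(4)], axis=-1
    )
    vent_prior = vent.astype(float)
    if smoothing_mm > 0:
        sigma_vox = [smoothing_mm / d for d in voxel_dims]
        for c in range(4):
            onehot[..., c] = ndimage.gaussian_filter(onehot[..., c], sigma_vox)
        vent_prior = ndimage.gaussian_filter(vent_prior, sigma_vox)
        onehot /= onehot.sum(axis=-1, keepdims=True)
        vent_prior = np.clip(vent_prior, 0.0, 1.0)

    if quantize_levels:
        onehot = np.round(onehot * quantize_levels) / quantize_levels
        onehot /= onehot.sum(axis=-1, keepdims=True)
        vent_prior = np.round(vent_prior * quantize_levels) / quantize_levels

    return TissueAtlas(onehot, vent_prior, affine_from_voxel_dims(voxel_dims))


# ---------------------------------------------------------------------------
# phantom images
# ---------------------------------------------------------------------------

#: default T2w class intensity means (arbitrary units); CSF > WM > GM because
#: neonatal white matter is unmyelinated and hyperintense relative to cortex
DEFAULT_CLASS_MEANS = {"background": 12.0, "csf": 220.0, "gm": 138.0, "wm": 160.0}
#: within-class intensity texture SD
DEFAULT_CLASS_SDS = {"background": 4.0, "csf": 10.0, "gm": 7.0, "wm": 7.0}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic T2w phantom.

    ``dwma_blobs`` is a list of ``(center, radius_mm, offset)`` or
    ``(center, radius_mm, offset, z_extent)`` tuples: a sphere of the given
    radius (mm) around a WM voxel ``center`` (index triple), hyperintense by
    ``offset`` multiples of the WM texture SD. An optional ``z_extent``
    ``(z_lo, z_hi)`` clips the sphere to an inclusive axial slice range,
    modelling the sheet-like, in-plane-diffuse geometry of real DWMA (which
    is confined to a couple of axial slices rather than spherical).
    ``bias_amplitude`` is the peak multiplicative deviation of the bias field
    from 1; ``noise_sigma`` the additive Gaussian (or Rician) noise SD.
    """

    grid_shape: tuple = (96, 96, 96)
    voxel_dims: tuple = (0.93, 0.93, 1.0)
    class_means: dict = dc_field(default_factory=lambda: dict(DEFAULT_CLASS_MEANS))
    class_sds: dict = dc_field(default_factory=lambda: dict(DEFAULT_CLASS_SDS))
    dwma_blobs: list = dc_field(default_factory=list)
    bias_amplitude: float = 0.20
    noise_sigma: float = 2.0
    rician: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid_shape) <= 0 or min(self.voxel_dims) <= 0:
            raise SynthesisError("grid shape and voxel dims must be positive")
        means = [self.class_means[k] for k in ("background", "csf", "gm", "wm")]
        if len(set(means)) != len(means):
            raise SynthesisError("class means must be distinct")
        if self.bias_amplitude < 0 or self.noise_sigma < 0:
            raise SynthesisError("bias amplitude and noise sigma must be >= 0")
        for i, blob in enumerate(self.dwma_blobs):
            _, radius, offset = blob[:3]
            if radius <= 0:
                raise SynthesisError(f"dwma blob {i}: radius must be > 0")
            if offset <= 0:
                raise SynthesisError(f"dwma blob {i}: intensity offset must be > 0")


@dataclass
class PhantomTruth:
    """Ground truth recorded for a generated phantom."""

    label_volume: np.ndarray
    dwma_mask: np.ndarray
    bias_field: np.ndarray
    dwma_true_volume_mm3: float


def _voxel_center_distances_mm(shape, voxel_dims, center):
    grids = np.meshgrid(
        *[(np.arange(n) - c) * d for n, d, c in zip(shape, voxel_dims, center)],
        indexing="ij",
    )
    return np.sqrt(sum(g**2 for g in grids))


def _polynomial_bias(shape, amplitude, rng, order=2, support=None):
    """Random polynomial bias field with max |field - 1| == amplitude.

    The peak deviation is normalized over ``support`` (e.g. the brain) when
    given, so the stated amplitude is realized where it matters.
    """
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    cx, cy, cz = np.meshgrid(*coords, indexing="ij")
    p = np.zeros(shape)
    for ex in range(order + 1):
        for ey in range(order + 1 - ex):
            for ez in range(order + 1 - ex - ey):
                if ex == ey == ez == 0:
                    continue
                p += rng.normal() * cx**ex * cy**ey * cz**ez
    region = p[support] if support is not None else p
    p -= region.mean()
    region = p[support] if support is not None else p
    peak = np.max(np.abs(region))
    if peak > 0:
        p *= amplitude / peak
    # the polynomial may swing further outside the support; keep the
    # multiplicative field positive everywhere
    return np.maximum(1.0 + p, 0.05)


def make_phantom(spec: PhantomSpec, atlas: TissueAtlas) -> tuple[Volume, PhantomTruth]:
    """Render a T2w phantom from an atlas and record its ground truth.

    Labels are the deterministic atlas argmax; each voxel draws its intensity
    from the Gaussian of its class, DWMA voxels are shifted up by
    ``offset * WM SD``, the result is multiplied by a smooth polynomial bias
    field and additive noise is applied last.

    Raises
    ------
    SynthesisError
        If the atlas grid mismatches the spec or a blob center is not WM.
    """
    if atlas.shape != tuple(spec.grid_shape):
        raise SynthesisError(
            f"atlas grid {atlas.shape} does not match spec grid {tuple(spec.grid_shape)}"
        )
    rng = np.random.default_rng(spec.seed)
    labels = atlas.argmax_labels()
    means = np.array(
        [spec.class_means[k] for k in ("background", "csf", "gm", "wm")]
    )
    sds = np.array([spec.class_sds[k] for k in ("background", "csf", "gm", "wm")])

    mean_map = means[labels]
    sd_map = sds[labels]

    dwma_mask = np.zeros(spec.grid_shape, dtype=bool)
    wm_sd = spec.class_sds["wm"]
    for i, blob_spec in enumerate(spec.dwma_blobs):
        center, radius_mm, offset = blob_spec[:3]
        z_extent = blob_spec[3] if len(blob_spec) > 3 else None
        center = tuple(float(c) for c in center)
        nearest = tuple(int(round(c)) for c in center)
        if labels[nearest] != WM:
            raise SynthesisError(
                f"dwma blob {i} center {nearest} lies outside white matter"
            )
        dist = _voxel_center_distances_mm(spec.grid_shape, spec.voxel_dims, center)
        blob = (dist <= radius_mm) & (labels == WM)
        if z_extent is not None:
            z_lo, z_hi = int(z_extent[0]), int(z_extent[1])
            zs = np.arange(spec.grid_shape[2])
            blob &= ((zs >= z_lo) & (zs <= z_hi))[None, None, :]
        dwma_mask |= blob
        mean_map = mean_map + offset * wm_sd * blob

    clean = mean_map + rng.normal(0.0, 1.0, spec.grid_shape) * sd_map

    if spec.bias_amplitude > 0:
        bias = _polynomial_bias(
            spec.grid_shape, spec.bias_amplitude, rng, support=labels != BACKGROUND
        )
    else:
        bias = np.ones(spec.grid_shape)
    image = clean * bias

    if spec.noise_sigma > 0:
        if spec.rician:
            n1 = rng.normal(0.0, spec.noise_sigma, spec.grid_shape)
            n2 = rng.normal(0.0, spec.noise_sigma, spec.grid_shape)
            image = np.sqrt((image + n1) ** 2 + n2**2)
        else:
            image = image + rng.normal(0.0, spec.noise_sigma, spec.grid_shape)

    voxel_volume = float(np.prod(spec.voxel_dims))
    truth = PhantomTruth(
        label_volume=labels,
        dwma_mask=dwma_mask,
        bias_field=bias,
        dwma_true_volume_mm3=float(dwma_mask.sum()) * voxel_volume,
    )
    volume = Volume(image, affine_from_voxel_dims(spec.voxel_dims))
    return volume, truth


def radius_for_voxel_count(
    n_voxels: int, voxel_dims, center, wm_mask: np.ndarray
) -> float:
    """Sphere radius (mm) whose center-in voxel count over WM is exactly n.

    Voxels are counted when their center lies inside the sphere; the returned
    radius is the midpoint between the n-th and (n+1)-th nearest WM voxel
    center distances, so the count is exact by construction. The sphere
    center may be fractional (sub-voxel): off-lattice centers avoid the
    distance ties a symmetric lattice produces.
    """
    dist = _voxel_center_distances_mm(wm_mask.shape, voxel_dims, center)
    d = np.sort(dist[wm_mask])
    if n_voxels < 1 or n_voxels >= d.size:
        raise SynthesisError(
            f"cannot place a {n_voxels}-voxel sphere: only {d.size} WM voxels"
        )
    if d[n_voxels - 1] == d[n_voxels]:
        raise SynthesisError(
            "tied voxel-center distances: no radius gives exactly this count"
        )
    return float(0.5 * (d[n_voxels - 1] + d[n_voxels]))


def ventricle_top_slice(atlas: TissueAtlas, min_voxels: int = 5) -> int:
    """Topmost axial slice with a >= ``min_voxels`` ventricle cross-section.

    Applies the detector's own localization rule to the atlas argmax labels
    (the phantom's ground truth): CSF-labeled voxels inside the ventricle
    prior support (prior >= 0.5), then the minimum-cross-section top slice.
    On that voxel set the segmentation is unambiguous (bright CSF on a CSF
    prior), so generated lesions land in the slices the pipeline will
    actually evaluate.
    """
    labels = atlas.argmax_labels()
    vent = (labels == CSF) & (atlas.ventricle_prior >= 0.5)
    if not vent.any():
        raise SynthesisError("atlas has no ventricle component")
    counts = vent.sum(axis=(0, 1))
    qualifying = np.nonzero(counts >= min_voxels)[0]
    if qualifying.size == 0:
        qualifying = np.nonzero(counts > 0)[0]
    return int(qualifying.max())


def theoretical_cerebral_sd(
    atlas: TissueAtlas,
    class_means: dict | None = None,
    class_sds: dict | None = None,
    noise_sigma: float = 2.0,
) -> float:
    """Population SD of cerebral-tissue intensity implied by the generator.

    Mixes the GM and WM class Gaussians in their atlas-argmax proportions
    (the high-membership filter keeps class interiors, so the argmax ratio
    is the relevant mixing weight), adding scanner noise in quadrature.
    This is the SD scale the DWMA threshold (mu + alpha*sigma) operates on,
    and hence the natural unit for lesion contrast.
    """
    class_means = class_means or DEFAULT_CLASS_MEANS
    class_sds = class_sds or DEFAULT_CLASS_SDS
    labels = atlas.argmax_labels()
    n_gm = int((labels == GM).sum())
    n_wm = int((labels == WM).sum())
    if n_gm + n_wm == 0:
        raise SynthesisError("atlas has no confident GM/WM voxels")
    f = n_wm / (n_gm + n_wm)
    mu_gm, mu_wm = class_means["gm"], class_means["wm"]
    var = (
        f * class_sds["wm"] ** 2
        + (1 - f) * class_sds["gm"] ** 2
        + f * (1 - f) * (mu_wm - mu_gm) ** 2
        + noise_sigma**2
    )
    return float(np.sqrt(var))


def cs_lesion_blob(
    atlas: TissueAtlas,
    n_voxels: int,
    offset: float = 3.0,
    x_fraction: float = 0.22,
    offset_in: str = "cerebral_sd",
    class_means: dict | None = None,
    class_sds: dict | None = None,
    noise_sigma: float = 2.0,
) -> tuple:
    """Construct a DWMA lesion confined to the centrum semiovale window.

    Returns a ``(center, radius_mm, offset_wm_sd, z_extent)`` blob whose
    truth mask covers exactly ``n_voxels`` WM voxels spread over the two
    axial slices immediately above the ventricles — the sheet-like in-plane
    geometry of real DWMA. The lesion is placed off-midline (at
    ``x_fraction`` of the grid width) so it stays clear of the mid-sagittal
    exclusion band.

    ``offset`` is the lesion contrast above the WM mean. With
    ``offset_in='cerebral_sd'`` (default) it is expressed in multiples of
    the pooled cerebral-tissue SD — the unit the DWMA threshold itself uses
    — and converted to the WM-texture-SD unit the phantom stores; with
    ``offset_in='wm_sd'`` it is used as-is.
    """
    class_sds = class_sds or DEFAULT_CLASS_SDS
    if offset_in == "cerebral_sd":
        sigma_c = theoretical_cerebral_sd(atlas, class_means, class_sds, noise_sigma)
        offset_wm = offset * sigma_c / class_sds["wm"]
    elif offset_in == "wm_sd":
        offset_wm = offset
    else:
        raise SynthesisError("offset_in must be 'cerebral_sd' or 'wm_sd'")
    labels = atlas.argmax_labels()
    wm = labels == WM
    k = ventricle_top_slice(atlas)
    z_lo, z_hi = k + 1, k + 2
    nx, ny = labels.shape[:2]
    if z_hi >= labels.shape[2]:
        raise SynthesisError("no room above the ventricles for a lesion")
    slab = np.zeros_like(wm)
    slab[:, :, z_lo : z_hi + 1] = True
    eligible = wm & slab

    # the lesion must stay clear of (a) any CSF prior support, where the
    # membership filter could reject hyperintense voxels, (b) the
    # mid-sagittal exclusion band, and (c) the WM edge (in-plane erosion)
    safe = eligible & (atlas.probs[..., CSF] == 0.0)
    mid = (nx - 1) / 2.0
    band = np.abs(np.arange(nx) - mid) <= 2
    safe[band, :, :] = False

    # rough in-plane radius (index units; x/y spacing equal) for clearance;
    # the center must clear it on both slices of the window. On cramped
    # grids the margin relaxes stepwise, accepting a lesion whose rim
    # grazes the eroded WM boundary.
    r_lesion = float(np.sqrt(n_voxels / (2.0 * np.pi)))
    d_lo = ndimage.distance_transform_edt(safe[:, :, z_lo])
    d_hi = ndimage.distance_transform_edt(safe[:, :, z_hi])
    placement = None
    for margin in (2.0, 1.0, 0.0, -1.0):
        p = (d_lo >= r_lesion + margin) & (d_hi >= r_lesion + margin)
        if p.any():
            placement = p
            break
    if placement is None:
        raise SynthesisError(
            f"could not place a {n_voxels}-voxel centrum semiovale lesion"
        )
    # pick the placement voxel closest to the requested lateral position;
    # sub-voxel center offsets break lattice distance ties
    target = np.array([nx * x_fraction, ny / 2.0])
    cand = np.argwhere(placement)
    cx, cy = cand[np.argmin(((cand - target) ** 2).sum(axis=1))]
    center = (cx + 0.2183, cy + 0.3797, z_lo + 0.5)
    radius = radius_for_voxel_count(n_voxels, atlas.voxel_dims, center, eligible)
    return (center, radius, offset_wm, (z_lo, z_hi))


def wm_center_voxel(labels: np.ndarray, z_offset: int = 0) -> tuple[int, int, int]:
    """Centroid-nearest WM voxel, optionally shifted along the axial axis."""
    wm = np.argwhere(labels == WM)
    target = wm.mean(axis=0) + np.array([0, 0, z_offset])
    idx = np.argmin(((wm - target) ** 2).sum(axis=1))
    return tuple(int(v) for v in wm[idx])


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Generating model for a simulated very-preterm follow-up cohort.

    The Bayley-III motor composite is linear in normalized DWMA (slope per
    10-percentage-point increase), gestational age (per week) and the global
    brain abnormality score, with Gaussian residuals, floored at 40 (the
    "3 SD below the normative mean" assignment for untestable children) and
    capped at 160. Cerebral palsy is Bernoulli with log-odds linear in
    normalized DWMA per 10 percentage points.
    """

    n_subjects: int = 77
    intercept: float = 64.0
    beta_dwma_per10pct: float = -12.59
    beta_ga: float = 1.28
    beta_global: float = -0.89
    residual_sd: float = 9.5
    cp_intercept: float = -5.0
    cp_log_odds_per10pct: float = float(np.log(31.64))
    #: log-normal parameters for normalized DWMA, right-skewed with
    #: median exp(mu) ~ 0.0073, truncated below ndwma_max
    dwma_log_mu: float = float(np.log(0.0073))
    dwma_log_sigma: float = 1.9
    ndwma_max: float = 0.30
    ga_mean: float = 28.3
    ga_sd: float = 2.4
    pma_mean: float = 40.3
    pma_sd: float = 0.5
    n_centers: int = 4
    global_score_lambda: float = 2.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise SynthesisError("n_subjects must be positive")
        if self.residual_sd < 0:
            raise SynthesisError("residual_sd must be >= 0")
        if not 0 < self.ndwma_max < 1:
            raise SynthesisError("ndwma_max must lie in (0, 1)")


BAYLEY_FLOOR, BAYLEY_CEIL = 40.0, 160.0

COHORT_COLUMNS = {
    "id": "subject identifier",
    "gestational_age": "completed weeks at birth",
    "sex": "1 = male, 0 = female",
    "pma_at_mri": "postmenstrual age at MRI, weeks",
    "center": "NICU of birth, categorical code 0..n_centers-1",
    "global_score": "Kidokoro global brain abnormality total score",
    "visual_dwma_grade": "visual DWMA grade 0-3",
    "ndwma": "normalized DWMA volume (fraction of cerebral WM volume)",
    "bayley_motor": "Bayley-III motor composite (mean 100, SD 15, range 40-160)",
    "cp": "cerebral palsy diagnosis, 1 = yes",
}

#: visual grade prevalences: none/mild pooled ~60%, moderate ~27%, severe ~13%
_VISUAL_GRADE_P = (0.33, 0.27, 0.27, 0.13)


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a cohort as a DataFrame with the ``COHORT_COLUMNS`` schema."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    ga = np.clip(rng.normal(spec.ga_mean, spec.ga_sd, n), 23.0, 31.9)
    sex = rng.integers(0, 2, n)
    pma = rng.normal(spec.pma_mean, spec.pma_sd, n)
    center = rng.integers(0, spec.n_centers, n)
    global_score = rng.poisson(spec.global_score_lambda, n)
    visual = rng.choice(4, size=n, p=_VISUAL_GRADE_P)

    ndwma = np.minimum(
        np.exp(rng.normal(spec.dwma_log_mu, spec.dwma_log_sigma, n)),
        spec.ndwma_max,
    )
    x10 = ndwma * 10.0  # per 10-percentage-point units

    bayley = (
        spec.intercept
        + spec.beta_dwma_per10pct * x10
        + spec.beta_ga * ga
        + spec.beta_global * global_score
        + rng.normal(0.0, spec.residual_sd, n)
    )
    bayley = np.clip(bayley, BAYLEY_FLOOR, BAYLEY_CEIL)

    logit = spec.cp_intercept + spec.cp_log_odds_per10pct * x10
    p_cp = 1.0 / (1.0 + np.exp(-logit))
    cp = (rng.uniform(size=n) < p_cp).astype(int)

    return pd.DataFrame(
        {
            "id": [f"S{i:04d}" for i in range(n)],
            "gestational_age": ga,
            "sex": sex,
            "pma_at_mri": pma,
            "center": center,
            "global_score": global_score,
            "visual_dwma_grade": visual,
            "ndwma": ndwma,
            "bayley_motor": bayley,
            "cp": cp,
        }
    )
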