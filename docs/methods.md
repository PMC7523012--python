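# Methods

This note documents the models, parameter choices and numerical
conventions behind the package, and what the synthetic validation does and
does not establish.

## The quantification model

DWMA is operationalized as T2 signal intensity more than α population
standard deviations above the mean of all cerebral tissue, evaluated only
in the centrum semiovale. The statistics μ and σ are computed over voxels
whose GM **or** WM membership probability is at least τ (default 0.95);
this single filter is the partial-volume control — no explicit
partial-volume mixture classes are modelled. Candidate DWMA voxels must
additionally be confident WM (P(WM) ≥ τ), because the centrum semiovale is
by definition white matter; the strict inequality `I > μ + α·σ` is used.
σ is the population SD (ddof 0); with ~10⁵ eligible voxels the choice is
immaterial but it is fixed for bit-reproducibility.

**Cut-off α.** Default 1.8 SD. The 2.0 cut-off is exposed and tested:
because DWMA super-level sets are nested in α, the voxel count at 2.0 can
never exceed the count at 1.8, and in practice 2.0 labels only very small
regions.

**Centrum semiovale.** All volumes are reoriented to RAS+ on load, with
the axial (inferior→superior) direction along the third array axis, so
"the slice above" is always index + 1. Let k be the topmost axial slice in
which the lateral ventricles show a cross-section of at least 5 voxels
(the minimum-area rule makes the window robust to single-voxel
segmentation stragglers at the ventricular apex). The centrum semiovale is
the WM-labeled voxels of slices k+1 and k+2, eroded in-plane by 1 voxel
("central" white matter) with a ±2-voxel band around the mid-sagittal
plane removed. The slice window is localized on CSF-labeled voxels inside
the atlas ventricle-prior support (prior ≥ 0.5): on that voxel set the
intensity evidence and the prior agree, so the window does not depend on
how the EM resolves ambiguous boundary voxels. Erosion depth, band width,
window height and the minimum cross-section are all configuration fields.

**False-positive cleanup.** Isolated suprathreshold voxels (in practice
2–8 voxels near the interhemispheric fissure or peripheral WM) are removed
automatically by discarding 26-connected components smaller than 3 voxels;
the mid-sagittal exclusion band handles the fissure itself. Both replace a
manual editing step and are deliberately configuration-exposed since no
published rule exists.

**Volumes.** DWMA volume is exactly `n_voxels × ∏ voxel_dims`. The
normalization denominator (total cerebral WM volume) is the
posterior-weighted soft count by default, with a hard-count option
(`wm_volume_hard`); on clean segmentations the two agree to ≪1%.

## Preprocessing

**Bias field.** The corrector fits a degree-3 polynomial (in coordinates
normalized to [−1, 1]³) to log-intensities over the brain mask by least
squares and exponentiates the smooth part; the field is rescaled to mean 1
over the mask, so corrected global brightness is preserved. When an atlas
is available (the pipeline default) the fit target is first centred by a
piecewise-constant anatomy model — each voxel's expected log-intensity
given its atlas argmax tissue — which prevents the radial cortex/CSF
contrast pattern from being absorbed into the polynomial. Non-positive
masked intensities (possible after noise) are clamped to the smallest
positive masked value before the log. Order 3 against an order-2 truth
leaves headroom without inviting anatomy overfit.

**Normalization.** Robust median/IQR mapping to fixed anchors
(1000 / 100). This is an invertible positive-affine map, so the
μ + α·σ rule — itself affine-equivariant — makes the end-to-end DWMA mask
invariant to affine rescaling of the scanner output. A per-slice variant
is available but off by default: 3D acquisitions do not need it and it
breaks volume-wide affine equivariance. A z-score method is also provided.

## Tissue segmentation

A 3-class (CSF/GM/WM) Gaussian mixture with voxelwise priors from the
co-registered atlas, fitted by EM. The E-step computes posteriors
∝ prior × Gaussian likelihood in log space; the M-step re-estimates class
means and SDs from posterior-weighted masked intensities. Initialization
uses atlas-prior-weighted intensity moments — deterministic, so the whole
pipeline is seed-free after phantom generation. `prior_weight` blends the
atlas prior with a uniform prior (π′ = w·π + (1−w)/3); the default 1.0 is
pure atlas guidance. Convergence is declared when the relative change in
observed-data log-likelihood falls below 1e-5 (max 100 iterations);
non-convergence returns a result with a warning. A class whose posterior
mass falls below 10 voxels raises an error naming the class. SDs are
floored at 10⁻³ of the global intensity SD to keep likelihoods finite.
The likelihood sequence is asserted non-decreasing in the tests. Because
means and SDs are re-estimated each M-step, per-iteration EM updates are
exactly equivariant under positive affine intensity maps; only the
relative stopping rule can differ by an iteration.

Ventricles are recovered as 26-connected CSF-labeled components whose mean
atlas ventricle prior exceeds 0.5; the external CSF rim fails this rule.

## The synthetic phantom

The phantom is a nested-ellipsoid brain — background, CSF rim
(scaled radius 0.92–1.0), cortical GM ribbon (0.80–0.92), WM core, and two
ellipsoidal lateral ventricles strictly interior to the WM — sampled on a
96³ grid of 0.93 × 0.93 × 1.0 mm voxels by default. Class intensity means
are background 12, CSF 220, GM 138, WM 160 (arbitrary units): the ordering
CSF > WM > GM and the modest GM:WM contrast (0.86) reflect unmyelinated
neonatal white matter on T2; within-class texture SDs are 4/10/7/7 and
additive scanner noise has SD 2 (Rician optional), giving an overall
WM SNR of about 22. The multiplicative bias field is a random order-2
polynomial with peak deviation 0.20 over the brain. Atlas priors are
Gaussian-smoothed indicator maps (1.5 mm), quantized to 1/255 steps as
real 8-bit atlases are — so a class prior far from its tissue is exactly
zero rather than an infinitesimal tail, which matters for the ≥95%
membership filter at hyperintense lesion voxels.

Lesions are spheres (center-in voxel counting, so truth counts are
integers); an optional axial extent clips a sphere to a slice slab,
reproducing the sheet-like in-plane geometry of real DWMA, which spans
large in-plane areas but only a couple of axial slices. `cs_lesion_blob`
places such a lesion with an exact target voxel count inside the two
centrum semiovale slices, off-midline, and entirely within the
zero-CSF-prior white matter. Sphere centers may be fractional: on-lattice
centers produce tied voxel-center distances (symmetric shells), making
most exact counts unreachable. Lesion contrast is specified in multiples
of the pooled cerebral-tissue SD — the same σ unit the detection threshold
uses — and converted internally to the WM-texture-SD unit the phantom
stores; the default 3σ places a "clearly severe" lesion 1.2σ above the
1.8σ cut-off.

What the phantom does **not** emulate: cortical folding, myelination
gradients, partial-volume mixing at tissue interfaces, MR sequence physics
(no k-space), registration error between image and atlas, and motion.
Passing the phantom tests therefore demonstrates the correctness and
internal consistency of the algorithmic chain at realistic contrast and
noise — not performance on real scans, where registration quality and
anatomy-model mismatch dominate.

## The simulated cohort

Cohorts emulate a very-preterm follow-up study at term-equivalent age:
gestational age ~ N(28.3, 2.4²) weeks, PMA at scan ~ N(40.3, 0.5²), four
centers, a Poisson(2.8) global brain abnormality score, and visual DWMA
grades with prevalences 33/27/27/13%. Normalized DWMA is log-normal
(median 0.0073, log-SD 1.9, truncated at 0.30) — a right-skewed stand-in
matched to the observed median; the true distributional form beyond
median/IQR is unknown, and the log-normal choice is flagged as such. The
Bayley-III motor composite is linear in nDWMA (−12.59 points per
10-percentage-point increase), gestational age (+1.28/week) and global
score (−0.89/point) with residual SD 9.5, floored at 40 (the "3 SD below
the normative mean" assignment for untestable children) and capped at 160;
the floor is part of the generator, not re-imposed by any fitting code.
CP is Bernoulli with log-odds −5.0 + ln(31.64)·(nDWMA·10), giving ≈7%
prevalence. At n = 5000 both generating coefficients are recovered within
3 SEs in ≥95% of seeds; the acceptance script verifies this over 100
seeds.

## Statistics conventions

- **Clopper–Pearson**: Beta-quantile form; lower bound exactly 0 at x = 0
  and upper exactly 1 at x = n. Endpoints satisfy the defining binomial
  tail equations to 1e-9 (property-tested).
- **Likelihood-ratio CIs**: standard log-method (SE of log LR from the
  2×2 counts). No published method is attached to the reference values, so
  only LR point estimates are treated as exact.
- **Fisher's exact test**: two-sided probability-mass rule (all tables
  with the observed margins whose probability is at most the observed
  one, with 1e-7 numerical slack); delegated to `scipy.stats.fisher_exact`
  and cross-checked against full hypergeometric enumeration in the tests.
- **90th-percentile dichotomization**: strict `>` against the
  linear-interpolation percentile; with all values tied nothing is
  flagged.
- **Regression**: OLS and Newton-MLE logistic fits via statsmodels;
  rank-deficiency and complete separation raise informative errors
  (exact logistic methods are advised for the latter).
- **Bootstrap**: bias-corrected (BC) percentile interval by default, with
  full BCa (jackknife acceleration) as an option; B = 10 000 resamples by
  default, deterministic given a seed; a degenerate statistic returns a
  point interval with a warning.
- **Kidokoro categories**: total score 0–3 normal, 4–7 mild, 8–11
  moderate, ≥12 severe.
- Ties in posterior argmax resolve in the fixed order CSF < GM < WM.
  Coordinates are 0-based internally and 1-based in human-readable logs.

## Problem sizes

Unit tests run on 64³ phantoms; the acceptance suite and script use ten
96³ phantoms (lesion sizes 60–240 voxels, one of exactly 100) and 100
cohorts of n = 5000. The full test suite completes in well under a minute
of compute per phantom stage; the acceptance script takes a few minutes
end to end on one CPU.

## Known limitations

- The atlas is assumed perfectly co-registered; no registration is
  implemented or emulated.
- Single Gaussian per class: heavy partial-volume loads (real data) would
  inflate the fitted CSF SD and can attract very bright voxels where the
  CSF prior is nonzero; the τ filter mitigates but does not remove this.
- The polynomial bias model shares its basis with the generator's truth
  field (order 2 vs fitted order 3); real coil profiles are smooth but not
  polynomial, so real-data residuals will be larger.
- Skull stripping is atlas-derived only; mask-boundary voxels are not the
  tissue model's responsibility and are excluded from evaluation.
- With b ≠ 0, an affine intensity map a·x+b is not exactly invariant
  through the *log-domain* bias fit (only pure scaling is); the invariance
  property holds exactly from the normalization stage onward.
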