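# Methods

This note documents the models, parameter choices and numerical decisions
behind `petoverlap`, and what the synthetic experiments do and do not show
about real data.

## The phantom: what it emulates

Each generated case is a pair of co-acquired PET (SUV) + CT (HU) studies of
a pelvic tumor at two time points, with full ground truth.

**Geometry.** The PET grid defaults to 96×96×96 voxels at 4×4×4 mm (a
384 mm field of view); the CT covers the same field at 1.2×1.2×3 mm.
These are typical values for a modern whole-body TOF PET/CT scanner. Tests
and the acceptance script use a 48³ PET grid (192 mm field of view): the
pelvic organs and tumors up to ~120 cc fit comfortably, and every stage
runs an order of magnitude faster with identical intensity calibration.

**Anatomy.** A body ellipsoid (soft tissue, 40 HU), two iliac bone
ellipsoids (700 HU), a urine-filled bladder (10 HU), an air-filled rectum
(−900 HU) and the tumor bed between them. Organ positions and sizes carry
seeded jitter. The bladder *volume* differs between time points by
`bladder_fill_delta` (default +30% at recurrence): differential bladder and
rectum filling is the dominant failure mode of automatic pelvic
registration, and the hot-urine bladder (SUV 30, hotter than the tumor)
deliberately stresses ROI selection.

**Tumor.** The whole metabolic volume VT is a union of 2–4 overlapping
seeded ellipsoids — not a sphere, so overlap indices are not trivially
shape-symmetric — thresholded on its implicit union field at exactly the
voxel count matching `vt_target_cc`. The high-uptake sub-volume V1 is the
`v1_fraction` of VT voxels nearest a randomized interior anchor: a compact
blob strictly inside VT. Defaults (VT 41.9 cc, V1 fraction 0.43 → ≈18 cc,
V2 15.1 cc, SUVmax ≈19.5) match the cohort statistics the package is
calibrated against; cohort generation draws volumes from log-normal
distributions with those means/SDs (positive support, heavy right tail)
and SUVmax from a clipped normal (19.5 ± 7.4).

**Planted recurrence.** V2 is assembled directly from voxel counts: the
intersection part is the `round(X·|V1|)` voxels of V1 nearest a boundary
anchor, the remainder the nearest admissible voxels outside V1 (inside the
body, clear of bladder and rectum). Achieved X and Y are therefore exact
up to rounding (within ±0.02 by contract) and an inconsistent
(X, Y, v2_target_cc) request is rejected rather than approximated. When
X = 0 the recurrence is grown against a one-voxel clearance shell —
disjoint but adjacent, the regime in which delineation methods can
manufacture spurious overlap.

**Acquisition model.** The ideal piecewise-constant uptake map (background
SUV 1, tumor shell 6, high-uptake/recurrence 19.5, bladder 30) is convolved
with an isotropic Gaussian PSF (FWHM 6 mm, the resolution class of current
scanners) and corrupted by zero-mean Gaussian noise whose SD is the
tissue-class SD scaled by √(local uptake / background) — an approximation
to reconstructed OSEM noise without simulating reconstruction. A PSF FWHM
of exactly 0 means "no blur", so the zero-noise, zero-blur limit
reproduces the ideal map bit-exactly (used by the exactness tests). There
is no sinogram-level simulation, no scatter/randoms model, and no organ
deformation beyond bladder scaling.

**Misalignment.** The true rigid transform (intrinsic Z-Y-X Euler angles,
degrees; stored in every transform file) maps baseline-space points to
recurrence-space points. Inside `generate_case` the misalignment is
applied to the *ideal* recurrence content and the PSF/noise are applied
afterwards: the patient is repositioned before acquisition, so blurring
must happen in the misaligned frame — resampling an already-blurred noisy
image would smooth it a second time in a way no real acquisition does.

## Registration

Mattes mutual information (50 histogram bins) on the CT pair, initialised
by intensity centres of mass, optimised by regular-step gradient descent
over three resolution levels (shrink 4/2/1, smoothing 2/1/0 mm), with
regular (deterministic) metric sampling at 25%. The refined transform is
applied to the recurrence PET with linear interpolation onto the baseline
PET grid; masks are always resampled nearest-neighbour. If the final
metric is worse than the initial one the result is flagged as failed and
the initial transform returned. A manual correction is modelled as an
optional user-supplied transform composed after the automatic result (the
interactive step of the clinical workflow is not reproducible; a transform
file is). On 25-phantom batches with misalignments up to ~15 mm / 10°,
tumor-ROI target registration error is far below half a PET voxel.

## Fuzzy locally adaptive Bayesian segmentation

**Model.** Inside a tumor-bearing box ROI, intensities follow a mixture of
K hard Gaussian classes (K=3 baseline: background / tumor / high-uptake;
K=2 recurrence) plus fuzzy transition labels between each adjacent pair at
levels ε ∈ {0.25, 0.5, 0.75}: a fuzzy voxel has mean
(1−ε)μ_k + εμ_{k+1} and variance (1−ε)²σ_k² + ε²σ_{k+1}². Three levels
keep the label set small and testable. Per-voxel priors are locally
adaptive: 90% the mean posterior over the 3×3×3 neighbourhood plus 10%
the global label frequencies (λ = 0.1), renormalised.

**Estimation.** Deterministic EM-style iteration (posterior → parameter
update → prior re-estimation) to a 10⁻³ relative tolerance on the means,
capped at 100 iterations. Two details matter:

* *Mean update.* Each fuzzy label contributes weight (1−ε) to its lower
  class and ε to its upper class. Taking plain weighted moments with these
  weights drags the class means toward the middle of the partial-volume
  ramp (measured ~30% low on the 2-class tumor mean); the update instead
  solves the normal equations of the blended observation model — the
  proper M-step for means whose labels are ε-blends — with solutions
  clipped to the observed intensity range. Class SDs use the analogous
  weighted residual moments, floored at 10⁻⁶ of the intensity scale so the
  noiseless case stays non-degenerate.
* *Warm start.* A plain hard-class EM (same loop, no fuzzy labels) first
  locates the class plateaus from a deterministic quantile initialisation
  (means at the {25, 75}% or {25, 60, 95}% intensity quantiles; for K=3 a
  second candidate at {25%, midpoint, 95%} is also tried and the
  higher-likelihood fit kept). Without the warm start, fuzzy labels can
  capture plateau voxels while the parameters are still far off and the
  unconstrained mean solve diverges.

**Masks.** VT gathers both tumor classes and fuzzy voxels whose
tumor-side membership reaches 0.5; V1 the top class and high-side fuzzy
voxels at the same cut; V2 analogously for K=2. The cut is evaluated on
the *posterior-expected* class membership rather than on the arg-max fuzzy
label: the two agree when posteriors are concentrated, but the expected
membership places the boundary at the half-membership surface instead of
snapping to the discrete ε grid (which biased V2 outward by 2–3 cc).
Only the connected component containing the ROI seed (the SUVmax voxel,
computed with the bladder exclusion so hot urine cannot claim it) is
retained; V1 ⊆ VT by construction.

**ROI selection.** Automatic mode takes the bounding box of the largest
connected component above SUV 2.5 — ignoring a user-supplied exclusion box
around the bladder — dilated by 2 PET voxels. On phantoms the exclusion
box comes from the ground-truth bladder mask; on real data it is supplied
by the operator, mirroring the minimal manual input of clinical use.

**Comparator.** Fixed %SUVmax thresholding within the same ROI (largest
component, or the seeded component when a seed is given, in which case the
seed voxel defines SUVmax).

## Overlap analysis

Indices are computed by voxel-count set arithmetic on the baseline PET
grid; volumes convert by voxel volume. Reported values round to two
decimals; full precision is kept internally. Concordance bands are applied
after that rounding (the band grid is itself two-decimal, so rounding
closes the gap between 0.20 and 0.21). Jaccard is omitted as it ranks
identically to Dice. Whether published volumes were computed on the
baseline grid or native grids is generally ambiguous; this package fixes
the baseline PET grid for everything and says so.

The |V2| > |V1| exclusion: when the recurrence volume exceeds the baseline
sub-volume, V2 can swallow V1 entirely (X ≈ 1 regardless of spatial
specificity) and a boost volume smaller than the relapse volume is not a
useful escalation target, so flagged cases are summarised separately.
Cohort generation plants the flag deterministically in
`round(fraction·n)` cases so subgroup sizes are reproducible.

## The bias experiment

For true Dice strata {0, 0.1, …, 0.9}, phantom pairs are generated with
X = Y = Dice (hence |V2| = |V1|) and *no* misalignment — registration is
bypassed so the measured estimated-minus-true error isolates delineation
bias, which is what the experiment is about. Four cases per stratum keep
the stratum means stable. The `oracle` method (ground-truth masks) is a
zero-bias sanity row. At low true overlap (≤ 0.2) the 40%/40% threshold
pipeline shows a larger positive mean signed Dice error than the fuzzy
Bayesian pipeline: the threshold at 40% of the noise-inflated SUVmax sits
below the half-maximum of the blurred edge, dilating both masks and
inflating the thin intersection cap relatively more than the volumes.
70%/40% shows the opposite, negative bias at moderate-to-high overlap
(the 70% mask underestimates V1). Both reproduce, qualitatively, the known
failure modes of fixed thresholding.

## Problem sizes

Tests and the acceptance script use: 48³ PET grids; 25-case batches for
registration and segmentation recovery; 3 low-noise cases end-to-end;
10 strata × 4 cases for the bias experiment; 50 cases for cohort
calibration. These sizes give stable medians and fractions while keeping
a full run in the minutes range on a single CPU.

## Known limitations

* The phantom's tissue classes are piecewise-constant; real tumors have
  continuous heterogeneity, so segmentation accuracy here is an upper
  bound on real-data accuracy. Passing recovery tests demonstrates
  correctness of the implementation, not clinical performance.
* The noise model is Gaussian and spatially white; reconstructed PET noise
  is correlated, which would lower effective contrast-to-noise.
* Rigid registration only — deliberately, since deformable registration
  would itself bias the overlap being measured — so cases with true organ
  deformation are out of scope.
* The 2-class tumor mean remains a partial-volume compromise for very
  small or thin structures (tumor shells thinner than the PSF); this shows
  up as a minority of low-Dice VT outliers in the recovery batches.
* The estimation scheme is a deterministic EM-style variant chosen for
  reproducibility and testability; it makes no claim of bit-compatibility
  with stochastic implementations of the same model family.
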