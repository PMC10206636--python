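# Methods

## Ventilation defect segmentation

Both methods operate on the multiset of voxel intensities inside a
caller-supplied thoracic-cavity mask; no spatial regularization, connected
-component filtering, or minimum defect size is applied, and negative
intensities (possible in magnitude-MRI simulations) are accepted — they simply
fall below any threshold and into the lowest cluster.

### Adaptive threshold

The defect threshold is `factor × Mean_lower–upper` with defaults
`factor = 0.5`, window 5th–80th percentile. Percentile *interpolation* is
deliberately avoided: the window is a **rank window** — sort the N cavity
intensities ascending (ties in ordinal order) and keep ranks r with
`lower/100 · N < r ≤ upper/100 · N`. This is exact, hand-checkable, and
reproducible across languages; products within 1e-9 of an integer are snapped
before flooring so that the float representation of the percentile can never
shift the window by one rank. A voxel is defect when its intensity is
**strictly below** the threshold (a voxel exactly at the threshold is
ventilated). Cavities below 20 voxels are rejected: the window would be empty
or dominated by single voxels.

### 1-D k-means

Lloyd iteration on the cavity intensities with k = 5 clusters; the
`defect_clusters = 1` lowest-center cluster is the defect. Conventions:

* **Initialization** — deterministic multi-start: (i) the `(2i−1)/(2k)`
  quantiles of the intensities, (ii) the same quantiles of the *distinct*
  values, (iii) k points evenly spread over the value range. Each start runs
  to a Lloyd fixed point; the lowest within-cluster sum of squares (WCSS)
  wins. A single mass-quantile start is not enough: when one intensity mode
  holds most of the mass (a severe-defect lung, where ≥30% of the cavity sits
  in a tight near-zero mode), it seeds two or three centers inside that mode
  and Lloyd cannot merge them across the empty gap, so the "lowest cluster"
  is only a slice of the defect. The value-spread starts escape exactly that
  trap; no randomness is involved, so fits remain bit-reproducible.
* **Assignment ties** go to the lower-center cluster; an empty cluster is
  re-seeded at the sample point farthest from its current center.
* **Convergence** — centers move less than `tol × intensity range`
  (`tol = 1e-6`) *and* the assignment is unchanged, within `max_iter = 300`
  iterations; non-convergence returns a flagged result rather than an error.
* Fewer than k distinct intensities (e.g. a uniform field) is a degenerate
  distribution and raises.

At any returned fixed point every voxel is assigned to its nearest center and
every center equals its cluster mean; the test suite checks both conditions on
random instances and checks WCSS-optimality against an exact
dynamic-programming 1-D k-means oracle on instances of ≤ 60 points.

Both methods are scale-invariant: multiplying all intensities by c > 0 scales
the threshold linearly and maps k-means fixed points through the same affine
map, leaving both VDPs unchanged. VDP itself is a voxel count ratio; defect
and cavity volumes in mL follow from the voxel spacing.

## Digital lung phantom

The phantom provides the ground truth that patient data cannot: a ventilation
field whose true defect fraction is known by construction.

**Geometry.** Two ellipsoidal lungs (default semi-axes 45 × 80 × 55 mm,
30 mm medial gap) on a 128 × 128 × 64 grid at 2 mm isotropic — finer than
both output grids, so resampling is a genuinely degrading step. Defects are
random ellipsoids centered at cavity voxels with anisotropy ratios in
[0.6, 1.6]; a single global size scale is bisected until the realized cavity
fraction is within 0.01 of the target (bounded retries with re-randomized
centers; unreachable targets raise).

**Intensities.** Ventilated signal is an i.i.d. gamma field (shape 16, mean
1) smoothed over 10 mm and then re-scaled to restore the gamma marginal's
mean and coefficient of variation (CoV = 0.25). The smoothing sets only the
spatial correlation length; without the re-scale it would also flatten the
marginal, leaving an unrealistically homogeneous ventilated compartment —
real ventilation images show moderate regional heterogeneity, which is what
lets the adaptive threshold (which sweeps up hypo-ventilated voxels) read
slightly higher than k-means, as observed clinically. Defect voxels keep
`defect_contrast = 0.05` of the local ventilated value.

**SPECT-like observation.** Axial Gaussian smear (σ = 4 mm) as a surrogate
for averaging over tidal breathing → isotropic Gaussian PSF of 12 mm FWHM
(σ = FWHM/2.3548; the reconstruction filter width stands in for the
unspecified system PSF) → optional hot-spot foci (Gaussian bumps, σ = 4 mm ≈
a 1 cm focus, peak = `hotspot_amplitude ×` the 99th-percentile cavity
intensity, since real aerosol aggregation dwarfs the brightest normal
signal; default count 0) → exact volume-average resampling to 4.42 mm
isotropic voxels, 128 × 128 in-plane → global scaling to a cavity mean of 50
counts/voxel → Poisson sampling. The cavity mask is resampled by majority
vote (> 50% coverage).

**MRI-like observation.** Volume-average resampling to 3.125 × 3.125 × 15 mm
voxels (128 × 128 × 16) → smooth multiplicative bias field (Gaussian random
field, correlation length 80 mm, unit cavity mean, peak cavity deviation =
amplitude, default 0.2) → Rician noise `sqrt((S+n₁)² + n₂²)` with
σ = cavity mean / SNR (default SNR 20), the magnitude-image statistics an MRI
pipeline actually sees.

Resampling is separable exact overlap-weighted 1-D averaging (input and
output grids centered on the same physical midpoint), so a constant field
resamples to the same constant and integer-ratio resampling equals block
averaging.

**Seeding.** A master seed spawns fixed per-stage child streams (truth,
SPECT, MRI), so each observation of a phantom is reproducible independently
of whether the others ran. Experiment-level per-subject seeds derive from
(master seed, subject index), never from execution order.

**What the phantom does *not* emulate.** Airway trees and aerosol deposition
physics; attenuation and scatter; k-space acquisition; lung-inflation
differences between modalities (the axial smear is the single surrogate for
motion/inflation effects); and mask misregistration (truth masks are
perfectly aligned). One consequence is worth stating plainly: in this forward
model the SPECT branch *blurs more* than the MRI branch, and blurring a
low-contrast defect moves its measured boundary inward (the blurred edge
crosses the adaptive threshold — ≈ 0.45 × cavity mean, below the
defect/ventilated midpoint — inside the true defect). Simulated SPECT VDP
therefore reads ~2–3 percentage points *lower* than simulated MRI VDP on the
same phantom, whereas clinical studies report the opposite direction; the
clinical bias is attributed to lower lung inflation during tidal-breathing
acquisition, aerosol hot-spots in severe obstruction, and mask registration
error — mechanisms outside this model. Passing phantom tests therefore
validate the *quantification* pipeline and the sign and strength of
cross-modality correlation, not the sign of the clinical inter-modality bias.

## Statistics

* **Bland–Altman**: differences `d = y − x` (default convention MRI − SPECT,
  reported with every result, so a bias towards higher SPECT appears
  negative); bias = mean(d), SD with n−1, 95% limits of agreement =
  bias ± 1.96·SD.
* **Correlation**: Spearman = Pearson on average-ranked data (ties →
  average ranks). p-values by full permutation enumeration for n ≤ 10
  (exact, conditional on the tie pattern), t-approximation otherwise.
  Zero-variance series are an explicit error, not a NaN.
* **Paired comparison**: Shapiro–Wilk on the differences gates a paired
  t-test vs a Wilcoxon signed-rank (zeros dropped, tie-corrected normal
  approximation); the branch taken is always reported. All-zero differences
  → p = 1, "degenerate"; constant nonzero differences cannot be gated and
  raise.
* **Group comparison**: Shapiro–Wilk on pooled within-group residuals gates
  one-way ANOVA + Tukey HSD vs Kruskal–Wallis + Dunn's rank z-tests
  (tie-corrected, Bonferroni-adjusted — the adjustment choice is ours).
  Groups need ≥ 3 members; all-identical data short-circuit to p = 1.

## Problem sizes and tolerances

Unit tests use a desk-scale phantom (48 × 48 × 32 at 3 mm) where only
mechanics are exercised; parameter-recovery and cohort checks use the default
phantom (128 × 128 × 64 at 2 mm). The simulated comparison cohort is 20
subjects with defect fractions uniform on [0, 0.5] and default observation
models. `scripts/acceptance.py` uses 120 random cavities for the threshold
oracle, 60 instances (≤ 60 points) for the k-means/DP cross-check, 4
fractions (5–50%) for noise-free recovery, and the 20-subject cohort for the
cross-modality comparison. Grid-compatibility spacing tolerance is 1e-3 mm —
tight enough to catch silent resampling mismatches, loose enough for float
serialization round-trips.

## Known limitations

* The phantom's defect borders are sharp ellipsoid shells; real defects have
  graded borders and lobar anatomy.
* VDP is a single whole-lung number; regional/lobar quantification is out of
  scope, as are registration, DICOM I/O and 4-D data.
* The optional hot-spot and intensity-capping knobs are sensitivity tools,
  not calibrated models of aerosol aggregation.
* With heavily tied intensity data the k-means fixed point can in principle
  have coincident centers, which is reported as an error (strictly ascending
  centers are part of the result contract).
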