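# Methods

## Model and procedure

The pipeline analyzes a paired two-group, two-condition imaging design:
every subject contributes one scan per season (summer, winter) and belongs
to one group (nonSAD, SAD). Scans enter as 3-D parametric volumes with a
scalar intensity per voxel (BP_ND-like units), are optionally smoothed
with an isotropic Gaussian (σ = FWHM / (2√(2 ln 2)), reflect boundary),
and are masked to voxels with gray-matter probability strictly above 0.1
and CSF probability strictly below 0.3. Masked volumes become rows of
**X** (scans × voxels); the group × season cell of each scan is one-hot
coded in **Y** (scans × 4, column order nonSAD-summer, nonSAD-winter,
SAD-summer, SAD-winter).

Both matrices are standardized columnwise — mean 0, *sample* SD 1
(ddof = 1); zero-variance columns are set to zero rather than dropped so
voxel indexing survives. The contrast-based PLS model is the economy SVD
of the cross-product **E** = **Y**ᵀ**X** = **UΔV**ᵀ, truncated at
L = min(4, voxels, rank **E**). Covariance fractions use squared singular
values (δ²/Σδ², the common PLS convention; δ/Σδ is available as a
switch). The SVD sign indeterminacy is resolved per LV by making the
largest-magnitude element of each design salience positive, so output is
deterministic across linear-algebra backends.

## NPAIRS split-half validation

Each of `n_splits` (default 1,000) resamples assigns whole subjects to
two halves, stratified within group: a group's subjects divide as evenly
as possible, with the larger side of an odd group chosen at random. Both
scans of a subject stay together, so with 13 + 6 subjects the halves are
always 20 and 18 scans — exactly equal halves are impossible at the
subject level, which also caps the subspace dimension at
min(half size) − 1 = 17.

Each half is standardized with its own column statistics (a switch allows
global statistics instead), reduced to its top-k principal components,
and PLS-fit in that subspace. Training and prediction correlations use
the full cross-product: r_train,i = ρ(vec **Y**ᵢ, vec **X**ᵢ**E**ᵢᵀ) and
r_test,i the same with the held-out half projected through half i's PC
basis and cross-product (a per-LV variant — correlating the retained LV's
design and brain scores — is a switch). Spatial reproducibility is the
Pearson correlation of the two halves' retained voxel salience patterns,
mapped back to voxel space.

Three conventions make the per-voxel statistics well defined:

* **Retained-LV tracking.** The LV compared across halves is the one whose
  salience correlates most strongly (in absolute value) with the LV-1
  pattern of a full-data reference fit, guarding against LV order swaps
  between halves.
* **Sign alignment.** Half A's salience is flipped to correlate positively
  with the reference pattern; half B's is flipped to have positive inner
  product with half A's. Without alignment r_spatial, the across-split
  salience mean and its SE would all be meaningless.
* **Zero-SE voxels.** Saliences are unit-norm maps, so a split-half SE at
  the 1e-12 scale is floating-point jitter of identical patterns; such
  voxels are reported as missing (NaN) in the Z map rather than as
  infinite Z.

Per split the aligned salience pair is averaged into one split-map;
across splits the mean, SE (SD over split-maps, ddof = 1) and their ratio
(Z-score_split) are computed per voxel. Significance of a pattern is
empirical: p = (1 + #{samples ≤ 0}) / (1 + n) over the pooled r_test
samples (two per split) and over the r_spatial samples. The add-one rule
keeps p strictly positive and counts ties against the hypothesis.

## Subspace selection

`select_optimal_k` evaluates k = 1..k_max over one shared split schedule
(a master seed spawns one child seed per split, so every k — and the
no-reduction reference — sees identical splits and the curves are
directly comparable, as well as bitwise reproducible). Performance is the
printed sum-of-squares D(k) = (1 − mean r_spatial)² + (1 − mean r_test)²,
whose argmin coincides with that of the Euclidean distance from the ideal
point (1, 1); ties break toward the smallest k. PCA is computed per
training half, never globally, so no held-out information leaks into the
subspace. Pattern robustness across k is the correlation of each k's
sign-aligned mean salience map with the selected k\*'s map.

On planted phantoms the D(k) curve is nearly flat beyond the planted
rank (variations within ~0.01), so the exact argmin wanders among small
k values with resampling noise; the stable findings are that D(k\*) is at
or below the no-reduction reference and that the selected pattern barely
changes across k (correlations > 0.99).

## Reporting

The Z map is thresholded at ±2.8 (two-sided normal tail ≈ 0.005);
positive and negative exceedance sets are labeled separately by connected
components (default 26-connectivity; 6 and 18 available and recorded in
output metadata), so clusters of opposite sign never merge. Components
smaller than 640 mm³ (converted to voxels by the cube of the voxel size)
are discarded; the peak is the max-|Z| voxel, ties resolved to the
lexicographically smallest coordinate. NaN voxels never exceed threshold.

Brain scores (standardized **X** times **V**) are centered by the grand
mean over all scans (the unweighted mean of the four condition means is a
switch — with unequal group sizes the two differ) and summarized per cell
with percentile bootstrap 95% CIs (default 1,000 resamples, drawn within
each condition). Six pairwise contrasts are tested: the two within-group
season comparisons by paired t-tests (pairing on subject), the four
remaining cell comparisons by pooled-variance two-sample t-tests.
Pooled variance (not Welch) is used throughout because only the pooled
form reproduces the published demographic-table p-values from their
printed summary statistics. Bonferroni correction multiplies by exactly 6
and is deliberately not capped at 1, so corrected values remain
comparable across tables. `t_from_summary` exposes the pooled test
computed directly from (mean, SD, n) pairs.

## The synthetic cohort generator

`PhantomSpec` defaults define the study conditions the pipeline targets:
13 + 6 subjects scanned in both seasons (38 scans) on a 16³ grid of 2 mm
voxels. Each scan is

    volume = baseline + c(group, season) · effect_map + subject_offset + noise

with baseline 2.0 BP_ND (a typical high-binding-region scale), a planted
effect map of one positive and one negative 5 mm sphere of 0.3 BP_ND
(a moderate fraction of baseline, comparable to reported seasonal
serotonin-transporter changes), c = +1 for nonSAD-winter, −1 for
SAD-winter, 0 in summer (configurable), whole-volume subject intercepts
of SD 0.15 and i.i.d. voxel noise of SD 0.25. Spheres include a voxel iff
its center lies strictly within the radius; overlapping regions sum.
One RNG stream per cohort is seeded from `spec.seed`, with all subject
offsets drawn before any noise field so enlarging a simulation never
changes earlier draws. Companion GM/CSF probability volumes (GM = 1
inside a centered ellipsoid, CSF = 0) make the default masking keep
exactly the phantom "brain".

What the generator deliberately does **not** emulate: PET count noise
(Poisson, resolution-dependent), spatial noise correlation, anatomical
structure, kinetic-model bias, or registration error. Consequently,
passing tests demonstrate the statistical machinery — recovery of a
planted linear pattern under Gaussian noise with subject random effects —
not robustness to PET physics; effect sizes detectable here may not be
detectable in real parametric images.

## Numerical and design notes

* Column standardization equalizes every voxel's variance, so "signal
  strength" on a phantom is governed by the planted network's spatial
  extent and its correlation structure as much as by its amplitude; in
  the noise → 0 limit the background (pure-noise) voxels still carry
  unit-variance columns.
* The split Z-score measures within-cohort stability, not population
  significance: with very low noise even background structure becomes
  stable and exceeds |Z| = 2.8. At realistic noise and with protocol
  smoothing, planted-region exceedance rates separate cleanly from
  background.
* Under the null (no planted effect) the empirical p_test is approximately
  calibrated but mildly anticonservative in paired designs
  (type-I fraction ~0.05–0.12 across simulation batches at nominal 0.05);
  without subject random effects it is conservative. This reflects the
  pooling of correlated per-split metrics, not an implementation defect.
* Anisotropic voxels raise an error instead of silently resampling;
  coordinates are 0-based voxel indices (an affine from a NIfTI header is
  carried through I/O for downstream reporting in world coordinates).
* Smoothing is applied to the parametric volumes themselves; in
  acquisition pipelines smoothing may instead precede kinetic modeling —
  the two are not equivalent, and the choice is exposed as `fwhm_mm`.
* Default problem sizes in tests and the acceptance script (16³ and 12³
  grids, 80–200 splits, k ≤ 10) are chosen so the full suite runs on a
  single CPU in minutes while leaving every statistical property
  measurable; the protocol-scale defaults (1,000 splits, k up to 17) are
  the library defaults for real use.

## Known limitations

Behavioral PLS (continuous covariates), seed PLS, bootstrap salience
errors, FDR or permutation cluster inference, atlas labeling, and
between-space resampling are out of scope. The half sizes forced by
subject-level splitting (20/18) mean a "half" is not exactly half the
scans; metrics inherit a slight asymmetry that the matched-sampling
stratification keeps balanced across groups.
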