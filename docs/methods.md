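# Methods

## Volume-change maps

A registration of a subject brain to a reference atlas yields a
displacement field **u**(x) (µm) on the reference grid, with the
convention T(x) = x + **u**(x) mapping reference to subject coordinates.
The per-voxel Jacobian determinant J(x) = det(I + ∇**u**) is computed by
central differences in physical units (one-sided at the grid boundary, so
affine fields are reproduced exactly everywhere); anisotropic spacing is
handled by differencing in µm. The log Jacobian determinant (LJD) map
log J is the morphometry readout: 0 for a perfect match, negative where
the subject is locally smaller than the reference. Voxels with
J ≤ `min_jacobian` (default 0.05) indicate local folding of the
transform; they are clamped to log(min_jacobian) and reported, and a
field with more than 1% folded voxels is rejected as an invalid
registration rather than silently clamped.

Division volumes are measured by integrating J over atlas-space labels:
volume(d) = Σ_{label=d} J·(voxel volume). This equals the volume of the
label's image in subject space and is therefore mathematically equivalent
to counting voxels after inverse label propagation, but is smooth and not
limited by voxel quantization. The pull-back route (fixed-point inversion
x ← y − **u**(x), nearest-neighbour label lookup, voxel counting) is
provided as a cross-check; note it cannot resolve sub-voxel deformations,
so the two routes are compared on super-voxel (affine) test fields.

## Group statistics

Voxelwise two-group comparisons use two-sided independent-samples
t-tests, pooled-variance by default with a Welch option (the choice is
exposed because neither is canonical for imaging cohorts of this size).
Voxels with zero variance in both groups are assigned p = 1 and flagged.
Combining two crispant experiments uses an additive two-way ANOVA per
voxel — main effects of genotype and batch, no interaction, Type II model
comparison — which treats the experiment identity purely as a nuisance
shift; an interaction term is available behind a flag. Regional volume
comparisons report the t-test together with a seeded 5000-resample
percentile bootstrap CI of the mean difference; the three-condition
rescue design uses a one-way ANOVA with unadjusted pairwise two-sided
post hoc t-tests (multiplicity correction is deliberately not applied;
with three groups the reader can Bonferroni-adjust trivially).

## From p-map to affected-region mask

The filter chain is fixed as: p ≤ α threshold (α default 0.01, boundary
inclusive) → removal of connected components smaller than `min_cluster`
(default 50 voxels, 26-connectivity) → bilateral-symmetry filter → second
cluster pass. The symmetry filter keeps a voxel iff some retained voxel
lies within `sym_tol` voxels (Chebyshev distance, default 2) of its
mirror position about the grid mid-sagittal plane (index reflection
x → nx−1−x; the atlas is assumed midline-aligned). Each filter is
idempotent. The affected-region mask is directional by default: only
voxels where the mutant group is locally *smaller* are eligible, since
the mask is meant to delineate a hypotrophic region; a sign-blind mode
exists for exploratory maps.

Two properties of this chain are worth knowing. First, the second
cluster pass matters under spatially correlated noise: the symmetry
filter leaves small fragments wherever a noise blob partially matches a
mirror blob, and these fragments would otherwise survive as spurious
masks. Second, a cluster straddling the midline is its own mirror image,
so the symmetry criterion cannot reject midline noise; the directional
constraint and the cluster passes mitigate but do not remove this blind
spot. No voxelwise multiplicity correction is applied — the chain
implements the filter-an-uncorrected-map workflow, and its false-positive
behaviour is characterised empirically on null cohorts (below).

## Synthetic data: what it emulates and what it does not

The generator produces, deterministically from (spec, seed):

* **Atlas** — a 64×80×48 voxel grid at 2 µm isotropic spacing with eight
  ellipsoidal divisions (midline telencephalon, cerebellar plate,
  tegmentum and medulla; mirrored optic-tectum and lateral
  cerebellar-plate twins), exactly mirror-symmetric by construction, plus
  a 3-channel intensity image (pan-neuronal / glutamatergic-like /
  GABAergic-like) with division-specific means.
* **Cohorts** — per-subject fields u = (random warp) + (implanted
  atrophy). The random warp emulates residual registration error:
  per-component Gaussian-smoothed white noise, kernel σ = 12 µm
  (6 voxels), scaled to 0.5 µm RMS per component. These defaults were
  chosen so that (a) the fields are comfortably diffeomorphic
  (J ∈ ~[0.83, 1.19]) as the generator's positivity contract requires,
  and (b) between-subject LJD noise (SD ≈ 0.04–0.06) gives the designed
  study sizes (14 vs 17) high power against a 20% volume loss — i.e.
  they encode the regime in which the original workflow operates, where
  the imaging phenotype is robustly detectable and replicable. Larger
  warp amplitudes at this smoothness fold the transform.
* **Atrophy** — a radially symmetric contraction of the target ellipsoid
  with uniform linear scale a = s^(1/3) (so J = s exactly inside),
  blended to identity across a surrounding shell (outer radius 2× the
  division) by a monotone C¹ cubic profile that maps the shell onto
  itself: the volume lost inside is regained in the shell, total brain
  volume changes by < 1%, and untouched divisions keep their volumes to
  within 0.1%. This mirrors a localized deficit with no overall
  brain-size phenotype. The default implanted s = 0.8 is a test-bed
  choice, not an empirical effect size.
* **DE tables** — two 3 vs 3 negative-binomial experiments
  (var = µ + 0.05 µ², lognormal means) sharing `n_shared_de` genes with
  identical effect signs, plus experiment-specific DE genes. Per-gene
  p-values are a two-sided t-test on log2(count+1): a deliberate,
  documented simplification standing in for a GLM fit — the downstream
  convergence analysis consumes only (baseMean, log2FC, p) tables, so
  the stand-in only needs calibrated nulls and monotone power, not
  DESeq2's estimator.
* **Traces** — electropherograms as Gaussian peaks (width 0.7 bp,
  consistent with single-base CE resolution) on a noisy baseline, with
  the wildtype peak carrying a known fraction of total area and the rest
  split over indel peaks at ±bp offsets.

What passing tests on these data do **not** show: robustness to real
registration failure modes (anatomy-correlated distortion, intensity-
dependent bias), to non-Gaussian LJD noise, to library-size or
dispersion misspecification in counts, or to CE stutter and dye
artifacts. The generator's noise is exchangeable across subjects by
construction, which is exactly what makes the statistical calibration
checks meaningful.

## Numerical and design choices

* Peak detection: prominence threshold 2% of max signal plus an absolute
  floor of 5× a robust noise SD (MAD of the first-differenced signal).
  The low relative threshold is required because an efficient guide
  leaves indel peaks of only a few percent of the dominant peak; the
  absolute floor keeps all-noise traces empty. Peak areas are trapezoid
  integrals between the signal minima separating adjacent peaks.
* Expected wildtype product size = declared amplicon size + 25 bp
  (18 bp forward + 7 bp reverse fluorescent primer tags), configurable;
  matching tolerance 2 bp.
* BH FDR is a direct step-up implementation (sorted p·m/rank with
  cumulative-min monotonicity enforcement); significance is adjusted
  p strictly below α = 0.1. The expression filter requires
  baseMean ≥ 100 in *both* experiments. The hypergeometric overlap test
  is evaluated through the survival function (log-space internally) and
  applied to the total overlap; a sign-stratified variant is available.
* Null calibration is assessed on a decorrelated voxel lattice (stride
  12 voxels = 2× the warp smoothing kernel, staggered across runs)
  pooled over replicate null cohorts: LJD maps are spatially correlated,
  so the binomial reference for the rejection fraction is only valid on
  approximately independent voxels. The per-voxel test itself needs no
  such adjustment.
* Bootstrap CIs use 5000 percentile resamples seeded from the run
  configuration; all generators are pure functions of (spec, seed), and
  per-subject seeds derive from a seed sequence, so every stage is
  exactly reproducible.
* Problem sizes in the shipped test-suite and acceptance script (20 and
  10 replicate cohorts respectively, 64³ oracle fields) were chosen so a
  full run completes in minutes on one CPU while leaving the binomial
  acceptance bands meaningful.

## Known limitations

Elastic registration itself is out of scope — the pipeline consumes
displacement fields. The symmetry filter assumes a midline-aligned
atlas and cannot reject midline-straddling clusters (above). The
pull-back volumetry mode is quantization-limited for sub-voxel effects.
The DE p-value stand-in is not a count-model fit and should not be used
on real counts — real DESeq2/edgeR output tables are the intended input.
Percentile-bootstrap CIs can be mildly anti-conservative at very small
group sizes.
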