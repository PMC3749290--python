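# Methods

This note records the models implemented by `lungdens`, the parameters that
matter, the choices made where the design was genuinely open, and what the
synthetic data do and do not establish.

## Densitometry

A lung voxel belongs to the emphysema density mask when its value is **at or
below** the threshold (default −950 HU).  The comparison is inclusive;
implementations in the literature differ on this point, so it is fixed
explicitly and tested at exactly −950 HU.

- **LV, EV** are voxel counts times the voxel volume (product of the spacings
  / 1000, in ml).  **EI = EV/LV** is stored as a fraction and displayed as a
  percentage with one decimal.
- **MLD** is the arithmetic mean HU over the lung mask.
- **LW** uses the linear water–air density model ρ(HU) = (HU + 1000)/1000
  g/ml, clamped at 0 below −1000 HU.  No authoritative formula exists for
  this quantity in scanner software; the water–air model is the standard
  reconstruction and is labelled as such.
- **15th percentile** is the inverse empirical CDF without interpolation:
  the smallest observed HU value h such that the fraction of lung voxels
  strictly below h is ≥ 0.15.  Ties and discreteness are resolved by that
  "smallest h" rule; if no observed value qualifies (e.g. a constant lung),
  the maximum observed value is returned so the result stays inside the
  observed range.  The target fraction 0.15 = 3/20 is handled in integer
  arithmetic to avoid float-boundary errors.
- The density **histogram** uses uniform 1 HU bins over [−1024, 200] HU by
  default; out-of-range values are clipped into the edge bins with a logged
  warning, preserving the count-conservation invariant.
- **Exclusion masks** (cysts, sacculations, bronchiectases) are subtracted
  from the emphysema mask only.  MLD and the 15th percentile are computed
  over the uncorrected lung mask: a correction can therefore only lower EI,
  never change MLD.  This matches the clinical workflow in which manual
  correction redefines which low-attenuation voxels count as emphysema, not
  which voxels are lung.
- **MinIP** is a sliding-slab minimum filter along one axis (default 5 mm
  slab); the output grid matches the input.

## Segmentation

The pipeline is a classical, fully deterministic threshold design; every
parameter is recorded in the result for reproducibility.

1. **Body**: largest 26-connected component above −200 HU, holes filled
   per slice.
2. **Airways**: seeded 3D region growing from a trachea seed.  The seed is
   found automatically as a round air component of 50–500 mm² inside the
   body on the top third of slices (a manual seed can be supplied).  The
   growing threshold is relaxed from −1000 HU in 10 HU steps up to the lung
   air threshold; when the grown volume jumps by more than the leak step
   (default 20 ml) between consecutive thresholds, growth has escaped into
   parenchyma and the last pre-leak tree is returned.  The whole grown tree
   is excluded from the lung so airway lumen air is never counted as
   emphysema.
3. **Lungs**: voxels below the air threshold (default −500 HU) inside the
   body minus the airway tree; connected components of at least the minimum
   lung volume (default 50 ml) are retained, at most two.  Morphological
   closing (default 2 mm radius, as an anisotropic ellipsoid in voxel
   units) reincorporates vessels and septa.  If the lungs touch across the
   midline, the merged component is eroded (6-connected, for fine steps)
   until two cores appear, and every voxel is assigned to the nearer core
   by Euclidean distance, ties toward the right lung, for determinism.
   Right = label 1 is the lung with the smaller centre-of-mass column
   (supine patient convention).
4. **Air calibration**: mean HU of air outside the body (excluding the
   bottom 15 % of rows per slice, where the patient table sits) is checked
   against −1000 HU with a default tolerance of 6 HU, a typical scanner QA
   band.  The clinical procedure behind "controlled for extra-corporal air
   attenuation" is not publicly specified; this region definition is our
   reconstruction.  A failed check logs a warning but does not abort.

Defaults (−500 HU air threshold, 20 ml leak step, 2 mm closing, 50 ml
minimum lung volume) are standard values in the CT-densitometry literature
and all overridable.  Whether clinical software includes intrapulmonary
vessels in LV is not documented; this implementation excludes the airway
tree and includes closed-in vessels.

## Phantoms

Phantoms are two lung ellipsoids inside a soft-tissue body ellipsoid
(+40 HU) surrounded by −1000 HU air, on a 56×72×72 grid at 3 mm isotropic
spacing by default (≈ 420 ml per lung — compact enough for fast tests while
large against the 50 ml component filter).  Parenchyma is −850 HU,
emphysema −980 HU, so the −950 HU threshold separates them cleanly at the
tested noise levels (σ ≤ 7 HU).

The airway is a vertical trachea (8 mm radius) branching into two main
bronchi, carved at −1000 HU **inside a soft-tissue wall**.  The wall is
dilated to at least one voxel thickness whatever the grid spacing: real
airway walls are what keep seeded region growing confined to the lumen, and
a sub-voxel wall would let the growing escape through diagonal adjacency.

Emphysema lesions are spheres of 2–8 mm radius placed by rejection-free
weighted sampling with pattern-specific priors: distance-to-pleura decay
(subpleural), distance-to-airway decay (bronchovascular), an interior core
prior (centrilobular), or uniform (diffuse).  Placement continues until the
designed voxel fraction is reached, then the mask is trimmed voxel-exactly
to `round(fraction · n_lung)` voxels by seeded random removal.  The
recorded *achieved fraction* (count / n_lung) is what ground-truth
densitometry reproduces exactly; it differs from the requested fraction by
at most half a voxel's worth of quantization.  Cysts are air lumina inside
soft-tissue walls; cyst voxels are removed from the emphysema truth because
they are lesions, not emphysema.  Gaussian HU noise is added last; all
ground-truth masks are constructed before noise.

The noise model is additive white Gaussian.  Real CT has correlated,
kernel-dependent texture, partial-volume boundaries, gravity-dependent
density gradients, and motion artefacts — none of which are simulated.
Passing phantom tests therefore establishes the *logic* of segmentation and
densitometry (thresholding, connectivity, exclusion arithmetic, metric
definitions), not performance on clinical images.

## Cohorts

Each synthetic cohort has 41 CF and 21 control subjects (39 and 15 with
pulmonary function data).  Ages are clipped log-normals matched to the
group medians (20.1 and 30.4 years) over ranges 7–66 and 4–68 years.

EI (in %) follows a group-specific line in age plus Gaussian noise, floored
at 0: slopes 0.35 (CF) and 0.04 (control) %/year, noise SD 2.0 and 0.7 %,
control intercept 0.3 % at age 0.  The noise SDs and baseline were chosen
once so that the floor at 0 remains a small perturbation relative to the
slope's confidence interval (large noise at young ages, where the line is
near 0, would otherwise bias the OLS slope) while keeping group spreads in
a clinically plausible range.  With zero noise and age ranges where the
floor is inactive, EI is an exact linear function of age.

The **designed onset age** (13 years) is the age at which the *expected*
95 % confidence bands of the two regressions separate.  The CF intercept is
solved from that condition using the realized age moments and the true
noise SDs; the mean-line crossing is correspondingly earlier.  This
operationalizes "the CI limits intersect at ~13 years" as the first age at
which the CF band's lower limit reaches the control band's upper limit —
the rule also used by `ci_band_intersection`, found by grid scan plus
bisection to 0.1-year precision.

FEV1% is a bounded logistic link decreasing in EI plus Gaussian noise whose
SD is **calibrated by an internal Monte-Carlo** (fixed internal RNG, cached
per parameter set, independent of the user seed) so that the mean realized
Spearman correlation between EI and FEV1% in CF equals the target −0.66.
The remaining lung-function variables carry the sign structure of the
clinical design: RV/TLC increases with EI plus a CF offset, RV = RV/TLC ·
TLC, VC = TLC − RV, perc15 decreases with EI, LW increases with RV plus a
CF offset, MLD carries both a negative EI effect and a positive CF
(mucus/inflammation) offset so the group means stay similar, and CT lung
volume tracks TLC minus a 400 ml offset with 150 ml noise (pooled Pearson
r > 0.99).  A crude body-size factor (linear in age up to 20 years) scales
the absolute volumes so children are smaller.  Subjects losing their PFT
values are chosen at random.

## Statistics

- Group comparison `auto` mode uses Student's t (equal variances) when both
  groups pass Shapiro–Wilk at 0.05, otherwise the Wilcoxon rank-sum
  (Mann–Whitney U) test; summaries are mean ± SD or median (range)
  accordingly.
- Correlation method rule: Spearman when either variable is EI or a
  dimensionless percent-predicted/ratio variable (FEV1%, VC%, RV%, TLC%,
  RV/TLC, FEV1/VC); Pearson for absolute-valued variables.  Spearman ties
  use average ranks; p-values are exact permutation below n = 10 and the
  t-approximation otherwise.
- Bonferroni: the per-test threshold is α/m with m the number of PFT
  variables tested per densitometry metric (7 in the default design,
  0.05/7 ≈ 0.007); m is recomputed when the variable list changes.
- Variance explained is 100·r² **truncated** (not rounded) to an integer
  percent, matching the conventional display (0.66² = 43.56 → 43 %).
- Slope comparison uses the group×age interaction term of a pooled OLS
  model (ANCOVA) rather than a z-test on separate fits, so the residual
  variance is pooled.
- Regression bands are the standard t-based mean-response confidence
  intervals; the band is fully determined by (slope, intercept, residual
  SD, n, age mean, age sum-of-squares), which are all stored.

## Problem sizes

Default phantoms are 56×72×72 voxels; brute-force oracle comparisons use
40×48×48 grids; cohort Monte-Carlo checks use 100–200 replicates of the
62-subject design.  These sizes were chosen so the complete suite runs in
well under an hour on a single core while keeping every Monte-Carlo
tolerance comfortably away from its decision boundary.

## Known limitations

- No resampling, registration, or kernel harmonization; all masks must
  share the CT grid.  Direction cosines are preserved through I/O but
  ignored by computation (densitometry is orientation-invariant).
- No lobe segmentation, no machine-learned segmentation, no
  expiratory-scan air-trapping index (the −860 to −950 HU band), and no
  texture-based emphysema subtyping.
- The phantom airway tree has only two generations; the cohort generator's
  link functions are structural stand-ins, not physiological models — they
  reproduce sign structure and designed correlation/slope targets, not
  clinical marginal distributions.
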