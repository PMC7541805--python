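# Methods

## Grid and unit conventions

An SUV volume is a 3D grid of body-weight-normalised standardized uptake
values with per-axis voxel spacing (mm) and a world origin at the centre of
voxel (0, 0, 0); world position = origin + index × spacing. Masks must
share the SUV grid exactly — feature values are spacing-sensitive, so a
mismatch raises an alignment error rather than triggering an implicit
resample. Lesions are connected components of the binary mask
(26-neighbourhood by default, configurable to 6 or 18; with touching
lesions the count is connectivity-dependent), labelled deterministically by
descending voxel count with lexicographic tie-break. Units follow the
field's convention: volumes cm³, surfaces cm², distances mm, SUV unitless.

## The twelve parameters

* **SUVmax / SUVmean** — maximum and voxel-count-weighted mean SUV over the
  union of all lesion voxels. The voxel-weighted mean (rather than a mean
  of per-lesion means) is chosen so that TLG equals the voxelwise integral
  of SUV for uniform uptake.
* **TMTV** — Σ lesion voxels × voxel volume.
* **TLG** — TMTV × SUVmean.
* **TMTS** — Σ per-lesion triangulated iso-surface areas. Meshing is
  marching cubes at level 0.5 on the zero-padded binary lesion, scaled to
  world mm, after a 1-voxel Gaussian pre-smooth. The smoothing matters:
  counting exposed voxel faces overestimates a sphere's area by ~50 % and
  never converges; meshing the raw binary still overestimates by ~9 %
  (staircase bias); meshing the smoothed field is accurate to ~2 % at
  radius/spacing = 20 and converges as spacing shrinks. Lesions too small
  to survive the smooth fall back to the raw binary mesh; exposed-face
  counting is retained as `surface_mode='faces'` for sensitivity analysis.
* **TVSR** — TMTV/TMTS expressed in mm (mm³/mm²), a massiveness index
  (r/3 for a sphere of radius r).
* **TumBB** — volume of the axis-aligned bounding box over all lesion
  voxels, extent per axis (max − min + 1) voxels in world mm.
* **Dmax** — largest centroid-to-centroid distance between lesions. A
  single-lesion patient still occupies a nonzero extent, so the fallback is
  the maximal voxel-centre pair distance inside the lesion (computed on
  surface voxels via the convex hull); `dmax_single_mode='zero'` disables
  this.
* **nROI** — the number of lesions.
* **itErosion** — per-lesion count of iterative morphological erosions
  (3×3×3 six-connected cross, native grid) until the lesion disappears,
  averaged over lesions — hence fractional for multisite disease. Erosion
  counts are grid-defined, not metric; a warning is emitted for
  anisotropic spacing.
* **medPCD** — median Euclidean distance (mm) from each lesion's surface
  voxels (voxels with a 6-neighbour outside the lesion) to *its own*
  volume centroid, pooled over lesions. Using the per-lesion centroid
  (not the whole-disease centroid) keeps medPCD a massiveness measure;
  a global centroid would make it track half of Dmax instead.
* **medEdgeD** — median length (run voxels × spacing, mm) of maximal
  in-mask runs along the three grid axes, pooled over lesions: the
  distance between opposite lesion edges along a grid line. Simple and
  deterministic; sensitive to rotation, which is accepted and documented.
  An alternative mode measures the three axis-aligned chords through each
  lesion's centroid voxel (`edge_mode='centroid_chords'`).

itErosion, medPCD and medEdgeD are declared *modes* of this package, not
claimed equivalences to any external software's internal definitions.

A 41 %-of-SUVmax isocontour grower is provided for completeness, but the
pipeline's contract input is the final (already validated) mask:
physician-adapted segmentations are not reproducible from code.

## Circulating DNA

One haploid genome equivalent weighs 3.3 pg, so [cfDNA] (hGE/mL) =
cfDNA (pg/mL)/3.3 and [ctDNA] (hGE/mL) = mean(VAF) × cfDNA (pg/mL)/3.3,
with the unweighted arithmetic mean over the mutations used for detection
calling. A patient with no detected mutation has a *null* ctDNA — an assay
false negative, not a zero — and is retained in the cohort table but
excluded (and counted) in every ctDNA-specific analysis.

## Machine-effect gate and ComBat

Features measured on two PET/CT machines are compared per feature with a
two-sided Wilcoxon–Mann–Whitney test (exact enumeration when n₁·n₂ ≤ 400
and no ties; tie/continuity-corrected normal approximation otherwise),
BH-adjusted across the 12-feature family within each disease. Flagged
features (adjusted p < 0.05) are replaced by ComBat-adjusted values;
unflagged features pass through bit-identically. Harmonizing all features
regardless of the gate is available (`mode='all'`), and whether BH is
applied before selecting features is configurable in the sense that the
raw p-values are always reported alongside.

ComBat here is the parametric empirical-Bayes location/scale model without
biological covariates: standardize each feature by the batch-size-weighted
grand mean and pooled variance, estimate per-batch location γ̂ and scale
δ̂² on the standardized data, shrink them toward across-feature prior
moments (normal prior for γ, moments-matched inverse-gamma for δ²) by the
standard iterative point estimates (convergence 1e-9), adjust and rescale.
Numerical edge cases: a single feature offers no across-feature prior, so
no shrinkage is applied; a feature with zero within-batch variance gets a
location-only, unshrunk adjustment with a warning; a single batch returns
the input unchanged. Re-running the gate on harmonized data is part of the
workflow and any still-flagged feature is reported, never hidden.

ComBat is *not* exactly idempotent: EB shrinkage leaves residual batch
means of order (γ̂ − γ̄), and the pooled-variance (1/N) vs per-batch
(1/(n_b−1)) denominators rescale by √((N−B)/N) on every pass. The tested
invariant is therefore contraction — a second pass changes the data by
less than 10 % of what the first pass changed.

## Correlation and regression battery

Spearman ρ uses midranks for ties with the t-approximation p-value;
correlations with a DNA target drop null-target rows pairwise and report
the n actually used (pairs with < 4 complete observations are NA). BH
families follow the tables: one family of 12 tests per (disease × target)
for feature–DNA tables and univariate fits; one family over all 66 feature
pairs per disease for the feature–feature matrix. High-correlation
clusters are the connected components (size ≥ 2) of the graph with edges
where adjusted p < 0.05 and ρ ≥ rho_min; the "high" threshold is not
canonical, the default is rho_min = 0.7, configurable.

Univariate OLS reports slope, intercept, slope p and adjusted
R² = 1 − (1 − R²)(n − 1)/(n − 2). Stepwise selection is bidirectional by
AIC from the full 12-candidate model (the standard reading of "stepwise in
both directions", as in R's `step()`), one add/drop per step, ties broken
by fixed candidate order with drops preferred, trace recorded; exactly
collinear or zero-variance candidates (condition number > 1e10) are
removed with a warning before selection. The reported model p-value is the
overall F-test and is labelled as such. Note a structural property of
AIC stepwise: each pure-noise candidate is retained with probability
≈ P(χ²₁ > 2) ≈ 0.16, so the *exact* generating set is recovered rarely
even when every true predictor is always selected with accurate
coefficients; criteria should be judged accordingly.

## Synthetic cohorts — what they emulate and what they do not

The generator produces, per patient: a 3D phantom (ellipsoidal lesions,
axis ratios 0.7–1.0, lognormal radii median 15 mm σ_log 0.45, count
max(1, Poisson(9)), uniform per-lesion SUV lognormal median 8 σ_log 0.35,
background 0, ≥ 8 mm surface gap, 360×360×560 mm body box at 4 mm
isotropic spacing), the twelve features extracted from it, and linked
blood values: log ctDNA = 1.6 + 1.0·log TMTS + N(0, 0.5²) hGE/mL (the
tumour–host interface hypothesis: surface, where cytolysis happens, drives
DNA release; TMTV/TumBB/medPCD selectable as alternative drivers), cfDNA =
ctDNA + lognormal baseline (median 8000 hGE/mL, σ_log 0.6) so ctDNA ≤
cfDNA and cfDNA correlates more weakly. Mutation counts are 1 + Poisson(2)
and VAFs Beta-distributed with mean ctDNA/cfDNA and concentration 200, so
re-quantification through the hGE formula recovers the drawn ctDNA in
expectation and nulls arise only through the 20 % detection false-negative
probability. Machines alternate 1/2 and machine-2 measurements of
{TumBB, Dmax, itErosion, medPCD} are shifted by +1.5 pooled SD (a
measurement artifact: the biology is driven by unshifted values). Scales
were chosen once to land in the clinically reported ranges for aggressive
lymphoma (TMTV 10²–10³ cm³, cfDNA ~10⁴ hGE/mL, ctDNA ~10³ hGE/mL).

Not emulated: physiological background uptake and PET noise/PSF (masks are
ground truth by construction), anatomically plausible lesion placement,
inter-observer segmentation variability, sequencing error and panel
design, and any survival endpoint. A green end-to-end test therefore
establishes that the pipeline recovers *structure the generator put in*
(linked driver, shifted features, false-negative accounting) — not that
any clinical effect size is reproduced.

All randomness flows from one integer seed through numpy's SeedSequence;
cohorts are bit-reproducible for a fixed (spec, link, n, seed).

## Performance notes

Simulation-heavy checks are scaled for one CPU: the end-to-end acceptance
properties use 20 image-based cohorts of 50 patients (~2 minutes) and 50
feature-level stepwise replicates; per-lesion operations (meshing,
erosion, runs) work on cropped bounding boxes, and intra-lesion diameters
use convex-hull vertices beyond 400 surface voxels.
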