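# Methods

## Model and procedure

The analysis treats a neurocognitive network's structural covariance as the
within-age-group correlation between a network seed value and every voxel of
modulated gray-matter volume.  For participants partitioned into G ordered
age groups, the seed vector Y (average gray-matter volume over the network's
four 10.5 mm cubical seed ROIs) and the masked voxel matrix X are centered
and scaled to unit Euclidean norm inside each group, so the stacked
cross-products Z[g] = Yᵍᵀ Xᵍ are per-group Pearson correlation profiles.
The SVD Z = U Δ Vᵀ yields G latent variables (LVs); covariance explained is
100·δᵢ²/Σδ².  The assumptions are those of the correlation itself:
participants are exchangeable within groups, the seed-voxel relation is
linear at the voxel level, and groups are treated as fixed strata (no
shrinkage or pooling across them).

Inference is resampling-based and distribution-free:

* **Permutation** (default 5,000): Y is permuted across *all* participants
  while group labels stay with the rows of X, then renormalized within
  groups.  This breaks the seed–brain coupling but preserves group sizes
  and the within-group normalization.  p-values use the positively biased
  estimator (count + 1)/(n + 1), which can never report zero and is
  consistent with floor-style reporting at large n.  Permutations that
  leave a group's seed values constant (possible with discrete data) are
  redrawn and counted.
* **LV selection**: p < 0.001 and covariance explained ≥ 5%, jointly.
* **Bootstrap** (default 1,000): participants are resampled with
  replacement *within* groups, preserving per-group n so the normalization
  stays defined.  Each resample's SVD is aligned to the original by
  orthogonal Procrustes on U (rotation + reflection), the standard remedy
  for axis reflection and rotation in PLS resampling.  Bootstrap ratios
  (original salience / bootstrap SE) are thresholded two-tailed at the
  normal quantile — 1.959964 at the default 95% level.  A voxel with an
  exactly zero bootstrap SE receives a signed-infinity sentinel and is
  counted, never silently dropped.
* **Brain scores** L = X V use the *raw* (non-normalized) voxel data, so
  they retain global volume differences — group means of LV1 scores
  therefore reflect both network-pattern expression and overall gray-matter
  decline, as they would in real data.  Per-group score–seed correlations
  carry percentile bootstrap CIs; a CI spanning zero marks the group
  unreliable for interpretation.
* **Covariate correction**: per LV, scores are residualized by OLS on an
  intercept, scanner field strength and a sex indicator, with the grand
  mean added back so corrected scores stay on the original scale.
  Constant covariates are dropped with a warning.  Correction is
  idempotent.
* **Trajectories**: corrected scores are regressed on age with polynomials
  of degree 1–3; the degree is chosen by AICc (residual sums of squares
  are floored at 1e−12 of the total sum of squares so exact fits tie, and
  ties resolve to the lowest degree).  The peak age is an *interior*
  stationary maximum of the selected curve that also exceeds both boundary
  values; monotone or boundary-peaked curves report no peak.  Ages are
  standardized internally for conditioning; coefficients are reported in
  natural units (years).

Numerical conventions: SVD signs are fixed per LV so the
largest-magnitude group salience is positive (reproducible across LAPACK
backends); singular-value ties keep backend column order and are documented
as non-identifiable; voxels with zero variance in any group are removed
from the mask before analysis with a logged count; world-to-voxel mapping
requires an axis-aligned affine and rounds half away from zero; a cubical
ROI includes voxel centers within edge/2 of the center (closed interval),
averages the masked intersection when clipped (with a warning), and errors
only when the intersection is empty.

## What the synthetic generator emulates

The generator stands in for a pooled multi-repository life-span sample:
N participants in six age bins (ages uniform within bins), one modulated
gray-matter volume each on a common grid, smoothed to 8 mm FWHM.  Each
volume is

    baseline + cohort decline + Σₖ eᵢₖ · mapₖ + scanner/sex offsets + noise,

then Gaussian-smoothed.  The defaults describe the desk-scale reference
study (all values in the units of the data, where voxel noise σ = 0.1):

| parameter | default | meaning |
|---|---|---|
| `grid_shape`, `voxel_size_mm` | 26×30×26 at 3 mm | ~12,000 masked voxels; the smallest centred grid whose mask holds a complete four-seed network (ventral attention) with full 10.5 mm cubes |
| mask | exponent-3 superellipsoid, 0.98 semi-axes | slightly boxier than an ellipsoid, as a brain outline is; keeps the insula seeds (x = ±31) interior |
| `baseline` | 0.6 | typical modulated gray-matter value |
| `noise_sd` | 0.1 | i.i.d. voxel noise before smoothing |
| `global_decline_slope` | −0.0002 / year | cohort-level (age-bin midpoint) whole-mask decline |
| `scanner_effect`, `sex_effect` | 0.001, 0.0005 | small uniform offsets (residual site/sex effects after modulation) |
| `smoothing_fwhm_mm` | 8 | single-pass Gaussian smoothing |
| `prob_3t_by_group` | .25 .45 .80 .55 .35 .20 | 3T probability per age bin (see below) |
| pattern amplitude | 5 × noise_sd | planted signal-to-noise ratio 5 |
| `subject_sd_frac` | 1.5 (stable), 0.9 (contrast) | subject expression variability as a fraction of the age-mean expression |

**Expression model.** A pattern's per-subject expression is
`amplitude · f(age) · (1 + c·ε)` with ε standard normal: multiplicative
subject variability proportional to the age-mean expression.  This is the
part of the generative model that *creates* structural covariance — with
purely age-determined expression there is no within-group covariation for
the analysis to find — and it ties each pattern's group-wise covariance
strength to its trajectory f, which is what makes planted trajectories
recoverable from the LV structure.  Trajectory families: a softplus ramp
that declines from 1 at age 6 and flattens toward a plateau fraction around
a plateau age (default 70 y); a concave quadratic with a configurable
vertex (default 45 y); and a flat profile.

**The two-pattern reference study.** The stable pattern loads on the
anterior-cingulate seed pair (insula 0.3) plus two association-cortex
blobs.  The age-dependent pattern is a purely distal bipolar contrast
(insular-adjacent and dorsomedial blobs against a posterior blob) that
expresses the *same* subject factor with an inverted-U weight crossing zero
near ages 21 and 69: the seed regions covary positively with those
territories in mid-adulthood and negatively at both ends of life — the
covariance topography migrates with age.  This shared-factor construction
is essential for identifiability: two patterns with independent factors
both produce all-positive group covariance profiles, which are nearly
collinear across groups, and no SVD can then separate their maps.  The
signed profile of the shared-factor contrast is close to orthogonal to the
stable pattern's declining profile, so the two LVs separate cleanly.
Bipolar patterns are demeaned against the smoothing-plus-masking operator
(their planted map sums to ~0 *after* smoothing), which makes them
orthogonal to global volume changes; without this, the cohort decline
leaks a dataset-dependent linear trend into the contrast LV's brain scores
and biases fitted peak ages by several years.

**Scanner assignment and a known correction bias.** Field strength is
assigned per age group with children and the oldest cohorts mostly 1.5T
and young adults mostly 3T, echoing pooled open-access repositories.
Because field strength then tracks age group, the scanner covariate is
collinear with any age-dependent score trajectory, and residualizing
scores on scanner removes part of the genuine age signal.  With the full
imbalance observed in real pooled samples (3T fractions ranging 0.07–0.93
across bins) this shifts the fitted inverted-U peak by about +3.5 years;
the moderated default profile keeps the shift near +1 year.  This is a
property of the correction method itself, worth remembering when
interpreting corrected trajectories from pooled multi-scanner samples.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: tissue segmentation and registration error,
spatially structured (non-stationary) noise, motion artifacts, non-Gaussian
morphometric distributions, site effects beyond a uniform offset,
longitudinal dependence, and unequal group sizes.  Recovery results show
the *pipeline* is correct and calibrated, not that real structural
covariance has this effect size or geometry.

## Problem sizes used by the test suite and acceptance script

Unit tests run on a 12×14×12 grid at 6 mm (~1,000 masked voxels, 30
participants).  The calibration study uses 200 pure-noise replicates of 6
groups × 10 participants × 500 voxels with 200 permutations each.  The
reference recovery study uses 6 × 50 participants on the default grid
(~12,000 voxels) with 2,000 permutations and 500 bootstraps — 2,000 rather
than the reporting default of 5,000 because the p-value estimator's floor
1/(n+1) must lie below the 0.001 selection threshold while keeping the
study desk-scale; bootstraps are reduced from 1,000 to 500 for the same
reason.  Full-default resampling depths (5,000 / 1,000) remain the
pipeline defaults for reportable runs.

## Known limitations

* One seed-PLS per network; no cross-network multiplicity control (by
  design, matching standard practice for this analysis).
* The permutation scheme permutes Y across all participants; schemes that
  permute within groups answer a subtly different null and are not
  implemented.
* Brain scores use raw X; with group-normalized X the score trajectories
  would lose their global-decline component.  The raw choice matches the
  described derivation but couples LV1 trajectories to overall volume.
* Peak ages are only reported for interior stationary maxima of a
  polynomial fit; saturating ("decline then plateau") shapes are described
  by the degree-3 fit but yield no peak, and no spline/GAM alternative is
  provided.
* Axis-aligned affines only; rotated or sheared grids are rejected rather
  than resampled.
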