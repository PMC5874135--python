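# seedpls

Grouped seed-PLS analysis of gray-matter structural covariance across the
life span.

## The problem

Structural covariance describes how regional gray-matter morphology covaries
across individuals: people with more gray matter in one node of a
neurocognitive network tend to have more in the network's other territories.
How these covariance patterns change from childhood to old age — whether a
network's covariance is a stable trait whose integrity fades, or reorganizes
its topography with age — is a central question in developmental and aging
neuroimaging. `seedpls` implements the seed-based partial least squares
(PLS) correlation approach to this question for researchers who want a
tested, scriptable version of the full pipeline: from voxelwise modulated
gray-matter volume maps and network seed coordinates to significant latent
variables, bootstrap-thresholded spatial patterns, brain-score trajectories
and peak-age estimates.

Because the multi-repository MRI collections such analyses are usually run
on cannot be redistributed, the package ships a synthetic life-span
generator that plants known covariance patterns with known age trajectories,
so every stage of the pipeline is testable end to end without any download.

## The method

Participants are partitioned into six ordered age groups
(6–15, 16–25, 26–35, 36–59, 60–75, 76–94 years).  For a given network, the
seed value of participant *i* is the mean gray-matter volume in 10.5 mm
cubical ROIs at the network's four seed coordinates (top-two high-confidence
seeds plus contralateral x-sign mirrors; the default network instead uses
two midline seeds and one bilateral pair).  Collect these into the vector
**Y** and the masked voxel data into the matrix **X**.  Within each age
group *g*, both are centered and scaled to unit norm, so the stacked
cross-products

&nbsp;&nbsp;&nbsp;&nbsp;**Z**<sub>g</sub> = **Y**<sub>g</sub>ᵀ**X**<sub>g</sub>

are exactly the within-group Pearson correlations of the seed value with
every voxel.  The singular value decomposition

&nbsp;&nbsp;&nbsp;&nbsp;**Z** = **U** Δ **V**ᵀ

yields one latent variable (LV) per age group: a group salience profile
(column of **U**), a voxelwise spatial pattern (column of **V**) and a
singular value δ whose squared share of Σδ² is the percent covariance
explained.  Inference:

* **Permutation test** — **Y** is permuted across all participants,
  renormalized within groups, and the singular values recomputed
  (5,000 permutations by default); p = (#{δ\* ≥ δ} + 1)/(n + 1).
  An LV is retained when p < 0.001 *and* it explains ≥ 5% of the covariance.
* **Bootstrap** — participants are resampled with replacement within age
  groups (1,000 resamples by default), each resample's SVD aligned to the
  original by orthogonal Procrustes; the bootstrap ratio
  BSR = salience / SE behaves like a z-score and spatial patterns are
  thresholded at |BSR| ≥ 1.96 (95%).
* **Brain scores** — **L** = **X V** projects each participant's raw voxel
  data onto an LV's spatial pattern.  Per-group correlations of **L** with
  **Y** carry percentile bootstrap CIs; a group whose CI crosses zero is
  flagged unreliable.  Scores are corrected for scanner field strength and
  sex by multiple regression, and their age trajectories fitted with
  polynomials (degree 1–3, AICc-selected); an interior maximum of the
  selected curve is reported as the peak age.

## Worked example

Generate the reference synthetic study — a stable declining pattern plus an
inverted-U age contrast, both expressed through the ventral-attention seeds
at a signal-to-noise ratio of 5 — and run the full analysis:

```python
import numpy as np
import seedpls

config = seedpls.two_pattern_config(n_per_group=50, rng_seed=1)
dataset = seedpls.generate_dataset(config)
table = seedpls.builtin_seed_table()

y = seedpls.network_seed_average(dataset, table, "ventral_attention").values
groups = seedpls.assign_groups(dataset.ages)
X = dataset.voxel_matrix

Xn, Yn = seedpls.group_normalize(X, y, groups)
lvs = seedpls.decompose(seedpls.covariance_stack(Xn, Yn, groups))

rng = np.random.default_rng(0)
p, _ = seedpls.permutation_test(X, y, groups, n_perm=2000, rng=rng)
boot = seedpls.bootstrap_saliences(X, y, groups, n_boot=500, rng=rng, lvset=lvs)
selected = seedpls.select_lvs(p, lvs.cov_explained)

print("covariance explained (%):", np.round(lvs.cov_explained, 2))
print("permutation p-values:   ", np.round(p, 4))
print("selected LVs:           ", np.flatnonzero(selected) + 1)

L = seedpls.brain_scores(X, lvs.v)
corrected = seedpls.correct_scores(
    L,
    dataset.participants["scanner_tesla"].to_numpy(),
    dataset.participants["sex"].to_numpy(),
).corrected
truth = dataset.ground_truth.patterns[1]
sign = np.sign(np.corrcoef(lvs.v[:, 1], truth.smoothed_map)[0, 1])
fit = seedpls.fit_trajectory(sign * corrected[:, 1], dataset.ages)
print(f"LV2 trajectory: degree {fit.degree}, peak at {fit.peak_age:.1f} years")
```

Output:

```
covariance explained (%): [50.48 30.06  5.29  5.07  4.76  4.34]
permutation p-values:    [5.000e-04 5.000e-04 7.166e-01 4.888e-01 4.813e-01 6.882e-01]
selected LVs:            [1 2]
LV2 trajectory: degree 2, peak at 45.5 years
```

Exactly the two planted patterns are significant: the stable pattern
dominates (50% covariance explained, declining brain scores), the
age-dependent contrast comes second (30%), the four remaining LVs are noise
(p ≈ 0.5), and the fitted trajectory of the second LV peaks at 45.5 years —
the planted vertex was 45.  (An SVD's sign per LV is arbitrary, hence the
alignment to the planted map before interpreting the trajectory.)

The same pipeline is available from the shell:

```bash
seedpls simulate --out ds/ --n-per-group 50 --seed 1
seedpls pls --dataset ds/ --network ventral_attention --out out/ --seed 1
seedpls trajectories --scores out/ventral_attention/brain_scores.tsv --lv 1 --out fit.json
```

`seedpls run-all --config run.yaml` chains every configured network;
outputs are NIfTI salience/BSR/thresholded maps, brain-score TSVs and a
canonical `results.json` that is byte-identical across runs with the same
configuration and seed.

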