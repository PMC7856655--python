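# Methods

This note records the statistical model, the synthetic-generator design, the
default parameters and why they were chosen, and the numerical decisions that
matter for reproducing results.

## 1. Winner-take-all structural covariance mapping

**Partial correlation.** `partial_correlation(x, y, Z)` is the Pearson
correlation of the residuals of `x` and `y` after ordinary least squares on
`[1, Z]`. Residualization uses a QR decomposition of the covariate design
(one orthonormal projector shared across all voxels of a map), which is
numerically stabler than normal equations and makes voxelwise maps a single
matrix product. The estimate equals the classical precision-matrix identity
`-P[0,1] / sqrt(P[0,0] P[1,1])`, which the tests verify to 1e-8 on random
fixtures. Two degenerate cases are distinguished: a constant input raises an
error (the correlation is undefined), while an input fully absorbed by the
covariates (residual norm below 1e-10 of its centered norm) returns 0 — it
carries no information beyond the covariates, so its unique association with
anything else is zero.

**Seeding and labeling.** For each subcortical voxel, five seed correlations
are computed: GMV of the voxel against each cortical lobe's mean GMV,
controlling the other four lobes' means and TIV. The voxel is labeled with
the `argmax` over signed correlations (an `use_abs` option switches to
magnitude). Ties break to the lowest lobe id and are counted. Labels always
partition the structure mask: counts over the five lobes sum to the mask
size, an invariant the suite checks.

**Map comparison.** The per-lobe statistic is the voxel-count difference
between groups. The null is group-label permutation with *full WTA
recomputation* per permutation (the labeling is part of the statistic, so it
must be recomputed for exchangeability). Two-sided p = (1 + b) / (1 + n_perm)
where b counts permutations with |null| ≥ |observed|; ties count as
exceedances, which keeps the test valid for the discrete count statistic.

**Sensitivity of count statistics.** Voxel counts respond only to assignment
*flips*. Scaling up an already identifiable coupling does not change which
lobe wins a voxel, so count-based tests are sensitive to couplings appearing
or disappearing (or to competition near the decision boundary), not to
uniform strengthening. Planted-effect tests therefore abolish a coupling in
one group rather than amplifying it; with one thalamic coupling set to zero
the affected lobe's count drops detectably (see the README example).

## 2. The 20-node network

Nodes are the 5 cortical lobes plus the 5 WTA subregions in each of
striatum, thalamus and cerebellum; node signals are mean GMV over the
respective voxel sets. Each group's nodes use that group's own WTA maps. A
lobe that wins zero voxels in a structure yields a missing node whose edges
are reported as NaN. Edges are pairwise partial correlations given TIV
(configurable), requiring more subjects than nodes plus covariates (n > 21).

Group comparison uses the Fisher-z difference per edge under group-label
permutation, again with full recomputation (including each pseudo-group's WTA
maps). A permutation draw in which a pseudo-group has an empty subregion
leaves that edge inestimable; such draws are counted as exceedances, which is
conservative. The 190-edge family is screened by the FPA omnibus rule: edge
findings are reported as significant only if the number of edges with
p < alpha exceeds `alpha * edges_tested`, the count expected under the global
null.

## 3. Duration-modulation models

Within one patient group (df = n − 5):

```
GM_target ~ 1 + GM_seed + Duration + GM_seed:Duration + TIV
```

The tested term is the seed-by-duration interaction β3. Between two patient
groups (df = n − 9), the design adds Group and all its interactions; the
tested term is the three-way Group × GM_seed × Duration interaction β7, with
the first-listed group coded 1.

Significance uses a one-tailed convention on the magnitude:
`p = P(T_df ≥ |t|)`. Under this convention t = −2.284 at df = 106 gives
p = .012 and t = −2.966 at df = 213 gives p = .002, which the suite pins
down. The sign (direction) of the interaction is reported separately. All
t statistics are invariant to centering of the regressors and (for the
between-group model) to affine recodings of the group indicator; the suite
checks both at 1e-8.

The `subnetwork_modulation_scan` evaluates the model for every lobe and every
ordered seed→target pair among cortex, striatum, thalamus and cerebellum
(5 × 12 = 60 rows per scope). The between-group scan needs one shared
territory definition and uses WTA maps computed on the pooled patients.

## 4. Voxelwise morphometry

Three maps over the in-mask GMV matrix, all with an explicit per-voxel OLS
reference implementation in the tests (agreement to 1e-8):

- **Group ANOVA F** — full model (intercept, two group dummies, TIV, age,
  sex) versus reduced model without the dummies; df = (2, n − rank).
- **Duration partial r** — GMV against duration within one patient group,
  controlling TIV, sex, age.
- **Slope interaction t** — Group × Duration term between the patient
  groups, controlling TIV, age, sex.

Family-wise error over voxels is controlled nonparametrically rather than by
Gaussian random-field theory: the map is thresholded at an uncorrected voxel
p, 26-connected clusters are formed, and each cluster's extent is referred to
the permutation null of the *maximum* cluster size. Nuisance covariates are
handled by Freedman-Lane-style residual permutation: reduced-model residuals
are permuted and re-added to the reduced-model fit (group ANOVA and
interaction maps) or the residualized duration vector is permuted
(correlation map). Permutation is exact under exchangeability and needs no
smoothness estimation, at the cost of computation; this is the one deliberate
methodological divergence from common GRF-based VBM pipelines, and the null
calibration study in the acceptance suite verifies its family-wise error
empirically.

## 5. Synthetic cohort generator

**Geometry.** The atlas lives on an isotropic grid (default 32³ at 1.5 mm).
The cortex is a spherical shell (0.75 R to R, R = 0.45 × grid extent) split
into five azimuthal sectors; the striatum, thalamus and cerebellum are three
disjoint interior spheres. Subcortical ground-truth territories are an
equal-count azimuthal partition of each structure's voxels, which guarantees
five non-empty territories even on small grids.

**Signal model.** Each subject draws five latent lobe factors from a
multivariate normal with compound-symmetric correlation 0.3 (lobes covary,
as cortical volumes do, without being collinear). Cortical voxels load on
their lobe's factor with weight 0.05; subcortical voxels in territory *l*
load with weight `w0 + w1 * duration`, so `w0` is the structural coupling and
`w1` its duration modulation, settable per (group, structure, lobe). Optional
atrophy subtracts `slope * duration` from a region's GMV. A TIV confound adds
`5e-5 * (TIV − 1500)` everywhere. Noise is white Gaussian smoothed at FWHM
4 mm and rescaled to sd 0.03, around a baseline GMV of 0.5; values are
clipped to [0, 1] with a warning if ≥5% clip and an error if ≥50%.

**Demographics.** Age ~ N(26, 7.8²); sex male with probability 71/111;
TIV ~ N(1500, 120²); duration (patients only) from a normal with mean 83 and
sd 94 months truncated at 1 — matching the scale of adult epilepsy cohorts
where duration is strongly right-spread.

**Determinism and n-invariance.** Every subject gets an independent
`SeedSequence` stream keyed by (group index, subject index), so subject k is
bit-identical regardless of cohort size, and the whole cohort is a pure
function of the config. Default sizes (32³ grid, 40 subjects/group) keep a
full generate-plus-analyze cycle in seconds on one CPU; tests and examples
use 16³–24³ grids, chosen as the smallest geometries with ≥20 voxels per
structure.

**Scope.** The generator emulates the covariance structure the analyses
consume — not anatomy. There is no registration, segmentation, bias field,
or realistic cortical folding; smoothing is the only spatial process. It is a
validation instrument, not a simulator of MRI.

## 6. Reporting conventions and numerical choices

- All report tables are TSV with floats formatted `%.6g` and `NA` for
  missing; identical configs and seeds give byte-identical files (checked).
- Permutation p values are always `(1 + exceedances) / (1 + n_perm)`, never
  zero; `n_perm` below 100 triggers a warning.
- FWHM converts to Gaussian sigma as `FWHM / (2 sqrt(2 ln 2))`; smoothing
  assumes axis-aligned affines and zero-pads at the boundary.
- One-way ANOVA from reported summaries reconstructs group SDs as
  `SEM * sqrt(n)` and is exactly equal to ANOVA on any raw data with those
  summaries (tested against a raw-data oracle).

## 7. Limitations

- The WTA count statistic cannot detect uniform coupling-strength changes
  (section 1); edge-level network tests cover that axis.
- The FPA omnibus screen controls the false-positive *count* expectation; it
  is insensitive to a single true edge in a large family, as the README
  example shows. It mirrors a reporting convention, not an FDR procedure.
- Permutation cluster correction assumes exchangeability of subjects given
  the covariates; heavy group-specific variance differences would violate it.
- Between-group modulation requires a shared territory definition; pooling
  patients for the WTA map is one defensible choice among several.
- The generator's clipping at [0, 1] slightly truncates extreme noise draws;
  with default parameters the clipped fraction is far below the warning
  threshold.
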