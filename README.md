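# scnwta

Structural covariance network analysis of cortico-striato-thalamo-cerebellar
circuits, with a winner-take-all (WTA) mapping of subcortical territories and
permutation-based group comparison — plus a synthetic cohort generator with
known ground truth for validating every step.

## Scientific problem

In generalized-seizure epilepsies, gray-matter volume (GMV) changes are not
confined to isolated regions: they follow networks that link the cerebral
cortex with the striatum, thalamus and cerebellum. A standard way to study
this with anatomical MRI is *structural covariance*: across subjects, the GMV
of connected regions co-varies, so inter-regional correlation of GMV is used
as a proxy for network integrity.

This package implements a complete analysis of that kind for a three-group
design — two patient groups (labelled `GE_GTCS` and `FE_FBTS`) and healthy
controls (`HC`):

1. **WTA mapping.** The cortex is divided into five lobes (frontal,
   motor/premotor, somatosensory, parietal/occipital, temporal). For every
   voxel of the striatum, thalamus and cerebellum, the partial correlation of
   its GMV with each lobe's mean GMV is computed across subjects (controlling
   the other four lobes and total intracranial volume, TIV), and the voxel is
   assigned to the lobe with the highest correlation. This partitions each
   structure into five lobe territories per group.
2. **Map comparison.** Group differences in the per-lobe voxel counts are
   tested by group-label permutation with full WTA recomputation in every
   permutation.
3. **20-node network.** Five cortical nodes plus five WTA subregions in each
   of the three structures give a 20-node network whose edges are pairwise
   partial correlations of node mean GMV (given TIV). Group networks are
   compared edge by edge with a Fisher-z difference statistic under
   permutation, and the 190-edge family is screened with a
   false-positive-adjustment (FPA) omnibus check.
4. **Duration modulation.** Within a patient group, the model
   `GM_target ~ GM_seed + Duration + GM_seed x Duration + TIV` tests whether
   disease duration modulates a seed-target coupling (the interaction term,
   one-tailed). A nine-term two-group model tests whether that modulation
   differs between patient groups.
5. **Voxelwise morphometry.** Group ANOVA F maps, within-group
   GMV-vs-duration partial-correlation maps, and group-by-duration slope
   interaction t maps, with family-wise error controlled by permutation
   cluster-extent correction (Freedman-Lane residual permutation,
   26-connectivity).

Real cohort volumes are rarely shareable, so the package ships a **synthetic
generator**: a spherical five-lobe cortical shell with three interior
structures, latent per-lobe factors that couple cortex to its subcortical
territories, configurable duration-dependent coupling and atrophy, a TIV
confound, and smoothed Gaussian noise. Every planted parameter is recorded as
ground truth, which makes parameter-recovery and null-calibration testing
possible.

## Worked example

Plant a single abolished cortico-thalamic coupling in one patient group and
recover it:

```python
import scnwta as sw

cfg = sw.GeneratorConfig(
    grid=(24, 24, 24), n_per_group=60, seed=7,
    coupling_w0_default=0.08,
    coupling_w0={("GE_GTCS", "thalamus", 2): 0.0},  # abolish one coupling
    noise_sd=0.03)
atlas, truth = sw.generate_atlas(cfg)
ds, report = sw.generate_cohort(cfg, atlas, truth)
print(f"{ds.n_subjects} subjects, {ds.n_voxels} in-mask voxels")

cmp_ = sw.permutation_map_test(ds, "GE_GTCS", "HC", "thalamus",
                               n_perm=999, seed=1)
print(cmp_.table.to_string(index=False))

net = sw.compare_networks(ds, "GE_GTCS", "HC", n_perm=499, seed=2)
print("edge cortex(motor)–thalamus(motor): p =", net.p_matrix[1, 11])
print("FPA:", net.fpa)
```

Output:

```
180 subjects, 3304 in-mask voxels
 lobe          lobe_name  count_a  count_b  diff  p_perm direction
    1            frontal       19       16     3   0.002 Increased
    2     motor_premotor        8       16    -8   0.001 Decreased
    3      somatosensory       21       16     5   0.001 Increased
    4 parietal_occipital       16       16     0   1.000     Equal
    5           temporal       16       16     0   1.000     Equal
edge cortex(motor)–thalamus(motor): p = 0.002
FPA: {'alpha': 0.05, 'n_edges_tested': 190, 'n_significant': 9, 'expected_false': 9.5, 'omnibus_pass': False}
```

The abolished motor/premotor coupling halves that territory's voxel count in
the patient group (16 → 8, p = .001); the freed voxels scatter into
neighbouring territories. The single affected network edge is strongly
significant on its own (p = .002), but nine significant edges out of 190 do
not exceed the 9.5 expected by chance, so the FPA omnibus screen —
deliberately conservative for a one-edge effect — does not pass.

The same analyses are available from the command line
(`scnwta generate | smooth | map | compare-maps | network | modulate | vbm |
report | run-all`); `scnwta run-all --out mydir` writes all report tables
(demographics, WTA counts and normalized counts, map comparisons, network
comparisons with FPA, modulation scans, VBM clusters) plus a manifest with
the full configuration. Identical configs and seeds give byte-identical
tables.

## Reproduction

```bash
pytest -q                                              # full test suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script generates seeded synthetic cohorts, runs every analysis
stage on them, and writes the headline quantities (summary-statistic checks,
WTA territory recovery, permutation p values for the planted effects,
modulation t statistics, cluster statistics, and a pipeline determinism flag)
to the JSON file. It completes in well under a minute on one CPU; the test
suite takes several minutes, dominated by a 200-replicate null-calibration
study.

See `docs/methods.md` for the model, parameter defaults and numerical
choices.
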