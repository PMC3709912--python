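# rehomvpa

Regional-homogeneity mapping and SVM-based multivariate pattern analysis
(MVPA) for resting-state fMRI case-control studies, with a synthetic-cohort
generator for end-to-end validation.

## What it does

Conventional voxelwise group comparisons test each brain location
separately and ignore the joint spatial pattern of activity.  This package
implements the alternative analysis stream used to discriminate patients
with a functional disorder (the motivating case is functional dyspepsia)
from healthy controls on the basis of resting-state regional homogeneity:

1. **Temporal preprocessing** — motion QC (1.5 mm / 1.5° gate), discard of
   the first 10 volumes, nuisance regression (6 motion parameters, linear
   trend, white-matter and ventricular means), 0.01–0.08 Hz band-pass.
   No spatial smoothing.
2. **ReHo mapping** — for each gray-matter voxel, Kendall's coefficient of
   concordance W of its time series with its 26 nearest neighbors,

       W = 12 S / (K² (n³ − n) − K ΣT),   K = 27,

   normalized by the mean W over gray matter.
3. **Classification** — PCA onto all N−1 components (a lossless rotation,
   since N subjects ≪ D voxels), linear soft-margin SVM (C = 1), and
   leave-one-out cross-validation with PCA refit inside every fold.
   Reported as generalization rate (GR), sensitivity (SS), specificity
   (SC).
4. **Discriminative map** — the SVM weight vector back-projected to voxel
   space (w_voxel = U w), with voxel- and cluster-level significance from
   a label-permutation null (default 5000 permutations, voxel p < 0.02,
   cluster extent ≥ 10 voxels, cluster p < 0.001).
5. **ROI–symptom correlation** — 6 mm spheres at the peak |weight| of each
   significant cluster; mean normalized ReHo per patient correlated
   (Pearson, Bonferroni at 0.01) with symptom severity and disease
   duration.

Real cohorts are read from NIfTI volumes plus TSV motion/phenotype tables;
the `rehomvpa.synthetic` module generates aligned cohorts with *planted*
local synchrony and symptom couplings so every stage can be validated
against known ground truth.  See `docs/methods.md` for the full model
description and design choices.

## Worked example

```python
from rehomvpa import (PipelineConfig, SimulationConfig, PermutationConfig,
                      run_pipeline)

config = PipelineConfig(
    simulation=SimulationConfig(n_per_group=15, synchrony_lambda=0.9),
    permutation=PermutationConfig(n_perm=200, cluster_alpha=0.05),
    seed=33,
)
report = run_pipeline(config)
print(report.metrics)
print(report.clusters[0])
print(report.correlations[0])
```

prints (a 15+15-subject cohort on a 16³ grid with one planted sphere of
elevated synchrony):

```
{'GR': 100.0, 'SS': 100.0, 'SC': 100.0}
{'cluster_id': 0, 'size': 16, 'peak_ijk': (8, 8, 8), 'peak_mm': (1.5, 1.5, 1.5),
 'peak_weight': 0.03436260611409618, 'p_voxel_peak': 0.004975124378109453,
 'p_cluster': 0.004975124378109453, 'significant': True}
{'roi_id': 0, 'variable': 'ndi', 'r': 0.42900217890328624,
 'p_raw': 0.1435248018383435, 'p_adjusted': 0.287049603676687,
 'significant': False}
```

The classifier separates the groups perfectly (the planted effect is
strong), and the permutation test flags one significant 16-voxel cluster
whose peak sits exactly on the planted sphere's center (grid (8, 8, 8)).
The patients' mean ReHo in the 6 mm peak ROI correlates positively with
the generated symptom scores (r = 0.43 at n = 15); at this small cohort
size the correlation is not significant after Bonferroni adjustment —
recovering the planted r ≈ 0.6 reliably takes the n = 30 cohorts used in
the validation studies.

The same pipeline is available from the shell:

```bash
rehomvpa simulate --out cohort/ --seed 3 --n-per-group 15
rehomvpa run --out results/ --seed 3 --n-per-group 15 --n-perm 200
```

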