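# Methods

`rehomvpa` implements a case-control resting-state fMRI analysis stream:
regional homogeneity (ReHo) mapping, PCA + linear-SVM multivariate pattern
analysis with leave-one-out cross-validation, permutation-based
discriminative-map inference, and ROI–symptom correlation.  This note
records the models, the defaults and the design choices that were
genuinely open.

## Regional homogeneity

For every gray-matter voxel whose full 3×3×3 neighborhood lies inside the
mask, the K = 27 time series (center + 26 nearest neighbors) are ranked
over the n time points and their concordance summarized by Kendall's W:

    W = 12 S / (K² (n³ − n) − K ΣT),

where S is the sum over time points of squared deviations of rank sums
from their mean K(n+1)/2, and ΣT is the standard midrank tie-correction
term (ΣT = 0 without ties).  W ∈ [0, 1]; under independent noise
E[W] = 1/K ≈ 0.037.  The classical ReHo formulation assumes untied data;
midranks with the tie-corrected denominator are used because band-passed
and storage-rounded data can tie, and the correction reduces to the
uncorrected formula when no ties exist.  A policy that raises on ties is
available.

Edge rule: the strict reading — W is computed only where all 26 neighbors
are in-mask, and excluded voxels do not enter the normalization mean — is
the default; a permissive variant (use available in-mask neighbors,
minimum 7 members) is provided via `edge_policy="available_neighbors"`.
Maps are normalized by the mean W over the computable gray matter, so the
normalized map has mean 1 by construction.  7- and 19-voxel neighborhoods
are included for completeness; 27 is the default.

## Temporal preprocessing

Order: discard the first 10 volumes → nuisance regression → band-pass.
The nuisance design holds an intercept, a linear trend, the six motion
parameters, and mean white-matter and ventricular signals; global-signal
regression is deliberately absent.  No spatial smoothing is applied
anywhere: ReHo depends on fine-grained local structure that smoothing
would artificially inflate.

The band-pass (0.01–0.08 Hz) is an ideal rectangular DFT filter: bins
with frequency in [low, high] are retained, all others including DC are
zeroed.  That convention makes the filter exactly linear and idempotent,
which the tests exploit; a zero-phase order-2 Butterworth is available via
`filter_type="butterworth"`.

Motion QC excludes a subject when any |translation| exceeds 1.5 mm or any
|rotation| exceeds 1.5° at any time point.  Boundary values pass (strict
inequality), and rotations are interpreted in degrees — the reporting
convention of the major preprocessing packages; the threshold's unit was
an open choice.  Failing subjects are excluded and logged rather than
scrubbed.

## Classification

Subjects' normalized ReHo maps restricted to the intersection of
computable masks form an N×D matrix (N subjects ≪ D voxels).  PCA onto
the d = N−1 leading components of the training covariance is a lossless
change of coordinates on the centered training span (computed by thin
SVD, so Uᵀ U = I exactly up to float error); the soft-margin linear SVM
(C = 1, the conventional default) is trained in that space.  Labels are
patient = +1, control = −1; a decision value of exactly 0 is classified as
control.

LOOCV refits PCA (d = N−2) and SVM inside every fold, so the held-out
subject never contributes to the fold's mean, eigenvectors or weights.
Fitting PCA once on all N subjects would leak the test subject; the leaky
variant can be reproduced by composing `fit_pca` on the full matrix
manually, but the fold-internal placement is the default and the one the
tests certify.  Performance is reported as generalization rate,
sensitivity and specificity (percentages).

## Discriminative map and permutation inference

The reduced-space weight vector w is mapped to voxel space as U w, an
isometry (‖Uw‖ = ‖w‖).  Significance is assessed by label permutation:
n_perm = 5000 by default, each permutation retraining the classifier on
the full cohort (one map per permutation).  Because PCA depends only on
the features, it is fit once and shared across permutations —
mathematically identical to refitting it each time.

Voxel p-values are two-sided empirical exceedance probabilities of |w|
with the add-one convention p = (1 + b)/(m + 1), never 0 and never above
1.  Weight maps are scaled to unit L2 norm before comparison: a
soft-margin SVM's weight magnitude shrinks as the achieved margin grows,
so the raw weights of a well-separated observed fit are systematically
*smaller* than those of inseparable permuted fits and a raw comparison
loses all power precisely when the signal is strong.  The unit-norm
statistic (each voxel's relative contribution to the discriminating
direction) is exchangeable under the null, so p-values remain exact;
`unit_norm=False` restores the raw comparison.

Cluster-level inference uses the max-cluster-size statistic: the observed
p-map is thresholded at voxel α = 0.02, components smaller than 10 voxels
are dropped, and each candidate's size is referred to the null
distribution of per-permutation maximum cluster sizes (each permuted map
thresholded at its own (1−α) |w| quantile — rank-based, hence invariant
to the map's scale; thresholding against the pooled per-voxel null
quantile is available via `threshold_mode="pooled_quantile"`).  Cluster
significance is declared below 0.001 by default.  Connectivity is
26-neighbor by default (6/18 available); the add-one convention applies
to cluster p-values as well, so α = 0.001 requires n_perm ≥ 1000 — the
configuration warns when the level is unresolvable.

## ROIs and symptom correlations

For each significant cluster a 6 mm sphere is centered on the world-mm
coordinate of the in-cluster voxel of largest |weight| (ties resolve to
the lowest linear voxel index).  The sphere is intersected with the
gray-matter computable mask before averaging, and the mean *normalized*
ReHo per patient is correlated with symptom severity (NDI) and disease
duration using Pearson's r with two-tailed t-distribution p-values
(df = n−2).  Correlations use patients only — controls lack the symptom
variables.  Bonferroni adjustment multiplies by m = (#ROIs × 2 variables)
and caps at 1, compared against α = 0.01; whether that level is pre- or
post-correction was open, and the adjusted-p reading was chosen (the
per-test p < α/m variant is available and makes identical decisions).
Zung scale scoring: index = raw sum × 1.25, normal below 53 (depression)
and 50 (anxiety).

## Synthetic cohorts

The generator emulates two groups on a common 3 mm grid — by default 150
volumes at TR = 2 s, matching a 5-minute acquisition.  Baseline voxel
series are white Gaussian noise plus a slow subject-level AR(1) drift
(ρ = 0.3, amplitude 0.3 of the noise sd) shared by all voxels, giving the
band-pass something nontrivial to remove.  Patients additionally receive,
inside each configured spherical region, a mixture
v′ = (1 − λᵢ)v + λᵢ s with a shared per-region Gaussian series s(t):
local temporal synchrony — exactly what ReHo measures — rises
monotonically in λ.  λᵢ varies across patients (default sd 0.1 around the
configured mean of 0.9) and is recorded as ground truth; NDI symptom
scores are linear in λᵢ (slope 100, residual sd 13.8, reproducing a
realistic patient NDI spread of ≈ 17 with a built-in ReHo–symptom
correlation of ≈ 0.6).  Zung raw scores, control NDI and disease duration
are drawn around typical dyspepsia-cohort means.  Motion tables are
0.05 mm/°-step random walks that pass the QC gate; a flag injects a
2.5 mm spike for QC testing.  Gray matter is a cuboid two voxels inside
the grid; thin slabs on opposite faces stand in for the white-matter and
ventricle compartments.

What the generator does *not* emulate: hemodynamic response shapes,
physiological (cardiac/respiratory) noise, susceptibility artifacts, and
inter-subject anatomical variability — cohorts are generated already
aligned.  Passing the recovery tests therefore certifies the statistical
machinery (ranking, cross-validation hygiene, permutation calibration,
back-projection), not robustness to registration error or structured
physiological confounds in real data.

## Validation studies and problem sizes

The studies in `rehomvpa.evaluation` (also run by
`scripts/acceptance.py`) use deliberately scaled-down cohorts chosen to
keep a full run in the minutes range while leaving each property
detectable:

- Kendall's W vs the naive Friedman-route oracle: 200 random instances,
  K ≤ 30, n ≤ 20, half rounded to force ties; agreement to 1e-12.
- White-noise null: 12³ full-mask volumes, n = 140, mean W vs 1/27.
- Null calibration: 40 effect-free cohorts of 10+10 subjects on a 16³
  grid, 200 permutations, cluster α = 0.05 (the smallest level 201
  permutations can resolve; the production default of 0.001 requires the
  full 5000).
- Signal recovery: 10 cohorts of 15+15 with one planted sphere at
  λ = 0.9, 500 permutations; success = LOOCV GR ≥ 90% and a significant
  cluster overlapping the planted region with Jaccard > 0.2.
- Correlation recovery: 50 patient groups of n = 30 on a 12³ grid;
  symptom scores generated against each patient's measured in-ROI
  normalized ReHo with noise calibrated to a theoretical r of 0.6 from
  the sample sd of the ReHo means.

## Numerical notes and limitations

- Kendall's W is rank-based and therefore exactly invariant to strictly
  monotone transforms of the series; the vectorized map implementation
  (rank transform once, neighborhood sums by array shifting) matches a
  triple-loop reference voxel-for-voxel.
- The SVM is solved by libsvm with tolerance 1e-7 so that algebraic
  identities (back-projection, reduced/voxel-space equivalence,
  antisymmetry under label swap) hold to ~1e-6.
- Degenerate inputs: all-constant series raise; voxels whose whole
  neighborhood is constant are dropped from the computable mask; an empty
  computable intersection across subjects is an error.
- Permutations are sampled uniformly with replacement from the
  permutation group (exhaustive enumeration is infeasible at N = 60);
  duplicated permutations slightly discretize the null but do not bias it.
- With small cohorts (≲ 12 subjects) the label-permutation null contains
  relabelings close to the truth, which inflates null weights at signal
  voxels; cluster-level power is accordingly poor at toy sizes even when
  LOOCV accuracy is perfect.  This is a property of the statistic, not a
  defect of the implementation.
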