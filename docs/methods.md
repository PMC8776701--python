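# Methods

`ventdose` implements a complete analysis chain for predicting symptomatic
radiation pneumonitis (RP, grade >= 2) after thoracic radiotherapy from
4D-CT-derived lung-function images, and a synthetic-phantom generator that
makes the chain testable without patient data. This note records the models,
the parameter choices, and what the synthetic experiments do and do not
demonstrate.

## Ventilation imaging

Regional lung ventilation is estimated as regional volume change between
peak-exhale and peak-inhale CT, using a displacement field `u` from
deformable image registration (DIR). The field lives on the exhale (fixed)
grid and maps each voxel to its position in the inhale (moving) image; this
direction convention is required for the HU metric's indexing and is
asserted in the file metadata.

**HU metric.** Treating CT intensity as a linear mixture of air (-1000 HU)
and tissue (~0 HU), the fractional air-volume change of a voxel is

    V_HU = (HU_ex - HU_in_reg) / (HU_in_reg + 1000)

with `HU_in_reg(x) = HU_in(x + u(x))` obtained by trilinear interpolation.
Voxels whose denominator magnitude falls below 50 HU (registered intensity
within 50 HU of pure air) are excluded rather than allowed to blow up; the
guard is configurable. Sample points outside the inhale volume take the air
padding value and are flagged in a validity mask.

**Jacobian metric.** The volume change implied by the field itself,

    V_Jac = det(I + grad u) - 1,

with derivatives from spacing-scaled central finite differences (one-sided
on volume faces). Central differences are exact for affine fields, which is
the basis of the oracle tests; for the radial field family the truncation
error scales as (spacing / sigma)^2 and is bounded below 1e-3 for
sigma >= 20 mm at 1 mm spacing (measured worst case ~9e-4).

**Percentile conversion.** Ventilation values are converted per patient to
rank percentiles 100*rank/N over the evaluation mask, ties receiving their
mean rank, yielding values in (0, 100]. Two open choices were resolved as
follows: percentiles are computed per patient (not pooled over a cohort),
and negative ventilation values are ranked like any other value rather than
clipped — percentile rank is invariant under monotone transforms, so any
monotone clipping would only collapse ties.

## Dose features

Physical dose is first converted voxelwise to the equivalent dose in 2-Gy
fractions, EQD2 = D (d + a/b) / (2 + a/b) with d = D / n_fractions and
alpha/beta = 3 Gy for lung. The fraction count is uniform; the fraction
dose varies spatially. The conversion is the identity exactly at
2 Gy/fraction.

All features are computed over the evaluation mask = lungs minus the gross
internal tumor volume (GITV) minus the airway/vessel exclusion mask:

- DVH: mean lung dose MLD (Gy) and Vx = percent of lung volume with dose
  strictly exceeding x Gy, x in {5, 10, 20, 30, 40, 50};
- DFH: the same quantities weighted by the percentile function map,
  fVx = 100 * sum(f_v over voxels with dose > x) / sum(f_v) and
  fMLD = sum(f_v D_v) / sum(f_v). A uniform function map reduces DFH to
  DVH exactly.
- Clinical geometry: GITV centroid position normalized to [0, 1] within the
  lung bounding box along the superior-inferior, anterior-posterior and
  left-right axes (0 = superior / anterior / left — a fixed convention,
  since either end is defensible), GITV volume in cc, age, and Brinkman
  index (cigarettes per day x years smoked).

MLD and fMLD are emitted in Gy. Thresholds are strict (">") by design.

## Prediction protocol

- Repeated stratified splits: 70% train / 30% test, per-class sampling
  without replacement with train count round(0.7 * class size), 50 repeats
  by default. Within a repeat, every feature set sees the identical split
  (paired design), so set comparisons use the paired Wilcoxon signed-rank
  test on per-repeat test AUCs.
- Z-scoring (mean 0, population SD 1) is fit on the training partition only
  and applied to both partitions, so no test information leaks into the
  scaler; constant training features are dropped with a warning.
- The classifier is an RBF-kernel SVM. C and gamma are chosen by Bayesian
  optimization (Gaussian-process surrogate, Matern 5/2 kernel with a white
  noise term and fixed hyperparameters on the unit cube, expected-improvement
  acquisition over 256 random candidates) of the mean stratified 5-fold
  inner-CV AUC, over the log-uniform box C in [1e-3, 1e3] and gamma in
  [1e-4, 1e1], with a 30-evaluation budget (10 initial random points). All
  of box, budget and folds are configurable; the values are defaults chosen
  for reproducibility, since no canonical setting exists.
- Model scores are the SVM decision function (signed margins); AUC is
  rank-based, so calibration is unnecessary. AUC ties count 1/2.
- Four nested candidate sets: clinical; + DVH; + DFH; + DVH + DFH.
- Summaries report the median and IQR of test AUCs across repeats, plus two
  95% CI constructions (empirical percentile and normal-theory mean +- 1.96
  SE), because neither is canonical for AUCs over repeated splits.
- Per-feature screening uses the two-sided Mann-Whitney U test (exact null
  for combined n <= 20, tie-corrected normal approximation beyond);
  feature-set comparison uses the two-sided paired Wilcoxon signed-rank
  test with zero differences dropped (exact for <= 25 nonzero pairs).
  Feature redundancy is summarized with tie-corrected Spearman matrices.
- Class imbalance (~25% positives) is handled by stratification only; no
  class weights.
- One master seed derives all split and optimizer seeds via
  `numpy.random.SeedSequence`, making whole experiments bit-reproducible.

## The phantom generator

The generator emulates the structural assumptions of a thoracic
radiotherapy cohort, not its anatomy:

- **Geometry.** Two ellipsoidal lungs (semi-axes 0.17/0.28/0.38 of the
  grid extent), a spherical GITV (radius 8-18 mm) placed inside the lung
  bounding box, and a central cylinder standing in for trimmed airways.
  Default grid 32 x 32 x 40 voxels at 4 mm spacing.
- **Displacement fields** come from families with closed-form Jacobians:
  linear u = Ax + b (det(I+A) constant, rejected unless positive), radial
  u = a exp(-r^2/2s^2)(x - c) with Jacobian (1+f')(1+f/r)^2, and an
  axis-separable sinusoidal family used to exercise finite-difference
  truncation. Cohort patients use the radial family with amplitude
  0.08-0.25 and sigma 35-70 mm.
- **CT pair by construction.** The exhale image is built by inverting the
  HU metric: HU_ex = HU_in_reg + V_target (HU_in_reg + 1000), where
  V_target is the field's analytic Jacobian ventilation plus smooth noise
  (SD 0.02). Because the identical interpolation path is reused downstream,
  the HU metric recovers V_target exactly — this trades realism for an
  exact ground truth. Parenchymal texture (-870 +- 30 HU) extends past the
  lung by the field's maximum reach so in-lung samples never straddle the
  soft-tissue boundary; everything further out is +50 HU.
- **Dose.** Prescription plateau inside the GITV with Gaussian falloff
  (width 15 mm) in distance-to-target; the width was set so cohort DVH
  features land at a realistic scale (V5 ~ 37%, V20 ~ 20%, MLD ~ 11 Gy).
  This replaces beam transport entirely.
- **Function-dose overlap.** A per-patient parameter in [-1, 1] places the
  high-function (radial field) centre between the tumor (+1) and its
  left-right mirror point (-1), controlling how much high-function lung is
  irradiated and hence the spread of the DFH features.
- **Clinical scalars** are drawn from the reference cohort's summary
  distributions (age N(70.3, 10.9), Brinkman N(667.8, 487.7), both
  clipped); fractionation schemes are sampled with the reference
  frequencies (60 Gy/30 fr : 66/33 : 69/23 : 72/24 = 56 : 19 : 6 : 4).
- **Labels.** RP is Bernoulli with logit = sum of stated coefficients on
  cohort-standardized features plus an intercept calibrated (by root
  finding) so the expected incidence equals the target, 24.7% by default.
  The default label model loads on fV20 (coefficient 1.5) and MLD (0.5).

What passing the synthetic experiments shows: the pipeline's arithmetic is
correct against closed forms, the protocol does not leak (null calibration
near AUC 0.5), and it recovers injected dose-function signal. What it does
not show: performance on real patients — the phantom has no CT texture,
artifacts, registration error, or anatomically realistic dose, and clinical
scalars are label-independent except through geometry.

## Problem sizes and numerics

The shipped experiments use 85-100 patients at 32 x 32 x 40 / 4 mm
(~41k voxels, ~5-6k lung voxels), 50 repeats, 30-call optimizer budgets;
one full experiment runs in about a minute on one core. Degenerate inputs
are rejected early with diagnostics (empty masks, non-invertible linear
maps, negative dose, single-class partitions). Percentile ties use mean
ranks; Vx thresholds are strict; all randomness flows from explicit seeds.

## Known limitations

- The exactness of the HU-metric round trip is by construction, not a
  statement about HU-metric accuracy on real CT.
- The radial-family Jacobian oracle tolerance (1e-3) is a truncation bound
  at the stated resolution, not a general guarantee.
- The achieved incidence of a single cohort draw has binomial spread
  (SD ~4.7 points at n=85); only its expectation is calibrated.
- The exclusion cylinder is a crude stand-in for manual airway trimming.
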