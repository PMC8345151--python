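# Methods

This note documents the models, algorithms and numerical choices behind
`pdxrad`, in the order the pipeline runs them.

## Synthetic phantoms (`pdxrad.phantom`)

The generator emulates a two-contrast (T1w/T2w) axial fast-spin-echo
acquisition of a mouse bearing a single subcutaneous tumor:

* **Geometry.** Default grid 128 x 128 in-plane over 14 slices at
  0.25 x 0.25 mm with 1.1 mm slice pitch (1 mm slices, 0.1 mm gap), matching
  common small-animal protocols.  The tumor is an ellipsoid whose radius is
  modulated by a random low-order spherical-harmonic field (degrees 2-3),
  giving smooth, lumpy, seeded boundaries.  With zero lumpiness the ground
  truth is exactly the discretized ellipsoid.
* **Contrast.** Per channel, tumor and background mean intensities plus an
  intra-tumor texture field (Gaussian-filtered white noise, in-plane
  correlation length ~2 voxels).  Defaults make the tumor bright on T2w and
  give T2w roughly three times the T1w texture variability, reflecting the
  higher texture heterogeneity of T2w tumor tissue.  Additive Gaussian noise
  (sigma 8 intensity units against tumor means of 260/520) is the default;
  a Rician option models magnitude images.  Intensities are rounded to
  non-negative integers so DICOM round trips are bit-exact.
* **Raters.** A simulated expert applies a smooth random boundary
  displacement (RMS `boundary_jitter_mm`, implemented as a perturbation of
  the signed Euclidean distance transform) and then independent voxel
  flips: foreground dropped with probability `1 - sensitivity`, background
  added with probability `1 - specificity`.  Jitter precedes the flips so
  the flip rates remain the asymptotic per-rater performance parameters a
  consensus algorithm should recover.
* **What the phantom does not model:** bias fields beyond an optional
  multiplicative term, respiratory motion, partial-volume mixing at tissue
  interfaces, anatomy other than a single tumor, and scanner-specific noise
  correlations.  Green tests therefore demonstrate algorithmic correctness
  and desk-scale end-to-end behaviour, not clinical-grade performance on
  real PDX data.

All randomness flows through one seeded `numpy` generator per operation;
cohorts spawn per-subject child seeds so any subject can be regenerated
independently.

## I/O conventions (`pdxrad.imgio`)

Arrays are `(slice, row, col)` with spacing in mm in the same order;
volumes add a trailing channel axis ordered (T1w, T2w).  DICOM series are
ordered by the projection of `ImagePositionPatient` onto the slice normal,
never by file name; stored values are returned unscaled.  Masks travel as
NIfTI with 0/1 voxels (values > 0.5 read as 1).  Intensity normalization is
a per-channel z-score computed over the whole 3-D volume by default;
whether per-slice or per-volume statistics are preferable is genuinely open
for thick-slice acquisitions, so a per-slice mode is available by flag.

## Segmentation networks (`pdxrad.nn`, `pdxrad.nets`)

The five architectures (U-Net, dense U-Net, residual U-Net, R2U-Net,
D-R2UNet) are built on a small reverse-mode automatic-differentiation core
over numpy, written for exactly the operations these networks need:
same-padded 3x3/1x1 convolution, 2x2 max-pooling, nearest-neighbour
up-sampling followed by a 3x3 convolution (the "up-convolution"), ReLU,
sigmoid, channel concatenation, elementwise addition, spatial dropout and a
soft Dice loss.  Gradients are verified against central finite differences
to 1e-8, including the weight-sharing path of recurrent convolutions.

Architectural blocks compose three mechanisms:

* **dense**: the block input is concatenated with a fresh convolution of
  itself before further processing (feature reuse);
* **residual**: a 1x1-projected shortcut is added to the block output;
* **recurrent (RCL)**: after a feedforward convolution `y0`, the activation
  is refined for `t` time steps as `h <- relu(conv_r(h) + y0)` with shared
  recurrent weights (default `t = 2`).

D-R2UNet uses all three.  Spatial dropout (channelwise, default rate 0.2)
is applied before pooling in the deeper encoder levels and between RCL
units, and is disabled at inference.  Weights are Xavier-initialized. The
final 1x1 convolution ends in a sigmoid; its bias is initialized to
`logit(0.05)` so that initial predictions sit near a realistic foreground
fraction — starting at 0.5 makes early Dice training slam the logits
toward the all-background local optimum, from which the loss surface is
nearly flat.  This one-line initialization was the difference between
stable and seed-dependent training in our experiments.

Training minimizes soft Dice loss, `1 - (2|P.T| + eps)/(|P| + |T| + eps)`
with `eps = 1` on per-batch sums, using Adam.  The configured default
learning rate is 1e-5: the protocol we follow prints the rate as "1 x 10^5",
which can only sensibly be read as 10^-5 (a rate of 10^5 diverges
immediately); the field is configurable and the desk-scale runs in this
package use 1e-3 with about 10 epochs, a size chosen so a full study runs
in well under a minute per epoch on one CPU.  Augmentation applies the same
geometric transform to image (bilinear) and mask (nearest-neighbour):
rotations restricted to 90/180/270 degrees, horizontal/vertical flips, and
continuous shifts and shears of fraction 0.05.  Cross-validation folds are
assigned at the subject level with a fixed seed; slices of one subject
never straddle a fold boundary.

The binarization threshold is chosen where the precision and recall curves
of pooled training predictions cross (linear interpolation between grid
points, grid 0.02..0.98 step 0.02).  Multiple or vanishing crossings
resolve toward 0.5; degenerate predictions fall back to 0.5 with a
warning.  Prediction is slice-wise 2-D inference stacked to 3-D (the data
are thick-slice multi-slice 2-D acquisitions), followed by keeping only the
largest 8-connected component per slice; equal-size ties keep the
component with the smallest row-major index, making the operation
deterministic and idempotent.

## STAPLE (`pdxrad.staple`)

Expectation-maximization over the hidden true segmentation: the E-step
computes posterior foreground weights from the current per-rater
sensitivities/specificities and a scalar prior; the M-step re-estimates
the rater parameters from the weights.  Choices the underlying method
leaves open:

* prior: scalar, the mean foreground fraction across raters within the
  analysis region (standard practice); held fixed during EM so the
  observed-data log-likelihood is provably non-decreasing (asserted on
  every run);
* initialization `p = q = 0.99`; convergence when the largest parameter
  change drops below 1e-6, at most 100 iterations;
* the computation is restricted to the bounding box of the rater union
  dilated by 10 voxels — without this, the vast empty background saturates
  specificity at 1 and slows convergence; `crop_margin=None` disables it.

E-step products are evaluated in log space.  Consensus masks threshold the
weight map at 0.5 (the MAP rule).

## Radiomics (`pdxrad.radiomics`)

The default bank holds exactly **144 features**: morphological 12,
statistical 18, histogram 23, GLCM 24, GLRLM 16, GLSZM 16, GLDZM 16,
NGLDM 14, NGTDM 5.  A candidate bank of 148 additionally computes
Compactness 1, Compactness 2 and Spherical Disproportion (all monotone
transforms of sphericity) and GLCM Sum Average (identical to twice the
joint average for a symmetric matrix); these four are excluded by default.
Note one documented oddity: a bank described as 144-with-4-exclusions is
sometimes percentaged against 143 in the literature this design follows;
the report denominator is therefore configurable (`denominator=` in
`consensus_feature_report`), with 144 the default.

* **Quantization.** Histogram features use 64-level fixed-bin quantization
  over the ROI range (topmost edge inclusive); texture families use a
  64-level Lloyd-Max quantizer — alternating boundary-midpoint and
  conditional-mean updates until the MSE stabilizes (tolerance 1e-8
  relative to the sample variance, at most 500 iterations), empty cells
  re-seeded at their cell midpoint, deterministic initialization from
  fixed-bin representatives.  With fewer distinct intensities than levels
  it falls back to fixed-bin with a warning.
* **Morphology.** Surface quantities come from a marching-cubes mesh of
  the mask after padding and Gaussian anti-aliasing (sigma 0.8 voxels):
  meshing the raw binary indicator inflates surface area by the staircase
  artifact (about +9% for a radius-20 digital ball, pushing sphericity
  down to 0.92), while the anti-aliased mesh is within 0.1% of the
  analytic sphere area.  The cost is rounding of genuinely sharp corners,
  which real tumors do not have.  Axis lengths use the eigenvalues of the
  population covariance of voxel centres (`4*sqrt(lambda)`); the maximum
  3-D diameter uses convex-hull vertices.  The centre-of-mass shift is
  defined geometrically (voxel centroid vs mesh centroid) so that every
  morphological feature depends on the mask alone and is identical across
  contrasts of one subject.
* **Texture.** 3-D matrices with 26-voxel connectivity.  GLCM and GLRLM
  merge the 13 unique direction vectors into one matrix before feature
  computation; GLSZM/GLDZM zones are 26-connected equal-level components;
  GLDZM distances are Chebyshev distances to the ROI border (the volume
  edge counts as border); NGLDM uses exact-level dependence counts
  (coarseness parameter alpha = 0).  The NGLDM family is fixed at 14
  features by the bank contract; of the commonly listed super-set this
  bank keeps the eight emphasis features, the two non-normalized
  non-uniformities, both variances, dependence-count entropy and energy,
  and omits the normalized non-uniformity duplicates and the dependence
  percentage (constant 1 with a full neighbourhood).  Undefined values
  (e.g. GLCM correlation on a constant ROI) are reported as NaN, never
  silently as 0.

Each texture family is validated against an independent brute-force
builder (explicit voxel/neighbour/zone enumeration) with exact equality on
random small ROIs.

## Robustness statistics (`pdxrad.robustness`)

* **Spearman correlation** uses average ranks; p-values come from the
  exact permutation null for n <= 8 without ties (the study sizes this
  targets have 8 test subjects) and the t-approximation otherwise.
  High-correlation flag: rho >= 0.9 and p <= 0.05.  P-values are reported
  raw; a Benjamini-Hochberg column is available but off by default, since
  the comparison protocol thresholds raw p-values.
* **CCC** is Lin's coefficient with population (1/n) moments (Lin's
  original convention; 1/(n-1) available).  Reproducibility flag:
  CCC >= 0.9.  The identity CCC <= |Pearson r| is property-tested.
* **Bland-Altman** works on percent differences relative to the reference
  volume, `(ref - test)/ref * 100`, so underestimation by the test method
  yields a positive bias; limits of agreement are bias +/- 1.96 SD, and
  the Pearson correlation of difference vs mean volume is reported.
* **Boundary sensitivity**: per feature, Spearman rho of the per-subject
  feature change (consensus minus network) against the volume change;
  robust iff -0.4 <= rho <= 0.4.  Features with identically zero change
  are flagged `degenerate` rather than silently robust.  Note the band is
  a descriptive cut, not a test: under an independence null at n = 8 the
  exact permutation distribution of rho places only ~67% of its mass
  inside +/-0.4, so even a perfectly boundary-insensitive feature has a
  ~33% chance of falling outside the band at this sample size.
* **Clustering**: complete-linkage agglomeration on the correlation
  distance `1 - rho` between feature-change profiles (Spearman by default,
  Pearson optional), pairwise-complete observations with a minimum-pairs
  rule (fewer than 3 complete pairs gives the maximal distance 2).  The
  cut height is a required explicit parameter: correlation distances live
  in [0, 2], so no universal default exists and reported cluster counts
  depend on it.  Cophenetic correlation coefficients are computed for
  single, average and complete linkage so the linkage choice can be
  justified from the data.

## Desk-scale study (`pdxrad.study`) and problem sizes

`run_study(seed)` executes the full loop at sizes one CPU handles in about
40 s: 6 subjects (4 train / 2 test), 8 slices of 64 x 64, three raters
(sensitivities 0.93-0.96, specificities ~0.998, 0.2 mm jitter), D-R2UNet
with depth 3 and 8 base filters, 10 epochs at learning rate 1e-3 with
augmentation disabled (at 10 epochs on easy phantoms it only slows
convergence; it stays on by default for real training runs).  Test F1
is scored against the STAPLE consensus on the held-out subjects; volume
concordance (CCC) compares predicted volumes to the analytic ground truth
across all six subjects, a deliberate choice to give the CCC more than two
points while keeping overlap scoring strictly held-out.  These sizes are
the package's defaults for demonstration and validation; every dimension
scales up by configuration.

## Known limitations

* The CNN core is CPU/numpy; it is meant for method validation and small
  studies, not for training at 250 epochs on large cohorts.
* Phantom realism is limited as listed above; real-data performance claims
  cannot be derived from it.
* Feature definitions follow the common standardized formulations, but
  no claim of numerical identity with any specific external radiomics
  implementation is made beyond the properties the tests assert.
* Multi-label consensus and spatially varying STAPLE priors are out of
  scope, as are surface-distance segmentation metrics and wavelet/filtered
  radiomic features.
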