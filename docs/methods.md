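# Methods

This note documents the models, procedures and numerical choices behind
`mfiseg`, and states what the simulation-based validation does and does not
demonstrate about real data.

## Dixon signal model and MFI

Two-point Dixon MRI yields in-phase (IP = W + F) and out-of-phase
(OOP = W − F) magnitude images of the water (W) and fat (F) signal, from
which fat-only and water-only images follow algebraically:
F = (IP − OOP)/2, W = (IP + OOP)/2. The toolkit treats fat/water and
IP/OOP as interchangeable representations of one `DixonVolume`; the
compose/decompose pair is an exact linear bijection, so round trips are
lossless to machine precision.

Muscle fat infiltration for a labelled region is the **ratio of means**,

MFI = 100 · mean(F) / (mean(F) + mean(W)),

not the mean of voxelwise fat fractions. The two differ on heterogeneous
regions; the ratio-of-means form is used throughout because it is the
definition quantified against here, and because it is unbiased to first
order under independent zero-mean noise added to F and W (the noise
averages out of both means before the ratio is taken). Negative F or W
voxels arising from noisy decomposition are therefore **kept** by default
(clipping would bias the means upward); they are counted and logged, and
clipping is available as an explicit opt-in (`clip_negative=True`).
Muscle volume is voxel count × voxel volume (ml), with no partial-volume
weighting.

Degenerate regions (zero voxels, or a non-positive mean-signal
denominator) yield `nan` with a flag rather than an exception, so batch
quantification never aborts on one bad label. Bilateral averaging uses the
mean of the two sides' MFI percentages; when one side is undefined, the
defined side is reported with a `one_sided` flag.

Coordinate convention: axis order (x = left→right, y = posterior→anterior,
z = inferior→superior), 0-based indices; NIfTI affines are respected on
I/O and voxel spacing defaults to the acquisition resolution
0.7 × 0.7 × 3.0 mm.

## Label scheme

The default scheme covers seven bilateral cervical muscle groups with
paired integer labels (left/right): MFSS 2/1, LC 4/3, SSCap 8/7,
SPCap 6/5, LS 14/13, SCM 10/9, TR 12/11, background 0. Each group carries
an inclusive axial slice interval standing in for the vertebral-level
restriction of the manual protocol (muscles are segmented only at levels
where they are consistently present). Schemes serialise to YAML/JSON and
arbitrary schemes are supported; left and right labels must differ so that
mirroring can swap them.

## Phantom simulator

The simulator exists so that every stage — quantification, metrics,
reliability, augmentation, training — is testable with exact ground truth
and no data download.

A phantom is a 3D grid (default 64 × 48 × 12 voxels at 0.7 × 0.7 × 3.0 mm)
with: air background (zero signal), an elliptic body filled with soft
tissue (fat fraction 0.25), a subcutaneous fat ring (0.90), a central
low-signal vertebral-body compartment, and one elliptic muscle column per
label placed bilaterally and mirror-symmetrically about the mid-sagittal
plane, restricted to its group's slice band. Default per-group fat
fractions place the deep groups higher (MFSS 0.17, LC 0.14, SSCap 0.15)
than the superficial ones (SPCap 0.10, SCM 0.09, TR 0.08, LS 0.07),
matching the depth gradient reported for cervical muscle composition.
Voxelwise fat = f·S and water = (1 − f)·S for compartment signal S
(muscle/soft tissue S = 100, bone S = 30), plus independent additive
zero-mean Gaussian noise of configurable SD on the fat and water grids.

Gaussian rather than Rician noise is the default deliberately: applying
noise in the fat/water domain keeps the compose/decompose round trip exact
and keeps the MFI estimator analysable (unbiased under symmetric noise).
Magnitude-MRI noise is Rician near zero signal; this matters in air, not
inside muscle at the SNR simulated here.

Per-phantom jitter (fat fractions, radii; jitter is applied identically to
both sides so mirror symmetry is preserved) gives a cohort of phantoms
between-scan variance, without which reliability coefficients would be
degenerate. Overlapping muscle geometries are rejected with an error; the
jitter clip (±15% on radii) is chosen so the default layout can never
collide.

A compact three-structure variant (`PhantomSpec.training`, 48 × 48 × 12,
labels 1–3 with fat fractions ≈ 0.45/0.12/0.28 and asymmetric positions)
is used for desk-scale network training: the classes are separable by a
combination of intensity and position, which is the same cue structure a
real multi-muscle segmentation task presents, at toy scale.

**Simulated raters.** `perturb_mask` emulates an imperfect human rater via
boundary-localised noise applied per label: an integer in-plane shift
(uniform in ±b voxels), an optional single erosion/dilation pass
(erosion never annihilates a region), and random flips of boundary voxels
at a configurable rate. Labels are written in ascending order onto a fresh
canvas, so the label set can shrink but never grow and regions stay
disjoint.

**Synthetic cohorts.** `generate_cohort` draws per-subject tables under a
linear mixed model: MFI(subject, group) = baseline(group) + 1.8·I(female)
+ slope(group)·(age − 34.2) + 0.03·(BMI − 25) + subject effect + residual,
truncated to [0, 100]. Defaults mirror the cohort whose analyses the
statistics module implements: n = 84 with 61 F / 23 M, age 34.2 ± 10.7
years (truncated to 18–65), a 1.8 percentage-point female MFI excess, and
age slopes of 0.10 %/year for the deep groups versus 0.02 %/year for the
superficial ones — sized so the deep-muscle age correlation is moderate
(partial r ≈ 0.3–0.4) while the superficial one is weak, the qualitative
pattern the analyses are meant to detect. BMI is drawn from a truncated
normal (25 ± 4 kg/m², 16–45); subject and residual SDs default to 1.5
percentage points each. The BMI slope and the variance components are not
published quantities; they are this package's choices, set once to yield
realistic effect-to-noise ratios.

## Segmentation overlap metrics

Per label, one-vs-rest: Dice, Jaccard (JI), conformity coefficient
(CC = (3·Dice − 2)/Dice, negative below Dice = 2/3, undefined at 0), TPR,
TNR, PPV and volume ratio (VR = predicted/reference volume). TNR is
computed over the **full grid**, which is why it saturates near 1.00 for
small structures in a large volume — the familiar pattern in multi-label
reports. When a label is empty in both masks the ratio metrics are
reported as `nan` rather than defined as 1; aggregate rows (mean ± SE
across labels) skip `nan` entries, avoiding silent inflation of means.
The JI and CC identities hold exactly per comparison; they do not hold
for averaged rows (Jensen), so averages are reported but never fed back
into the identities.

## Agreement battery

For paired series (reference vs test, differences oriented
test − reference): Bland-Altman bias and 95% limits of agreement
(bias ± 1.96 × sample SD, n − 1 denominator — conventional Bland-Altman
practice), MAE, RMSE, squared Pearson r², and the through-origin slope β
of reference on test (β = Σtr/Σt²), usable as a multiplicative bias
correction.

ICC(2,1) — two-way random effects, absolute agreement, single measure —
is computed in closed form from the two-way ANOVA mean squares
(Shrout–Fleiss): (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n). The p
value is the F-test of ICC = 0 (F = MSR/MSE on (n−1, (n−1)(k−1)) df) and
the confidence interval uses the McGraw–Wong F-based method with
Satterthwaite degrees of freedom (α = 0.05 by default). Incomplete tables
raise — no imputation; the all-constant table is undefined (`nan`). The
implementation is verified in the test suite against an explicit
sums-based ANOVA oracle (agreement to 1e-10) and against pingouin's
ICC(A,1) row.

No multiple-testing correction is applied anywhere in the battery or the
cohort statistics: the analyses are exploratory and p values are reported
raw, by design.

## Augmentation

The chain applied per augmented sample, in this fixed order: left-right
mirroring (probability 0.5) → elastic deformation → anisotropic scaling +
three-axis rotation. Defaults: 3 elastic control points with
displacement SD sigma = 10 voxels (interpreted as the SD of control-point
displacements, interpolated to voxel resolution with a cubic B-spline),
±2.5% per-axis scaling, ±2.5° rotations about the left-right and
anterior-posterior axes and ±5.0° about superior-inferior, 2000 samples
drawn uniformly from the source pool. Intensities are interpolated
linearly, labels nearest-neighbour; voxels mapped from outside the field
of view become background. Rotations are applied in voxel space; at the
±2.5–5° magnitudes used, the error from ignoring voxel anisotropy is far
below the resampling tolerance.

Mirroring **always swaps each left label with its paired right label**.
Without the swap, flipped samples would label right-sided anatomy with
left-side labels and teach the network anatomically impossible
associations; with it, double mirroring is exactly the identity, which the
tests assert bit-exactly.

Intensity preprocessing is piecewise-linear histogram standardisation onto
pooled decile landmarks (Nyúl-style), monotone by construction, with
linear extension beyond the outer landmarks so intensity tails are not
clamped. Label normalisation maps an arbitrary scheme onto contiguous
training indices 0..K with an invertible lookup.

## Dense V-Net and training

The segmentation model is a compact 3D dense V-Net implemented directly in
NumPy with hand-written backpropagation: dense feature stacks at three
resolution levels (each unit = BatchNorm → ReLU → 3³ convolution
contributing `growth` channels to the stack), dilated convolutions in the
coarser blocks, average-pool downsampling between levels with the
full-resolution stack forwarded by a skip connection, upsampled
concatenation of all stacks, batch-wise spatial (channel) dropout on the
fused features, and a 1×1×1 convolution to per-class logits at input
resolution. Convolutions are lowered with im2col to one BLAS matmul per
layer, which is what makes desk-scale CPU training practical. The
architecture is specified functionally rather than replicated
layer-for-layer from any reference implementation; channel widths are
configuration, and the desk default (growth 6/8/8, two units per block,
~18k parameters, 2 input channels for IP+OOP, 4 classes) trains in
minutes on one CPU.

The loss is **Dice hinge**: per foreground class, soft Dice loss
1 − (2Σpt + ε)/(Σp + Σt + ε) pooled over the batch, with classes whose
loss is already below a hinge margin (default 0.1) clamped to zero
contribution, and the mean taken over the remaining classes (zero when
all are clamped). The clamp stops well-fitted classes (typically the
dominant background, which is excluded from the average anyway, and any
easy foreground class) from diluting the gradient — the mechanism that
limits bias toward predicting background. Plain soft Dice is the
margin-zero special case (`loss="dice"`). The analytic gradient through
the softmax is verified against finite differences in the test suite, as
is the full network backward pass.

Training follows the full-scale recipe at desk size: Adam (lr 0.001), L2
weight decay 1e-5, ReLU, uniform spatial-window sampling with a fixed
number of windows per volume per pass (3), batch size 2–3, stopping when
validation mean foreground Dice plateaus or at `max_iterations`.
Validation defaults to the non-augmented training volumes. All randomness
(window sampling, dropout, initialisation) flows from explicit seeds, so
single-threaded runs are bit-reproducible; a non-finite loss aborts with
diagnostics rather than training through NaNs.

Preprocessing resamples to a target spacing (default 0.7 × 0.7 × 3.0 mm;
linear for intensities, nearest for labels) and zero-pads symmetrically to
a requested shape — never silently cropping; a too-small pad target is an
error. Inference tiles volumes larger than the window with
half-overlapping windows and averages softmax probabilities.

Problem sizes: the validation suite trains the desk model for up to 800
iterations on 20 phantoms of 48 × 48 × 12 voxels with a 48 × 48 × 8
window (about two minutes of CPU time), and the reliability ladder uses
5 severity rungs × 20 phantoms. These sizes were chosen as the smallest
at which the qualitative phenomena of interest — convergence of the
Dice-hinge optimisation, reliability degradation under rater noise,
cohort-level effect recovery — are stable and clearly resolved.

## Cohort statistics

Inputs are per-subject tables (sex, age, BMI, one bilaterally-averaged
MFI column per muscle group). Implemented analyses:

* **Paired t-tests** between all group pairs (two-tailed, uncorrected).
  Identical columns give t = 0, p = 1; a constant nonzero offset with
  zero difference variance is flagged rather than assigned an infinite
  statistic.
* **One-way ANCOVA per group**: MFI ~ sex + age + BMI with sex coded
  female = 1 (a positive coefficient means higher female MFI), F = t² for
  the sex term, and estimated marginal means at the covariate means.
  Zero-variance covariates are dropped, which makes the model reduce
  exactly to the two-sample t-test.
* **Partial Pearson correlations** by residual regression, with p from
  the t transform on n − k − 2 df; with no controls this is exactly the
  plain Pearson correlation.
* **Repeated-measures ANCOVA** with muscle group within subjects, sex
  between, and mean-centred age and BMI as covariates, via the univariate
  approach on orthonormal (Helmert) within-subject contrasts. Sphericity
  is handled by the Greenhouse–Geisser epsilon estimated from the
  residual contrast covariance; both within-subject tests (group, and
  group × sex) report ε-corrected degrees of freedom. At the reference
  cohort size (n = 84, 7 groups, design {1, sex, age, BMI}) this yields
  the df structure F(6ε, 480ε) with error df 80. Greenhouse–Geisser was
  chosen over Huynh–Feldt as the more conservative standard correction;
  with no covariates and no between factor the group test reduces exactly
  to the classical one-way repeated-measures ANOVA, which is how it is
  cross-validated against pingouin in the tests.

## What the simulations do and do not show

Passing tests demonstrate: algebraic exactness of the Dixon operations;
exact agreement of the metric and ICC implementations with brute-force
oracles; unbiasedness of ratio-of-means MFI under additive symmetric
noise; that reliability coefficients degrade monotonically under
increasing boundary noise with MFI more robust than volume (because
boundary errors perturb the voxel count directly but only mildly change
the mean fat fraction of a region whose neighbourhood has similar
composition); that the network, loss and training loop can learn a
position-and-intensity segmentation task to Dice ≥ 0.7 and recover MFI to
within ~2–3 percentage points; and that the cohort statistics recover
injected effects with nominal CI coverage and calibrated null p values.

They do not demonstrate performance on clinical MRI: the phantoms lack
bias fields, chemical-shift and metal artifacts, fat-water swaps, partial
volume at 3 mm slices, true muscle morphology and inter-subject anatomy.
Quantitative values on real scans (Dice, biases, ICCs) cannot be inferred
from these simulations.

## Known limitations

* 2-point Dixon algebra only: no multi-echo fitting, T2* correction,
  phase unwrapping or swap correction.
* The NumPy network is desk-scale; there is no GPU path, and the
  full-scale window (360 × 240 × 32) is configurable but not practical on
  one CPU.
* Surface-distance metrics (Hausdorff, ASSD) are not implemented.
* The rm-ANCOVA is asserted only against its own documented definition
  (orthonormal contrasts, GG correction, mean-centred covariates);
  other software may centre or correct differently.
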