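# Methods

This note documents the statistical procedures, the synthetic-data model, the
network and training defaults, and the numerical choices behind `fedlnm`.

## Diagnostic-accuracy engine

All point metrics are exact ratios of the 2×2 counts (TP/FP/FN/TN) of a
binary reader call against the histopathology gold standard. Undefined ratios
(empty margin) are reported as `None` with a named flag — never silently
coerced to 0 or NaN.

**AUC of a binary test.** A reader who issues one binary call has a
one-threshold empirical ROC; its trapezoidal area is (sensitivity +
specificity)/2. This is the only ROC construction consistent with the
published AUC values, which equal that expression at printed precision for
all seven imaging groups. The AUC variance uses DeLong's nonparametric
estimator specialised to binary scores: positive-class placement values take
two levels, so `var = se(1−se)/(4 n₊) + sp(1−sp)/(4 n₋)` (a Hanley–McNeil-type
reduction). Confidence intervals are normal-approximation, truncated to
[0, 1]. The exact CI method behind the published intervals is not stated, so
our intervals are asserted to *overlap* the published ones, not to match
digit-for-digit.

**Group comparisons.** Proportions are compared by Pearson's chi-squared test
on the 2×2 group table, 1 df, two-sided, *without* Yates continuity
correction — the uncorrected statistic reproduces the published p-values
(e.g. 0.001 and 0.652 for the CT-vs-PET/CT and CT-vs-MRI sensitivity
contrasts). AUCs are compared with an unpaired z-test on independent
estimates, because only marginal 2×2 tables per modality are published —
per-patient paired reader data would be required for a paired analysis and do
not exist publicly. No multiple-testing correction is applied (none was in
the source analysis).

**Published-cell verification.** Recomputing every published table cell from
the published counts reveals three internal inconsistencies (M-P NPV printed
87.1 vs 189/216 = 87.5; C-M-P PPV printed 43.06 vs 31/71 = 43.66; C-M-P NPV
printed 85.44 vs 135/159 = 84.91). These are treated as print errors: the
tool reports them in a discrepancy note and they are excluded from
exact-match assertions.

## Synthetic cohort generator

The generator emulates the *structure* of a two-center gynecologic-oncology
cohort; it is the test bed for the pipeline, not a clinical simulator.

- **Exact quotas.** Positive counts are `round(n·prevalence)` per diagnosis
  (89/423 cervical, 14/144 endometrial in the epidemiologic preset), so
  headline counts are deterministic regression anchors rather than Bernoulli
  draws.
- **Reader calls.** Each performed examination is positive with probability
  equal to the modality's sensitivity (node-positive patients) or
  1 − specificity (node-negative). Defaults: CT (0.3263, 0.9215),
  MRI (0.3590, 0.9337), PET/CT (0.5769, 0.8571). A shared standard-normal
  "nodal conspicuity" latent per patient can correlate calls across
  modalities (`conspicuity` ∈ [0, 1), default 0 = conditional independence
  given the true nodal status); the thresholding construction leaves every
  marginal operating point exact for any correlation level.
- **Coverage.** Which patients received which scan is modeled as independent
  per-modality inclusion with probabilities fitted to the published
  examination-group sizes (439/567, 440/567, 393/567). The true overlap
  structure of the examination groups is unpublished; independence is a
  modeling choice and the pairwise group sizes are therefore only
  approximately reproduced.
- **Covariates** (age, FIGO stage, LVSI, stromal invasion, histology, grade)
  are sampled independently from the published marginal category frequencies
  per diagnosis. Ages are a clipped normal (median 49, SD 12, range 19–78).
- **Planted signal.** The federated presets add a covariate→LNM logistic
  link: with coefficients β over the encoded features, the exact positive
  quota is drawn by a Gumbel race (weighted sampling without replacement with
  weights ∝ exp(βᵀx)). This preserves quota exactness while making nodal
  status strongly predictable from stage, invasion depth, LVSI and age.
  Preset coefficients (5·LVSI + 4·FIGO + 3·stromal + 2·age_z + 2·high-risk
  histology, on the unit-scaled feature encoding) were fixed once at design
  time to give a near-ceiling Bayes AUC (≈0.97 by logistic-regression
  cross-check), so recovery failures indicate pipeline defects rather than an
  unlearnable task.
- **Two presets for an unreconciled source.** The published client partition
  (111+115 / 226+115 ⇒ 337 positives of 567) is arithmetically incompatible
  with the published pathology counts (103 positives). The generator exposes
  both as presets — `epidemiologic_config()` (pathology truth) and
  `federated_config()` (partition truth, prevalence 0.5944 in both diagnoses)
  — and never guesses a reconciliation.
- **Phantoms.** 64×64 single-channel images: smoothed Gaussian background
  texture (level 0.35, amplitude 0.06, correlation length 2 px) plus, for
  node-positive cases, one elliptical blob (semi-axes 3–6 px, peak contrast
  0.35) with a quartic intensity falloff `exp(−r⁴)` so the annotated mask
  (the geometric ellipse, r ≤ 1) coincides with the visible intensity edge.
  20% of node-negative cases carry a faint sub-threshold blob (25% contrast)
  as hard negatives; their masks stay empty, keeping the mask-iff-label
  invariant. Matrix size and preprocessing of the real scans are unpublished;
  64×64 is a CPU-friendly choice.

What the generator does **not** emulate: 3-D anatomy, scanner physics,
multiple lesions or slices per patient, covariate–covariate dependence,
inter-reader variability drift. Passing tests therefore demonstrate pipeline
correctness and signal recovery under the stated generative model — not
clinical performance on real images.

## Network and training

- **Text branch:** MLP, two hidden layers of 32 ReLU units (configurable).
- **Image branch:** U-Net-style encoder–decoder, 3 down/3 up stages,
  LeakyReLU slope 0.01, skip concatenations, nearest-neighbour upsampling,
  1×1 output convolution to two per-pixel classes. Base width is 4 channels
  (doubling per stage) — small enough that a pure-numpy implementation trains
  the full federated benchmark on one CPU in minutes; width is configurable.
  The case-level logit is a dense head on the globally averaged bottleneck.
- **Fusion:** `softmax(α·mlp_logits + β·cnn_logits)`; α, β unconstrained
  scalars initialised to 1. With β = 0 or no image input the model reduces
  exactly to the text-only mode (a tested identity).
- **Loss:** mean cross-entropy on the fused prediction (probability clip
  1e-12), plus λ = 0.5 times a per-pixel cross-entropy against the phantom
  mask. Nodal pixels are ~1% of the image, so the pixel loss carries a
  positive-class weight (default 50); without it the segmentation head
  collapses to all-background. The summed (unaveraged) loss is available for
  literal single-sample accounting.
- **Optimizer:** minibatch SGD with classical momentum 0.9, batch 16. The
  library default learning rate is 1e-3; the experiment presets use 0.02,
  the smallest rate in a design sweep (0.02/0.05/0.1) that converges within
  the 20-round budget in both modes. Momentum state is local to each client
  round; a single full-batch step from fresh state equals the plain gradient
  step, which keeps the FedAvg one-round/centralized-step identity exact.
- **Federation:** FedAvg `w = Σ (nₖ/n)wₖ` with weights from training-split
  sizes, all clients every round, 1 local epoch, 20 rounds. The published
  aggregation formula contains both a 1/K factor and nₖ/n weights, which
  double-normalizes (it shrinks parameters K-fold even for identical
  clients); the standard FedAvg form is used, with the literal scaling
  available behind `literal_scaling=True` for comparison. Aggregation covers
  every parameter, including α and β. The privacy contract is structural:
  the aggregation path receives only named parameter arrays.

## Numerical choices

- All randomness flows through `numpy.random.default_rng([seed, stream])`
  with fixed stream offsets per purpose (covariates, labels, calls, coverage,
  images, batching), so cohorts, partitions, splits and training runs are
  bit-reproducible per seed.
- Softmax is max-shifted; probabilities are clipped at 1e-12 before logs.
- Published-value comparisons round half-up at the printed precision
  (2 decimals for percentages, 3 for AUC).
- Train/test splits round the train size half-up per class, reconciling the
  total on the larger class — this reproduces the published 181/45 and
  273/68 splits exactly.
- Model arrays default to float32 for speed; float64 is a constructor option
  and is used where tests check 1e-8-level algebraic identities.
- Max-pooling gradient routes to the argmax (first index on ties); ties have
  measure zero under the continuous phantom intensities.

## Problem sizes

The default federated benchmark is 2 clients (226 and 341 records, stratified
8:2 splits), 20 rounds × 1 local epoch, batch 16, 3 seeds, 64×64 phantoms —
sizes chosen so the whole benchmark (both modes) completes in a few minutes
on a single CPU while matching the published cohort and partition sizes
exactly. The external ovarian-cancer-like preset is 115 patients at 40%
prevalence with an older age distribution and 30%-reduced image contrast; the
real external cohort's characteristics are unpublished, so this preset is a
synthetic stand-in used only for relative, property-based checks.

## Known limitations

- The headline clinical performance figures of the source analysis depend on
  private hospital data and are not reproducible here; the federated
  benchmark asserts *recovery properties* on synthetic data instead
  (text-only AUC ≥ 0.90; multimodal within 0.02 of text-only or better).
- The unpaired AUC comparison is an approximation forced by the absence of
  per-patient paired reader calls; with access to paired data a paired
  DeLong test would be strictly better.
- The U-Net is deliberately small; it segments high-contrast elliptical
  phantoms, not clinical MRI.
- Single-slice phantoms: the aggregation convention for multi-slice cases
  (max of per-slice positive probabilities) is defined but unexercised by the
  default generator.
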