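# Methods

`liverprog` re-implements, at desk scale, a multimodal survival-prediction
workflow for unresectable hepatocellular carcinoma (HCC) treated with
immune-checkpoint inhibitors plus targeted therapy.  The clinical system it
mirrors predicts overall survival (OS) and progression-free survival (PFS)
from triphasic contrast CT and baseline clinical covariates, by fusing
three deep survival networks into an ensemble signature and fusing that
signature with clinical features using random survival forests (RSFs).
Because the underlying patient cohorts are not redistributable, every
stage here is developed and validated against a synthetic cohort generator
with a known data-generating process.

## The synthetic cohort

Each simulated patient consists of:

* **Latent covariates.** Tumor diameter (6 mm + Gamma(2, 2), clipped to
  fit the phantom), intra-tumor heterogeneity amplitude η ~ U(0, 5),
  lesion count 1 + Binomial(2, 0.2), and clinical flags (AFP > 400,
  PVTT, ECOG 1, Child–Pugh B, HBV, cirrhosis, metastases, therapy line,
  prior local therapy) with marginals matching a BCLC-C–dominated
  population (median age 58, 85 % male, 84 % HBV).
* **Survival.** OS times are Weibull with shape 1.5 (right-skewed,
  non-exponential) and scale 23.6 months, so the baseline median
  (scale · ln2^(1/shape)) is ≈ 18.5 months; the hazard is multiplied by
  `exp(LP)` with `LP = Σ β·covariate`.  PFS shares the LP with a larger
  baseline hazard (scale factor 0.41, baseline median ≈ 7.6 months) and
  is capped at the OS time.  One independent exponential censoring time
  per patient right-censors both endpoints; its rate is solved
  numerically (Gauss–Legendre quadrature + Brent root-finding) so the
  expected OS censoring fraction equals the configured value (default
  0.35, matching ~22-month median follow-up behaviour).
* **Default hazard weights.** Continuous covariates enter standardized:
  size 0.70/SD, η 0.55/SD, extra lesions 0.30 each, AFP 0.50, PVTT 0.50,
  ECOG 0.40, Child–Pugh B 0.40.  These give the oracle linear predictor a
  C-index of ≈ 0.72–0.74, in the range of strong published prognostic
  models; nothing in the source material pins these effect sizes, so they
  were set once to that target and not revisited.  Preset variants
  concentrate the budget in the image channel (network training studies),
  zero it (null calibration), or split it between channels
  (fusion-ordering studies).
* **Phantom.** A jittered ellipsoidal liver (HU 60 + smooth Gaussian
  texture, SD 6 HU) containing ellipsoidal tumors whose largest diameter
  equals the size covariate within one voxel and whose internal texture
  SD is 4 HU per unit η; three contrast phases share the geometry and
  differ by mean enhancement offsets (arterial hyper-enhances tumor,
  portal-venous enhances parenchyma, delayed washes out) plus scanner
  noise (SD 0.6 HU).  Default cube edge is 32 voxels at 1 mm — a
  miniature liver; 128 mirrors the clinical input but is not required by
  any shipped study.

What the phantom does **not** emulate: anatomy (vessels, adjacent
organs), inter-phase misregistration, scanner/protocol heterogeneity,
segmentation error, or any realistic radiomic covariance structure.
Passing tests therefore demonstrate that the *pipeline machinery*
(preprocessing, feature definitions, selection logic, losses, fusion and
statistics) behaves correctly under a known truth — not that the models
would attain clinical performance on real CT.

Reproducibility: every patient draws from named RNG substreams
(`SeedSequence([seed, patient, purpose])` for purpose ∈ clinical / image /
survival), so adding or removing a stage never perturbs another, and
identical configs give identical cohorts.

## Preprocessing

Resample to isotropic 1 mm (cubic B-spline for images, nearest neighbour
for masks, via SimpleITK) → clip HU to [−200, 250] → rescale to [0, 1] →
CLAHE → crop to the liver bounding box (default pad 0) → resize each
phase to an E³ cube (cubic; anisotropic stretch) and stack (A, V, D).
CLAHE is applied per axial slice (clip limit 0.01, 8×8 tiles) because the
filter is 2D-native; it runs after windowing so it always sees a fixed
dynamic range.  The order, window, CLAHE parameters and crop box are
recorded in the `ModelInput` provenance; the chain is deterministic and
mask voxel counts are conserved by cropping.  Registration is a plug-in
hook; synthetic data are co-registered by construction and pass through a
no-op registrar.

## Radiomics

A self-contained IBSI-style extractor computes 107 features per region
(tumor `T`, liver `L`) per phase: 14 mesh-based shape, 18 first-order,
and 75 texture features (24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM)
— 214 per scan, 642 per patient, named `{region}_{phase}_{class}{Name}`.
Numerical conventions: fixed 25-HU bins anchored at
`floor(min/width)·width`; 13 symmetric 3D directions at distance 1 with
per-direction averaging (GLCM, GLRLM); 26-connected zones (GLSZM) and
dependencies with zero gray-level tolerance (GLDM); shape features from
marching cubes at iso-level 0.5 on a lightly Gaussian-smoothed mask (the
voxel staircase otherwise inflates surface area ~8 %, pushing a digital
ball's sphericity to 0.92 instead of ≈ 1), with principal axis lengths
from the physical-coordinate covariance.

Feature selection (training split only):

1. **Univariate screen** — keep features whose univariate Cox model
   concordance exceeds `t_uni = 0.55` (strict).  Since the C-index is
   rank-invariant and the univariate fit orients its coefficient with the
   concordant direction, this equals `max(c, 1−c)` of the raw feature's
   Harrell C, which is what is computed (642 closed-form pair counts
   instead of 642 iterative fits); anti-concordant features are retained.
2. **VIF pruning** — iteratively drop the feature with the largest
   variance inflation factor (diagonal of the inverse correlation matrix,
   ridge-stabilized) until all VIF ≤ `t_vif = 10`.  The single-pass set
   subtraction the selection rule literally describes is order-ambiguous;
   greedy removal is deterministic and guarantees the bound.  Constant
   features leave first (infinite VIF).
3. **RSF importance** — fit an RSF (default 500 trees, √p candidate
   features, minimum node size 15, log-rank splits, fixed seed) and keep
   features whose permutation importance (mean training-concordance drop
   over 5 seeded shuffles) exceeds `t_mul = 0.05`.  Cox and VIF stages
   see z-scored features (training mean/SD stored in the trace); the RSF
   sees raw values.

OS and PFS selections run independently.  Applying a locked trace to new
data is a pure column projection.

## Survival networks

All three networks map the (3, E, E, E) cube to two risk scores (OS,
PFS; higher = worse) and are trained with the negative Cox partial
log-likelihood, Breslow ties, averaged over events, with **full-cohort
risk sets each epoch** (no within-batch truncation at desk scale).  The
loss is translation-invariant and is verified against brute-force
risk-set expansion to 1e−8.

* **Network 1 (local CNN):** inverted-bottleneck convolutional encoder on
  a tumor-gated input — the input is multiplied by
  `0.2 + 0.8 · soft tumor mask`, making the "local tumor focus" an
  explicit, testable mechanism.
* **Network 2 (semi-supervised):** strided conv encoder → bottleneck →
  nearest-neighbour-upsampling decoder, pretrained to reconstruct the
  (unlabeled) training volumes under MSE with best-checkpoint restore;
  fine-tuning trains the survival head plus encoder with the encoder
  learning rate scaled ×0.1.
* **Network 3 (conv-attention):** conv stem, then the feature map is
  mean-pooled into token sequences along the axial, coronal and sagittal
  axes; each sequence gets learned positional encodings and single-head
  scaled-dot-product self-attention, is mean-pooled, concatenated and
  mapped to the two heads.

The networks run on a small in-package reverse-mode autodiff engine
(im2col 3D convolution, batched matmul, softmax, reductions; float32;
Adam with per-parameter learning-rate scales).  Desk configs are < 70 k
parameters and train in ~1–3 minutes at edge 32, n = 120 on one CPU.
Checkpoint selection uses validation OS concordance when a validation set
is supplied, otherwise the final epoch.

## Fusion

* **Ensemble-DL signature:** RSF over the three network risks.  Two
  deliberate choices beyond the bare recipe:
  * the forest also receives the mean of the three z-scored risks as a
    derived input — forests split one axis at a time, and the diagonal
    average is exactly the noise-cancelling direction of an ensemble, so
    exposing it lets shallow splits use it directly (without it the fused
    signature trailed the best single input held-out);
  * alongside the full-split model, a **3-fold cross-fitted training
    signature** is produced.  A forest's scores on its own training set
    partly memorize outcomes; stacking the next model on them leaks and
    collapses held-out performance (in a cohort whose imaging channel is
    pure noise, the fused model lost ~0.12 C-index versus the clinical
    benchmark until the cross-fitted signature was used).  All downstream
    fusers train on the cross-fitted signature.  Because cumulative-hazard
    sums from different forests live on different scales, each signature
    is additionally rank-normalized through the ECDF of the scores of the
    model that produced it (cross-fitted values against themselves at
    training time, full-model values against the full model's training
    scores at scoring time), so the fusion forest's split thresholds
    transfer between fitting and scoring.
* **MMF:** RSF over the signature plus encoded clinical covariates
  (binary flags 0/1, Child–Pugh/BCLC ordinal, age/size continuous).  The
  covariates entering the fusion default to the benchmark's prescreened
  set (configurable to all).
* **Fusion forest defaults:** 500 trees, log-rank splits, minimum node
  size 20, seeded.  Node size 10 was tried first and overfits the
  low-dimensional risk inputs (held-out C ≈ 0.55 vs 0.62 for a single
  input); 20 restores generalization.
* **Comparators:** clinical benchmark (univariate Cox prescreen at
  p < 0.05, then an RSF whose minimum leaf size is chosen by 3-fold
  cross-validated concordance, refit and frozen; falls back to all
  covariates with a warning if nothing passes), mRECIST comparator (Cox
  on one-hot response with CR reference; single-category fits return an
  explicit zero-information scorer), and the radiomics RSF from the
  selection above.

Every frozen model records the patient ids it was fitted on; evaluation
flags (but does not block) scoring patients from a model's own fit set.

## Evaluation harness

* **Harrell C-index:** exact vectorized pair count — comparable pair
  `(i, j)` iff `T_i < T_j` and `E_i = 1` (a patient censored exactly at
  an event time stays in the risk set), tied risks ½.  Verified against
  exhaustive enumeration (n ≤ 8) and scikit-survival.  CIs by percentile
  bootstrap (default 1000 replicates, seeded).
* **Model comparison:** two-sided z-test with the SE of ΔC from a paired
  bootstrap (patients resampled jointly); identical models give p = 1.
* **Time-dependent AUC:** cumulative/dynamic AUC with IPCW from the
  Kaplan–Meier censoring estimator (scikit-survival); with no censoring
  it equals the plain binary AUC exactly.  Default horizons 12/24/36
  months (OS) and 3/6/12 months (PFS).
* **KM / log-rank / HR:** lifelines; never-reached medians are reported
  as missing, not NaN.  The single-covariate Cox HR uses lifelines' Efron
  tie handling — synthetic times are continuous, so this coincides with
  Breslow on all shipped data.
* **Cutoff search:** grid over the 10th–90th risk percentiles maximizing
  the log-rank statistic, each group ≥ 10 % of patients; deterministic
  and rank-invariant.  The published operating thresholds (MMF 1.26 OS /
  1.98 PFS; Ensemble-DL 0.45 OS / 0.90 PFS) are shipped as named
  constants; they pertain to the original clinical fit and the ambiguous
  pairing in the source is resolved in that order, configurable.

## Interpretability

Grad-CAM targets the OS risk output by default and the last convolutional
block (configurable among captured conv layers): channel weights are
spatially averaged gradients, the map is the rectified weighted sum,
trilinearly upsampled and min-max normalized; an all-non-positive
response returns an explicit all-zero map with a flag rather than a
normalized artifact.  Shapley attributions use permutation sampling with
a background sample: each Monte-Carlo draw takes a random permutation and
background row and credits sequential output deltas, which makes local
accuracy hold exactly against the sampled-background expectation and
recovers additive models in closed form.  Signature–feature association
is per-feature Spearman rank correlation with two-sided t-approximation
p-values and no multiplicity correction; aggregation across features is
left to the caller.

## Pipeline, I/O and sizes

`run_pipeline` chains simulate → preprocess → radiomics → networks →
fusion → evaluation → interpretability, with per-stage toggles, a
schema-validated config (unknown keys rejected), a resolved-config JSON +
hash in every output directory, and per-stage wall-time logging; a stage
failure halts with the stage name while earlier artifacts persist.
Cohorts live on disk as NIfTI volumes/masks plus `clinical.csv`,
`outcomes.csv` and `ground_truth.json`; loading validates vocabularies,
positive times and id alignment and reports every problem with its row.
The split is a seeded 8:2 train/validation partition (external test
cohorts are separate directories by design).

Shipped study sizes (chosen to keep the default suite and the acceptance
script in the minutes range on one CPU): phantom edge 32; n = 120 for
network training; n = 200 × 50 replicates for selection recovery;
n = 300 × 10 seeds for fusion ordering; n = 2000 for the Weibull median
check; 200 simulations for log-rank calibration.  All are configurable
upward.

## Known limitations

* The phantom's radiomic features are far more redundant than real CT
  features; the VIF stage consequently prunes aggressively on synthetic
  tables.
* Per-coefficient CI coverage estimated from 20 replicates is itself a
  Binomial(20, 0.95) draw; the minimum over seven coefficients can fall
  below 0.9 for some seeds without indicating miscalibration.
* The networks are deliberately small; nothing here speaks to the
  behaviour of ImageNet-scale backbones at 128³.
* mRECIST categories are generated from the latent hazard (ordered
  logit), not from longitudinal imaging; the mRECIST comparator is
  structural, not radiological.
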