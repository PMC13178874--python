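# Methods

## Overview

`fundusvae` studies whether explicitly separating a fundus image into its
anatomical constituents — photometric background, optic disc/cup, and
vasculature — before unsupervised encoding yields latent phenotypes that are
more disentangled, more anatomically localized, and more powerful for
genetic discovery than a single whole-image ("monolithic") encoder of equal
latent capacity. Real cohort imaging is replaced by a parametric simulator
whose generative factors are known exactly, which turns every claim into a
measurable property.

## Synthetic fundus simulator

Each subject carries twelve morphological factors drawn independently and
uniformly within fixed bounds (units in fractions of image width unless
noted):

| factor | bounds | stream |
|---|---|---|
| illumination gradient | [−1, 1] | background |
| pigment density | [0, 1] | background |
| tessellation amplitude | [0, 1] | background |
| disc radius | [0.05, 0.15] | disc/cup |
| cup-to-disc ratio | [0.1, 0.9] | disc/cup |
| disc ovality | [0.7, 1.3] | disc/cup |
| disc centre x, y | x ∈ [0.22, 0.42] (sampling), y ∈ [0.38, 0.62] | disc/cup |
| major vessel count | {4…8} | vessel |
| vessel tortuosity | [0, 1] | vessel |
| vessel caliber | [0.004, 0.02] | vessel |
| branch depth | {1…4} | vessel |

Rendering is a pure function of (factors, resolution, seed); a per-sample
seed derived from (global seed, subject id, eye) makes datasets reproducible
sample by sample. The painter composes: (1) a reddish base colour darkened
by pigment, modulated by a linear horizontal illumination ramp and a
three-component band-limited sinusoidal texture; (2) concentric disc/cup
ellipses (area preserved under ovality, so cup area / disc area equals the
squared cup-to-disc ratio); (3) a recursive vessel tree grown from the disc
boundary, with tortuosity realized as a deterministic sinusoidal
displacement perpendicular to the path (amplitude 0.03·tortuosity,
wavelength 0.07) over a gentle random heading walk, one child branch per
segment at 30 % of the parent's length, child width 0.8× and length 0.75×.
Sub-pixel calibers are drawn with coverage proportional to width
(anti-aliasing), so caliber stays visible in intensities even when the
binary mask cannot express it. A drawing budget caps vessel coverage at
13 % of the frame so the mask-sparsity invariant (≤ 15 %) always holds.

Paired eyes share subject-level factors; the right eye mirrors the disc's
horizontal position and each eye receives Gaussian noise with standard
deviation `eye_noise_sd` (default 0.02) expressed as a fraction of each
factor's range. Genetic effects shift factors additively per allele, with
both eyes of a subject shifted identically and values clipped to bounds
(clips are recorded).

**Generator adequacy.** The suite requires that ordinary least squares of
each factor on simple hand-crafted image statistics (mask areas, centroids,
intensity summaries, skeleton arc lengths, ring crossings, branch-point
counts, arc-over-chord tortuosity) explains more than 90 % of its variance
at 64 px — i.e. every factor is genuinely expressed in the image and is a
meaningful disentanglement target.

**What the simulator does not emulate:** pathology (hemorrhages, drusen),
explicit foveal geometry, camera vignetting and defocus heterogeneity,
inter-subject correlation structure between factors, and linkage
disequilibrium between variants. Passing tests therefore demonstrate that
the architecture separates structures *when the structures are separable
and the masks are correct*; they do not certify performance on real
photographs or real genotypes.

## Preprocessing

The background stream input is a per-channel k×k sliding-window median with
edge replication. The canonical kernel is 17×17 at a 512 px working
resolution; at other resolutions k scales as the nearest odd integer of
17·(H/512) with a floor of 3, preserving the physical smoothing scale. The
disc/cup input gates intensities by the disc∪cup masks and crops to the
disc bounding box plus a 25 % margin (maximizing geometric resolution); the
vessel stream consumes the binary mask itself; the monolithic baseline sees
the raw resized image. Learned image QC is replaced by an input contract:
all-black images or mask/image shape mismatches are rejected with the
offending sample named. Train/validation splitting shuffles unique subject
ids and cuts at the requested fraction (default 0.75), so both eyes of a
subject always land on the same side.

## Model and objective

All four models share one backbone: five stride-2 convolution blocks
(3×3 kernels, batch normalization, leaky ReLU 0.2; channel widths
`base_width · 2^i`), linear heads for μ and log σ² (log-variance clamped to
±12 for numerical safety), and a mirrored decoder of five
nearest-neighbour-upsample + convolution blocks ending in a sigmoid. The
resolution must be divisible by 2⁵. The objective is

&nbsp;&nbsp;total = MSE + β·KL + λ_s·sharpness,

with MSE averaged over pixels and channels, KL in its closed Gaussian form
averaged over the batch, and the sharpness term — vessel stream only,
default λ_s = 0.5 — the mean squared difference of Sobel gradient-magnitude
maps over the image interior (borders excluded so constants score zero; the
functional form is this package's choice). Encoder dropout (default 0.1)
after each of the five vessel-stream blocks counters overfitting to sparse
binary masks. β defaults to 1.0 in `StreamConfig` per the standard VAE
objective; the pipeline sets β = 3×10⁻⁴, i.e. approximately 1/(3·32·32),
which restores the conventional sum-MSE/KL balance under a mean-MSE
objective. The monolithic baseline's latent dimensionality always equals
the sum of the stream dimensionalities (capacity-matched comparison).

Training uses Adam (learning rate 10⁻³, batch 32) with a fixed epoch count
and no early stopping, so runs are comparable across latent dimensions; the
best checkpoint is the epoch with minimal validation loss. Everything — 
initialization, batch order, reparameterization noise, dropout masks — is
driven by explicit seeds; identical configuration and seed reproduce
identical parameters bitwise. The engine is a compact numpy layer library
with hand-written backpropagation (im2col convolutions, exact col2im
adjoint), gradient-checked against central finite differences in float64.

Latent dimensionality selection formalizes the reconstruction-saturation
idea: over the grid d ∈ {8, 16, 32, 64, 128, 256}, choose the smallest d
whose validation-SSIM gain over the previous grid point is ≤ ε (default
0.01) while lying within ε of the grid maximum; if no plateau exists, take
the argmax. Stream defaults are 64 (background), 64 (disc/cup), 128
(vessel); the desk-scale replication uses 16/16/16 against a monolithic 48.

## Disentanglement evaluation

Ground-truth targets are obtained by PCA *within* each stream's dedicated
factor block (factors standardized first; components retained to 95 %
variance). Because the simulator draws factors independently, a PCA across
all twelve factors would have a near-spherical spectrum whose directions are
sampling noise; block-wise PCA keeps every orthogonal target attributable
to one anatomical domain. For the same reason, the classical textbook
property "PCA of orthogonal factors returns the factors" only holds when
the factors have distinct variances, which is how the unit test constructs
its fixture (with standardization disabled).

The importance matrix R (latents × targets) comes from one gradient-boosted
tree ensemble per target (40 trees, depth 3, fixed seed; lasso available as
a fast alternative), fitted on a random half of the samples; per-target
informativeness error is held-out MSE normalized by target variance,
clipped to [0, 1]. DCI follows the entropy formulation: per-latent
disentanglement D_j = 1 − H(row_j)/log(#targets), aggregated with
row-mass weights; completeness is the column-wise mirror with log(#latents);
informativeness I = 1 − mean error. MIG discretizes latents and targets
into 20 quantile bins and reports the mean normalized gap between the top
two latent–target mutual informations (plug-in estimator; degenerate
single-bin targets are excluded with a warning).

**The comparison that matters** fits the importance matrix *jointly* over
the concatenated structure-aware latents, then reads per-stream block
scores as the row-mass-weighted mean D_j over that stream's latents; the
monolithic model is scored on identical targets. Joint fitting is essential:
fitted per-model in isolation, an uninformative model's importances are
concentrated noise (trees must put their splits somewhere), which *inflates*
D precisely when the model knows nothing — the known pathology of reading
DCI's D without its I. In the joint fit, latents that carry no signal are
outcompeted to near-zero importance instead.

Metrics are averaged over 10 resampling iterations (subsets drawn without
replacement when the population allows, indices sorted so equal multisets
give equal metrics). Inter-ocular robustness recomputes the per-stream
block D separately from left-eye and right-eye rows; the tolerance on the
absolute difference is 0.1. Reconstruction quality is reported as SSIM
(Gaussian-weighted, σ = 1.5) and PSNR; LPIPS requires pretrained perceptual
weights and is reported as "not computed".

## Latent traversals and locality

For each latent i, the decoder is evaluated along μᵢ + s·σᵢ,
s ∈ linspace(−3, 3, 7), holding other coordinates at the base code; σᵢ is
the *population* standard deviation of that latent (the per-sample
posterior width would conflate subject variability with encoder
uncertainty). The t-map is the per-pixel variance across the sweep,
channel-averaged and max-normalized (constant stacks are flagged, not
normalized; a variance floor of 10⁻¹² absorbs float rounding). The locality
score is t-map mass inside an anatomical mask divided by total mass; masks
are dilated by 2 px to absorb rasterization misalignment. Aggregated
locality averages over all non-degenerate dimensions and (by default) 16–32
base images, each scored against its own vessel mask.

## Genetic simulation and association

SNPs are simulated independently: minor-allele frequency uniform in
[0.05, 0.5], genotypes Binomial(2, maf), map positions 600 kb apart so
every simulated SNP is clump-independent by construction (the clumping rule
is exercised by explicitly constructed correlated duplicates in tests). Six
causal SNPs (two per anatomical domain, fixed MAF 0.3 so the toy scan is
well powered) shift their target factor by 0.25 of its population standard
deviation per allele.

The scan is closed-form OLS of each standardized latent on each SNP
(optionally covariate-adjusted via QR residualization), with two-sided
t-tests. Multi-trait significance uses the Bonferroni-adjusted minimum p
across latents — a deliberately simple rule with controlled family-wise
error, standing in for heavier multi-trait combination machinery, which
belongs to its own methodology. Significant SNPs are reduced to independent
loci by greedy clumping (take the most significant, absorb SNPs within
250 kb with genotype r² > 0.1, repeat). The toy-scale significance
threshold is 0.05/#SNPs on the adjusted p; null calibration additionally
counts false loci at the conventional genome-wide 5×10⁻⁸, where the
expected count is essentially zero. Recovery is the fraction of causal
SNPs cleared by the adjusted threshold; attribution is correct when a
recovered SNP's best-associated latent carries the causally targeted
stream's prefix.

## Study conditions (replication experiment)

The canonical experiment, shared by the acceptance tests and
`scripts/acceptance.py`, runs five seeds. Per seed: 120 paired-eye training
subjects at 32×32 px (75/25 participant split), four models trained 10
epochs (d = 16 per stream, monolithic 48, base width 16); 250 paired-eye
evaluation subjects with 10 resampling iterations of n = 400; locality over
16 base images with 7-step sweeps; association on 2,000 single-eye subjects
and 200 SNPs, 20 null scans and 500 null SNPs for FWER. These sizes were
chosen so the full experiment (twenty model trainings plus evaluation)
completes in minutes on one CPU while keeping every comparison
well-powered; they are the package's study conditions, not tuning knobs.

## Numerical choices and edge cases

* Median filtering uses replicate padding; even kernels are rejected.
* Constant latent columns standardize to zero and are flagged.
* An all-zero importance matrix raises (DCI undefined) rather than
  returning a score.
* PSNR of identical images returns +inf, excluded from resampled means.
* Clumping breaks significance ties by sort order (stable, deterministic).
* Rank-deficient SNPs (monomorphic after residualization) are excluded and
  named.
* Batch-vs-single forward passes agree to ~10⁻⁶ (float32 accumulation
  order); tests and contracts use that tolerance where batching varies.

## Known limitations

* The vessel stream's pixel-level reconstruction quality (SSIM ≈ 0.01–0.1
  at 32 px) is intrinsically poor because thin-structure masks punish any
  sub-pixel shift; its latents are nonetheless informative, which is what
  the DCI/MIG and association stages measure.
* DCI's D is only meaningful alongside informativeness; the joint-fit
  design above addresses this, but single-model DCI numbers from
  `resample_evaluate` should be read with the I column.
* The association stage omits population structure, relatedness and LD;
  conclusions about relative (structure-aware vs monolithic) recovery do
  not transfer to absolute GWAS yield on real cohorts.
* At 32 px some factors (notably vessel caliber and tortuosity) are near
  the resolution floor; their recovery by any encoder is partial, which is
  visible in per-factor attribution.
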