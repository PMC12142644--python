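# Methods

## The task

A patient's brain MRI is summarized as a vector of d continuous
anatomical measurements (volumes, thicknesses, areas), min-max
normalized to [−1, 1]. Given the baseline vector `i1` and a vector of
demographic/outcome labels `l`, the package models the conditional
distribution `P(i2 | i1, l)` of the follow-up measurements, so that a
missing second visit can be imputed by sampling. The practical obstacle
is composition: in a biobank-style cohort only ~12% of patients have a
follow-up scan, while the unpaired majority still carries information
about the marginal distribution of plausible anatomy.

## Model

**Diffusion process.** A discrete denoising-diffusion model with T = 100
steps and a linear variance schedule β running from 0.0015 to 0.02
(both endpoints inclusive; ᾱ_t is the running product of α_t = 1 − β_t,
reaching ᾱ_T ≈ 0.339). The network is trained to predict the noise ε in
x_t = √ᾱ_t·x₀ + √(1 − ᾱ_t)·ε from (x_t, t, i1, l), with a mean-squared
loss and one uniformly drawn t per sample per epoch. Generation runs the
ancestral chain from a standard Gaussian draw.

**Reverse-process variance.** The reverse step uses the posterior
variance σ_t² = β_t (1 − ᾱ_{t−1})/(1 − ᾱ_t) rather than the simpler
σ_t² = β_t. Both are standard; the posterior choice injects markedly
less noise in the late (small-t) steps, where injected noise can no
longer be contracted away, and measured better sample fidelity on the
synthetic benchmark at identical cost. σ_1 = 0 follows from ᾱ_0 = 1.

**Clipping the denoised estimate.** At every reverse step the implied
clean signal x̂₀ = (x_t − √(1 − ᾱ_t)·ε̂)/√ᾱ_t is clipped to the data
range [−1, 1] before the posterior mean is formed. The features are
defined on [−1, 1], so this is a hard prior, and it is load-bearing: the
denoiser normalizes its input (layer normalization), so its noise
prediction cannot grow with the state magnitude, and without the clip
the chain has no restoring force — in diagnostics the unclipped state
norm grew ~25× over the chain. Intermediate *states* are never clipped;
the final sample is additionally clamped to [−1, 1].

**Denoiser.** A 1D UNet-style multilayer perceptron. The normalized
step t/T is embedded with paired sinusoids over embed_dim/2 geometric
frequencies spanning 1..2T (the top frequency still resolves adjacent
steps without aliasing); the conditioning [i1; l] is affinely embedded
to the same width, and the two are summed into one steering embedding.
Encoder blocks apply LayerNorm, then map the representation and the
embedding separately to the block width, sum them, pass through a
sigmoid-linear unit, and finish with an affine enrichment. Two residual
blocks (pairs of SiLU linear layers at the bottleneck width) sit between
encoder and decoder; decoder blocks mirror the encoder but first
concatenate the skip activation saved at the matching encoder depth
(concatenate-then-affine; the first decoder skip is the bottleneck's
encoder input, the last is the raw network input). An optional single
self-attention head over the bottleneck (treated as 16 tokens) is off by
default. Initialization is fan-in-scaled Gaussian, seeded. The whole
network, its backward pass, and the Adam optimizer are implemented in
numpy; gradients are exact (verified against finite differences).

**Self-conditioned training set.** Every epoch rebuilds the sample list:
paired records contribute (target = i2, conditioning = i1); unpaired
records contribute (target = i1, conditioning = i1 or, with probability
1/2, a copy of i1 noised by k = 5 forward steps). The coin and the
perturbation noise are redrawn each epoch — the mechanism is a data
augmentation, so fixing them per record would waste its diversity.

**Gradient manipulation.** After each batch the global L2 norm G of the
gradient (over all parameters) is compared with thresholds
δ_max < δ_err: pass unchanged if G ≤ δ_max, rescale to norm δ_max
(direction preserved) if δ_max < G ≤ δ_err, and skip the update entirely
otherwise. Skipping bypasses the optimizer call — feeding zeros to Adam
would still move parameters through its momentum. Thresholds are either
fixed (0.3/0.75, the published operating point for the biobank-scale
model) or calibrated from one update-free pass as (mean norm,
3 × max norm). At desk scale the calibrated mode is the practical
default: small-d networks on synthetic cohorts have initial gradient
norms far above 0.75, and the fixed thresholds would skip every update.

**Model selection.** After each epoch the current network generates one
follow-up per longitudinal validation patient (fixed per-record seeds,
identical across epochs) and the mean per-patient Euclidean distance to
the real follow-up is the selection score. The best-scoring parameters
are kept; training stops after `patience` epochs without improvement
(defaults: 1,000 epochs, patience 50, learning rate 0.001, Adam,
batch 128). Validation is subsampled to at most 400 longitudinal
records.

## Synthetic cohort generator

Each patient has a rank-r latent anatomical state S (r = 8 of d = 24 by
default); both visits are noisy measurements of it. The follow-up state
applies a near-identity gain (0.95 diagonal plus weak random coupling)
to S and adds per-label decay vectors; by default the binary disease
flag (prevalence 0.3) subtracts 0.3 raw units from a designated
6-feature block, mimicking a small subcortical region's disease-linked
volume decay. Measurement noise is 0.3 of the unit signal scale on both
visits — scan-rescan reliability around 0.9, typical of small-structure
volumetry. A configurable paired fraction (default 12%) keeps its
follow-up; a small fraction of entries (default 1%) is masked missing.
Everything is min-max normalized to [−1, 1] and the noiseless follow-up
means are returned for all patients as ground truth.

Two consequences matter for interpretation. First, copying the baseline
forward has an irreducible error floor of √d × noise_scale (raw scale)
— the baseline's own measurement noise — even under identity
progression, so a model can beat the copy heuristic only by exploiting
the low-rank structure that the unpaired pool reveals. Second, the
generator is linear-Gaussian with exchangeable paired/unpaired subsets;
real imaging features are heavier-tailed, nonlinearly related, and
paired availability may correlate with health status. Passing tests
here demonstrate mechanism correctness and recoverability of planted
structure, not real-data performance.

## Evaluation

Per-patient similarity (Pearson correlation, Euclidean distance, cosine
distance between real and generated follow-ups, averaged over patients;
degenerate zero-variance/zero-norm vectors are excluded and tallied);
distribution-level similarity (Fréchet distance between Gaussians
fitted to the two sets, computed through the symmetric eigendecomposition
of Σ_a^{1/2} Σ_b Σ_a^{1/2} with 1e−6 diagonal jitter; Pearson
correlation of per-feature means; mean absolute off-diagonal difference
of the two feature-correlation matrices); downstream utility (AUROC of
an MLP classifier — two hidden layers of 256, Adam, batch 128, learning
rate 0.001, early stopping with patience 5 on a 10% validation split —
trained on [i1; i2; labels minus the task label], with `all_first` and
`limited_paired` naive modes for comparison); and a case-study statistic
(denormalized mean change of an averaged feature-block volume, compared
between a labelled group and the rest, for real and generated
follow-ups).

## Desk-scale benchmark and problem sizes

`secondgram.benchmark.run_recovery_benchmark` trains on a synthetic
cohort with 3,000 unpaired + 300 paired training records, a
40-paired/300-unpaired validation set, and 100 paired test records at
d = 24, for up to 300 epochs with batch size 32 and calibrated
thresholds, then compares generations against the noiseless truth and
against the copy-the-baseline heuristic. The smaller batch gives the
optimizer enough steps to converge within the epoch budget at this
problem size; the network is scaled to the data (widths 96/64/48,
embedding 64) rather than the published 512/256/128 used for d = 769.
The test suite uses the same or smaller problem sizes throughout so the
full run completes in minutes.

## Numerical choices and degenerate inputs

Constant features normalize to 0 and denormalize to their constant.
Values outside supplied normalization ranges are clipped. Within-vector
missingness is filled by iterative chained regression (per-feature means
as the starting point, least-squares refits, at most 10 rounds,
tolerance 1e−3 — the imputer's tolerance is relative to the largest
absolute value, which on [−1, 1] data effectively matches an absolute
1e−3); a fully missing feature is an error. Split sizes use ceilings:
test = ⌈0.2 × longitudinal⌉, then validation = ⌈0.1 × stratum⌉ per
stratum of the remaining pool — the unique convention reproducing the
published cohort table from its input counts. Per-record generation
seeds derive from SHA-256 of (master seed, patient id), making
enrichment order-independent. All randomness flows through seeded numpy
generators; identical seeds give bit-identical cohorts, training runs,
and metric reports.

## Known limitations

The conditional distribution learned from an unpaired-dominant mixture
is itself a mixture: roughly ten of eleven training targets are the
self-conditioned identity task, so the learned conditional concentrates
near the conditioning baseline, and a single well-calibrated draw
cannot land much closer to the true follow-up mean than the baseline
copy does — the expected squared distance of a perfect sampler's draw
equals the conditional variance plus the mean's offset. Beating the
copy heuristic therefore depends on the model's manifold denoising
(shrinking measurement noise toward the learned low-rank structure),
which demands more optimization than the epoch budgets used in the
tests reliably provide; the benchmark reports both the model and the
copy numbers rather than assuming which is smaller. Sampling quality is
also bounded by the prescribed schedule: with ᾱ_T ≈ 0.34 the forward
process never reaches the standard Gaussian that sampling starts from,
so the earliest reverse steps operate off-distribution. Training is
single-threaded numpy: correct and transparent, but far slower per step
than a GPU framework, which bounds the problem sizes used in the test
suite.
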