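# Methods

## Problem setting

`perturbdiff` models drug-perturbed bulk gene-expression profiles as draws
from a conditional generative model. A profile x ∈ R^G (G landmark genes;
L1000-style level-3, quantile-normalised values) is observed under a
condition c = (basal profile of the same cell line, compound structure, dose
in µM, time in h). The package learns p(x | c) in two stages: a variational
autoencoder compresses x to a d-dimensional latent z, and a Gaussian
diffusion model learns the conditional distribution of those latents.

## VAE

The encoder is an MLP predicting a diagonal Gaussian posterior q(z|x) =
N(μ, diag σ²) via (μ, log σ²); the decoder is an MLP with a linear output
layer (expression values are real and roughly centred, so no squashing).
Training minimises, per batch of N samples,

    L = (1/N) Σ_i ‖x_i − x̂_i‖²  +  k · (1/N) Σ_i Σ_j (μ_ij² + σ_ij² − log σ_ij² − 1)

with k = 1 by default. The KL term is written without the conventional 1/2
factor; k can absorb constant factors, and `kl_half=True` selects the
standard Gaussian KL. Reconstruction uses the reparameterisation z = μ +
σ ⊙ ε during training; the latent handed to the diffusion stage is the
posterior mean μ (a config switch samples instead), which gives the
diffusion model a deterministic, low-noise target per profile.

Latents are standardised per dimension by their training mean/SD before
diffusion and de-standardised before decoding. This puts the diffusion data
on unit scale, so the sampler's N(0, I) starting distribution matches the
forward process's terminal marginal even at moderate T.

## Diffusion model

Forward process: z_t = √(1−β_t) z_{t−1} + √β_t ε with a linear schedule
β_t = β_min + (t−1)/(T−1)(β_max−β_min), endpoints 1e-5 and 0.01, closed form
z_t = √ᾱ_t z_0 + √(1−ᾱ_t) ε with ᾱ_t = Π_{s≤t}(1−β_s).

Reverse process: a conditional network predicts the step mean μθ and an
interpolation vector s ∈ [0,1]^d; the step variance is

    Σθ = exp(s·log β_t + (1−s)·log β̃_t),   β̃_t = (1−ᾱ_{t−1})/(1−ᾱ_t)·β_t,

bounded between the forward variance (upper) and the forward-posterior
variance (lower). β̃_1 = 0 exactly — the t=1 posterior is degenerate at z_0 —
so inside the variance interpolation only, β̃_1 is clamped to β_1 to keep
log β̃ finite, and the final ancestral-sampling step returns μθ without
added noise.

Training draws t ~ U{1..T}, forms z_t by the closed form and a stochastic
posterior target z_{t−1} = √ᾱ_{t−1} β_t/(1−ᾱ_t)·z_0 + √α_t(1−ᾱ_{t−1})/(1−ᾱ_t)·z_t
+ √β̃_t ε, and minimises the Gaussian negative log-likelihood

    L = ½ E[(z_{t−1} − μθ)²/Σθ + log Σθ]

averaged over batch and latent dimensions (so the loss scale is independent
of d). An analytic-KL variant of the objective is available (`kl_loss`) for
comparison.

### Mean parameterisation

The mean head does not emit μθ directly. Because β̃_t falls to ~1e-9 at small
t, the precision weight 1/Σθ in the NLL spans ~5 orders of magnitude across
timesteps; a directly predicted mean would need far higher accuracy at small
t than at large t, which in practice destabilises training (we observed loss
spikes and a collapse of the conditional signal). The network therefore
predicts the forward noise ε̂ and the mean is formed analytically as
μθ = (z_t − β_t/√(1−ᾱ_t)·ε̂)/√α_t — the standard noise-prediction form of
the posterior mean, which flattens the effective per-timestep loss weights
to a ~400-fold range. The module's contract is unchanged: `denoise` returns
(μθ, s), with s produced by a sigmoid so the [0,1] bound holds by
construction. `parameterization="mu"` restores the direct head.

### Conditioning

c = τ(concat(MLP_basal(basal), f(compound), MLP_dose(dose'), MLP_time(time')))
where f is a pluggable featurizer — default: hashed circular-substructure
(Morgan radius-2) fingerprint folded to 64 bits and unit-normalised; a table
backend loads externally precomputed per-SMILES embeddings from CSV. Dose is
log10-transformed and standardised by training statistics (doses span orders
of magnitude); time is expressed as a fraction of a day. The timestep enters
the denoiser as a sinusoidal embedding through one linear layer. Every
branch can be ablated (replaced by a zero vector of the same width) without
shape changes. All networks are small tanh MLPs trained jointly with Adam;
they are implemented in numpy with explicit reverse-mode gradients
(`_nn.py`), which keeps the package dependency-light and fully seeded on
CPU.

## Data handling

Matrices are samples×genes; formats are plain TSV and GCT 1.2 (genes as
rows on disk, transposed on load). Cleaning follows the standard screen
preprocessing order: compounds observed fewer than 5 times among perturbed
records in the entire dataset are removed (a compound seen exactly 5 times
is kept; identity is the RDKit-canonical SMILES so spelling variants count
as one compound); records whose SMILES cannot be parsed are removed; each
perturbed record is then paired with its control through an explicit
`pair_id` (no plate/vehicle inference is attempted — the pairing key is part
of the input contract). Filters are idempotent and order-preserving.
Cross-validation splits partition compounds (or cell lines) into disjoint
fold subsets; control records ride with every training set since they are
conditioning inputs, not prediction targets.

## Synthetic data

The simulator generates L1000-like paired screens with known ground truth:

* per-cell-line basal profiles drawn once from N(0, basal_spread²) per gene,
  giving separable cell-line clusters;
* per-compound effect vectors supported on whole gene modules (each compound
  moves `modules_per_compound` of the `n_modules` contiguous blocks, with
  N(0, effect_scale²) gene weights);
* monotone saturating dose response h(dose) = log1p(dose/d₀)/log1p(d_max/d₀)
  (d₀ the smallest configured dose, so h(0)=0 and h(d_max)=1), mirroring
  pharmacological dose scaling;
* saturating time kinetics g(t) = t/(t+τ½) with τ½ the median configured
  time;
* residual noise with correlation `module_rho` within modules, 0 between,
  marginal SD `noise_sd`.

A perturbed sample is basal + h(dose)·g(time)·effect + noise; controls are
basal + independent noise. Default conditions — 4 cell lines, 10 compounds,
doses (0.1, 1, 10) µM, times (6, 24) h, 20 replicates, G=50 genes in 5
modules, basal_spread 1.0, module_rho 0.6, effect_scale 2.0, noise_sd 0.5 —
define the package's reference desk-scale study. Compound "SMILES" cycle
through a built-in list of real molecules so validity filtering and
fingerprinting run without downloads.

What the simulator does *not* emulate: bead-level measurement noise,
quantile-normalisation artifacts, any relationship between a compound's
actual chemistry and its effect direction, or transcriptome-scale gene
counts. Passing the recovery studies therefore demonstrates that the
machinery can learn condition-dependent, module-structured responses at
desk scale — not that it attains any particular accuracy on real L1000
data.

## Evaluation statistics

* **Reconstruction**: per-sample Pearson r across genes and R² = 1 −
  SS_res/SS_tot with SS_tot centred on the true sample's own mean;
  zero-variance samples are excluded and counted. A per-gene variant is
  available by flag.
* **Top-k correlation overlap**: per compound, genes are scored by mean
  absolute off-diagonal Pearson correlation across the compound's samples
  ("max" available by flag); the statistic is |top_k(real) ∩
  top_k(generated)|, with hypergeometric null expectation k²/G. The default
  sample floor is 30 per compound.
* **Heatmap matrices**: k×k correlation matrices over a fixed gene list,
  symmetric with unit diagonal; constant genes yield 0 with a log flag.
* **Trajectory analysis**: per ordered condition level (dose or time), the
  centroid of generated latent embeddings is projected onto the first
  principal axis of the centroid set; the statistic is the Spearman
  correlation between level rank and projection. The axis sign is
  canonicalised (largest-magnitude component positive) so the statistic is
  invariant to the order levels are supplied in and its permutation null is
  centred at zero.

## Reference studies (`perturbdiff.workflows`)

* `vae_overfit_study`: 64 simulated profiles (G=50), d=8, 1500 epochs —
  checks VAE capacity via reconstruction PCC/R².
* `parameter_recovery_study`: default simulator conditions; VAE with
  (256, 256) hidden layers, 500 epochs; diffusion with T=100, a (256, 256)
  denoiser, 20 000 Adam steps at batch 256. Generation mirrors the screen's
  sampling design: one draw per perturbed sample conditioned on that
  sample's own paired control. Reported: mean per-condition Pearson r
  between generated condition means and the simulator's noise-free
  conditional means; mean top-10 overlap across compounds with its k²/G
  null; |Spearman| of the latent dose trajectory for one cell-line/compound
  pair at 24 h, 500 draws per dose. The whole study runs in a few minutes
  on one CPU core.
* `null_overlap_study`: 200 pairs of independent Gaussian matrices
  (40×300), k=30 — calibrates the overlap statistic against its
  hypergeometric expectation of 3.

## Numerical choices and limitations

* All randomness flows through `numpy.random.default_rng` seeds; identical
  seeds give bit-identical results on a fixed platform (single-threaded
  BLAS variation aside).
* T defaults to 1000 scale in full configurations but the reference studies
  use T=100, which together with latent standardisation keeps the sampler's
  N(0,I) start consistent with the forward terminal.
* The learned variance s tends toward a near-constant profile across
  conditions in our studies — expected for population-averaged responses
  whose conditional uncertainty is small — so it should not be read as a
  per-condition confidence signal.
* Divergent training (non-finite loss) aborts with a diagnostic rather than
  continuing; the VAE posterior log-variance is unconstrained, which at
  extreme learning rates can overflow — lower the learning rate rather than
  clamping.
* No GCTX/HDF5 parsing, no GSEA, no IC50 downstream regression, no
  t-SNE/UMAP inside the core (embeddings and centroid tables are exported
  for external projection).
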