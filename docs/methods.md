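# Methods

## Problem

Given, for each cancer patient, (a) a bag of pre-extracted feature
vectors — one 1024-dimensional embedding per 256×256 whole-slide-image
(WSI) patch, with patch-grid coordinates — and (b) a wide omics profile
(gene expression, copy-number, mutation blocks), predict right-censored
overall survival, quantify risk stratification, and support inference
when the omics modality is missing at prediction time.

## Model

Three trainable components are coupled end to end.

**Slide encoder (transformer MIL).** Patch embeddings are projected to
width `d_w` (default 128) with a ReLU, the sequence is padded to the next
perfect square M = ⌈√N⌉² by repeating its first M−N tokens, and a learned
class token is prepended. Two pre-norm residual self-attention layers
(default 4 heads) process the sequence, with a pyramid positional
encoding between them: the tokens are reshaped to a √M×√M grid and three
depthwise convolutions (kernels 7/5/3) are added residually; the class
token bypasses the convolution. The final class token, after layer norm,
is the slide embedding h_w. Sequences longer than four times the landmark
count (default 16 landmarks) use Nystrom-approximated attention: segment-
mean landmarks, the three-factor softmax product with a fixed six-step
pseudoinverse iteration (deliberately truncated — the landmark kernel is
often near-singular and the converged pseudoinverse amplifies noise), and
row renormalization so the implied attention stays row-stochastic.
Shorter sequences use exact softmax attention.

**Omics encoder (self-normalizing network).** The standardized omics
vector passes through two Linear→SELU→alpha-dropout blocks
(F→64→`d_o`=64 by default, dropout 0.3), with lecun-normal
initialization. SELU's fixed point keeps activations near zero mean and
unit variance without batch normalization, which matters for wide,
sample-poor omics tables.

**Bridge and head.** Two-layer SELU MLPs map each embedding into the
other space: f_wo: h_w → ĥ_o and f_ow: h_o → ĥ_w. The fusion head is a
two-layer MLP from [h_w; h_o] to `n_bins` = 4 logits. With hazards
h_j = σ(logit_j), survival is S(j) = ∏_{k≤j}(1−h_k) and the scalar risk
is −Σ_j S(j) (uses every bin, unlike 1−S(last)).

**Loss.**

    L = L_surv + λ · ( ‖f_wo(h_w) − sg(h_o)‖²/d_o + ‖f_ow(h_o) − sg(h_w)‖²/d_w )

L_surv is the censoring-aware discrete-time negative log-likelihood
(event in bin j: −log h_j − Σ_{k<j} log(1−h_k); censored in bin j:
−Σ_{k≤j} log(1−h_k); hazards clamped to [1e-7, 1−1e-7]). sg is
stop-gradient: the bridge regression targets are detached so the survival
task cannot collapse both embedding spaces onto a constant. Residuals are
normalized per dimension so λ (default 0.5) is comparable when d_w ≠ d_o.
Ablations: `single_directional` keeps only the slide→omics term;
`non_bridge` sets λ = 0 (plain late concatenation).

**Modality dropout.** During multimodal training, a random half of the
steps (default `modality_dropout` = 0.5) route the bridge-generated
pseudo-omics embedding f_wo(h_w) through the fusion head instead of the
real omics embedding. This trains the head on the same inputs it will
see at missing-modality inference, couples the bridge into the survival
objective, and acts as a strong regularizer on the fusion; in desk-scale
experiments it was the single most effective fusion choice.

**Missing-modality inference.** With no omics available, the pseudo-omics
embedding f_wo(h_w) is routed through the same fusion head. Slide-only
inference is supported; omics-only inference through the bridge is not.

## Time discretization and evaluation

Bin edges are the {1/4, 1/2, 3/4} quantiles (linear interpolation,
type 7) of *uncensored* training-fold event times; bins are right-closed
with an open last bin. All preprocessing statistics (feature mean/sd,
bin edges) come from the training fold only.

Concordance is Harrell's C: pair (i,j) comparable iff t_i < t_j and
patient i had the event; tied risks count 0.5; pairs with exactly equal
times are excluded (including event-event ties — chosen for symmetry, so
C(risks) + C(−risks) = 1 on risk-tie-free data). Cross-validation folds
are aggregated with a 95% t-interval over fold C-indices (sample sd,
k−1 df); the interval method is recorded in the output because other
choices (bootstrap within folds) exist. Stratification splits at the
median pooled out-of-fold risk (> median → high). Kaplan–Meier curves
and the two-group log-rank test come from lifelines; the hazard ratio of
the high/low indicator is a univariate Cox fit by Newton iteration on
the Breslow partial likelihood with |β| capped at 15 and a divergence
flag for monotone likelihoods.

## Alignment and interpretability

Embedding alignment between the slide and omics spaces is measured two
ways: the Jaccard overlap of directed k-nearest-neighbor graphs (k = 50,
cosine distance, ties broken by lower index, self excluded) and the
Kraskov–Stögbauer–Grassberger mutual-information estimator (variant 1,
Chebyshev balls, k = 3, seeded 1e-10 jitter for tie-breaking).

Omics attributions use integrated gradients on the scalar risk with a
midpoint Riemann rule (default 50 steps, 300 where the completeness
residual is checked) and a zero baseline in standardized space, i.e. the
training-cohort mean patient. Cohort-level ranking is by mean |IG| per
feature. Patch attention is the class-token attention row of the final
attention layer, averaged over heads, truncated to the original N
patches and min-max normalized to [0,1]; a constant row is exported as
all zeros and flagged uninformative.

## Synthetic cohort

The generator emulates the paired-data layout: shared latents
z_shared ∈ R^8 drive (a) the mean of a planted 30% of "informative"
patches in each bag, (b) part of the omics features, and (c) the hazard
through η = β·z_shared (β = 0.35·1 by default, giving sd(η) ≈ 1 and a
true-risk C-index near 0.75). Each modality expresses only a fraction of
the shared components (bags the first 75%, omics the last 75%), so the
two overlap on half and each holds a quarter privately — the regime in
which fusion has something to gain; private latents (4 per modality) add
survival-irrelevant structure. Mixing matrices are drawn once per cohort,
scaled by 1/√d so feature variances are O(1). The omics table is split
into blocks: expression stays continuous, copy-number is clip-rounded to
{−2..2}, mutation thresholds the latent at its 85th percentile. Event
times are exponential with rate h0·exp(η), h0 = 0.1; independent
exponential censoring is calibrated by 1-d root finding on the exact
marginal censoring probability E[c/(c+h0 e^η)] = target (default 0.4),
avoiding rejection sampling.

What the generator does *not* emulate: pixel-level histology, batch
effects, missing clinical covariates, nonlinear hazard effects, realistic
gene–gene correlation structure, or bag sizes of real slides (default
bags of 16–64 patches versus thousands in practice). Passing tests
therefore demonstrate that the machinery recovers a planted linear-latent
signal at desk scale, not performance on real cohorts.

## Defaults and problem sizes

The package's architecture defaults are deliberately CPU-scale: d_w=128,
4 heads, 2 layers, d_o=64, epochs=8, Adam (lr 1e-3, weight decay 1e-4),
gradient accumulation over 4 slides, batch = one slide with its omics,
modality dropout 0.5.
The reference experiment is n = 600 patients, 40% censoring, five-fold
cross-validation; the acceptance script uses n = 300 and three folds.
All values are exposed through YAML (`encoder:`, `bridge:`, `train:`)
and can be raised for larger experiments.

## Numerical and design choices

- Sequence squaring pads by repeating leading tokens, which breaks
  permutation invariance even without the positional encoding; exact
  invariance holds only for perfect-square bags on the exact-attention
  path with the positional encoding disabled (tested as such).
- The Nystrom class-token attention row is clipped at zero and
  renormalized; the approximation can produce small negative weights.
- Zero-variance features standardize to 0 with sd replaced by 1 and are
  flagged rather than erroring.
- Patients with multiple slides are not supported in the container
  format; one bag per patient id is enforced by the readers.
- Fold splits are a seeded permutation into near-equal blocks;
  stratification by event status is available but off by default.
- Checkpoints store parameter arrays (npz) plus a JSON sidecar with
  config, preprocessing statistics and seeds; save/load round trips
  reproduce predictions bit-identically.

## Known limitations

**Attention maps at desk scale.** On the synthetic cohort the trained
slide encoder's class-token attention does *not* concentrate on the
planted informative patches — the acceptance suite computes top-decile
enrichment below 1 and keeps that check failing deliberately. The
mechanism is visible already at initialization: informative patches form
a tight cluster in key space, so they share softmax mass, while the
maximum over many diffuse background scores captures the top decile; and
because near-uniform attention over value vectors already recovers the
planted signal (bags are small and the per-patch signal strong), the
survival loss exerts no pressure to concentrate attention. Sparser
plantations, stronger lesion signatures, longer training, the
gated-attention encoder and alternative score exports (first layer,
value-norm weighting) were all examined and none yields enrichment ≥ 1.
Informative attention maps likely require the regime of real slides —
thousands of patches with subtle per-patch signal and long training —
which is outside this package's CPU-scale defaults. Exported attention
should therefore be read as a description of what the encoder attends
to, not validated evidence of lesion localization.

Training is single-threaded numpy; wall-clock scales linearly with bag
size and epochs. The discrete-time head with 4 bins coarsens time; rank
metrics are insensitive to this but calibrated survival probabilities
would need more bins. The bridge is trained jointly with the survival
task; a staged schedule (align first, then fit) is plausible and
unexplored. Alignment metrics are reported on training-fold embeddings
of a single fold; they are descriptive, not inferential.
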