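# Methods

## Model

`omicvae` fits a conditional multi-view variational autoencoder to a set
of aligned omic matrices (cell lines x features, one matrix per omic
layer) plus a complete conditional matrix (binary driver-mutation /
fusion / tissue / MSI flags and standardized continuous covariates such
as growth rate).

Per view `d` with encoder feature count `p_d` and `q` conditionals:

- encoder: input `[x_d, c]` of size `p_d + q` → fully connected hidden
  layer of `round(0.7 (p_d + q))` units (PReLU, elementwise dropout 0.4)
  → view latent of `min(round(0.25 (p_d + q)), cap)` units (PReLU);
- joint path: concatenation of all view latents → fully connected PReLU
  layer → two linear heads producing `mu` and `log sigma^2` of the joint
  code (200 dimensions at full scale);
- decoder: `[z, c]` → mirror of the encoder sized from the **full**
  feature count of the view → linear output over all features.

The code is sampled as `z = mu + exp(logvar/2) * eps`, `eps ~ N(0, I)`
during training; all inference-time operations use `z = mu`.

The asymmetry (encoders see only highly variable features, decoders
reconstruct everything) cuts parameter count without giving up output
coverage. The view-latent width is additionally capped (default 512)
because 25% of a very wide view would dwarf the joint code; the cap is a
config field.

### Loss

`L = sum_d MSE_d + lambda KL + alpha L_con` with defaults
`lambda = 1e-4`, `alpha = 5e-3`.

- `MSE_d` averages squared error over *observed* cells only; cells that
  were missing on disk are zero-filled for the forward pass but excluded
  from every statistic and from the loss. A view a sample lacks entirely
  contributes nothing for that sample; no renormalization across views is
  applied.
- `KL` is the closed-form divergence from the diagonal-Gaussian posterior
  to `N(0, I)`, summed over latent dimensions and averaged over the
  batch (the batch-averaging convention is a choice; the alternative sum
  only rescales `lambda`).
- `L_con` puts a margin hinge on cosine similarities of within-batch
  pairs: positive pairs (same tissue) pay `[0.85 - cos]_+`, negative
  pairs `[cos - 0.15]_+`. The two pair classes are averaged separately
  and summed so the (much larger) negative class cannot drown the
  positive one; the per-pair definition does not dictate an aggregation,
  and this one is the package's choice. The embeddings entering the loss
  are the sampled `z` (the representation the decoder actually sees); a
  config switch substitutes `mu`.

### View dropout

With probability `view_dropout_p` per (sample, view) during training, an
entire view's input block is set to zero — no inverted-dropout
rescaling, so a dropped view is indistinguishable from a genuinely
missing screen. If every view of a sample is drawn dropped, the draw is
repeated for that sample (a sample must keep at least one view). This
conditioning deflates the marginal drop rate by the factor
`(1 - r^(V-1)) / (1 - r^V)`, negligible for the configured rates.
Conditionals are exempt from both element and view dropout. The default
rate is 0.3; 0.5 is the alternative documented operating point for final
models and is a single config field away.

### Optimization

Adam (lr 3e-4 at full scale, weight decay 5e-4 applied as L2 on the
gradient), seeded shuffled mini-batches, and a reduce-on-plateau
schedule on the epoch-mean total loss: multiply the lr by 0.6 after 7
epochs without a *relative* improvement of at least 1e-4, floor 1e-7.
The relative-improvement convention is stated explicitly because library
defaults differ. No early stopping; epoch count is fixed by config.
Gradient clipping is off by default and available as a config flag.

The network runs on a package-internal reverse-mode autodiff engine over
NumPy arrays (`omicvae.autodiff`). Every operation's vector-Jacobian
product is tested against central finite differences, and training is
bit-reproducible given the config seed.

## Preprocessing

Fixed order per view:

1. CRISPR views: per-sample affine scaling mapping the sample's median
   over an essential reference gene set to -1 and over a non-essential
   set to 0 (reference sets are inputs, not hard-coded); then removal of
   never-essential genes — kept only if the score reaches -0.5 or lower
   in at least one sample (observed entries only).
2. Missing-rate filter: drop features unobserved in strictly more than
   85% of samples.
3. Per-feature z-scoring over observed entries (ordinal views — the copy
   number analogue — pass through untouched). Zero-variance features are
   zeroed with a warning.
4. Encoder feature selection: a two-component Gaussian mixture is fitted
   to the per-feature SDs (sklearn EM, 10 seeded restarts) and the
   threshold is the *largest* point where the two weighted component
   densities are equal; features strictly above it become encoder input.
   The crossing is solved in closed form (the log-density difference is
   quadratic in x) with a point-of-closest-approach fallback when one
   density dominates everywhere. Degenerate fits (vanishing weight or
   variance) raise an error recommending a fixed quantile threshold.

The SDs feeding step 4 are computed on the pre-z-score scale: after
z-scoring every feature has SD 1 and a mixture over SDs would be
meaningless. All filter statistics use observed entries only, so the
zero fill applied at load time never contaminates them.

Continuous conditionals are standardized over their finite entries and
missing entries are then set to 0 (mean imputation on the standardized
scale) — the model requires a complete conditional matrix, and the mean
is the least-informative fill.

## Augmentation products

- `impute()` returns, per view, `observed ? measured : decoded` — a
  projection (applying it twice changes nothing) that never alters a
  measured cell.
- `synthesize_view(name)` returns decoder output over the view's full
  feature set for exactly the samples with no observed cell in that
  view; their reconstruction is driven by the other views and the
  conditionals.
- every augmented matrix carries a per-cell provenance tag
  (`measured | imputed | synthesized`).

Downstream statistics: a Gaussian linear-model likelihood-ratio scan of
gene dependencies on binary genomic features (one-sided toward increased
dependency in carriers, BH-corrected across all tested pairs — the
simplest model consistent with a log-ratio test, since the upstream
formulation is not fully specified), and the adjusted Fisher-Pearson
skewness `g1 sqrt(n(n-1))/(n-2)` per gene as a selectivity measure.

## Attribution

Expected gradients: `attr(o,s,i)` is the Monte-Carlo average over
`(baseline, alpha)` draws of `(x_si - x'_i) * d f_o/d x_i` at
`x' + alpha (x_s - x')`, with baselines drawn from a seeded background
subset of the training samples (default size 100) and
`alpha ~ U(0,1)`. Exact for linear maps at any draw count; completeness
(`sum_i attr ≈ f(x) - mean_bg f`) is tested at 200 draws on a trained
model. Optional Gaussian smoothing of the interpolation points is
available but off by default — no principled noise scale presents
itself, so it is exposed rather than imposed. Conditional inputs are
attributed alongside omic features.

Aggregations: latent importance = `mean_s sum_o |attr|` (one ranked
number per input feature); output importance = `mean_s attr` (an
outputs x features matrix supporting row- or column-wise ranking).

## Protein co-abundance evaluation

Pearson r with a two-sided t-test per protein pair, and a whitened OLS:
the sample x sample covariance `S` of the column-standardized matrix is
shrunk as `(1-gamma) S + gamma mean(diag S) I` (default `gamma = 0.1`),
`W = L^{-1}` from `S = L L'` decorrelates the samples, and each pair is
scored by the OLS slope of one whitened profile on the other
(lexicographically first protein as predictor; t-test with n-2 df, with
no correction for the estimated whitening — a documented limitation).
Shrinkage is not optional in practice: column centering makes `S`
singular by construction, and toy settings can have more samples than
proteins. "Covariance" here is sample-side — the transform exists to
decorrelate samples, not features.

Recall curves sort pairs by ascending p (ties: |statistic| descending,
then lexicographic); each reference pair contributes 1/k, so the curve
ends at exactly 1; AUC is the mean of the curve over ranks.

## Synthetic data

The generator draws tissue labels, a K-dimensional latent factor per
sample around tissue-specific means, binary conditionals with planted
additive effects, and per-view signal features as `Z L + C B + noise`;
non-signal features are low-SD noise, giving the bimodal SD structure
the mixture filter expects. One view can be discretized to ordinal
copy-number-like levels; one can carry essential / non-essential /
never-essential gene blocks on the essentiality scale. MCAR cell masking
and whole-view sample absence are applied last; `GroundTruth` retains
latents, loadings, pre-masking values and complex memberships, so every
evaluation can be scored without re-reading inputs. An optional tanh
squashing on the first view stresses the nonlinear pathway.

Default study conditions: 400 samples, 3 views (60/50/40 features), 8
latent factors, signal-to-noise ratio ~3 in SD terms (noise sd 0.33
against unit-variance signal), 20% MCAR masking, last view absent for
25% of samples. The desk-scale model configuration used in the recovery
benchmarks is 16 joint latent dimensions, batch 128, lr 1e-3, 100
epochs — small enough to train in seconds while leaving headroom above
the mean-imputation and column-mean baselines.

The confounded-proteome scenario used for the PPI evaluation plants 5
complexes of 4 proteins (within-complex shared factor, strength 1.0) in
a 100 x 60 matrix and adds a block confounder: samples fall into 4
blocks whose latent factor loads on every protein with random weights of
scale 4.0. This is the regime whitening exists for — confounding strong
enough to reorder naive correlation rankings. A uniform per-sample shift
would inflate all pairs equally and leave Pearson's ranking intact,
which is why the confounder loads per protein.

### What the generator does not emulate

Real screens have structured (not MCAR) missingness, batch effects
entangled with tissue, count-like or heavy-tailed measurement
distributions, and nonlinear dose-response relations. Passing the
synthetic benchmarks therefore demonstrates that the machinery is
correct and that cross-view information is exploited — not that the
model's headline performance transfers to any particular real panel.

## Numerical choices and limitations

- All statistics over observed entries; ties at filter boundaries follow
  the stated strict/non-strict conventions (missing rate: strictly
  greater than the cutoff is dropped; never-essential: a gene reaching
  exactly -0.5 is kept).
- Sample ordering after assembly is lexicographic, so results are
  independent of input file order.
- Zero-norm embeddings in the contrastive loss have their cosines
  treated as 0 (with a warning) rather than raising.
- The KL/contrastive weights act on different scales than the summed
  reconstruction term; the defaults reflect the tuned full-scale values
  and are not rebalanced at desk scale.
- Checkpoints are single `.npz` files carrying a format version, the
  config, the per-view encoder feature lists and all parameters.
- The one-hidden-layer-per-branch depth is a deliberate floor: deeper
  "multiple fully connected layers" are compatible with the design but
  unnecessary at the scales this package targets, and the depth is not
  currently a config knob.
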