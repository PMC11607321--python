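# omicvae

Conditional multi-view variational autoencoder for integrating, imputing
and synthesizing cancer cell-line multi-omics.

## The problem

Large cell-line panels are profiled across many omic layers — copy
number, methylation, transcriptome, proteome, metabolome, drug response,
CRISPR-Cas9 gene essentiality — but few lines have every screen, and the
screens that do exist are sparse. That missingness limits the statistical
power of any analysis that crosses layers (biomarker discovery, genetic
association with gene dependencies, protein co-abundance mapping).

`omicvae` addresses this with a conditional multi-view VAE. Each view
`x_d` is encoded through its own branch (restricted to highly variable
"encoder features", with a vector of conditionals `c` — driver mutations,
tissue of origin, fusions, MSI status, growth rate — appended), the
per-view latents are concatenated and mapped to the mean and log-variance
of a joint Gaussian code `z ~ N(mu, diag(sigma^2))`, and per-view decoders
reconstruct the **full** feature set of every view from `[z, c]`
(the asymmetric design). Training minimizes

```
L = sum_d MSE_d(observed cells only)
    + lambda * KL( N(mu, sigma^2) || N(0, I) )
    + alpha  * L_contrastive(z, tissue labels)
```

with `L_contrastive = [m_pos - s_p]_+ + [s_n - m_neg]_+` on cosine
similarities of within-batch pairs (positive = same tissue), plus
**whole-view dropout**: during training an entire view's input block is
zeroed per sample with some probability, so the network learns cross-view
structure and behaves sensibly when a screen is genuinely missing.

A fitted model supports:

- **partial augmentation** — fill the unobserved cells of a screen a
  sample does have (measured values are never touched);
- **full augmentation** — synthesize an entire omic layer for samples
  lacking that screen;
- **explanation** — expected-gradients Shapley attribution of the latent
  space and of any view's reconstruction;
- **evaluation** — k-fold reconstruction quality, genetic-association
  scans with BH correction, Fisher skewness of essentiality profiles, and
  protein co-abundance recovery of known complexes (Pearson vs
  Cholesky-whitened OLS, ranked recall curves and AUC).

Everything runs on synthetic data with known ground truth
(`omicvae.synthetic`); no downloads are required.

## Worked example

```python
import numpy as np
import omicvae as ov

spec = ov.SyntheticSpec(n_samples=400, view_features=(60, 50, 40),
                        latent_dim=8, mcar_rate=0.2,
                        view_absence_rate=0.25, absent_view=2, seed=7)
dataset, truth = ov.generate(spec)

cfg = ov.ModelConfig(joint_latent_dim=16, batch_size=128,
                     view_latent_cap=64, learning_rate=1e-3, seed=3)
results = ov.MultiOmicVAE(dataset, cfg).fit(epochs=100)
print(results.summary())
```

```
Conditional multi-view VAE results
============================================
samples: 400    views: 3    conditionals: 5
joint latent dim: 16    parameters: 18,220
epochs run: 100
final loss: total 3.29534  (rec 3.28755, kl 60.4336, con 0.3478)
--------------------------------------------
view                  features   encoder missing %
view0                       60        60      20.3
view1                       50        50      19.7
view2                       40        40      40.9
```

`view2` is missing entirely for a quarter of the samples (hence its
higher overall missing rate). Imputing the MCAR-masked cells and
synthesizing the absent screens:

```python
aug = results.impute()                       # per-view completed matrices
syn = results.synthesize_view("view2")       # only samples lacking view2
```

On this run the imputed cells of `view0` reach RMSE 0.92 against the
generator's noiseless truth versus 1.34 for per-feature-mean imputation,
and the synthesized `view2` profiles correlate with the truth at mean
per-sample Pearson r = 0.71 versus 0.32 for the column-mean baseline —
the model is pulling real cross-view signal, not just reproducing
marginals.

A command-line interface mirrors the same stages
(`omicvae simulate / preprocess / train / augment / explain / ppi`); see
`omicvae --help`.

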