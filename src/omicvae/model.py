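"""Conditional multi-view VAE: architecture, losses and the Model/Results API.

The model encodes each omic view (restricted to its highly variable
encoder features, with the conditionals appended) through a per-view
branch, concatenates the per-view latents, and maps them to the mean and
log-variance of a joint Gaussian latent code.  The decoder receives the
sampled code concatenated with the conditionals and reconstructs the FULL
feature set of every view (the asymmetric design).  Training minimizes

    L = sum_d MSE_d(observed cells)  +  lambda * KL(q(z|x) || N(0, I))
        +  alpha * L_contrastive(z, tissue labels)

with whole-view dropout regularization: during training each (sample,
view) input block is zeroed with probability ``view_dropout_p`` so the
network learns cross-view structure and behaves sensibly when an entire
screen is missing at inference time.

Usage follows the model/results convention::

    model = MultiOmicVAE(dataset, config)
    res = model.fit()
    res.summary()
    completed = res.impute()
"""

from __future__ import annotations

import dataclasses
import json
import time

import numpy as np
import yaml

from . import nn
from .autodiff import Tensor, concat, matmul, maximum0
from .io import MultiOmicDataset, OmicMatrix

__all__ = [
    "ModelConfig",
    "LatentState",
    "MultiOmicVAE",
    "VAEResults",
    "view_dropout",
    "reparameterize",
    "loss_reconstruction",
    "loss_kl",
    "loss_contrastive",
    "loss_total",
]


@dataclasses.dataclass
class ModelConfig:
    """Hyperparameters of the conditional multi-view VAE.

    Defaults are the tuned values for the full cell-line corpus; the view
    dropout probability is also reported as 0.5 for the final model and
    can be raised accordingly.
    """

    epochs: int = 500
    batch_size: int = 256
    learning_rate: float = 3e-4
    cv_folds: int = 3
    max_missing: float = 0.85
    view_latent_frac: float = 0.25
    joint_latent_dim: int = 200
    hidden_frac: float = 0.7
    dropout_p: float = 0.4
    view_dropout_p: float = 0.3
    kl_weight: float = 1e-4
    contrastive_weight: float = 5e-3
    m_pos: float = 0.85
    m_neg: float = 0.15
    weight_decay: float = 5e-4
    scheduler_threshold: float = 1e-4
    scheduler_factor: float = 0.6
    scheduler_patience: int = 7
    scheduler_min_lr: float = 1e-7
    view_latent_cap: int = 512
    contrastive_on_mu: bool = False
    grad_clip: float | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.m_neg < self.m_pos <= 1.0:
            raise ValueError("need 0 <= m_neg < m_pos <= 1")
        for name in ("max_missing", "view_latent_frac", "hidden_frac",
                     "dropout_p", "view_dropout_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.kl_weight, self.contrastive_weight, self.weight_decay) < 0:
            raise ValueError("loss weights must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)


@dataclasses.dataclass
class LatentState:
    """Joint latent code: posterior mean, log-variance and sampled embedding."""

    mu: np.ndarray
    logvar: np.ndarray
    z: np.ndarray


# ---------------------------------------------------------------------------
# stochastic pieces


def view_dropout(
    view_inputs: list[np.ndarray], rate: float, rng: np.random.Generator
) -> tuple[list[np.ndarray], np.ndarray]:
    """Zero whole per-sample view blocks with probability ``rate``.

    A dropped view looks exactly like a missing screen (all-zero input, no
    activation rescaling).  If every view of a sample would be dropped the
    draw is repeated for that sample so at least one view survives.
    Conditionals are never passed through here.

    Returns the masked inputs and the (samples x views) dropped indicator.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"view dropout rate must be in [0, 1), got {rate}")
    n = view_inputs[0].shape[0]
    n_views = len(view_inputs)
    if rate == 0.0:
        return [x.copy() for x in view_inputs], np.zeros((n, n_views), dtype=bool)
    dropped = rng.random((n, n_views)) < rate
    all_dropped = dropped.all(axis=1)
    while all_dropped.any():
        redraw = rng.random((int(all_dropped.sum()), n_views)) < rate
        dropped[all_dropped] = redraw
        all_dropped = dropped.all(axis=1)
    out = []
    for j, x in enumerate(view_inputs):
        x = x.copy()
        x[dropped[:, j]] = 0.0
        out.append(x)
    return out, dropped


def reparameterize(
    mu: np.ndarray, logvar: np.ndarray, rng: np.random.Generator | None
) -> np.ndarray:
    """z = mu + exp(logvar / 2) * eps with eps ~ N(0, I); mu if rng is None."""
    mu = np.asarray(mu, dtype=np.float64)
    if rng is None:
        return mu.copy()
    logvar = np.asarray(logvar, dtype=np.float64)
    if mu.shape != logvar.shape:
        raise ValueError("mu and logvar shapes differ")
    return mu + np.exp(0.5 * logvar) * rng.standard_normal(mu.shape)


# ---------------------------------------------------------------------------
# loss terms (autodiff-aware; NumPy in, float out convenience wrappers below)


def _masked_mse_terms(
    recons: list[Tensor], targets: list[np.ndarray], masks: list[np.ndarray]
) -> tuple[Tensor, dict[int, float]]:
    """Sum over views of the MSE over observed entries only."""
    total = Tensor(0.0)
    breakdown: dict[int, float] = {}
    for i, (rec, tgt, mask) in enumerate(zip(recons, targets, masks)):
        m = np.asarray(mask, dtype=bool)
        n_obs = int(m.sum())
        if n_obs == 0:
            import warnings

            warnings.warn(f"view {i}: no observed entries; contributes 0 to loss",
                          stacklevel=2)
            breakdown[i] = 0.0
            continue
        diff = rec - Tensor(np.where(m, tgt, 0.0))
        sq = (diff * Tensor(m.astype(np.float64))) ** 2.0
        mse = sq.sum() * (1.0 / n_obs)
        breakdown[i] = float(mse.data)
        total = total + mse
    return total, breakdown


def loss_reconstruction(recons, targets, masks):
    """Masked reconstruction loss: per-view MSE over observed cells, summed.

    Accepts NumPy arrays or Tensors; returns ``(total, per_view)`` floats
    when called with arrays.
    """
    rec_t = [r if isinstance(r, Tensor) else Tensor(r) for r in recons]
    total, breakdown = _masked_mse_terms(rec_t, targets, masks)
    return float(total.data), breakdown


def _kl_term(mu: Tensor, logvar: Tensor) -> Tensor:
    # mean over samples of 0.5 * sum_j (mu^2 + sigma^2 - logvar - 1)
    sigma2 = logvar.exp()
    per_sample = (mu**2.0 + sigma2 - logvar - 1.0).sum(axis=1) * 0.5
    return per_sample.mean()

def loss_kl(mu, logvar) -> float:
    """KL(q(z|x) || N(0, I)) averaged over samples."""
    mu = Tensor.as_tensor(mu)
    logvar = Tensor.as_tensor(logvar)
    if mu.shape != logvar.shape:
        raise ValueError("mu and logvar shapes differ")
    return float(_kl_term(mu, logvar).data)


def _contrastive_term(
    z: Tensor, tissue_labels: np.ndarray, m_pos: float, m_neg: float
) -> Tensor:
    """Margin hinge on cosine similarity over within-batch pairs.

    Positive pairs (same tissue) contribute [m_pos - cos]_+, negative
    pairs [cos - m_neg]_+; the two pair classes are averaged separately
    and summed, so neither class dominates by count.
    """
    n = z.shape[0]
    labels = np.asarray(tissue_labels)
    norms_sq = (z**2.0).sum(axis=1, keepdims=True)
    zero = norms_sq.data.ravel() <= 1e-24
    if zero.any():
        import warnings

        warnings.warn("zero-norm embedding(s); their cosines treated as 0",
                      stacklevel=2)
    # safe inverse norms: zero rows get factor 0 so cos == 0 for their pairs
    inv = np.where(zero, 0.0, 1.0 / np.sqrt(np.maximum(norms_sq.data.ravel(), 1e-24)))
    zn = z * Tensor(inv[:, None])
    cos = matmul(zn, zn.T)  # n x n cosine similarities
    iu, ju = np.triu_indices(n, k=1)
    pos_sel = labels[iu] == labels[ju]
    total = Tensor(0.0)
    if pos_sel.any():
        pos_cos = cos[iu[pos_sel], ju[pos_sel]]
        total = total + maximum0(Tensor(float(m_pos)) - pos_cos).mean()
    if (~pos_sel).any():
        neg_cos = cos[iu[~pos_sel], ju[~pos_sel]]
        total = total + maximum0(neg_cos - Tensor(float(m_neg))).mean()
    return total


def loss_contrastive(embeddings, tissue_labels, m_pos: float = 0.85,
                     m_neg: float = 0.15) -> float:
    """Tissue-label contrastive loss on an embedding matrix (samples x dim)."""
    z = Tensor.as_tensor(embeddings)
    if z.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    return float(_contrastive_term(z, tissue_labels, m_pos, m_neg).data)


def loss_total(rec: float, kl: float, con: float, kl_weight: float = 1e-4,
               contrastive_weight: float = 5e-3) -> float:
    """Weighted sum of the three loss terms."""
    return rec + kl_weight * kl + contrastive_weight * con


# ---------------------------------------------------------------------------
# network


class _ViewEncoder(nn.Module):
    def __init__(self, n_in: int, cfg: ModelConfig, rng: np.random.Generator):
        hidden = max(1, round(cfg.hidden_frac * n_in))
        vlat = max(1, min(round(cfg.view_latent_frac * n_in), cfg.view_latent_cap))
        self.body = nn.Sequential(
            nn.Linear(n_in, hidden, rng),
            nn.PReLU(),
            nn.Dropout(cfg.dropout_p, rng),
            nn.Linear(hidden, vlat, rng),
            nn.PReLU(),
        )
        self.out_dim = vlat

    def forward(self, x: Tensor) -> Tensor:
        return self.body(x)


class _ViewDecoder(nn.Module):
    def __init__(self, n_latent_in: int, n_out: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        # mirror of the encoder, sized from the full output feature count
        vlat = max(1, min(round(cfg.view_latent_frac * n_out), cfg.view_latent_cap))
        hidden = max(1, round(cfg.hidden_frac * n_out))
        self.body = nn.Sequential(
            nn.Linear(n_latent_in, vlat, rng),
            nn.PReLU(),
            nn.Dropout(cfg.dropout_p, rng),
            nn.Linear(vlat, hidden, rng),
            nn.PReLU(),
            nn.Linear(hidden, n_out, rng),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.body(x)


class _Network(nn.Module):
    """The full conditional multi-view VAE graph."""

    def __init__(self, enc_sizes: list[int], dec_sizes: list[int], n_cond: int,
                 cfg: ModelConfig, seed: int):
        rng = np.random.default_rng(seed)
        self.encoders = [_ViewEncoder(s + n_cond, cfg, rng) for s in enc_sizes]
        concat_dim = sum(e.out_dim for e in self.encoders)
        joint_hidden = max(cfg.joint_latent_dim, round(cfg.hidden_frac * concat_dim))
        self.joint = nn.Sequential(
            nn.Linear(concat_dim, joint_hidden, rng), nn.PReLU()
        )
        self.mu_head = nn.Linear(joint_hidden, cfg.joint_latent_dim, rng)
        self.logvar_head = nn.Linear(joint_hidden, cfg.joint_latent_dim, rng)
        self.decoders = [
            _ViewDecoder(cfg.joint_latent_dim + n_cond, s, cfg, rng)
            for s in dec_sizes
        ]
        self.n_cond = n_cond

    def encode(self, view_inputs: list[Tensor], cond: Tensor) -> tuple[Tensor, Tensor]:
        branches = []
        for enc, x in zip(self.encoders, view_inputs):
            branches.append(enc(concat([x, cond], axis=1)))
        h = self.joint(concat(branches, axis=1))
        return self.mu_head(h), self.logvar_head(h)

    def decode(self, z: Tensor, cond: Tensor) -> list[Tensor]:
        zc = concat([z, cond], axis=1)
        return [dec(zc) for dec in self.decoders]


# ---------------------------------------------------------------------------
# Model / Results


class MultiOmicVAE:
    """Conditional multi-view VAE over an assembled multi-omic dataset.

    Parameters
    ----------
    dataset : MultiOmicDataset
        Preprocessed (zero-filled, standardized) aligned views with a
        complete conditional matrix.
    config : ModelConfig, optional
    """

    def __init__(self, dataset: MultiOmicDataset, config: ModelConfig | None = None):
        self.dataset = dataset
        self.config = config or ModelConfig()
        enc_sizes = [
            len(dataset.encoder_features[name]) + 0 for name in dataset.view_names
        ]
        if min(enc_sizes) < 1:
            raise ValueError("every view needs at least one encoder feature")
        dec_sizes = [v.n_features for v in dataset.views]
        self.network = _Network(
            enc_sizes, dec_sizes, dataset.conditionals.n_conditionals,
            self.config, self.config.seed,
        )
        self._enc_values = [
            dataset.encoder_matrix(name)[0] for name in dataset.view_names
        ]
        self._cond = dataset.conditionals.values

    # -- forward passes ------------------------------------------------------

    def encode(
        self, view_values: list[np.ndarray] | None = None,
        cond: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
    ) -> LatentState:
        """Posterior latent state; deterministic (z = mu) unless rng given."""
        xs = view_values if view_values is not None else self._enc_values
        c = cond if cond is not None else self._cond
        self.network.eval()
        mu_t, logvar_t = self.network.encode(
            [Tensor(x) for x in xs], Tensor(c)
        )
        mu, logvar = mu_t.data, logvar_t.data
        return LatentState(mu, logvar, reparameterize(mu, logvar, rng))

    def decode(self, z: np.ndarray, cond: np.ndarray | None = None) -> list[np.ndarray]:
        """Reconstruct every view's full feature set from a latent code."""
        c = cond if cond is not None else self._cond
        if z.shape[0] != c.shape[0]:
            raise ValueError("z and conditionals disagree on sample count")
        self.network.eval()
        return [r.data for r in self.network.decode(Tensor(z), Tensor(c))]

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.network.parameters()))

    # -- training ------------------------------------------------------------

    def fit(
        self, epochs: int | None = None, verbose: bool = False,
    ) -> "VAEResults":
        """Train with Adam + plateau scheduler and return a results object."""
        cfg = self.config
        epochs = cfg.epochs if epochs is None else int(epochs)
        rng = np.random.default_rng(cfg.seed + 1)
        params = self.network.parameters()
        opt = nn.Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
        sched = nn.PlateauScheduler(
            opt, factor=cfg.scheduler_factor, patience=cfg.scheduler_patience,
            threshold=cfg.scheduler_threshold, min_lr=cfg.scheduler_min_lr,
        )
        ds = self.dataset
        n = ds.n_samples
        targets = [v.values for v in ds.views]
        masks = [v.mask for v in ds.views]
        tissues = ds.tissues
        history = {"total": [], "reconstruction": [], "kl": [], "contrastive": [],
                   "lr": [], "seconds": []}

        for epoch in range(epochs):
            t0 = time.perf_counter()
            self.network.train()
            order = rng.permutation(n)
            ep = {"total": 0.0, "reconstruction": 0.0, "kl": 0.0, "contrastive": 0.0}
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                if len(idx) < 2:
                    continue
                xs = [x[idx] for x in self._enc_values]
                xs, _ = view_dropout(xs, cfg.view_dropout_p, rng)
                cond_t = Tensor(self._cond[idx])
                mu_t, logvar_t = self.network.encode(
                    [Tensor(x) for x in xs], cond_t
                )
                eps = rng.standard_normal(mu_t.shape)
                z_t = mu_t + (logvar_t * 0.5).exp() * Tensor(eps)
                recons = self.network.decode(z_t, cond_t)
                rec_t, _ = _masked_mse_terms(
                    recons, [t[idx] for t in targets], [m[idx] for m in masks]
                )
                kl_t = _kl_term(mu_t, logvar_t)
                if tissues is not None and cfg.contrastive_weight > 0:
                    emb = mu_t if cfg.contrastive_on_mu else z_t
                    con_t = _contrastive_term(emb, tissues[idx], cfg.m_pos, cfg.m_neg)
                else:
                    con_t = Tensor(0.0)
                total_t = rec_t + cfg.kl_weight * kl_t + cfg.contrastive_weight * con_t
                if not np.isfinite(total_t.data):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: rec={rec_t.data!r} "
                        f"kl={kl_t.data!r} con={con_t.data!r}"
                    )
                opt.zero_grad()
                total_t.backward()
                if cfg.grad_clip is not None:
                    norm = np.sqrt(sum(
                        float((p.grad**2).sum()) for p in params if p.grad is not None
                    ))
                    if norm > cfg.grad_clip:
                        scale = cfg.grad_clip / norm
                        for p in params:
                            if p.grad is not None:
                                p.grad = p.grad * scale
                opt.step()
                ep["total"] += float(total_t.data)
                ep["reconstruction"] += float(rec_t.data)
                ep["kl"] += float(kl_t.data)
                ep["contrastive"] += float(con_t.data)
                n_batches += 1
            for key in ("total", "reconstruction", "kl", "contrastive"):
                history[key].append(ep[key] / max(n_batches, 1))
            history["lr"].append(opt.lr)
            history["seconds"].append(time.perf_counter() - t0)
            sched.step(history["total"][-1])
            if verbose and (epoch % 10 == 0 or epoch == epochs - 1):
                print(f"epoch {epoch:4d}  total {history['total'][-1]:.5f}  "
                      f"lr {opt.lr:.2e}")
        self.network.eval()
        return VAEResults(self, history)

    # -- persistence -----------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint config, schema and parameters to one ``.npz`` file."""
        arrays = {
            f"param_{i}": p.data for i, p in enumerate(self.network.parameters())
        }
        meta = {
            "format_version": 1,
            "config": dataclasses.asdict(self.config),
            "view_names": self.dataset.view_names,
            "encoder_features": {
                k: list(map(str, v)) for k, v in self.dataset.encoder_features.items()
            },
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def from_checkpoint(cls, path, dataset: MultiOmicDataset) -> "MultiOmicVAE":
        """Rebuild a model from a checkpoint against a compatible dataset.

        The checkpoint's config and per-view encoder feature lists take
        precedence over whatever the dataset carries, so the restored
        network matches the saved parameter shapes.
        """
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
        config = ModelConfig(**meta["config"])
        enc = {
            k: np.asarray(v, dtype=object)
            for k, v in meta["encoder_features"].items()
        }
        dataset = MultiOmicDataset(
            dataset.views, dataset.conditionals, enc,
            dataset.view_observed, dataset.tissues,
        )
        model = cls(dataset, config)
        model.load_parameters(path)
        return model

    def load_parameters(self, path) -> dict:
        """Restore parameters from a checkpoint into this model (shapes must match)."""
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = self.network.parameters()
            for i, p in enumerate(params):
                arr = data[f"param_{i}"]
                if arr.shape != p.data.shape:
                    raise ValueError(f"checkpoint parameter {i} shape mismatch")
                p.data = arr.copy()
        return meta


class VAEResults:
    """Fitted-model results: history, latent state, augmentation, summary."""

    def __init__(self, model: MultiOmicVAE, history: dict):
        self.model = model
        self.history = history

    @property
    def dataset(self) -> MultiOmicDataset:
        return self.model.dataset

    def latent(self, rng: np.random.Generator | None = None) -> LatentState:
        return self.model.encode(rng=rng)

    def reconstruct(self) -> list[np.ndarray]:
        """Deterministic reconstruction (z = mu) of every view, full features."""
        state = self.model.encode()
        return self.model.decode(state.mu)

    def impute(self) -> dict[str, OmicMatrix]:
        from .augment import impute_partial

        return impute_partial(self)

    def synthesize_view(self, view_name: str):
        from .augment import synthesize_view

        return synthesize_view(self, view_name)

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)

    def final_loss(self) -> float:
        return self.history["total"][-1] if self.history["total"] else np.nan

    def summary(self) -> str:
        ds = self.dataset
        lines = [
            "Conditional multi-view VAE results",
            "=" * 44,
            f"samples: {ds.n_samples}    views: {len(ds.views)}    "
            f"conditionals: {ds.conditionals.n_conditionals}",
            f"joint latent dim: {self.model.config.joint_latent_dim}    "
            f"parameters: {self.model.parameter_count():,}",
            f"epochs run: {len(self.history['total'])}",
        ]
        if self.history["total"]:
            lines.append(
                f"final loss: total {self.history['total'][-1]:.5f}  "
                f"(rec {self.history['reconstruction'][-1]:.5f}, "
                f"kl {self.history['kl'][-1]:.4f}, "
                f"con {self.history['contrastive'][-1]:.4f})"
            )
        lines.append("-" * 44)
        lines.append(f"{'view':<20}{'features':>10}{'encoder':>10}{'missing %':>10}")
        for v in ds.views:
            lines.append(
                f"{v.name:<20}{v.n_features:>10}"
                f"{len(ds.encoder_features[v.name]):>10}"
                f"{100 * v.missing_fraction():>10.1f}"
            )
        return "\n".join(lines)
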