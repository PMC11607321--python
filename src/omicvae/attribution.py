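"""Gradient-based Shapley attribution (expected gradients).

Approximates Shapley values for a differentiable map by integrating
gradients along straight paths from background (baseline) samples to the
explained input:

    attr(o, s, i) = E_{x' ~ background, a ~ U(0,1)}
                    [ (x_si - x'_i) * d fn_o / d x_i |_{x' + a (x_s - x')} ]

Monte-Carlo averaged over ``n_draws`` (baseline, a) pairs per sample.  For
linear maps the integrand is constant, so any number of draws is exact.

Two aggregation schemes mirror the two explanation targets:

* latent importance — absolute values summed over latent output
  dimensions, then averaged over samples (one number per input feature);
* output importance — signed values averaged over samples only, leaving
  an (outputs x features) matrix for per-output feature ranking.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .autodiff import Tensor

__all__ = [
    "AttributionTensor",
    "expected_gradients",
    "aggregate_latent_importance",
    "aggregate_output_importance",
    "subsample_for_attribution",
    "model_latent_fn",
    "model_view_fn",
]


@dataclasses.dataclass
class AttributionTensor:
    """(outputs x samples x features) Shapley-gradient values + metadata."""

    values: np.ndarray
    output_ids: np.ndarray
    sample_ids: np.ndarray
    feature_ids: np.ndarray
    feature_view: np.ndarray  # per-feature view tag, incl. "conditional"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (len(self.output_ids), len(self.sample_ids), len(self.feature_ids))
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attribution values must be finite")


def expected_gradients(
    fn,
    inputs: np.ndarray,
    background: np.ndarray,
    n_draws: int = 200,
    rng: np.random.Generator | int | None = None,
    smoothing_sd: float = 0.0,
) -> np.ndarray:
    """Monte-Carlo expected-gradients attribution.

    Parameters
    ----------
    fn : callable Tensor -> Tensor
        Differentiable map from (n x features) to (n x outputs), built
        from autodiff ops.
    inputs : ndarray, samples x features
    background : ndarray, baseline samples x features
    n_draws : int
        Path samples per explained sample.
    smoothing_sd : float
        Optional Gaussian noise SD added to interpolation points
        (the SmoothGrad component); 0 disables it.

    Returns
    -------
    ndarray of shape (outputs, samples, features).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(rng)
    X = np.asarray(inputs, dtype=np.float64)
    B = np.asarray(background, dtype=np.float64)
    if B.size == 0:
        raise ValueError("background must be non-empty")
    n, p = X.shape
    n_out = fn(Tensor(X[:1])).shape[1]
    acc = np.zeros((n_out, n, p))
    for _ in range(n_draws):
        base = B[rng.integers(0, B.shape[0], size=n)]
        alpha = rng.random((n, 1))
        point = base + alpha * (X - base)
        if smoothing_sd > 0:
            point = point + smoothing_sd * rng.standard_normal(point.shape)
        diff = X - base
        for o in range(n_out):
            x_t = Tensor(point, requires_grad=True)
            out = fn(x_t)
            out[:, o].sum().backward()
            acc[o] += diff * x_t.grad
            x_t.grad = None
    return acc / n_draws


def aggregate_latent_importance(attr: AttributionTensor) -> pd.DataFrame:
    """Global per-feature importance toward the latent space.

    |values| summed across output (latent) dimensions, then averaged over
    samples; returned ranked descending with view tags.
    """
    imp = np.abs(attr.values).sum(axis=0).mean(axis=0)
    df = pd.DataFrame(
        {"feature": attr.feature_ids, "view": attr.feature_view, "importance": imp}
    )
    return df.sort_values("importance", ascending=False, ignore_index=True)


def aggregate_output_importance(attr: AttributionTensor) -> pd.DataFrame:
    """Per-output feature importance: signed mean over samples.

    Rows are outputs (e.g. drugs), columns input features; rank a row
    descending to find the features driving one reconstruction, or a
    column to find the outputs most driven by one feature.
    """
    M = attr.values.mean(axis=1)
    return pd.DataFrame(M, index=attr.output_ids, columns=attr.feature_ids)


def subsample_for_attribution(
    sample_ids, fraction: float | None = None, count: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Seeded uniform subsample of sample ids (by fraction or count)."""
    ids = np.asarray(sample_ids)
    rng = np.random.default_rng(rng)
    if count is None:
        if fraction is None:
            raise ValueError("give fraction or count")
        count = int(round(fraction * len(ids)))
    if count > len(ids):
        raise ValueError("requested more samples than available")
    sel = rng.choice(len(ids), size=count, replace=False)
    return ids[np.sort(sel)]


# ---------------------------------------------------------------------------
# adapters exposing the fitted VAE as attribution targets


def _flatten_inputs(model) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Concatenate encoder inputs of all views + conditionals into one matrix."""
    ds = model.dataset
    blocks = [ds.encoder_matrix(name)[0] for name in ds.view_names]
    blocks.append(ds.conditionals.values)
    feature_ids = np.concatenate(
        [np.asarray(ds.encoder_features[name], dtype=object)
         for name in ds.view_names]
        + [ds.conditionals.names]
    )
    view_tags = np.concatenate(
        [np.full(len(ds.encoder_features[name]), name, dtype=object)
         for name in ds.view_names]
        + [np.full(ds.conditionals.n_conditionals, "conditional", dtype=object)]
    )
    sizes = [b.shape[1] for b in blocks]
    return np.concatenate(blocks, axis=1), feature_ids, view_tags, sizes


def _split_cols(x: Tensor, sizes: list[int]) -> list[Tensor]:
    out, off = [], 0
    for s in sizes:
        out.append(x[:, off:off + s])
        off += s
    return out


def model_latent_fn(model):
    """(flat inputs -> joint latent mu) as an attribution target.

    Returns ``(fn, inputs, feature_ids, view_tags)``.
    """
    flat, fids, tags, sizes = _flatten_inputs(model)
    net = model.network
    net.eval()

    def fn(x: Tensor) -> Tensor:
        parts = _split_cols(x, sizes)
        cond = parts[-1]
        mu, _ = net.encode(parts[:-1], cond)
        return mu

    return fn, flat, fids, tags


def model_view_fn(model, view_name: str):
    """(flat inputs -> reconstruction of one view) as an attribution target."""
    flat, fids, tags, sizes = _flatten_inputs(model)
    v_i = model.dataset.view_names.index(view_name)
    net = model.network
    net.eval()

    def fn(x: Tensor) -> Tensor:
        parts = _split_cols(x, sizes)
        cond = parts[-1]
        mu, _ = net.encode(parts[:-1], cond)
        return net.decode(mu, cond)[v_i]

    return fn, flat, fids, tags


def explain_latent(
    model, n_draws: int = 50, background_size: int = 100,
    sample_fraction: float | None = None, sample_count: int | None = None,
    seed: int = 0,
) -> AttributionTensor:
    """Expected-gradients attribution of the joint latent code.

    Background is a seeded subset of the model's own samples (up to
    ``background_size``); explained samples default to all.
    """
    rng = np.random.default_rng(seed)
    fn, flat, fids, tags = model_latent_fn(model)
    sample_ids = model.dataset.sample_ids
    if sample_fraction is not None or sample_count is not None:
        chosen = subsample_for_attribution(
            np.arange(len(sample_ids)), sample_fraction, sample_count, rng
        )
    else:
        chosen = np.arange(len(sample_ids))
    bg_idx = rng.choice(
        flat.shape[0], size=min(background_size, flat.shape[0]), replace=False
    )
    values = expected_gradients(fn, flat[chosen], flat[bg_idx], n_draws, rng)
    out_ids = np.array(
        [f"latent_{j}" for j in range(values.shape[0])], dtype=object
    )
    return AttributionTensor(values, out_ids, sample_ids[chosen], fids, tags)


def explain_view(
    model, view_name: str, n_draws: int = 50, background_size: int = 100,
    sample_fraction: float | None = None, sample_count: int | None = None,
    seed: int = 0,
) -> AttributionTensor:
    """Expected-gradients attribution of one view's reconstruction."""
    rng = np.random.default_rng(seed)
    fn, flat, fids, tags = model_view_fn(model, view_name)
    sample_ids = model.dataset.sample_ids
    if sample_fraction is not None or sample_count is not None:
        chosen = subsample_for_attribution(
            np.arange(len(sample_ids)), sample_fraction, sample_count, rng
        )
    else:
        chosen = np.arange(len(sample_ids))
    bg_idx = rng.choice(
        flat.shape[0], size=min(background_size, flat.shape[0]), replace=False
    )
    values = expected_gradients(fn, flat[chosen], flat[bg_idx], n_draws, rng)
    return AttributionTensor(
        values, model.dataset.view(view_name).feature_ids,
        sample_ids[chosen], fids, tags,
    )
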