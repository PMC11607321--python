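"""Per-view preprocessing: filters, scaling and standardization.

The pipeline applied before model training, in this fixed order:

1. CRISPR views only: per-sample affine scaling so the median score of a
   reference essential gene set is -1 and of a non-essential set is 0,
   then removal of "never essential" genes (minimum observed score above
   -0.5 in every sample).
2. Removal of features missing in more than 85% of samples.
3. Per-feature z-scoring over observed entries (ordinal views, i.e. copy
   number, are exempt).
4. Encoder feature selection: a two-component Gaussian mixture is fitted
   to the per-feature standard deviations; the SD threshold is the
   rightmost point where the two weighted component densities cross, and
   only features above it enter the encoder (decoders keep all features).

All statistics are computed over observed entries only — the zero fill
applied at load time never contaminates means, SDs or medians.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .io import MultiOmicDataset, OmicMatrix

__all__ = [
    "SDMixtureFit",
    "fit_sd_mixture_threshold",
    "filter_variable_features",
    "filter_missing_rate",
    "scale_crispr",
    "filter_never_essential",
    "zscore_standardize",
    "observed_feature_sds",
    "preprocess_dataset",
]


@dataclasses.dataclass
class SDMixtureFit:
    """Two-component Gaussian mixture over feature SDs and the crossing point.

    ``threshold`` is the largest x at which the two weighted component
    densities are equal, separating the low-variability component from the
    high-variability one.
    """

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    threshold: float

    def component_density(self, x, k: int):
        return self.weights[k] * norm.pdf(x, self.means[k], self.sds[k])


def _rightmost_crossing(means, sds, weights) -> float:
    """Largest x where w0*phi(x; m0, s0) == w1*phi(x; m1, s1).

    The log-density difference is a quadratic in x, so the crossings are
    roots of a quadratic; equal-variance components give a single linear
    crossing. Falls back to bisection on a bracketing grid if the
    closed-form roots are degenerate.
    """
    m0, m1 = means
    s0, s1 = sds
    w0, w1 = weights
    # log(w0) - 0.5*log(2pi) - log(s0) - (x-m0)^2/(2 s0^2) = same for 1
    a = 0.5 * (1.0 / s1**2 - 1.0 / s0**2)
    b = m0 / s0**2 - m1 / s1**2
    c = (
        np.log(w0 / s0)
        - np.log(w1 / s1)
        - m0**2 / (2 * s0**2)
        + m1**2 / (2 * s1**2)
    )
    if abs(a) < 1e-14:  # equal variances -> linear
        if abs(b) < 1e-14:
            raise ValueError("mixture components are indistinguishable")
        return -c / b
    disc = b**2 - 4 * a * c
    if disc < 0:
        # no analytic crossing (one density dominates everywhere); use the
        # point of closest approach
        return -b / (2 * a)
    roots = sorted([(-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a)])
    lo, hi = min(m0, m1), max(m0, m1)
    # prefer the largest crossing lying between the two component means;
    # otherwise take the largest crossing overall
    between = [r for r in roots if lo <= r <= hi]
    return max(between) if between else max(roots)


def fit_sd_mixture_threshold(feature_sds, seed: int = 0) -> SDMixtureFit:
    """Fit a k=2 Gaussian mixture to per-feature SDs and locate the crossing.

    Parameters
    ----------
    feature_sds : array of non-negative floats, length >= 10
    seed : int
        Makes the EM restarts deterministic.

    Raises
    ------
    ValueError
        On degenerate fits (vanishing weight or SD), advising a fixed
        quantile threshold instead.
    """
    x = np.asarray(feature_sds, dtype=np.float64).ravel()
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("need at least 10 finite SD values")
    if np.ptp(x) == 0:
        raise ValueError("feature SDs have zero spread")
    gm = GaussianMixture(
        n_components=2,
        n_init=10,
        init_params="random_from_data",
        random_state=int(seed) % (2**31),
        reg_covar=1e-10,
    ).fit(x[:, None])
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    if weights.min() < 1e-6 or sds.min() < 1e-9:
        raise ValueError(
            "degenerate mixture fit (vanishing weight or variance); "
            "use a fixed quantile threshold for this view instead"
        )
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    threshold = float(_rightmost_crossing(means, sds, weights))
    return SDMixtureFit(means, sds, weights, threshold)


def observed_feature_sds(view: OmicMatrix) -> np.ndarray:
    """Per-feature SD over observed entries (NaN if < 2 observations)."""
    vals = np.where(view.mask, view.values, np.nan)
    with np.errstate(invalid="ignore"):
        n = view.mask.sum(axis=0)
        sds = np.full(view.n_features, np.nan)
        ok = n >= 2
        sds[ok] = np.nanstd(vals[:, ok], axis=0, ddof=0)
    return sds


def filter_variable_features(view: OmicMatrix, fit: SDMixtureFit) -> np.ndarray:
    """Feature ids whose observed-entry SD strictly exceeds ``fit.threshold``.

    Used to populate the encoder feature subset; the decoder still
    reconstructs every feature.
    """
    sds = observed_feature_sds(view)
    keep = np.where(sds > fit.threshold)[0]
    if keep.size == 0:
        raise ValueError(
            f"view {view.name}: no feature exceeds SD threshold {fit.threshold:.4g}"
        )
    return view.feature_ids[keep]


def filter_missing_rate(view: OmicMatrix, max_missing: float = 0.85) -> OmicMatrix:
    """Drop features whose unobserved fraction is strictly above ``max_missing``."""
    missing = 1.0 - view.mask.mean(axis=0)
    keep = missing <= max_missing
    return OmicMatrix(
        view.name,
        view.values[:, keep],
        view.mask[:, keep],
        view.sample_ids,
        view.feature_ids[keep],
        view.modality,
    )


def scale_crispr(
    view: OmicMatrix, essential_ids, nonessential_ids
) -> OmicMatrix:
    """Per-sample affine scaling of CRISPR log2 fold-changes.

    Each sample is mapped by x -> (x - m_non) / (m_non - m_ess) * -1 ... i.e.
    the affine transform sending the sample's median over the essential
    reference set to -1 and over the non-essential set to 0.  Masks are
    unchanged.
    """
    ess = np.isin(view.feature_ids, np.asarray(list(essential_ids), dtype=object))
    non = np.isin(view.feature_ids, np.asarray(list(nonessential_ids), dtype=object))
    if not ess.any() or not non.any():
        raise ValueError("reference gene sets must be non-empty and present in the view")
    vals = np.where(view.mask, view.values, np.nan)
    out = view.values.copy()
    for i, sid in enumerate(view.sample_ids):
        if not view.mask[i].any():
            continue
        m_ess = np.nanmedian(vals[i, ess])
        m_non = np.nanmedian(vals[i, non])
        if not np.isfinite(m_ess) or not np.isfinite(m_non) or m_ess == m_non:
            raise ValueError(
                f"sample {sid!r}: essential and non-essential medians coincide"
            )
        # affine map: m_non -> 0, m_ess -> -1
        out[i] = (view.values[i] - m_non) / (m_non - m_ess)
    out = np.where(view.mask, out, 0.0)
    return OmicMatrix(
        view.name, out, view.mask, view.sample_ids, view.feature_ids, view.modality
    )


def filter_never_essential(view: OmicMatrix, cutoff: float = -0.5) -> OmicMatrix:
    """Drop genes never essential in any sample.

    A gene is kept if its fitness score falls below ``cutoff`` in at least
    one sample (observed entries only). Assumes the view is already on the
    essentiality scale produced by :func:`scale_crispr`, where -1 is the
    median essential-gene effect.
    """
    vals = np.where(view.mask, view.values, np.nan)
    with np.errstate(invalid="ignore", all="ignore"):
        min_score = np.nanmin(vals, axis=0)
    # kept iff depleted to at least the cutoff in >= 1 sample
    keep = np.isfinite(min_score) & (min_score <= cutoff)
    return OmicMatrix(
        view.name,
        view.values[:, keep],
        view.mask[:, keep],
        view.sample_ids,
        view.feature_ids[keep],
        view.modality,
    )


def zscore_standardize(view: OmicMatrix) -> OmicMatrix:
    """Per-feature z-score over observed entries; ordinal views pass through.

    Zero-variance features are set to all-zero with a warning (they carry
    no signal but keep the decoder's output shape intact).
    """
    if view.modality == "ordinal":
        return view.copy()
    vals = np.where(view.mask, view.values, np.nan)
    mean = np.nanmean(vals, axis=0)
    sd = np.nanstd(vals, axis=0, ddof=0)
    zero_var = ~(sd > 0)
    if zero_var.any():
        import warnings

        warnings.warn(
            f"view {view.name}: {int(zero_var.sum())} zero-variance feature(s) "
            "set to zero",
            stacklevel=2,
        )
    sd_safe = np.where(zero_var, 1.0, sd)
    out = (view.values - mean) / sd_safe
    out[:, zero_var] = 0.0
    out = np.where(view.mask, out, 0.0)
    return OmicMatrix(
        view.name, out, view.mask, view.sample_ids, view.feature_ids, view.modality
    )


def preprocess_dataset(
    dataset: MultiOmicDataset,
    crispr_view: str | None = None,
    essential_ids=None,
    nonessential_ids=None,
    sd_filter_views: tuple = (),
    max_missing: float = 0.85,
    seed: int = 0,
) -> MultiOmicDataset:
    """Run the full preprocessing pipeline over an assembled dataset.

    ``sd_filter_views`` names the views whose encoder inputs are restricted
    by the Gaussian-mixture SD threshold (transcriptomics/methylation
    analogues); other views keep all surviving features as encoder input.
    """
    views = []
    encoder_features: dict[str, np.ndarray] = {}
    for v in dataset.views:
        v = v.copy()
        if crispr_view is not None and v.name == crispr_view:
            v = scale_crispr(v, essential_ids, nonessential_ids)
            v = filter_never_essential(v)
        v = filter_missing_rate(v, max_missing)
        if v.name in sd_filter_views:
            fit = fit_sd_mixture_threshold(observed_feature_sds(v), seed=seed)
            encoder_features[v.name] = filter_variable_features(v, fit)
        v = zscore_standardize(v)
        views.append(v)
        if v.name not in encoder_features:
            encoder_features[v.name] = v.feature_ids.copy()
    return MultiOmicDataset(
        views,
        dataset.conditionals,
        encoder_features,
        tissues=dataset.tissues,
    )
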