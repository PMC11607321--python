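"""Dataset augmentation and downstream association statistics.

Two augmentation products:

* partial — fill the unobserved cells of a screen a sample does have,
  keeping every measured value untouched;
* full — synthesize an entire omic layer for samples that lack that
  screen, decoding from the joint latent code learned from their other
  views and conditionals.

Every augmented matrix carries a per-cell provenance tag
(measured | imputed | synthesized).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import OmicMatrix

__all__ = [
    "AugmentedView",
    "impute_partial",
    "synthesize_view",
    "fisher_skewness",
    "genetic_association_scan",
]

MEASURED, IMPUTED, SYNTHESIZED = "measured", "imputed", "synthesized"


@dataclasses.dataclass
class AugmentedView:
    """A completed matrix plus per-cell provenance."""

    name: str
    values: np.ndarray
    provenance: np.ndarray  # object array of MEASURED/IMPUTED/SYNTHESIZED
    sample_ids: np.ndarray
    feature_ids: np.ndarray

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        idx, cols = self.sample_ids, self.feature_ids
        return (
            pd.DataFrame(self.values, index=idx, columns=cols),
            pd.DataFrame(self.provenance, index=idx, columns=cols),
        )


def impute_partial(results) -> dict[str, AugmentedView]:
    """Complete every view: measured cells kept, unobserved cells decoded.

    Idempotent: the output has no missing entries, and re-imputing an
    already complete matrix returns it unchanged.
    """
    ds = results.dataset
    recons = results.reconstruct()
    out: dict[str, AugmentedView] = {}
    for view, recon in zip(ds.views, recons):
        values = np.where(view.mask, view.values, recon)
        prov = np.where(view.mask, MEASURED, IMPUTED).astype(object)
        # rows where the sample lacks the screen entirely are synthesized
        absent = ~view.mask.any(axis=1)
        prov[absent] = SYNTHESIZED
        out[view.name] = AugmentedView(
            view.name, values, prov, view.sample_ids, view.feature_ids
        )
    return out


def synthesize_view(results, view_name: str) -> AugmentedView:
    """Decode the full feature set of ``view_name`` for samples lacking it.

    Only samples with no observed cell in the target view are returned;
    their reconstruction is driven purely by the other views and the
    conditionals (any values stored under the target view's all-false mask
    rows never enter the encoder input for that view — they are zero by
    the fill convention).
    """
    ds = results.dataset
    view = ds.view(view_name)
    v_i = ds.view_names.index(view_name)
    absent = ~view.mask.any(axis=1)
    recon = results.reconstruct()[v_i]
    prov = np.full(view.values.shape, SYNTHESIZED, dtype=object)
    return AugmentedView(
        view_name,
        recon[absent],
        prov[absent],
        view.sample_ids[absent],
        view.feature_ids,
    )


def fisher_skewness(values) -> float:
    """Adjusted Fisher-Pearson skewness g1 * sqrt(n(n-1)) / (n-2).

    Used per gene on essentiality profiles: strongly negative skew marks a
    selectively essential gene (a few strongly depleted cell lines).
    """
    x = np.asarray(values, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size < 3 or x.std(ddof=0) == 0:
        return np.nan
    return float(stats.skew(x, bias=False))


def genetic_association_scan(
    dependency: pd.DataFrame, features: pd.DataFrame, min_positives: int = 3
) -> pd.DataFrame:
    """Scan gene dependencies against binary genomic features.

    For every (gene, feature) pair, a Gaussian linear model of the
    dependency profile on the binary feature is compared with the
    intercept-only model by a likelihood-ratio test.  The p-value is
    one-sided in the direction of increased dependency (more negative
    score) in carriers; Benjamini-Hochberg correction is applied over all
    tested pairs.

    Parameters
    ----------
    dependency : DataFrame, samples x genes
    features : DataFrame, samples x binary features (shared sample index)

    Returns
    -------
    DataFrame with columns gene, feature, lrt, beta, p, q.
    """
    common = dependency.index.intersection(features.index)
    if len(common) < 4:
        raise ValueError("need at least 4 shared samples")
    Y = dependency.loc[common]
    F = features.loc[common]
    n = len(common)
    rows = []
    for feat in F.columns:
        f = F[feat].to_numpy(dtype=np.float64)
        if not np.all(np.isin(f, (0.0, 1.0))):
            raise ValueError(f"feature {feat!r} is not binary")
        k = int(f.sum())
        if k < min_positives or n - k < 1:
            continue
        fc = f - f.mean()
        sxx = float(fc @ fc)
        for gene in Y.columns:
            y = Y[gene].to_numpy(dtype=np.float64)
            if y.std(ddof=0) == 0:
                continue  # constant profile carries no association signal
            yc = y - y.mean()
            beta = float(fc @ yc) / sxx
            rss1 = float(yc @ yc) - beta**2 * sxx
            rss0 = float(yc @ yc)
            if rss1 <= 0:
                rss1 = np.finfo(float).tiny
            lrt = n * np.log(rss0 / rss1)
            p_two = stats.chi2.sf(lrt, df=1)
            # one-sided: carriers more dependent means beta < 0
            p = p_two / 2.0 if beta < 0 else 1.0 - p_two / 2.0
            rows.append({"gene": gene, "feature": feat, "lrt": lrt,
                         "beta": beta, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    else:
        table["q"] = []
    return table
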