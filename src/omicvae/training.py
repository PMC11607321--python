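"""Data splitting and cross-validated reconstruction-quality evaluation.

The reconstruction-quality protocol: split samples into k folds; for each
fold, train the VAE on the remaining folds and reconstruct the held-out
samples; concatenate all held-out reconstructions and score each feature
by the Pearson correlation between reconstruction and truth over observed
entries.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedShuffleSplit, ShuffleSplit

from .io import MultiOmicDataset
from .model import ModelConfig, MultiOmicVAE

__all__ = ["split_stratified", "kfold_reconstruction_quality"]


def split_stratified(
    dataset_or_n,
    test_fraction: float = 0.2,
    stratify_flag: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified shuffle split into train/test index arrays.

    Stratification is by a per-sample boolean flag (in the cell-line
    setting: hematopoietic-and-lymphoid origin), keeping the flagged-class
    proportion in the test set within one sample of the global proportion.
    Falls back to a plain shuffle with a warning when a stratum has fewer
    than 2 members.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    n = (
        dataset_or_n.n_samples
        if isinstance(dataset_or_n, MultiOmicDataset)
        else int(dataset_or_n)
    )
    if stratify_flag is None:
        stratify_flag = np.zeros(n, dtype=bool)
    flag = np.asarray(stratify_flag).astype(int)
    counts = np.bincount(flag, minlength=2)
    present = counts[counts > 0]
    if len(np.unique(flag)) < 2 or present.min() < 2:
        if len(np.unique(flag)) >= 2:
            warnings.warn("stratum smaller than 2; plain shuffle split used",
                          stacklevel=2)
        splitter = ShuffleSplit(n_splits=1, test_size=test_fraction,
                                random_state=seed)
        train, test = next(splitter.split(np.zeros(n)))
    else:
        splitter = StratifiedShuffleSplit(
            n_splits=1, test_size=test_fraction, random_state=seed
        )
        train, test = next(splitter.split(np.zeros(n), flag))
    return np.sort(train), np.sort(test)


def _pearson_per_feature(recon: np.ndarray, truth: np.ndarray,
                         mask: np.ndarray) -> np.ndarray:
    """Per-feature Pearson r over observed entries; NaN where undefined."""
    n_features = truth.shape[1]
    out = np.full(n_features, np.nan)
    for j in range(n_features):
        obs = mask[:, j]
        if obs.sum() < 3:
            continue
        a, b = recon[obs, j], truth[obs, j]
        if a.std() == 0 or b.std() == 0:
            continue
        out[j] = stats.pearsonr(a, b).statistic
    return out


def kfold_reconstruction_quality(
    dataset: MultiOmicDataset,
    config: ModelConfig | None = None,
    k: int = 10,
    seed: int = 0,
    epochs: int | None = None,
) -> pd.DataFrame:
    """k-fold cross-validated per-feature reconstruction quality.

    Returns a long DataFrame with columns ``view``, ``feature``, ``r`` and
    ``n_observed``; ``r`` is NaN for features with fewer than 3 observed
    held-out values.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    config = config or ModelConfig()
    n = dataset.n_samples
    recon_full = [np.zeros_like(v.values) for v in dataset.views]
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in kf.split(np.zeros(n)):
        train_ds = dataset.subset_samples(train_idx)
        model = MultiOmicVAE(train_ds, config)
        model.fit(epochs=epochs)
        # reconstruct the held-out fold with the trained network
        test_ds = dataset.subset_samples(test_idx)
        test_model = MultiOmicVAE.__new__(MultiOmicVAE)
        test_model.dataset = test_ds
        test_model.config = config
        test_model.network = model.network
        test_model._enc_values = [
            test_ds.encoder_matrix(name)[0] for name in test_ds.view_names
        ]
        test_model._cond = test_ds.conditionals.values
        state = test_model.encode()
        recons = test_model.decode(state.mu)
        for v_i in range(len(dataset.views)):
            recon_full[v_i][test_idx] = recons[v_i]
    rows = []
    for v_i, view in enumerate(dataset.views):
        r = _pearson_per_feature(recon_full[v_i], view.values, view.mask)
        for j, fid in enumerate(view.feature_ids):
            rows.append(
                {
                    "view": view.name,
                    "feature": fid,
                    "r": r[j],
                    "n_observed": int(view.mask[:, j].sum()),
                }
            )
    return pd.DataFrame(rows)
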