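"""Reading, writing and assembly of multi-omic matrices.

One omic "view" is a samples x features matrix of continuous (or ordinal,
for copy number) measurements with an explicit observed-mask: cells left
blank or marked NA on disk are recorded as unobserved and stored as zero,
so downstream statistics and losses can exclude them.

Assembly aligns an arbitrary set of views onto a common sample index
(samples present in at least ``min_views`` views and in the conditional
matrix), padding absent screens with fully masked rows.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OmicMatrix",
    "ConditionalMatrix",
    "MultiOmicDataset",
    "read_omic_csv",
    "write_omic_csv",
    "read_conditionals",
    "read_pair_set",
    "assemble_dataset",
]

_NA_TOKENS = {"", "NA", "NaN", "nan", "na"}


@dataclasses.dataclass
class OmicMatrix:
    """A single omic view.

    Attributes
    ----------
    name : str
        View identifier, e.g. ``"transcriptomics"``.
    values : ndarray, (n_samples, n_features)
        Measurements; unobserved cells hold 0.
    mask : ndarray of bool, same shape
        True where the cell was actually measured.
    sample_ids, feature_ids : ndarray of str
    modality : {"continuous", "ordinal"}
        Ordinal marks views (copy number) exempt from z-scoring.
    """

    name: str
    values: np.ndarray
    mask: np.ndarray
    sample_ids: np.ndarray
    feature_ids: np.ndarray
    modality: str = "continuous"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        if self.values.shape != self.mask.shape:
            raise ValueError(f"view {self.name}: mask shape differs from values")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(f"view {self.name}: id lengths do not match values")
        for label, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"view {self.name}: duplicate {label} ids")
        if self.modality not in ("continuous", "ordinal"):
            raise ValueError(f"unknown modality {self.modality!r}")
        # enforce the zero-fill convention
        self.values = np.where(self.mask, self.values, 0.0)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> float:
        return 1.0 - self.mask.mean()

    def copy(self) -> "OmicMatrix":
        return OmicMatrix(
            self.name,
            self.values.copy(),
            self.mask.copy(),
            self.sample_ids.copy(),
            self.feature_ids.copy(),
            self.modality,
        )

    def subset_features(self, feature_ids) -> "OmicMatrix":
        idx = [int(np.where(self.feature_ids == f)[0][0]) for f in feature_ids]
        return OmicMatrix(
            self.name,
            self.values[:, idx],
            self.mask[:, idx],
            self.sample_ids,
            self.feature_ids[idx],
            self.modality,
        )


@dataclasses.dataclass
class ConditionalMatrix:
    """Covariates appended to encoder inputs and the latent code.

    Binary columns (driver mutations, fusions, tissue flags, MSI) hold
    {0,1}; continuous columns (growth rate) are standardized.
    """

    values: np.ndarray
    names: np.ndarray
    kinds: np.ndarray  # per-column "binary" | "continuous"
    sample_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.names = np.asarray(self.names, dtype=object)
        self.kinds = np.asarray(self.kinds, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        for j, kind in enumerate(self.kinds):
            if kind == "binary":
                col = self.values[:, j]
                if not np.all(np.isin(col[np.isfinite(col)], (0.0, 1.0))):
                    raise ValueError(f"binary conditional {self.names[j]} not in {{0,1}}")
            elif kind != "continuous":
                raise ValueError(f"unknown conditional kind {kind!r}")

    @property
    def n_conditionals(self) -> int:
        return self.values.shape[1]

    def standardized(self) -> "ConditionalMatrix":
        """Standardize continuous columns over finite entries; NaN -> 0 after."""
        vals = self.values.copy()
        for j, kind in enumerate(self.kinds):
            if kind != "continuous":
                vals[~np.isfinite(vals[:, j]), j] = 0.0
                continue
            col = vals[:, j]
            obs = np.isfinite(col)
            mu = col[obs].mean() if obs.any() else 0.0
            sd = col[obs].std(ddof=0) if obs.any() else 1.0
            if sd == 0:
                sd = 1.0
            col = (col - mu) / sd
            col[~obs] = 0.0  # mean-impute unmeasured covariates post-standardization
            vals[:, j] = col
        return ConditionalMatrix(vals, self.names, self.kinds, self.sample_ids)


@dataclasses.dataclass
class MultiOmicDataset:
    """Aligned views + conditionals on one shared sample index.

    ``encoder_features`` records the per-view feature subset fed to the
    encoder (the asymmetric design: decoders still reconstruct all
    features).  ``view_observed`` flags which samples have each screen at
    all.  ``tissues`` carries the tissue-of-origin label used by the
    contrastive loss term; None disables that term.
    """

    views: list[OmicMatrix]
    conditionals: ConditionalMatrix
    encoder_features: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    view_observed: np.ndarray | None = None
    tissues: np.ndarray | None = None

    def __post_init__(self):
        sample_ids = self.views[0].sample_ids
        for v in self.views[1:]:
            if not np.array_equal(v.sample_ids, sample_ids):
                raise ValueError(f"view {v.name} sample index differs")
        if not np.array_equal(self.conditionals.sample_ids, sample_ids):
            raise ValueError("conditional sample index differs from views")
        if self.view_observed is None:
            self.view_observed = np.stack(
                [v.mask.any(axis=1) for v in self.views], axis=1
            )
        for name, feats in self.encoder_features.items():
            view = self.view(name)
            if not set(feats) <= set(view.feature_ids):
                raise ValueError(f"encoder features for {name} not a subset")
        for v in self.views:
            if v.name not in self.encoder_features:
                self.encoder_features[v.name] = v.feature_ids.copy()

    @property
    def sample_ids(self) -> np.ndarray:
        return self.views[0].sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def view_names(self) -> list[str]:
        return [v.name for v in self.views]

    def view(self, name: str) -> OmicMatrix:
        for v in self.views:
            if v.name == name:
                return v
        raise KeyError(f"no view named {name!r}")

    def encoder_matrix(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(values, mask) restricted to the encoder feature subset."""
        sub = self.view(name).subset_features(self.encoder_features[name])
        return sub.values, sub.mask

    def subset_samples(self, indices) -> "MultiOmicDataset":
        indices = np.asarray(indices)
        views = [
            OmicMatrix(
                v.name,
                v.values[indices],
                v.mask[indices],
                v.sample_ids[indices],
                v.feature_ids,
                v.modality,
            )
            for v in self.views
        ]
        cond = ConditionalMatrix(
            self.conditionals.values[indices],
            self.conditionals.names,
            self.conditionals.kinds,
            self.conditionals.sample_ids[indices],
        )
        return MultiOmicDataset(
            views,
            cond,
            {k: v.copy() for k, v in self.encoder_features.items()},
            self.view_observed[indices],
            None if self.tissues is None else self.tissues[indices],
        )


# ---------------------------------------------------------------------------
# file I/O


def _read_table(path, sep=None) -> pd.DataFrame:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    return df


def read_omic_csv(path, name: str, modality: str = "continuous") -> OmicMatrix:
    """Read a samples x features delimited file into an :class:`OmicMatrix`.

    Header row holds feature ids; first column holds sample ids.  Blank or
    NA cells become unobserved (mask False, value 0).  Duplicate ids or
    non-numeric cells raise ``ValueError``.
    """
    # pandas silently renames duplicate header entries, so check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    sep = "\t" if "\t" in header else ","
    header_ids = header.split(sep)[1:]
    if len(set(header_ids)) != len(header_ids):
        dupes = [h for h in header_ids if header_ids.count(h) > 1]
        raise ValueError(f"{path}: duplicate feature ids {sorted(set(dupes))[:5]}")
    df = _read_table(path)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes[:5]}")
    raw = df.to_numpy(dtype=object)
    mask = np.ones(raw.shape, dtype=bool)
    values = np.zeros(raw.shape, dtype=np.float64)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell in _NA_TOKENS:
                mask[i, j] = False
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row {df.index[i]!r}, "
                    f"column {df.columns[j]!r}: {cell!r}"
                ) from None
    return OmicMatrix(
        name, values, mask, df.index.to_numpy(object), df.columns.to_numpy(object), modality
    )


def write_omic_csv(view: OmicMatrix, path, sep: str | None = None) -> None:
    """Write a view back to disk; unobserved cells are written blank."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    vals = view.values.astype(object)
    vals[~view.mask] = ""
    df = pd.DataFrame(vals, index=view.sample_ids, columns=view.feature_ids)
    df.to_csv(path, sep=sep)


def read_conditionals(path, kinds_path) -> ConditionalMatrix:
    """Read a conditional matrix plus its sidecar column-kinds file.

    The kinds file is two-column delimited text: conditional name,
    ``binary`` or ``continuous``.
    """
    df = _read_table(path)
    vals = np.full(df.shape, np.nan)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = str(df.iat[i, j]).strip()
            if cell not in _NA_TOKENS:
                vals[i, j] = float(cell)
    kinds_df = pd.read_csv(
        kinds_path, sep=None, engine="python", header=None, names=["name", "kind"]
    )
    kind_map = dict(zip(kinds_df["name"].astype(str), kinds_df["kind"].astype(str)))
    kinds = np.array([kind_map.get(str(c), "binary") for c in df.columns], dtype=object)
    cm = ConditionalMatrix(
        vals, df.columns.to_numpy(object), kinds, df.index.to_numpy(object)
    )
    return cm


def read_pair_set(path) -> set[frozenset]:
    """Read a two-column file of id pairs into a set of unordered pairs.

    Symmetric duplicates collapse; self-pairs are dropped.
    """
    pairs: set[frozenset] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", "\t").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed pair line {line!r}")
            a, b = parts[0].strip(), parts[1].strip()
            if a != b:
                pairs.add(frozenset((a, b)))
    return pairs


def write_pair_set(pairs, path) -> None:
    with open(path, "w") as fh:
        for pair in sorted(tuple(sorted(p)) for p in pairs):
            fh.write(f"{pair[0]}\t{pair[1]}\n")


def assemble_dataset(
    views: list[OmicMatrix],
    conditionals: ConditionalMatrix,
    min_views: int = 2,
    tissues: dict | None = None,
) -> MultiOmicDataset:
    """Align views and conditionals on the shared sample universe.

    Keeps samples appearing in at least ``min_views`` views (a sample
    "appears" in a view if it has at least one observed cell there) and in
    the conditional matrix.  Views are reindexed onto the union sample
    index, ordered lexicographically; samples lacking a screen get a fully
    masked zero row there.  Continuous conditionals are standardized and
    mean-imputed.

    Parameters
    ----------
    tissues : mapping sample_id -> tissue label, optional
        Attached to the dataset for the contrastive loss.
    """
    if not views:
        raise ValueError("need at least one view")
    counts: dict[str, int] = {}
    for v in views:
        present = v.sample_ids[v.mask.any(axis=1)]
        for s in present:
            counts[s] = counts.get(s, 0) + 1
    cond_ids = set(conditionals.sample_ids)
    keep = sorted(s for s, c in counts.items() if c >= min_views and s in cond_ids)
    if not keep:
        raise ValueError(
            f"no samples present in >= {min_views} views and the conditionals"
        )
    keep_arr = np.array(keep, dtype=object)

    new_views = []
    for v in views:
        pos = {s: i for i, s in enumerate(v.sample_ids)}
        values = np.zeros((len(keep), v.n_features))
        mask = np.zeros((len(keep), v.n_features), dtype=bool)
        for i, s in enumerate(keep):
            if s in pos:
                values[i] = v.values[pos[s]]
                mask[i] = v.mask[pos[s]]
        new_views.append(
            OmicMatrix(v.name, values, mask, keep_arr, v.feature_ids, v.modality)
        )

    cpos = {s: i for i, s in enumerate(conditionals.sample_ids)}
    cvals = np.stack([conditionals.values[cpos[s]] for s in keep])
    cond = ConditionalMatrix(
        cvals, conditionals.names, conditionals.kinds, keep_arr
    ).standardized()

    tissue_arr = None
    if tissues is not None:
        tissue_arr = np.array([tissues.get(s, "unknown") for s in keep], dtype=object)
    return MultiOmicDataset(new_views, cond, tissues=tissue_arr)
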