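"""Seeded generator of multi-omic datasets with known ground truth.

The generative family is linear-Gaussian with the structure the VAE
assumes: a K-dimensional latent factor per sample (with tissue-specific
mean shifts), binary conditionals with planted additive effects on the
views, per-view loading matrices, bimodal feature variability (signal
features vs low-SD noise features, so the mixture-based SD filter has
something to find), one ordinal copy-number-like view, one CRISPR-like
view with designated essential / non-essential / never-essential gene
blocks, MCAR cell masking and whole-view sample absence.

``GroundTruth`` retains everything needed to score any downstream
evaluation (latents, loadings, the pre-masking values, planted complex
memberships) without re-reading inputs.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from .io import ConditionalMatrix, MultiOmicDataset, OmicMatrix

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "generate_confounded_proteome"]


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of the synthetic multi-omic generator.

    Defaults give 400 cell-line-like samples over 3 views sharing 8 latent
    factors at signal-to-noise ratio ~3, with 20% MCAR cell masking and a
    quarter of the samples lacking the last view entirely — the regime the
    recovery benchmarks run at.
    """

    n_samples: int = 400
    n_tissues: int = 4
    latent_dim: int = 8
    view_features: tuple = (60, 50, 40)
    signal_fraction: float = 0.7
    noise_sd: float = 0.33
    low_sd: float = 0.1
    tissue_shift: float = 1.0
    n_conditionals: int = 5
    conditional_effect: float = 1.5
    conditional_rate: float = 0.3
    mcar_rate: float = 0.2
    view_absence_rate: float = 0.25
    absent_view: int = -1  # index of the view subject to whole-view absence
    n_complexes: int = 0
    complex_size: int = 4
    complex_strength: float = 2.0
    confounder_strength: float = 0.0
    n_sample_blocks: int = 4
    ordinal_view: int | None = None  # index discretized to copy-number levels
    ordinal_levels: int = 5
    crispr_view: int | None = None  # index given essentiality block structure
    n_essential: int = 10
    n_nonessential: int = 10
    n_never_essential: int = 5
    nonlinear: bool = False  # squash the first view through tanh
    seed: int = 0

    def __post_init__(self):
        if min(self.n_samples, self.n_tissues, self.latent_dim) < 1:
            raise ValueError("counts must be >= 1")
        for name in ("signal_fraction", "mcar_rate", "view_absence_rate",
                     "conditional_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_complexes and self.complex_size > min(self.view_features):
            raise ValueError("complex size exceeds view feature count")


@dataclasses.dataclass
class GroundTruth:
    """Everything the generator knows: sufficient for every evaluation."""

    latents: np.ndarray  # n_samples x K
    loadings: list[np.ndarray]  # per view: K x features (signal cols only nonzero)
    cond_effects: list[np.ndarray]  # per view: n_cond x features
    true_values: list[np.ndarray]  # per view, pre-masking noisy values
    signal_features: list[np.ndarray]  # per view boolean over features
    tissue_labels: np.ndarray
    complex_members: list[list[str]]
    essential_ids: np.ndarray | None = None
    nonessential_ids: np.ndarray | None = None
    never_essential_ids: np.ndarray | None = None


def _tissue_means(spec: SyntheticSpec, rng) -> np.ndarray:
    return spec.tissue_shift * rng.standard_normal((spec.n_tissues, spec.latent_dim))


def generate(spec: SyntheticSpec) -> tuple[MultiOmicDataset, GroundTruth]:
    """Draw one dataset + ground truth; bit-reproducible for a given seed."""
    rng = np.random.default_rng(spec.seed)
    n, K = spec.n_samples, spec.latent_dim

    tissue_idx = rng.integers(0, spec.n_tissues, size=n)
    tissue_labels = np.array([f"tissue_{t}" for t in tissue_idx], dtype=object)
    Z = _tissue_means(spec, rng)[tissue_idx] + rng.standard_normal((n, K))

    cond_vals = (rng.random((n, spec.n_conditionals)) < spec.conditional_rate)
    cond_vals = cond_vals.astype(np.float64)
    cond_names = np.array(
        [f"cond_{j}" for j in range(spec.n_conditionals)], dtype=object
    )
    cond = ConditionalMatrix(
        cond_vals, cond_names,
        np.array(["binary"] * spec.n_conditionals, dtype=object),
        np.array([f"S{i:04d}" for i in range(n)], dtype=object),
    )

    sample_ids = cond.sample_ids
    views, loadings, cond_effects, true_values, signal_flags = [], [], [], [], []
    complex_members: list[list[str]] = []
    ess = non = never = None

    for v_i, p in enumerate(spec.view_features):
        fids = np.array([f"v{v_i}_f{j}" for j in range(p)], dtype=object)
        n_signal = max(1, int(round(spec.signal_fraction * p)))
        signal = np.zeros(p, dtype=bool)
        signal[:n_signal] = True
        L = np.zeros((K, p))
        # unit-variance latent contribution on signal features, then scaled
        # so var(signal)/var(noise) ~ (1/noise_sd)^2
        L[:, signal] = rng.standard_normal((K, n_signal)) / np.sqrt(K)
        B = np.zeros((spec.n_conditionals, p))
        # each conditional pushes a random subset of signal features
        for c in range(spec.n_conditionals):
            hit = rng.choice(np.where(signal)[0], size=max(1, n_signal // 5),
                             replace=False)
            B[c, hit] = spec.conditional_effect * rng.choice((-1.0, 1.0), len(hit))
        X = Z @ L + cond_vals @ B + spec.noise_sd * rng.standard_normal((n, p))
        # non-signal features: pure low-SD noise (bimodal SD structure)
        X[:, ~signal] = spec.low_sd * rng.standard_normal((n, (~signal).sum()))

        if spec.n_complexes and v_i == 0:
            for ci in range(spec.n_complexes):
                members = fids[ci * spec.complex_size:(ci + 1) * spec.complex_size]
                shared = spec.complex_strength * rng.standard_normal(n)
                for m in members:
                    j = int(np.where(fids == m)[0][0])
                    X[:, j] = X[:, j] + shared
                complex_members.append(list(members))

        if spec.nonlinear and v_i == 0:
            X = np.tanh(X)

        modality = "continuous"
        if spec.ordinal_view is not None and v_i == spec.ordinal_view % len(
            spec.view_features
        ):
            # copy-number analogue: integer levels around 2
            X = np.clip(np.round(2.0 + X), 0, spec.ordinal_levels - 1)
            modality = "ordinal"

        if spec.crispr_view is not None and v_i == spec.crispr_view % len(
            spec.view_features
        ):
            n_blocks = spec.n_essential + spec.n_nonessential + spec.n_never_essential
            if n_blocks > p:
                raise ValueError("essentiality blocks exceed view feature count")
            ess = fids[:spec.n_essential]
            non = fids[spec.n_essential:spec.n_essential + spec.n_nonessential]
            never = fids[spec.n_essential + spec.n_nonessential:n_blocks]
            # essential genes deplete strongly, non-essential sit near zero,
            # never-essential stay clearly above the -0.5 essentiality cutoff
            X[:, :spec.n_essential] = -2.0 + 0.3 * rng.standard_normal(
                (n, spec.n_essential)
            )
            X[:, spec.n_essential:spec.n_essential + spec.n_nonessential] = (
                0.3 * rng.standard_normal((n, spec.n_nonessential))
            )
            X[:, spec.n_essential + spec.n_nonessential:n_blocks] = np.abs(
                0.1 * rng.standard_normal((n, spec.n_never_essential))
            )

        true_values.append(X.copy())
        mask = rng.random((n, p)) >= spec.mcar_rate
        views.append(OmicMatrix(f"view{v_i}", np.where(mask, X, 0.0), mask,
                                sample_ids, fids, modality))
        loadings.append(L)
        cond_effects.append(B)
        signal_flags.append(signal)

    # whole-view absence for a subset of samples, applied last
    if spec.view_absence_rate > 0:
        target = spec.absent_view % len(views)
        absent = rng.random(n) < spec.view_absence_rate
        v = views[target]
        mask = v.mask.copy()
        mask[absent] = False
        views[target] = OmicMatrix(
            v.name, np.where(mask, v.values, 0.0), mask, v.sample_ids,
            v.feature_ids, v.modality,
        )

    dataset = MultiOmicDataset(views, cond, tissues=tissue_labels)
    truth = GroundTruth(
        Z, loadings, cond_effects, true_values, signal_flags, tissue_labels,
        complex_members, ess, non, never,
    )
    return dataset, truth


def generate_confounded_proteome(
    spec: SyntheticSpec,
) -> tuple[np.ndarray, np.ndarray, set[frozenset]]:
    """Proteome-like matrix with planted complexes plus sample-block confounding.

    Samples fall into ``n_sample_blocks`` blocks; each block carries a
    latent factor that loads on every protein with protein-specific
    random weights scaled by ``confounder_strength``.  Proteins sharing
    large same-sign weights become spuriously correlated under naive
    Pearson; whitening on the sample side removes the block structure.

    Returns ``(matrix, protein_ids, true_pairs)`` where ``true_pairs`` are
    the within-complex unordered pairs.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    p = spec.view_features[0]
    n_complex_feats = spec.n_complexes * spec.complex_size
    if n_complex_feats > p:
        raise ValueError("complexes do not fit in the protein set")
    ids = np.array([f"P{j:04d}" for j in range(p)], dtype=object)
    X = rng.standard_normal((n, p))
    for ci in range(spec.n_complexes):
        shared = spec.complex_strength * rng.standard_normal(n)
        cols = slice(ci * spec.complex_size, (ci + 1) * spec.complex_size)
        X[:, cols] += shared[:, None]
    if spec.confounder_strength > 0:
        blocks = rng.integers(0, spec.n_sample_blocks, size=n)
        factors = rng.standard_normal(spec.n_sample_blocks)
        weights = spec.confounder_strength * rng.standard_normal(p)
        X += factors[blocks][:, None] * weights[None, :]
    pairs = set()
    for ci in range(spec.n_complexes):
        members = ids[ci * spec.complex_size:(ci + 1) * spec.complex_size]
        for a, b in itertools.combinations(members, 2):
            pairs.add(frozenset((a, b)))
    return X, ids, pairs
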