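"""Synthetic fixture generator emulating sparse ordinal frequency data.

The generator draws non-negative latent factors U*, V* (gamma-distributed so
signatures are sparse-ish and non-negative), forms the low-rank score matrix
U* V*, adds Gaussian noise, rescales the scores to span [1, 5] and rounds
observed cells to the five ordinal classes.  A seeded mask keeps only a
target fraction of cells as "known".  Similarity views are built as kernels
of the ground-truth latent distances (so they genuinely carry information
about the factors), optionally mixed with an independent random similarity
to emulate noisy side information, plus the frequency-profile cosine views
computed from the generated matrix itself — mirroring how the real views
relate to the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import (
    FrequencyMatrix,
    write_frequency_tsv,
    write_labeled_matrix,
)
from .similarity import (
    ANNOTATION,
    FINGERPRINT,
    SimilarityView,
    cosine_profile_similarity,
)


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic dataset.

    ``density`` is the fraction of cells observed (the real benchmark is
    ~5% known; tests typically use 0.3-0.4 for signal at small n).
    ``view_noise`` in [0, 1] mixes an independent random similarity into the
    latent-distance kernels (0 = clean views).  ``mask_bias`` makes
    observation probability proportional to ``class^mask_bias`` (pharmaco-
    vigilance records frequent effects far more often than very rare ones;
    0 gives a uniform mask).
    """

    n: int = 100
    m: int = 150
    rank: int = 5
    density: float = 0.3
    class_count: int = 5
    noise_sd: float = 0.1
    view_noise: float = 0.2
    mask_bias: float = 1.0
    n_drug_views: int = 3
    n_effect_views: int = 2
    cold_start_drugs: int = 0
    cold_start_effects: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.density <= 1):
            raise ValueError("density must lie in (0, 1]")
        if self.rank > min(self.n, self.m):
            raise ValueError("rank cannot exceed min(n, m)")
        if self.noise_sd < 0 or not (0 <= self.view_noise <= 1):
            raise ValueError("noise_sd must be >= 0 and view_noise in [0, 1]")
        if self.mask_bias < 0:
            raise ValueError("mask_bias must be >= 0")
        if self.class_count != 5:
            raise ValueError("class_count is fixed at 5 ordinal classes")
        if self.cold_start_drugs >= self.n or self.cold_start_effects >= self.m:
            raise ValueError("cold-start counts must leave known entities")


@dataclass
class SyntheticDataset:
    """Generated fixture with ground truth retained for recovery tests."""

    freq: FrequencyMatrix
    drug_views: list[SimilarityView]
    effect_views: list[SimilarityView]
    U_true: np.ndarray
    V_true: np.ndarray
    scores_true: np.ndarray  # noiseless rescaled scores before rounding
    spec: SyntheticSpec = field(repr=False, default=None)


def _distance_kernel(Z: np.ndarray, rng: np.random.Generator, mix: float) -> np.ndarray:
    """Similarity in [0,1] decreasing in pairwise latent distance, mixed with
    an independent symmetric uniform similarity by weight ``mix``."""
    d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(-1)
    scale = np.median(d2[d2 > 0]) if (d2 > 0).any() else 1.0
    S = np.exp(-d2 / max(scale, 1e-12))
    if mix > 0:
        noise = rng.uniform(size=S.shape)
        noise = (noise + noise.T) / 2.0
        S = (1.0 - mix) * S + mix * noise
    np.fill_diagonal(S, 1.0)
    return np.clip(S, 0.0, 1.0)


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a dataset per ``spec``; same seed gives an identical dataset."""
    rng = np.random.default_rng(spec.seed)
    n, m, r = spec.n, spec.m, spec.rank

    U = rng.gamma(shape=2.0, scale=1.0, size=(n, r))
    V = rng.gamma(shape=2.0, scale=1.0, size=(r, m))
    scores = U @ V
    noisy = scores + rng.normal(scale=spec.noise_sd, size=scores.shape)

    # affine rescale of the noiseless scores to [1, 5] with equal-width class
    # bins; anchoring on the 1st/99th percentiles (rather than min/max) keeps
    # the right-skewed score distribution from starving the extreme classes
    lo, hi = np.quantile(scores, [0.01, 0.99])
    span = max(hi - lo, 1e-12)
    scores_true = np.clip(1.0 + 4.0 * (scores - lo) / span, 1.0, 5.0)
    noisy = 1.0 + 4.0 * (noisy - lo) / span
    classes = np.clip(np.round(noisy), 1, spec.class_count).astype(np.int64)

    if spec.density >= 1.0:
        mask = np.ones((n, m), dtype=bool)
    else:
        # observation odds grow with the true class (reporting bias);
        # normalized so the expected overall density matches the spec
        weights = classes.astype(float) ** spec.mask_bias
        p = np.clip(spec.density * weights / weights.mean(), 0.0, 1.0)
        mask = rng.uniform(size=(n, m)) < p
    values = np.where(mask, classes, 0)

    cold_drugs = rng.choice(n, size=spec.cold_start_drugs, replace=False) if spec.cold_start_drugs else np.array([], dtype=int)
    cold_effects = rng.choice(m, size=spec.cold_start_effects, replace=False) if spec.cold_start_effects else np.array([], dtype=int)
    values[cold_drugs, :] = 0
    values[:, cold_effects] = 0

    freq = FrequencyMatrix(values)

    drug_views = [cosine_profile_similarity(freq.values, axis="drug")]
    kinds = [FINGERPRINT, ANNOTATION]
    for v in range(spec.n_drug_views - 1):
        drug_views.append(
            SimilarityView(
                _distance_kernel(U, rng, spec.view_noise),
                kind=kinds[v % 2],
                axis="drug",
            )
        )
    effect_views = [cosine_profile_similarity(freq.values, axis="effect")]
    for _ in range(spec.n_effect_views - 1):
        effect_views.append(
            SimilarityView(
                _distance_kernel(V.T, rng, spec.view_noise),
                kind=ANNOTATION,
                axis="effect",
            )
        )

    return SyntheticDataset(
        freq=freq,
        drug_views=drug_views,
        effect_views=effect_views,
        U_true=U,
        V_true=V,
        scores_true=scores_true,
        spec=spec,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write the fixture in the same formats the loaders read.

    Returns a manifest of written paths.  Non-frequency views are written as
    precomputed similarity TSVs (the frequency-profile views are derived
    from the matrix at load time, so they are not persisted).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"frequency": str(outdir / "frequency.tsv")}
    write_frequency_tsv(ds.freq, paths["frequency"])
    for i, view in enumerate(ds.drug_views[1:], start=2):
        p = outdir / f"drug_view{i}_{view.kind}.tsv"
        write_labeled_matrix(view.matrix, ds.freq.drug_ids, ds.freq.drug_ids, p)
        paths[f"drug_view{i}"] = str(p)
    for i, view in enumerate(ds.effect_views[1:], start=2):
        p = outdir / f"effect_view{i}_{view.kind}.tsv"
        write_labeled_matrix(view.matrix, ds.freq.effect_ids, ds.freq.effect_ids, p)
        paths[f"effect_view{i}"] = str(p)
    comp = [f"z{c}" for c in range(ds.U_true.shape[1])]
    write_labeled_matrix(ds.U_true, ds.freq.drug_ids, comp, outdir / "U_true.tsv")
    write_labeled_matrix(ds.V_true, comp, ds.freq.effect_ids, outdir / "V_true.tsv")
    paths["U_true"] = str(outdir / "U_true.tsv")
    paths["V_true"] = str(outdir / "V_true.tsv")
    return paths
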