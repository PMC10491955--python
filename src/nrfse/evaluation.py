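"""Cross-validation protocols and evaluation metrics.

Two 10-fold schemes:

* **CV1 (warm start)** — the known drug-effect cells are randomly split into
  10 folds; each fold in turn is hidden (its cells set to 0 in the training
  matrix) and predicted.
* **CV2 (cold start)** — the drugs are split into 10 folds; all cells of the
  held-out drugs are zeroed, so each test drug is entirely new to the model
  and relies on the cold-start neighbor refinement.

In both schemes the frequency-profile similarity views are recomputed from
the *training* matrix of each fold so that held-out cells never leak into
the similarity graphs.

Association identification is scored per drug: for every drug with at least
one test-fold cell, the positives are that drug's test cells and the
negatives are all of its never-observed cells; AUC and AUPR are averaged over
eligible drugs.  Frequency-value prediction is scored over the fold's test
cells with RMSE, MAE and the Pearson correlation coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .data import FrequencyMatrix
from .model import NRFSE, default_hyperparameters
from .similarity import FREQUENCY_PROFILE, SimilarityView, cosine_profile_similarity

METRIC_NAMES = ("auc", "aupr", "rmse", "mae", "pcc")


@dataclass
class CVSplit:
    """A seeded 10-fold partition: cell indices (CV1) or drug rows (CV2)."""

    scheme: str
    folds: list[np.ndarray]
    seed: int
    shape: tuple[int, int]

    @property
    def n_folds(self) -> int:
        return len(self.folds)


@dataclass
class EvalReport:
    """Per-fold and averaged metrics for one cross-validation run."""

    scheme: str
    seed: int
    per_fold: list[dict] = field(default_factory=list)
    mean: dict = field(default_factory=dict)
    test_counts: list[int] = field(default_factory=list)
    skipped_drugs: list[int] = field(default_factory=list)
    hyperparameters: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(fold=i + 1, **f) for i, f in enumerate(self.per_fold)]
        rows.append(dict(fold="mean", **self.mean))
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self) -> dict:
        return {
            "scheme": self.scheme,
            "seed": self.seed,
            "per_fold": self.per_fold,
            "mean": self.mean,
            "test_counts": self.test_counts,
            "skipped_drugs": self.skipped_drugs,
            "hyperparameters": self.hyperparameters,
        }


def make_cv_split(
    freq: FrequencyMatrix, scheme: str, seed: int, n_folds: int = 10
) -> CVSplit:
    """Seeded random partition of known cells (CV1) or drugs (CV2)."""
    rng = np.random.default_rng(seed)
    if scheme == "CV1":
        cells = np.flatnonzero(freq.values.ravel() > 0)
        if cells.size < n_folds:
            raise ValueError(f"need >= {n_folds} known cells, have {cells.size}")
        folds = np.array_split(rng.permutation(cells), n_folds)
    elif scheme == "CV2":
        if freq.n_drugs < n_folds:
            raise ValueError(f"need >= {n_folds} drugs, have {freq.n_drugs}")
        folds = np.array_split(rng.permutation(freq.n_drugs), n_folds)
    else:
        raise ValueError("scheme must be 'CV1' or 'CV2'")
    return CVSplit(scheme=scheme, folds=[np.sort(f) for f in folds], seed=seed, shape=freq.shape)


def training_matrix(freq: FrequencyMatrix, split: CVSplit, fold: int) -> tuple[FrequencyMatrix, np.ndarray]:
    """Zero out the fold's test cells (CV1) or test-drug rows (CV2).

    Returns the training matrix and the flat indices of the test cells
    (known cells only, i.e. those with a ground-truth class).
    """
    values = freq.values.copy()
    if split.scheme == "CV1":
        test_cells = split.folds[fold]
        values.ravel()[test_cells] = 0
    else:
        rows = split.folds[fold]
        flat = (rows[:, None] * freq.n_effects + np.arange(freq.n_effects)[None, :]).ravel()
        test_cells = flat[freq.values.ravel()[flat] > 0]
        values[rows, :] = 0
    return freq.with_values(values), test_cells


def refresh_profile_views(
    views: list[SimilarityView], train: FrequencyMatrix, axis: str
) -> list[SimilarityView]:
    """Recompute frequency-profile views from the training matrix (leakage
    guard); other views pass through unchanged."""
    out = []
    for v in views:
        if v.kind == FREQUENCY_PROFILE:
            out.append(cosine_profile_similarity(train.values, axis=axis))
        else:
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def ranking_metrics_per_drug(
    scores: np.ndarray,
    full: FrequencyMatrix,
    test_cells: np.ndarray,
) -> tuple[float, float, int]:
    """Per-drug AUC/AUPR averaged over drugs with test positives.

    For each drug: positives are its test-fold cells, negatives are all its
    cells unknown in the *full* matrix; cells known in training are excluded
    from ranking.  Drugs with no test positive or no negative are skipped.

    Returns (mean AUC, mean AUPR, skipped-drug count); the skip count
    includes drugs that have test cells somewhere but no eligible pair for
    this drug.
    """
    n, m = full.shape
    test_mask = np.zeros(n * m, dtype=bool)
    test_mask[np.asarray(test_cells, dtype=int)] = True
    test_mask = test_mask.reshape(n, m)
    unknown = full.values == 0
    aucs, auprs, skipped = [], [], 0
    for i in np.flatnonzero(test_mask.any(axis=1)):
        pos = test_mask[i]
        neg = unknown[i]
        if pos.sum() == 0 or neg.sum() == 0:
            skipped += 1
            continue
        y = np.concatenate([np.ones(pos.sum()), np.zeros(neg.sum())])
        s = np.concatenate([scores[i, pos], scores[i, neg]])
        aucs.append(roc_auc_score(y, s))
        auprs.append(average_precision_score(y, s))
    if not aucs:
        return float("nan"), float("nan"), skipped
    return float(np.mean(aucs)), float(np.mean(auprs)), skipped


def regression_metrics(
    predictions: np.ndarray, truths: np.ndarray
) -> tuple[float, float, float]:
    """RMSE, MAE and Pearson correlation over the fold's test cells.

    A zero-variance side yields PCC = 0 with a warning (rather than NaN).
    """
    p = np.asarray(predictions, float).ravel()
    r = np.asarray(truths, float).ravel()
    if p.shape != r.shape:
        raise ValueError("predictions and truths must have equal length")
    diff = p - r
    rmse = float(np.sqrt(np.mean(diff**2)))
    mae = float(np.mean(np.abs(diff)))
    sp, sr = p.std(), r.std()
    if p.size < 2 or sp == 0 or sr == 0:
        warnings.warn("zero variance in predictions or truths; PCC set to 0")
        pcc = 0.0
    else:
        pcc = float(np.corrcoef(p, r)[0, 1])
    return rmse, mae, pcc


# ---------------------------------------------------------------------------
# cross-validation driver
# ---------------------------------------------------------------------------

def cross_validate(
    freq: FrequencyMatrix,
    drug_views: list[SimilarityView],
    effect_views: list[SimilarityView],
    scheme: str = "CV1",
    seed: int = 0,
    n_folds: int = 10,
    **overrides,
) -> EvalReport:
    """Run the full 10-fold protocol and return per-fold + mean metrics.

    Hyperparameters default to the warm-start set for CV1 and the cold-start
    set for CV2; keyword overrides are applied on top (e.g. smaller
    ``n_components`` / ``max_iter`` for quick runs).
    """
    scenario = "warm" if scheme == "CV1" else "cold"
    params = default_hyperparameters(scenario)
    params.update(overrides)
    split = make_cv_split(freq, scheme, seed, n_folds)
    report = EvalReport(scheme=scheme, seed=seed, hyperparameters=dict(params))
    for fold in range(split.n_folds):
        train, test_cells = training_matrix(freq, split, fold)
        dviews = refresh_profile_views(drug_views, train, "drug")
        eviews = refresh_profile_views(effect_views, train, "effect")
        est = NRFSE(random_state=seed, **params)
        scores = est.fit(train, dviews, eviews).predict()
        auc, aupr, skipped = ranking_metrics_per_drug(scores, freq, test_cells)
        rmse, mae, pcc = regression_metrics(
            scores.ravel()[test_cells], freq.values.ravel()[test_cells].astype(float)
        )
        report.per_fold.append(
            dict(auc=auc, aupr=aupr, rmse=rmse, mae=mae, pcc=pcc)
        )
        report.test_counts.append(int(test_cells.size))
        report.skipped_drugs.append(skipped)
    report.mean = {
        k: float(np.nanmean([f[k] for f in report.per_fold])) for k in METRIC_NAMES
    }
    return report


def sensitivity_sweep(
    freq: FrequencyMatrix,
    drug_views: list[SimilarityView],
    effect_views: list[SimilarityView],
    mu_values,
    alpha_values,
    scheme: str = "CV1",
    seed: int = 0,
    n_folds: int = 10,
    **overrides,
) -> pd.DataFrame:
    """Grid sweep over the Gaussian-prior mean and precision.

    Runs the full cross-validation at every (mu, alpha) grid point and
    returns a tidy table of the averaged metrics for trend inspection.
    """
    mu_values = list(mu_values)
    alpha_values = list(alpha_values)
    if not mu_values or not alpha_values:
        raise ValueError("sweep grid must be non-empty")
    rows = []
    for mu in mu_values:
        for alpha in alpha_values:
            rep = cross_validate(
                freq, drug_views, effect_views, scheme=scheme, seed=seed,
                n_folds=n_folds, mu=mu, alpha=alpha, **overrides,
            )
            rows.append(dict(mu=mu, alpha=alpha, **rep.mean))
    return pd.DataFrame(rows)
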