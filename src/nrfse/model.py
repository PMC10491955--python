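"""Class-weighted NMF with multiview neighborhood regularization (NRFSE).

The model completes a sparse ordinal drug x side-effect frequency matrix R by
a non-negative factorization R ~ U V (U: n x k drug signatures, V: k x m
effect signatures).  Known cells are fit by squared error; the predicted
scores of unknown cells are pulled toward a Gaussian prior with mean ``mu``
and precision ``alpha`` (= 1/sigma^2).  Latent signatures are smoothed over
several kNN similarity graphs per axis through graph-Laplacian penalties, with
simplex-constrained per-view weights w_p (drugs) and h_q (effects) raised to a
power ``delta`` and learned in closed form.  The full objective is

    J = 1/2 ||I_known . (R - UV)||_F^2
      + alpha/2 ||I_unknown . (UV - mu E)||_F^2
      + beta/2  tr(U^T sum_p w_p^delta L_dp U)
      + gamma/2 tr(V sum_q h_q^delta L_eq V^T),

minimized by multiplicative updates on U and V (which preserve
non-negativity) alternating with the closed-form view-weight updates
w_p propto tr(U^T L_dp U)^(-1/(delta-1)).

Cold-start entities (all-zero rows/columns of R) get their signatures
replaced after training by the similarity-weighted average of the signatures
of their k2 nearest neighbors among entities with known frequency items,
using only the non-frequency views.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_is_fitted

from .data import FrequencyMatrix
from .similarity import (
    FREQUENCY_PROFILE,
    LaplacianSet,
    NeighborGraph,
    SimilarityView,
    build_view_graphs,
)

#: Hyperparameter defaults for the warm-start scenario (held-out cells belong
#: to drugs that keep other known items in training).
WARM_DEFAULTS = dict(
    alpha=0.05, beta=2.0, gamma=2.0, mu=1.0,
    n_components=200, n_neighbors=20, n_cold_neighbors=10,
    delta=2.0, max_iter=500,
)

#: Defaults for the cold-start scenario (entire drugs held out): stronger
#: neighborhood regularization with tighter graphs.
COLD_DEFAULTS = dict(WARM_DEFAULTS, beta=4.0, gamma=4.0, n_neighbors=10)


def default_hyperparameters(scenario: str = "warm") -> dict:
    """Return the stock hyperparameter set for ``"warm"`` or ``"cold"``."""
    if scenario == "warm":
        return dict(WARM_DEFAULTS)
    if scenario == "cold":
        return dict(COLD_DEFAULTS)
    raise ValueError("scenario must be 'warm' or 'cold'")


# ---------------------------------------------------------------------------
# functional core: objective, updates, cold-start refinement
# ---------------------------------------------------------------------------

def _laplacian_trace_U(U: np.ndarray, L: np.ndarray) -> float:
    """tr(U^T L U)."""
    return float(np.sum(U * (L @ U)))


def _laplacian_trace_V(V: np.ndarray, L: np.ndarray) -> float:
    """tr(V L V^T)."""
    return float(np.sum((V @ L) * V))


def objective(
    U: np.ndarray,
    V: np.ndarray,
    freq: FrequencyMatrix,
    drug_laps: list[LaplacianSet],
    effect_laps: list[LaplacianSet],
    drug_weights: np.ndarray,
    effect_weights: np.ndarray,
    *,
    alpha: float,
    mu: float,
    beta: float,
    gamma: float,
    delta: float = 2.0,
) -> float:
    """Evaluate the regularized completion objective J (see module docstring)."""
    U = np.asarray(U, float)
    V = np.asarray(V, float)
    if not (np.isfinite(U).all() and np.isfinite(V).all()):
        raise ValueError("factor matrices contain non-finite entries")
    n, m = freq.shape
    if U.shape[0] != n or V.shape[1] != m or U.shape[1] != V.shape[0]:
        raise ValueError("factor dimensions inconsistent with frequency matrix")
    if len(drug_laps) != len(drug_weights) or len(effect_laps) != len(effect_weights):
        raise ValueError("Laplacian list lengths must match weight vectors")
    R = freq.values.astype(float)
    known = freq.known_mask
    unknown = freq.unknown_mask
    P = U @ V
    val = 0.5 * np.sum((known * (R - P)) ** 2)
    val += 0.5 * alpha * np.sum((unknown * (P - mu)) ** 2)
    for w_p, lap in zip(drug_weights, drug_laps):
        val += 0.5 * beta * (w_p ** delta) * _laplacian_trace_U(U, lap.L)
    for h_q, lap in zip(effect_weights, effect_laps):
        val += 0.5 * gamma * (h_q ** delta) * _laplacian_trace_V(V, lap.L)
    if not np.isfinite(val):
        raise ValueError("objective is non-finite")
    return float(val)


def _combine_graphs(
    graphs: list[NeighborGraph], weights: np.ndarray, delta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted symmetrized adjacency sum_p w_p^d (A~ + A~^T) and the matching
    degree vector diag(sum_p w_p^d (D + D~))."""
    n = graphs[0].matrix.shape[0]
    adj = np.zeros((n, n))
    deg = np.zeros(n)
    for w_p, g in zip(weights, graphs):
        c = w_p ** delta
        adj += c * (g.matrix + g.matrix.T)
        deg += c * (g.matrix.sum(axis=1) + g.matrix.sum(axis=0))
    return adj, deg


def update_U(
    U0: np.ndarray,
    V0: np.ndarray,
    freq: FrequencyMatrix,
    drug_graphs: list[NeighborGraph],
    drug_weights: np.ndarray,
    *,
    alpha: float,
    mu: float,
    beta: float,
    delta: float = 2.0,
    eps: float = 1e-12,
) -> np.ndarray:
    """One multiplicative update of the drug factor U (uses pre-sweep U0, V0)."""
    U0 = np.asarray(U0, float)
    V0 = np.asarray(V0, float)
    if (U0 < 0).any() or (V0 < 0).any():
        raise ValueError("factors must be non-negative")
    R = freq.values.astype(float)
    known = freq.known_mask
    unknown = freq.unknown_mask
    adj, deg = _combine_graphs(drug_graphs, drug_weights, delta)
    Rtil = R + alpha * mu * unknown
    W = known + alpha * unknown
    num = Rtil @ V0.T + beta * (adj @ U0)
    den = (W * (U0 @ V0)) @ V0.T + beta * (deg[:, None] * U0) + eps
    return U0 * num / den


def update_V(
    U: np.ndarray,
    V0: np.ndarray,
    freq: FrequencyMatrix,
    effect_graphs: list[NeighborGraph],
    effect_weights: np.ndarray,
    *,
    alpha: float,
    mu: float,
    gamma: float,
    delta: float = 2.0,
    eps: float = 1e-12,
) -> np.ndarray:
    """One multiplicative update of the effect factor V.

    Uses the already-updated U of the current sweep together with the
    pre-sweep V0.
    """
    U = np.asarray(U, float)
    V0 = np.asarray(V0, float)
    if (U < 0).any() or (V0 < 0).any():
        raise ValueError("factors must be non-negative")
    R = freq.values.astype(float)
    known = freq.known_mask
    unknown = freq.unknown_mask
    adj, deg = _combine_graphs(effect_graphs, effect_weights, delta)
    Rtil = R + alpha * mu * unknown
    W = known + alpha * unknown
    num = U.T @ Rtil + gamma * (V0 @ adj)
    den = U.T @ (W * (U @ V0)) + gamma * (V0 * deg[None, :]) + eps
    return V0 * num / den


def update_view_weights(
    traces: np.ndarray, delta: float = 2.0, eps: float = 1e-12
) -> np.ndarray:
    """Closed-form simplex view weights from Laplacian traces.

    ``w_p = t_p^(-1/(delta-1)) / sum_p' t_p'^(-1/(delta-1))`` minimizes
    ``sum_p w_p^delta t_p`` subject to ``sum w_p = 1, w_p >= 0``.
    """
    t = np.asarray(traces, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("need at least one view trace")
    if delta <= 1:
        raise ValueError("delta must exceed 1")
    t = np.maximum(t, eps)
    inv = t ** (-1.0 / (delta - 1.0))
    return inv / inv.sum()


def refine_cold_start(
    U: np.ndarray,
    V: np.ndarray,
    freq: FrequencyMatrix,
    drug_graphs: list[NeighborGraph],
    effect_graphs: list[NeighborGraph],
    drug_weights: np.ndarray,
    effect_weights: np.ndarray,
    *,
    delta: float = 2.0,
    n_cold_neighbors: int = 10,
    drug_view_kinds: list[str] | None = None,
    effect_view_kinds: list[str] | None = None,
    new_drug_indices: np.ndarray | None = None,
    new_effect_indices: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Replace signatures of cold-start entities by neighbor averages.

    For a new drug i (all-zero row of R), the combined similarity to a known
    drug j is ``s_ij = sum_p w_p^delta A~_dp(i, j)`` over the non-frequency
    views only (a new entity's frequency profile is identically zero, so the
    frequency view carries no signal for it).  Its signature becomes the
    s-weighted average of the signatures of the k2 known drugs with largest
    s.  If every combined similarity is zero the unweighted mean signature of
    all known drugs is used.  Columns of V are treated symmetrically for new
    effects.  Rows/columns not listed as new are returned unchanged.
    """
    U = np.array(U, dtype=float, copy=True)
    V = np.array(V, dtype=float, copy=True)
    n, m = freq.shape
    if new_drug_indices is None:
        new_drug_indices = freq.new_drug_indices()
    if new_effect_indices is None:
        new_effect_indices = freq.new_effect_indices()
    new_drug_indices = np.asarray(new_drug_indices, dtype=int)
    new_effect_indices = np.asarray(new_effect_indices, dtype=int)
    if new_drug_indices.size and (
        new_drug_indices.min() < 0 or new_drug_indices.max() >= n
    ):
        raise IndexError("new drug index outside matrix")
    if new_effect_indices.size and (
        new_effect_indices.min() < 0 or new_effect_indices.max() >= m
    ):
        raise IndexError("new effect index outside matrix")
    for idx in new_drug_indices:
        if freq.values[idx].any():
            raise ValueError(f"drug row {idx} listed as new but has known items")
    for idx in new_effect_indices:
        if freq.values[:, idx].any():
            raise ValueError(f"effect column {idx} listed as new but has known items")

    known_drugs = np.flatnonzero(freq.values.any(axis=1))
    known_effects = np.flatnonzero(freq.values.any(axis=0))

    def _included(n_views: int, kinds: list[str] | None) -> list[int]:
        if kinds is not None and FREQUENCY_PROFILE in kinds:
            return [i for i, kd in enumerate(kinds) if kd != FREQUENCY_PROFILE]
        return list(range(1, n_views))  # convention: view 0 is the freq profile

    d_incl = _included(len(drug_graphs), drug_view_kinds)
    e_incl = _included(len(effect_graphs), effect_view_kinds)

    def _replace(row_sims: np.ndarray, pool: np.ndarray, signatures: np.ndarray):
        s = row_sims[pool]
        if s.sum() <= 0:
            return signatures[pool].mean(axis=0)
        top = np.argsort(-s, kind="stable")[:n_cold_neighbors]
        s_top = s[top]
        return (s_top[:, None] * signatures[pool][top]).sum(axis=0) / s_top.sum()

    for i in new_drug_indices:
        s_row = np.zeros(n)
        for p in d_incl:
            s_row += (drug_weights[p] ** delta) * drug_graphs[p].matrix[i, :]
        if known_drugs.size:
            U[i] = _replace(s_row, known_drugs, U)
    for j in new_effect_indices:
        s_col = np.zeros(m)
        for q in e_incl:
            s_col += (effect_weights[q] ** delta) * effect_graphs[q].matrix[:, j]
        if known_effects.size:
            V[:, j] = _replace(s_col, known_effects, V.T)
    return U, V


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class NRFSE(BaseEstimator):
    """Multiview neighborhood-regularized NMF for frequency-class completion.

    Parameters
    ----------
    n_components : int, default=200
        Latent dimension k of the drug and effect signatures.
    alpha : float, default=0.05
        Precision (1/sigma^2) of the Gaussian prior pulling unknown-cell
        scores toward ``mu``.
    mu : float, default=1.0
        Prior mean score for unknown cells (the "very rare" class).
    beta, gamma : float, default=2.0
        Strength of the drug-side and effect-side Laplacian penalties.
    n_neighbors : int, default=20
        k1, neighborhood size for sparsifying each similarity view.
    n_cold_neighbors : int, default=10
        k2, neighbor count for the cold-start signature replacement.
    delta : float, default=2.0
        Exponent on the view weights; must exceed 1 so the closed-form
        weight update is defined.
    max_iter : int, default=500
        Number of full U -> V -> w -> h sweeps.
    tol : float or None, default=None
        Optional early stop on relative objective change; ``None`` runs all
        ``max_iter`` sweeps (matching the reference protocol).
    refine_cold : bool, default=True
        Whether to replace signatures of all-zero rows/columns after the
        iterations.
    eps : float, default=1e-12
        Additive guard for multiplicative-update denominators and traces.
    random_state : int, RandomState or None
        Seed for the uniform factor initialization.

    Attributes
    ----------
    U_ : ndarray of shape (n_drugs, n_components)
        Non-negative drug signatures.
    V_ : ndarray of shape (n_components, n_effects)
        Non-negative effect signatures.
    drug_weights_, effect_weights_ : ndarray
        Learned simplex view weights w and h.
    objective_trace_ : list of float
        Objective value after every sweep.
    cold_drugs_, cold_effects_ : ndarray
        Indices whose signatures were replaced by neighbor averages.

    Examples
    --------
    >>> from nrfse.simulate import SyntheticSpec, generate
    >>> ds = generate(SyntheticSpec(n=40, m=50, rank=3, density=0.4, seed=0))
    >>> est = NRFSE(n_components=5, max_iter=50, random_state=0)
    >>> scores = est.fit(ds.freq, ds.drug_views, ds.effect_views).predict()
    >>> scores.shape
    (40, 50)
    """

    def __init__(
        self,
        n_components: int = 200,
        *,
        alpha: float = 0.05,
        mu: float = 1.0,
        beta: float = 2.0,
        gamma: float = 2.0,
        n_neighbors: int = 20,
        n_cold_neighbors: int = 10,
        delta: float = 2.0,
        max_iter: int = 500,
        tol: float | None = None,
        refine_cold: bool = True,
        eps: float = 1e-12,
        random_state=None,
    ):
        self.n_components = n_components
        self.alpha = alpha
        self.mu = mu
        self.beta = beta
        self.gamma = gamma
        self.n_neighbors = n_neighbors
        self.n_cold_neighbors = n_cold_neighbors
        self.delta = delta
        self.max_iter = max_iter
        self.tol = tol
        self.refine_cold = refine_cold
        self.eps = eps
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------
    def _validate(self, freq, drug_views, effect_views):
        if not isinstance(freq, FrequencyMatrix):
            freq = FrequencyMatrix(np.asarray(freq))
        def _wrap(views, n_nodes, axis):
            if not views:
                raise ValueError(f"need at least one {axis} view")
            wrapped = []
            for v in views:
                if not isinstance(v, SimilarityView):
                    v = SimilarityView(np.asarray(v, float), axis=axis)
                if v.n_nodes != n_nodes:
                    raise ValueError(
                        f"{axis} view of size {v.n_nodes} does not match "
                        f"frequency matrix ({n_nodes})"
                    )
                if v.ids and axis == "drug" and v.ids != freq.drug_ids:
                    raise ValueError("drug view IDs do not align with matrix")
                if v.ids and axis == "effect" and v.ids != freq.effect_ids:
                    raise ValueError("effect view IDs do not align with matrix")
                wrapped.append(v)
            return wrapped
        dv = _wrap(drug_views, freq.n_drugs, "drug")
        ev = _wrap(effect_views, freq.n_effects, "effect")
        if self.delta <= 1:
            raise ValueError("delta must exceed 1")
        if self.n_components < 1 or self.max_iter < 1 or self.n_neighbors < 1:
            raise ValueError("n_components, max_iter and n_neighbors must be >= 1")
        return freq, dv, ev

    # -- API --------------------------------------------------------------
    def fit(self, freq, drug_views, effect_views):
        """Run the alternating optimization on the known entries of ``freq``.

        Parameters
        ----------
        freq : FrequencyMatrix or ndarray
            Integer class matrix with 0 for unknown pairs.
        drug_views : list of SimilarityView or ndarray
            Drug similarity matrices; by convention the frequency-profile
            view comes first.
        effect_views : list of SimilarityView or ndarray
            Effect similarity matrices, frequency-profile view first.
        """
        freq, drug_views, effect_views = self._validate(freq, drug_views, effect_views)
        rng = check_random_state(self.random_state)
        n, m = freq.shape
        k = self.n_components

        drug_graphs, drug_laps = build_view_graphs(drug_views, self.n_neighbors)
        effect_graphs, effect_laps = build_view_graphs(effect_views, self.n_neighbors)

        U = rng.uniform(size=(n, k))
        U /= np.linalg.norm(U)
        V = rng.uniform(size=(k, m))
        V /= np.linalg.norm(V)
        w = np.full(len(drug_views), 1.0 / len(drug_views))
        h = np.full(len(effect_views), 1.0 / len(effect_views))

        hp = dict(alpha=self.alpha, mu=self.mu, delta=self.delta, eps=self.eps)
        trace: list[float] = []
        for _ in range(self.max_iter):
            U = update_U(U, V, freq, drug_graphs, w, beta=self.beta, **hp)
            V = update_V(U, V, freq, effect_graphs, h, gamma=self.gamma, **hp)
            w = update_view_weights(
                np.array([_laplacian_trace_U(U, lap.L) for lap in drug_laps]),
                self.delta,
                self.eps,
            )
            h = update_view_weights(
                np.array([_laplacian_trace_V(V, lap.L) for lap in effect_laps]),
                self.delta,
                self.eps,
            )
            trace.append(
                objective(
                    U, V, freq, drug_laps, effect_laps, w, h,
                    alpha=self.alpha, mu=self.mu, beta=self.beta,
                    gamma=self.gamma, delta=self.delta,
                )
            )
            if (
                self.tol is not None
                and len(trace) > 1
                and abs(trace[-2] - trace[-1]) <= self.tol * max(abs(trace[-2]), 1.0)
            ):
                break

        cold_drugs = freq.new_drug_indices()
        cold_effects = freq.new_effect_indices()
        if self.refine_cold and (cold_drugs.size or cold_effects.size):
            U, V = refine_cold_start(
                U, V, freq, drug_graphs, effect_graphs, w, h,
                delta=self.delta,
                n_cold_neighbors=self.n_cold_neighbors,
                drug_view_kinds=[v.kind for v in drug_views],
                effect_view_kinds=[v.kind for v in effect_views],
                new_drug_indices=cold_drugs,
                new_effect_indices=cold_effects,
            )

        self.freq_ = freq
        self.U_, self.V_ = U, V
        self.drug_weights_, self.effect_weights_ = w, h
        self.objective_trace_ = trace
        self.n_iter_ = len(trace)
        self.cold_drugs_, self.cold_effects_ = cold_drugs, cold_effects
        self.drug_graphs_, self.effect_graphs_ = drug_graphs, effect_graphs
        self.drug_laplacians_, self.effect_laplacians_ = drug_laps, effect_laps
        return self

    def predict(self) -> np.ndarray:
        """Continuous score matrix U V (no rounding to classes)."""
        check_is_fitted(self, "U_")
        return self.U_ @ self.V_

    def fit_predict(self, freq, drug_views, effect_views) -> np.ndarray:
        return self.fit(freq, drug_views, effect_views).predict()
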