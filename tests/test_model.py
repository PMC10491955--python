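import numpy as np
import pytest

from conftest import random_instance

from nrfse.data import FrequencyMatrix
from nrfse.model import (
    NRFSE,
    COLD_DEFAULTS,
    WARM_DEFAULTS,
    default_hyperparameters,
    objective,
    refine_cold_start,
    update_U,
    update_V,
    update_view_weights,
)
from nrfse.similarity import build_view_graphs


def brute_objective(U, V, freq, drug_graphs, effect_graphs, w, h, *,
                    alpha, mu, beta, gamma, delta):
    """Term-by-term double-loop evaluation of the completion objective."""
    R = freq.values.astype(float)
    P = U @ V
    n, m = freq.shape
    val = 0.0
    for i in range(n):
        for j in range(m):
            if R[i, j] > 0:
                val += 0.5 * (R[i, j] - P[i, j]) ** 2
            else:
                val += 0.5 * alpha * (P[i, j] - mu) ** 2
    for w_p, g in zip(w, drug_graphs):
        A = g.matrix
        for i in range(n):
            for u_ in range(n):
                val += 0.5 * beta * w_p**delta * A[i, u_] * np.sum((U[i] - U[u_]) ** 2)
    for h_q, g in zip(h, effect_graphs):
        A = g.matrix
        for i in range(m):
            for u_ in range(m):
                val += 0.5 * gamma * h_q**delta * A[i, u_] * np.sum(
                    (V[:, i] - V[:, u_]) ** 2
                )
    return val


def simplex_grid_min(traces, delta, res=0.001):
    """Minimum of sum_p w_p^delta t_p over a simplex grid of given step."""
    t = np.asarray(traces, float)
    if t.size == 2:
        w1 = np.arange(0.0, 1.0 + res / 2, res)
        vals = w1**delta * t[0] + (1 - w1) ** delta * t[1]
        return vals.min()
    assert t.size == 3
    w1 = np.arange(0.0, 1.0 + res / 2, res)
    best = np.inf
    for a in w1:
        w2 = np.arange(0.0, 1.0 - a + res / 2, res)
        vals = a**delta * t[0] + w2**delta * t[1] + (1 - a - w2) ** delta * t[2]
        best = min(best, vals.min())
    return best


class TestObjective:
    def test_all_zero_factors_and_matrix(self):
        freq = FrequencyMatrix(np.zeros((3, 3), dtype=int))
        graphs, laps = build_view_graphs(
            [np.eye(3) * 0 + 0.5 - 0.5 * np.eye(3) + np.eye(3)], 2
        )
        U, V = np.zeros((3, 2)), np.zeros((2, 3))
        w = np.ones(1)
        val = objective(U, V, freq, laps, laps, w, w,
                        alpha=0.5, mu=0.0, beta=1.0, gamma=1.0)
        assert val == 0.0

    def test_perfect_factorization_no_regularization(self):
        U = np.array([[1.0, 0.0], [0.0, 1.0]])
        V = np.array([[2.0, 3.0], [4.0, 5.0]])
        freq = FrequencyMatrix(np.round(U @ V).astype(int))
        graphs, laps = build_view_graphs([np.ones((2, 2))], 1)
        val = objective(U, V, freq, laps, laps, np.ones(1), np.ones(1),
                        alpha=0.3, mu=1.0, beta=0.0, gamma=0.0)
        assert val == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_double_loop_oracle(self, seed):
        freq, dviews, eviews = random_instance(seed, n=10, m=8)
        dgraphs, dlaps = build_view_graphs(dviews, 4)
        egraphs, elaps = build_view_graphs(eviews, 3)
        rng = np.random.default_rng(100 + seed)
        U, V = rng.uniform(size=(10, 3)), rng.uniform(size=(3, 8))
        w = np.array([0.5, 0.3, 0.2])
        h = np.array([0.6, 0.4])
        hp = dict(alpha=0.05, mu=1.0, beta=2.0, gamma=2.0, delta=2.0)
        assert objective(U, V, freq, dlaps, elaps, w, h, **hp) == pytest.approx(
            brute_objective(U, V, freq, dgraphs, egraphs, w, h, **hp), rel=1e-10
        )

    def test_dimension_mismatch_raises(self):
        freq, dviews, eviews = random_instance(0, n=6, m=5)
        _, dlaps = build_view_graphs(dviews, 2)
        _, elaps = build_view_graphs(eviews, 2)
        with pytest.raises(ValueError, match="inconsistent"):
            objective(np.ones((7, 2)), np.ones((2, 5)), freq, dlaps, elaps,
                      np.ones(3) / 3, np.ones(2) / 2,
                      alpha=0.05, mu=1.0, beta=2.0, gamma=2.0)

    def test_non_finite_factors_raise(self):
        freq, dviews, eviews = random_instance(0, n=6, m=5)
        _, dlaps = build_view_graphs(dviews, 2)
        _, elaps = build_view_graphs(eviews, 2)
        U = np.ones((6, 2))
        U[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            objective(U, np.ones((2, 5)), freq, dlaps, elaps,
                      np.ones(3) / 3, np.ones(2) / 2,
                      alpha=0.05, mu=1.0, beta=2.0, gamma=2.0)


class TestMultiplicativeUpdates:
    def test_zero_factor_stays_zero(self):
        freq, dviews, eviews = random_instance(1, n=6, m=5)
        dgraphs, _ = build_view_graphs(dviews, 2)
        egraphs, _ = build_view_graphs(eviews, 2)
        U0, V0 = np.zeros((6, 3)), np.zeros((3, 5))
        w, h = np.ones(3) / 3, np.ones(2) / 2
        U = update_U(U0, np.ones((3, 5)), freq, dgraphs, w,
                     alpha=0.05, mu=1.0, beta=2.0)
        assert (U == 0).all()
        V = update_V(np.ones((6, 3)), V0, freq, egraphs, h,
                     alpha=0.05, mu=1.0, gamma=2.0)
        assert (V == 0).all()

    def test_negative_input_raises(self):
        freq, dviews, _ = random_instance(1, n=6, m=5)
        dgraphs, _ = build_view_graphs(dviews, 2)
        U0 = -np.ones((6, 3))
        with pytest.raises(ValueError, match="non-negative"):
            update_U(U0, np.ones((3, 5)), freq, dgraphs, np.ones(3) / 3,
                     alpha=0.05, mu=1.0, beta=2.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_reduces_to_classic_weighted_nmf(self, seed):
        """With no prior and no graphs on a fully known matrix, one sweep is
        the textbook multiplicative NMF update."""
        rng = np.random.default_rng(seed)
        n, m, k = 6, 5, 3
        freq = FrequencyMatrix(rng.integers(1, 6, size=(n, m)))
        dgraphs, _ = build_view_graphs([np.ones((n, n))], 2)
        egraphs, _ = build_view_graphs([np.ones((m, m))], 2)
        U0, V0 = rng.uniform(size=(n, k)), rng.uniform(size=(k, m))
        R = freq.values.astype(float)
        eps = 1e-12
        U_expect = U0 * (R @ V0.T) / ((U0 @ V0) @ V0.T + eps)
        U = update_U(U0, V0, freq, dgraphs, np.ones(1),
                     alpha=0.0, mu=1.0, beta=0.0)
        np.testing.assert_allclose(U, U_expect, atol=1e-10)
        V_expect = V0 * (U.T @ R) / (U.T @ (U @ V0) + eps)
        V = update_V(U, V0, freq, egraphs, np.ones(1),
                     alpha=0.0, mu=1.0, gamma=0.0)
        np.testing.assert_allclose(V, V_expect, atol=1e-10)

    def test_nonnegativity_over_many_random_instances(self):
        """U and V stay elementwise non-negative after sweeps on 100 seeds."""
        for seed in range(100):
            freq, dviews, eviews = random_instance(seed, n=8, m=6)
            dgraphs, _ = build_view_graphs(dviews, 3)
            egraphs, _ = build_view_graphs(eviews, 2)
            rng = np.random.default_rng(1000 + seed)
            U = rng.uniform(size=(8, 3))
            V = rng.uniform(size=(3, 6))
            w, h = np.ones(3) / 3, np.ones(2) / 2
            U = update_U(U, V, freq, dgraphs, w, alpha=0.05, mu=1.0, beta=2.0)
            V = update_V(U, V, freq, egraphs, h, alpha=0.05, mu=1.0, gamma=2.0)
            assert (U >= 0).all() and (V >= 0).all()
            assert np.isfinite(U).all() and np.isfinite(V).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_single_sweep_does_not_increase_objective(self, seed):
        freq, dviews, eviews = random_instance(seed, n=12, m=10)
        dgraphs, dlaps = build_view_graphs(dviews, 4)
        egraphs, elaps = build_view_graphs(eviews, 4)
        rng = np.random.default_rng(2000 + seed)
        U = rng.uniform(size=(12, 4))
        V = rng.uniform(size=(4, 10))
        w, h = np.ones(3) / 3, np.ones(2) / 2
        hp = dict(alpha=0.05, mu=1.0, beta=2.0, gamma=2.0, delta=2.0)
        before = objective(U, V, freq, dlaps, elaps, w, h,
                           alpha=0.05, mu=1.0, beta=2.0, gamma=2.0)
        U = update_U(U, V, freq, dgraphs, w, alpha=0.05, mu=1.0, beta=2.0)
        V = update_V(U, V, freq, egraphs, h, alpha=0.05, mu=1.0, gamma=2.0)
        after = objective(U, V, freq, dlaps, elaps, w, h,
                          alpha=0.05, mu=1.0, beta=2.0, gamma=2.0)
        assert after <= before + 1e-9


class TestViewWeights:
    def test_equal_traces_give_uniform_weights(self):
        np.testing.assert_allclose(
            update_view_weights(np.array([4.2, 4.2, 4.2])), np.ones(3) / 3
        )

    def test_hand_value(self):
        # traces (1, 3), delta=2: (1/1)/(1/1 + 1/3) = 0.75
        np.testing.assert_allclose(
            update_view_weights(np.array([1.0, 3.0]), delta=2.0), [0.75, 0.25]
        )

    def test_simplex_conservation_exact(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            w = update_view_weights(rng.uniform(0.1, 10, size=4), delta=2.5)
            assert abs(w.sum() - 1.0) < 1e-12 and (w >= 0).all()

    @pytest.mark.parametrize("delta", [2.0, 3.0])
    @pytest.mark.parametrize("size", [2, 3])
    def test_minimizes_weighted_trace_sum_vs_grid(self, delta, size):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            t = rng.uniform(0.05, 5.0, size=size)
            w = update_view_weights(t, delta=delta)
            ours = np.sum(w**delta * t)
            assert ours <= simplex_grid_min(t, delta) + 1e-12

    def test_empty_traces_raise(self):
        with pytest.raises(ValueError):
            update_view_weights(np.array([]))

    def test_delta_at_most_one_raises(self):
        with pytest.raises(ValueError, match="delta"):
            update_view_weights(np.array([1.0, 2.0]), delta=1.0)


class TestFit:
    def test_same_seed_reproduces_trace_bitwise(self, small_dataset):
        ds = small_dataset
        kw = dict(n_components=4, max_iter=30, random_state=11)
        t1 = NRFSE(**kw).fit(ds.freq, ds.drug_views, ds.effect_views).objective_trace_
        t2 = NRFSE(**kw).fit(ds.freq, ds.drug_views, ds.effect_views).objective_trace_
        assert t1 == t2

    def test_objective_decreases_from_start(self, small_dataset):
        ds = small_dataset
        est = NRFSE(n_components=3, max_iter=80, random_state=0).fit(
            ds.freq, ds.drug_views, ds.effect_views
        )
        assert est.objective_trace_[-1] < est.objective_trace_[0]
        diffs = np.diff(est.objective_trace_)
        assert (diffs <= 1e-9).all()

    def test_factors_nonnegative_and_weights_simplex(self, small_dataset):
        ds = small_dataset
        est = NRFSE(n_components=4, max_iter=40, random_state=2).fit(
            ds.freq, ds.drug_views, ds.effect_views
        )
        assert (est.U_ >= 0).all() and (est.V_ >= 0).all()
        assert est.drug_weights_.sum() == pytest.approx(1.0, abs=1e-12)
        assert est.effect_weights_.sum() == pytest.approx(1.0, abs=1e-12)

    def test_predict_before_fit_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            NRFSE().predict()

    def test_misaligned_view_raises(self, small_dataset):
        ds = small_dataset
        bad = np.eye(ds.freq.n_drugs + 1)
        with pytest.raises(ValueError, match="does not match"):
            NRFSE(n_components=3, max_iter=5).fit(
                ds.freq, [bad], ds.effect_views
            )

    def test_prior_limit_monotone_in_alpha(self, small_dataset):
        """Mean predicted score on unknown cells approaches mu as the prior
        precision alpha grows."""
        ds = small_dataset
        unknown = ds.freq.values == 0
        gaps = []
        for a in [0.05, 1.0, 20.0]:
            est = NRFSE(n_components=4, alpha=a, mu=1.0, max_iter=150,
                        random_state=3).fit(ds.freq, ds.drug_views, ds.effect_views)
            gaps.append(abs(est.predict()[unknown].mean() - 1.0))
        assert gaps[0] > gaps[1] > gaps[2]

    def test_reconstruction_of_clean_low_rank_matrix(self):
        """On a fully known noiseless rank-2 matrix (continuous scores, no
        class rounding) with no regularization, 500 multiplicative sweeps
        reconstruct the matrix to high accuracy."""
        rng = np.random.default_rng(0)
        U_true = rng.gamma(2.0, 1.0, size=(15, 2))
        V_true = rng.gamma(2.0, 1.0, size=(2, 12))
        S = U_true @ V_true
        S = 1.0 + 4.0 * (S - S.min()) / (S.max() - S.min())
        freq = FrequencyMatrix(np.clip(np.round(S), 1, 5).astype(int))
        freq.values = S  # continuous scores, every cell known
        est = NRFSE(n_components=2, alpha=0.0, beta=0.0, gamma=0.0,
                    max_iter=500, random_state=0, refine_cold=False).fit(
            freq, [np.ones((15, 15))], [np.ones((12, 12))]
        )
        P = est.predict()
        rmse = np.sqrt(np.mean((P - S) ** 2))
        assert rmse < 0.1

    def test_warm_and_cold_default_sets(self):
        assert default_hyperparameters("warm") == WARM_DEFAULTS
        cold = default_hyperparameters("cold")
        assert cold["beta"] == 4.0 and cold["gamma"] == 4.0
        assert cold["n_neighbors"] == 10 and cold["alpha"] == WARM_DEFAULTS["alpha"]

    def test_sklearn_param_interface(self):
        est = NRFSE(n_components=7)
        assert est.get_params()["n_components"] == 7
        est.set_params(alpha=0.5)
        assert est.alpha == 0.5


class TestColdStartRefinement:
    def _setup(self, seed=0, n=8, m=6):
        rng = np.random.default_rng(seed)
        values = rng.integers(1, 6, size=(n, m))
        values[0, :] = 0  # drug 0 is new
        freq = FrequencyMatrix(values)
        U = rng.uniform(size=(n, 3))
        V = rng.uniform(size=(3, m))
        return freq, U, V

    def _graphs(self, mats):
        from nrfse.similarity import NeighborGraph

        return [NeighborGraph(m, k1=m.shape[0] - 1) for m in mats]

    def test_single_neighbor_copies_embedding(self):
        freq, U, V = self._setup()
        n = freq.n_drugs
        A1 = np.zeros((n, n))  # frequency view: excluded from weighting
        A2 = np.zeros((n, n))
        A2[0, 3] = 0.7  # sole non-frequency similarity of the new drug
        Unew, _ = refine_cold_start(
            U, V, freq, self._graphs([A1, A2]), self._graphs([np.zeros((6, 6))]),
            np.array([0.5, 0.5]), np.array([1.0]), n_cold_neighbors=3,
        )
        np.testing.assert_allclose(Unew[0], U[3])
        np.testing.assert_allclose(Unew[1:], U[1:])  # others untouched

    def test_weighted_average_of_neighbors(self):
        freq, U, V = self._setup()
        n = freq.n_drugs
        A2 = np.zeros((n, n))
        A2[0, 2], A2[0, 5] = 0.6, 0.2
        Unew, _ = refine_cold_start(
            U, V, freq, self._graphs([np.zeros((n, n)), A2]),
            self._graphs([np.zeros((6, 6))]),
            np.array([0.5, 0.5]), np.array([1.0]), n_cold_neighbors=2,
        )
        np.testing.assert_allclose(Unew[0], (0.6 * U[2] + 0.2 * U[5]) / 0.8)

    def test_zero_similarity_falls_back_to_mean_embedding(self):
        freq, U, V = self._setup()
        n = freq.n_drugs
        zeros = np.zeros((n, n))
        Unew, _ = refine_cold_start(
            U, V, freq, self._graphs([zeros, zeros]),
            self._graphs([np.zeros((6, 6))]),
            np.array([0.5, 0.5]), np.array([1.0]), n_cold_neighbors=2,
        )
        np.testing.assert_allclose(Unew[0], U[1:].mean(axis=0))

    def test_frequency_view_excluded_from_weighting(self):
        """Similarity in the frequency-profile view alone must not drive the
        replacement (a new entity's profile is all-zero)."""
        freq, U, V = self._setup()
        n = freq.n_drugs
        A1 = np.zeros((n, n))
        A1[0, 4] = 0.9  # only the (excluded) frequency view sees a neighbor
        A2 = np.zeros((n, n))
        Unew, _ = refine_cold_start(
            U, V, freq, self._graphs([A1, A2]), self._graphs([np.zeros((6, 6))]),
            np.array([0.5, 0.5]), np.array([1.0]), n_cold_neighbors=2,
        )
        np.testing.assert_allclose(Unew[0], U[1:].mean(axis=0))  # fallback

    def test_listed_index_with_known_items_raises(self):
        freq, U, V = self._setup()
        n = freq.n_drugs
        zeros = np.zeros((n, n))
        with pytest.raises(ValueError, match="known items"):
            refine_cold_start(
                U, V, freq, self._graphs([zeros, zeros]),
                self._graphs([np.zeros((6, 6))]),
                np.array([0.5, 0.5]), np.array([1.0]),
                new_drug_indices=np.array([1]),
            )

    def test_out_of_range_index_raises(self):
        freq, U, V = self._setup()
        n = freq.n_drugs
        zeros = np.zeros((n, n))
        with pytest.raises(IndexError):
            refine_cold_start(
                U, V, freq, self._graphs([zeros, zeros]),
                self._graphs([np.zeros((6, 6))]),
                np.array([0.5, 0.5]), np.array([1.0]),
                new_drug_indices=np.array([99]),
            )

    def test_fit_refines_cold_columns_too(self, cold_dataset):
        ds = cold_dataset
        est = NRFSE(n_components=4, max_iter=30, random_state=0).fit(
            ds.freq, ds.drug_views, ds.effect_views
        )
        assert est.cold_drugs_.size == 4 and est.cold_effects_.size == 3
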