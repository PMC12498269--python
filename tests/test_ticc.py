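"""TICC: embedding, likelihoods, DP assignment, Toeplitz M-step, EM loop."""

import itertools

import numpy as np
import pytest
from scipy import stats as sstats

from nvad.synthetic import sample_block_toeplitz_precision
from nvad.ticc import (
    MRFCluster,
    TICCHyperparams,
    TICCModel,
    cluster_nll,
    estep_assign,
    fit_ticc,
    gmm_initialize,
    mstep_update,
    window_embed,
)
from nvad.types import FrameSequence, LabelSequence


def _frames(x):
    return FrameSequence(np.asarray(x, dtype=float))


def _random_cluster(rng, D):
    theta = sample_block_toeplitz_precision(D, 1, 0.4, 0.8, seed=int(rng.integers(1 << 30)))
    sign, logdet = np.linalg.slogdet(theta)
    return MRFCluster(mean=rng.standard_normal(D), precision=theta, log_det=float(logdet))


class TestWindowEmbed:
    def test_single_layer_is_identity(self):
        f = _frames(np.random.default_rng(0).standard_normal((20, 3)))
        assert window_embed(f, 1, 5) is f

    @pytest.mark.parametrize("w,expected_reach_ms", [(5, 200), (7, 300)])
    def test_dilated_context_reach(self, w, expected_reach_ms):
        C, d = 4, 5
        f = _frames(np.random.default_rng(1).standard_normal((60, C)))
        out = window_embed(f, w, d)
        assert out.values.shape == (60, w * C)
        # frame t sees back to t - (w-1)*d frames = reach in 10 ms units
        assert (w - 1) * d * 10 == expected_reach_ms
        t = 55
        for layer in range(w):
            np.testing.assert_array_equal(
                out.values[t, layer * C:(layer + 1) * C], f.values[t - layer * d])

    def test_out_of_range_layers_zero_filled(self):
        f = _frames(np.ones((8, 2)))
        out = window_embed(f, 3, 5)
        np.testing.assert_array_equal(out.values[0, 2:], 0.0)


class TestClusterNLL:
    def test_at_mean_with_identity_precision(self):
        D = 5
        c = MRFCluster(mean=np.zeros(D), precision=np.eye(D), log_det=0.0)
        assert cluster_nll(np.zeros(D), c) == pytest.approx(0.5 * D * np.log(2 * np.pi))

    def test_precision_scaling_shifts_by_half_logdet(self):
        D = 4
        base = MRFCluster(np.zeros(D), np.eye(D), 0.0)
        scaled = MRFCluster(np.zeros(D), 4 * np.eye(D), float(D * np.log(4)))
        delta = cluster_nll(np.zeros(D), base) - cluster_nll(np.zeros(D), scaled)
        assert delta == pytest.approx(0.5 * D * np.log(4))

    def test_matches_scipy_multivariate_normal(self):
        rng = np.random.default_rng(2)
        c = _random_cluster(rng, 4)
        x = rng.standard_normal(4)
        expected = -sstats.multivariate_normal(c.mean, np.linalg.inv(c.precision)).logpdf(x)
        assert cluster_nll(x, c) == pytest.approx(expected, rel=1e-10)

    def test_grows_with_distance(self):
        c = MRFCluster(np.zeros(3), np.eye(3), 0.0)
        vals = [cluster_nll(np.full(3, r), c) for r in (0.0, 1.0, 2.0, 5.0)]
        assert np.all(np.diff(vals) > 0)


def _brute_force_path(nll, beta):
    """Exhaustive minimizer over all K^T label paths (oracle)."""
    T, K = nll.shape
    best_cost, best_path = np.inf, None
    for path in itertools.product(range(K), repeat=T):
        cost = sum(nll[t, k] for t, k in enumerate(path))
        cost += beta * sum(path[t] != path[t - 1] for t in range(1, T))
        if cost < best_cost - 1e-12:
            best_cost, best_path = cost, path
    return best_cost, np.asarray(best_path)


class TestAssignment:
    def _model(self, rng, D, K, beta):
        clusters = [_random_cluster(rng, D) for _ in range(K)]
        return TICCModel(clusters=clusters, hyper=TICCHyperparams(K=K, beta=beta))

    def test_zero_beta_is_framewise_argmin(self):
        rng = np.random.default_rng(3)
        model = self._model(rng, 3, 3, beta=0.0)
        X = rng.standard_normal((40, 3))
        labels = estep_assign(_frames(X), model)
        nll = np.array([[cluster_nll(x, c) for c in model.clusters] for x in X])
        np.testing.assert_array_equal(labels.labels, nll.argmin(axis=1))

    def test_huge_beta_gives_single_segment(self):
        rng = np.random.default_rng(4)
        model = self._model(rng, 3, 2, beta=1e9)
        X = rng.standard_normal((50, 3))
        labels = estep_assign(_frames(X), model)
        assert len(np.unique(labels.labels)) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_dp_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        K, T = 2, 10
        model = self._model(rng, 2, K, beta=1.0)
        X = rng.standard_normal((T, 2))
        labels = estep_assign(_frames(X), model)
        nll = np.array([[cluster_nll(x, c) for c in model.clusters] for x in X])
        cost, path = _brute_force_path(nll, 1.0)
        dp_cost = nll[np.arange(T), labels.labels].sum() + \
            1.0 * np.count_nonzero(np.diff(labels.labels))
        assert dp_cost == pytest.approx(cost, abs=1e-9)
        np.testing.assert_array_equal(labels.labels, path)

    def test_switch_count_monotone_in_beta(self):
        rng = np.random.default_rng(6)
        model0 = self._model(rng, 3, 2, beta=0.0)
        X = rng.standard_normal((300, 3))
        switches = []
        for beta in (0.0, 5.0, 50.0, 500.0):
            model = TICCModel(clusters=model0.clusters,
                              hyper=TICCHyperparams(K=2, beta=beta))
            lab = estep_assign(_frames(X), model).labels
            switches.append(int(np.count_nonzero(np.diff(lab))))
        assert switches == sorted(switches, reverse=True)


class TestGMMInit:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((200, 3)) + 10
        b = rng.standard_normal((200, 3)) - 10
        f = _frames(np.vstack([a, b]))
        labels = gmm_initialize(f, 2, seed=0).labels
        truth = np.r_[np.zeros(200), np.ones(200)]
        acc = max(np.mean(labels == truth), np.mean(labels == 1 - truth))
        assert acc >= 0.99

    def test_k1_and_determinism(self):
        f = _frames(np.random.default_rng(8).standard_normal((50, 2)))
        assert np.all(gmm_initialize(f, 1, seed=3).labels == 0)
        a = gmm_initialize(f, 2, seed=3).labels
        b = gmm_initialize(f, 2, seed=3).labels
        np.testing.assert_array_equal(a, b)


def _check_block_toeplitz(P, w, C, tol=1e-8):
    assert np.allclose(P, P.T, atol=tol)
    assert np.linalg.eigvalsh(P)[0] > 0
    for m in range(w):
        ref = P[0:C, m * C:(m + 1) * C]
        for a in range(w - m):
            np.testing.assert_allclose(
                P[a * C:(a + 1) * C, (a + m) * C:(a + m + 1) * C], ref, atol=tol)


class TestMStep:
    def test_huge_lambda_gives_diagonal_precision(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((400, 4))
        labels = LabelSequence(np.zeros(400, dtype=int))
        (c,) = mstep_update(_frames(X), labels, lam=1e6, K=1)
        off = c.precision - np.diag(np.diag(c.precision))
        assert np.allclose(off, 0.0)

    @pytest.mark.parametrize("n", [1000, 10000])
    def test_consistency_toward_true_inverse_covariance(self, n):
        rng = np.random.default_rng(10)
        theta = sample_block_toeplitz_precision(4, 1, 0.5, 1.0, seed=1)
        L = np.linalg.cholesky(np.linalg.inv(theta))
        X = rng.standard_normal((n, 4)) @ L.T
        labels = LabelSequence(np.zeros(n, dtype=int))
        (c,) = mstep_update(_frames(X), labels, lam=0.0, K=1)
        err = np.linalg.norm(c.precision - theta) / np.linalg.norm(theta)
        assert err < (0.25 if n == 1000 else 0.08)

    def test_iid_data_shrinks_cross_time_blocks(self):
        rng = np.random.default_rng(11)
        C, w = 3, 2
        X = rng.standard_normal((4000, C))
        emb = window_embed(_frames(X), w, 1)
        labels = LabelSequence(np.zeros(4000, dtype=int))
        (c,) = mstep_update(emb, labels, lam=5.0, n_layers=w, K=1)
        _check_block_toeplitz(c.precision, w, C)
        within = np.abs(c.precision[:C, :C] - np.diag(np.diag(c.precision[:C, :C]))).sum()
        cross = np.abs(c.precision[:C, C:]).sum()
        assert cross <= within + 1e-9


class TestFitTICC:
    def test_k1_trivial_convergence(self):
        f = _frames(np.random.default_rng(12).standard_normal((300, 3)))
        model, labels = fit_ticc(f, TICCHyperparams(K=1, seed=0))
        assert model.converged
        assert np.all(labels.labels == 0)

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(13)
        X = np.vstack([rng.standard_normal((150, 3)) + s for s in (0, 3)] * 3)
        model, _ = fit_ticc(_frames(X), TICCHyperparams(K=2, beta=10.0, seed=0))
        trace = np.asarray(model.objective_trace)
        assert np.all(np.diff(trace) <= 1e-6 * np.abs(trace[:-1]))

    def test_returned_precisions_satisfy_invariants(self):
        rng = np.random.default_rng(14)
        X = np.vstack([rng.standard_normal((200, 3)),
                       rng.standard_normal((200, 3)) * 2.5])
        model, _ = fit_ticc(_frames(X), TICCHyperparams(K=2, n_layers=2, seed=1))
        for c in model.clusters:
            _check_block_toeplitz(c.precision, 2, 3)
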