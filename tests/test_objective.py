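"""Oracle battery for every loss term of the objective.

Each Monte-Carlo estimator and penalty is checked against an independent
naive-loop implementation (explicit Python loops and scalar Gaussian density
calls, no shared code with the vectorized path), plus the closed-form edge
cases the estimators must satisfy exactly.
"""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psvae.nn import Tensor
from psvae.objective import (LOG_2PI, LossBreakdown, aggregate_triplet,
                             frame_loglik, kl_supervised,
                             kl_unsup_decomposition, label_loglik_masked,
                             orth_penalty, total_objective, triplet_term)

rng = np.random.default_rng(42)


# ---------------------------------------------------------------------------
# naive-loop oracles (independent of the vectorized implementations)
# ---------------------------------------------------------------------------

def _gauss_logpdf(x, mu, var):
    return -0.5 * (math.log(2 * math.pi) + math.log(var) + (x - mu) ** 2 / var)


def naive_decomposition(z, mean, logvar, N):
    M, L = z.shape
    var = np.exp(logvar)
    log_q_joint = np.empty((M, M))
    log_q_dims = np.empty((M, M, L))
    for i in range(M):
        for j in range(M):
            s = 0.0
            for l in range(L):
                lq = _gauss_logpdf(z[i, l], mean[j, l], var[j, l])
                log_q_dims[i, j, l] = lq
                s += lq
            log_q_joint[i, j] = s

    def lse(vals):
        m = max(vals)
        return m + math.log(sum(math.exp(v - m) for v in vals))

    icmi = tc = dwkl = 0.0
    for i in range(M):
        lse_joint = lse([log_q_joint[i, j] for j in range(M)])
        lse_dims = [lse([log_q_dims[i, j, l] for j in range(M)]) for l in range(L)]
        icmi += log_q_joint[i, i] - lse_joint + math.log(N * M)
        tc += lse_joint - sum(lse_dims) + (L - 1) * math.log(N * M)
        for l in range(L):
            log_p = _gauss_logpdf(z[i, l], 0.0, 1.0)
            dwkl += lse_dims[l] - log_p - math.log(N * M)
    return icmi / M, tc / M, dwkl / M


def naive_orth(U):
    n, m = U.shape
    total = 0.0
    for i in range(n):
        for j in range(n):
            g = sum(U[i, k] * U[j, k] for k in range(m)) - (1.0 if i == j else 0.0)
            total += g * g
    return total


def naive_triplet(k_batch, j_batch, margin):
    g = len(k_batch) // 3
    k1, k2, k3 = k_batch[:g], k_batch[g:2 * g], k_batch[2 * g:]
    j1, j2, j3 = j_batch[:g], j_batch[g:2 * g], j_batch[2 * g:]

    def d(a, b):
        return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))

    total = 0.0
    for i in range(g):
        total += max(d(k1[i], k2[i]) - d(k1[i], j3[i]) + margin, 0.0)
        total += max(d(j1[i], j2[i]) - d(j1[i], k3[i]) + margin, 0.0)
    return total


# ---------------------------------------------------------------------------
# frame / label likelihoods
# ---------------------------------------------------------------------------

class TestFrameLoglik:
    def test_perfect_reconstruction_is_zero(self):
        x = rng.uniform(size=(3, 1, 4, 4))
        L, mse = frame_loglik(x, x.copy())
        assert float(L.data) == 0.0 and mse == 0.0

    def test_single_pixel_error(self):
        x = np.zeros((1, 1, 4, 4))
        xh = x.copy()
        xh[0, 0, 1, 2] = 1.0
        L, mse = frame_loglik(x, xh)
        assert float(L.data) == pytest.approx(-0.5)
        assert mse == pytest.approx(1.0 / 16)

    def test_matches_naive_loop(self):
        x = rng.uniform(size=(4, 1, 3, 3))
        xh = rng.uniform(size=(4, 1, 3, 3))
        L, _ = frame_loglik(x, xh)
        naive = -0.5 * sum((x[b, c, i, j] - xh[b, c, i, j]) ** 2
                           for b in range(4) for c in range(1)
                           for i in range(3) for j in range(3)) / 4
        assert float(L.data) == pytest.approx(naive, abs=1e-6)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shapes"):
            frame_loglik(np.zeros((2, 1, 4, 4)), np.zeros((2, 1, 4, 5)))


class TestMaskedLabelLoglik:
    def test_perfect_fit_is_zero(self):
        y = rng.normal(size=(5, 4))
        L, _ = label_loglik_masked(y, y.copy(), np.ones((5, 4)))
        assert float(L.data) == 0.0

    def test_masked_entries_are_ignored_exactly(self):
        y = rng.normal(size=(5, 4))
        yh = rng.normal(size=(5, 4))
        likes = np.ones((5, 4))
        likes[2, 1] = 0.5
        L1, _ = label_loglik_masked(y, yh, likes)
        y2 = y.copy()
        y2[2, 1] = 1e6  # arbitrary change below threshold
        L2, _ = label_loglik_masked(y2, yh, likes)
        assert float(L1.data) == float(L2.data)

    def test_masked_gradient_is_exactly_zero(self):
        y = rng.normal(size=(3, 2))
        yh = Tensor(rng.normal(size=(3, 2)), requires_grad=True)
        likes = np.ones((3, 2))
        likes[1, 0] = 0.1
        L, _ = label_loglik_masked(y, yh, likes)
        L.backward()
        assert yh.grad[1, 0] == 0.0
        assert np.all(yh.grad[likes >= 0.9] != 0.0)

    def test_matches_naive_masked_loop(self):
        y = rng.normal(size=(6, 4))
        yh = rng.normal(size=(6, 4))
        likes = rng.uniform(size=(6, 4))
        L, _ = label_loglik_masked(y, yh, likes, threshold=0.6)
        naive = -0.5 * sum((y[t, d] - yh[t, d]) ** 2
                           for t in range(6) for d in range(4)
                           if likes[t, d] >= 0.6) / 6
        assert float(L.data) == pytest.approx(naive, abs=1e-6)


# ---------------------------------------------------------------------------
# KL terms
# ---------------------------------------------------------------------------

class TestSupervisedKL:
    def test_standard_normal_posterior_is_zero(self):
        assert float(kl_supervised(np.zeros((3, 2)), np.zeros((3, 2))).data) == 0.0

    def test_unit_mean_spot_value(self):
        kl = kl_supervised(np.ones((1, 1)), np.zeros((1, 1)))
        assert float(kl.data) == pytest.approx(0.5)

    def test_matches_naive_formula_loop(self):
        mean = rng.normal(size=(4, 3))
        logvar = rng.normal(size=(4, 3))
        kl = kl_supervised(mean, logvar)
        naive = np.mean([sum(0.5 * (mean[b, d] ** 2 + math.exp(logvar[b, d])
                                    - 1.0 - logvar[b, d]) for d in range(3))
                         for b in range(4)])
        assert float(kl.data) == pytest.approx(naive, abs=1e-6)


class TestKLDecomposition:
    def _random_batch(self, M, L):
        mean = rng.normal(size=(M, L))
        logvar = rng.normal(scale=0.5, size=(M, L))
        z = mean + np.exp(logvar / 2) * rng.standard_normal((M, L))
        return z, mean, logvar

    def test_cancellation_identity(self):
        z, mean, logvar = self._random_batch(8, 3)
        icmi, tc, dwkl = kl_unsup_decomposition(z, mean, logvar, 100)
        direct = np.mean([
            sum(_gauss_logpdf(z[i, l], mean[i, l], math.exp(logvar[i, l]))
                - _gauss_logpdf(z[i, l], 0, 1) for l in range(3))
            for i in range(8)])
        assert float((icmi + tc + dwkl).data) == pytest.approx(direct, abs=1e-6)

    def test_single_sample_icmi_is_log_N(self):
        z, mean, logvar = self._random_batch(1, 4)
        icmi, _, _ = kl_unsup_decomposition(z, mean, logvar, 777)
        assert float(icmi.data) == pytest.approx(math.log(777), abs=1e-9)

    def test_one_dimensional_tc_is_exactly_zero(self):
        z, mean, logvar = self._random_batch(6, 1)
        _, tc, _ = kl_unsup_decomposition(z, mean, logvar, 50)
        assert float(tc.data) == 0.0

    def test_matches_naive_double_loop(self):
        z, mean, logvar = self._random_batch(8, 3)
        icmi, tc, dwkl = kl_unsup_decomposition(z, mean, logvar, 64)
        n_icmi, n_tc, n_dwkl = naive_decomposition(z, mean, logvar, 64)
        assert float(icmi.data) == pytest.approx(n_icmi, abs=1e-6)
        assert float(tc.data) == pytest.approx(n_tc, abs=1e-6)
        assert float(dwkl.data) == pytest.approx(n_dwkl, abs=1e-6)

    def test_dataset_smaller_than_batch_rejected(self):
        z, mean, logvar = self._random_batch(8, 2)
        with pytest.raises(ValueError, match="N"):
            kl_unsup_decomposition(z, mean, logvar, 4)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(lv=st.floats(-20, 20), seed=st.integers(0, 1000))
    def test_estimators_finite_for_extreme_logvariances(self, lv, seed):
        r = np.random.default_rng(seed)
        mean = r.normal(size=(5, 2))
        logvar = np.full((5, 2), lv)
        z = mean + np.exp(logvar / 2) * r.standard_normal((5, 2))
        terms = kl_unsup_decomposition(z, mean, logvar, 10)
        for t in terms:
            assert np.isfinite(t.data)

    def test_full_batch_sum_estimates_closed_form_kl(self):
        # with M = N, (1/M) sum_i [log q(z_i|n_i) - log p(z_i)] is an unbiased
        # one-sample estimate of E KL(q || p); average over repeated draws
        r = np.random.default_rng(0)
        M = 64
        mean = r.normal(size=(M, 2))
        logvar = r.normal(scale=0.3, size=(M, 2))
        closed = float(kl_supervised(mean, logvar).data)
        draws = []
        for _ in range(200):
            z = mean + np.exp(logvar / 2) * r.standard_normal((M, 2))
            terms = kl_unsup_decomposition(z, mean, logvar, M)
            draws.append(float(sum(t.data for t in terms)))
        se = np.std(draws) / np.sqrt(len(draws))
        assert abs(np.mean(draws) - closed) < 5 * se + 1e-3


# ---------------------------------------------------------------------------
# penalties
# ---------------------------------------------------------------------------

class TestOrthPenalty:
    def test_orthonormal_rows_give_zero(self):
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        assert float(orth_penalty(q[:4]).data) == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_row_spot_value(self):
        U = np.array([[1.0, 0.0], [1.0, 0.0]])
        assert float(orth_penalty(U).data) == pytest.approx(2.0)

    def test_matches_naive_triple_loop(self):
        U = rng.normal(size=(4, 7))
        assert float(orth_penalty(U).data) == pytest.approx(naive_orth(U), rel=1e-9)


class TestTriplet:
    def test_satisfied_margin_is_zero(self):
        a = np.array([0.0, 0.0])
        p = np.array([0.5, 0.0])   # d(a,p) = 0.5
        n = np.array([2.0, 0.0])   # d(a,n) = 2.0
        assert float(triplet_term(a, p, n, 1.0).data) == pytest.approx(0.0)

    def test_degenerate_triplet_equals_margin(self):
        a = np.array([1.0, 2.0])
        assert float(triplet_term(a, a, a, 1.0).data) == pytest.approx(1.0, abs=1e-5)

    def test_aggregate_matches_naive_and_is_symmetric(self):
        zk = rng.normal(size=(9, 3))
        zj = rng.normal(size=(9, 3))
        agg = float(aggregate_triplet(zk, zj, 1.0).data)
        assert agg == pytest.approx(naive_triplet(zk, zj, 1.0), abs=1e-6)
        assert agg == pytest.approx(float(aggregate_triplet(zj, zk, 1.0).data),
                                    abs=1e-9)

    def test_same_session_and_indivisible_batches_rejected(self):
        z = rng.normal(size=(9, 2))
        with pytest.raises(ValueError, match="different sessions"):
            aggregate_triplet(z, z, session_k="S0", session_j="S0")
        with pytest.raises(ValueError, match="divisible"):
            aggregate_triplet(rng.normal(size=(8, 2)), rng.normal(size=(8, 2)))


# ---------------------------------------------------------------------------
# total objective
# ---------------------------------------------------------------------------

class TestTotalObjective:
    def _terms(self):
        return {k: Tensor(np.asarray(v)) for k, v in
                [("frames", -3.0), ("labels", -1.2), ("kl_s", 0.7),
                 ("icmi", 2.1), ("tc", 0.4), ("dwkl", 0.9), ("orth", 0.05)]}

    def test_total_recomputable_from_parts(self):
        total, bd = total_objective(self._terms(), "ps-vae", alpha=1000,
                                    beta=5, gamma=500, anneal=0.7)
        assert bd.recompute_total() == pytest.approx(float(total.data), abs=1e-9)

    def test_reduces_to_beta_tc_vae(self):
        terms = self._terms()
        total, _ = total_objective(
            {k: terms[k] for k in ("frames", "icmi", "tc", "dwkl")},
            "beta-tc-vae", beta=5.0, anneal=1.0)
        expected = -3.0 - 2.1 - 5.0 * 0.4 - 0.9
        assert float(total.data) == pytest.approx(expected)

    def test_epoch_zero_annealing_keeps_only_likelihood_terms(self):
        total, _ = total_objective(self._terms(), "ps-vae", alpha=1000,
                                   beta=5, gamma=500, anneal=0.0)
        expected = -3.0 + 1000 * (-1.2) - 500 * 0.05
        assert float(total.data) == pytest.approx(expected)

    def test_missing_term_for_variant_raises(self):
        terms = self._terms()
        del terms["orth"]
        with pytest.raises(ValueError, match="orth"):
            total_objective(terms, "ps-vae")
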