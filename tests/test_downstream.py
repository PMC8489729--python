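"""Post-hoc decoding, ARHMM segmentation, motion energy, neural decoding."""
import numpy as np
import pytest

from psvae.downstream import (RIDGE_GRID, DecoderSpec, arhmm_states,
                              finetune_frame_decoder, fit_arhmm,
                              motion_energy, neural_decode,
                              posthoc_label_regression, simulate_arhmm,
                              state_overlap)

rng = np.random.default_rng(11)


def _split_map(n, n_test=2):
    # simple trial split helper for decoding tests
    return {i: ("test" if i >= n - n_test else
                "val" if i == n - n_test - 1 else "train")
            for i in range(n)}


class TestPosthocRegression:
    def _trials(self, n=10, T=40, d=5, k=3, noise=0.0):
        W = rng.normal(size=(d, k))
        latents = [rng.normal(size=(T, d)) for _ in range(n)]
        labels = [z @ W + noise * rng.normal(size=(T, k)) for z in latents]
        return latents, labels

    def test_linear_map_is_recovered(self):
        latents, labels = self._trials()
        res = posthoc_label_regression(latents, labels, _split_map(10),
                                       kind="ridge", n_bootstrap=100)
        assert res["r2_mean"] >= 0.999

    def test_independent_noise_labels_score_near_zero(self):
        latents = [rng.normal(size=(40, 5)) for _ in range(10)]
        labels = [rng.normal(size=(40, 3)) for _ in range(10)]
        res = posthoc_label_regression(latents, labels, _split_map(10),
                                       kind="ridge", n_bootstrap=100)
        assert res["r2_mean"] <= 0.1

    def test_protocol_grid_and_folds(self):
        assert RIDGE_GRID == (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0, 10000.0,
                              100000.0)
        latents, labels = self._trials(n=6)
        with pytest.raises(ValueError, match="folds"):
            # only 4 training trials -> cannot form the 5 folds
            posthoc_label_regression(latents, labels, _split_map(6),
                                     kind="ridge")

    def test_mlp_variant_runs(self):
        latents, labels = self._trials(n=10, T=30)
        res = posthoc_label_regression(latents, labels, _split_map(10),
                                       kind="mlp", grid=(0.01, 1.0),
                                       n_bootstrap=50, mlp_max_iter=200)
        assert np.isfinite(res["r2_mean"])

    def test_unknown_kind_rejected(self):
        latents, labels = self._trials()
        with pytest.raises(ValueError, match="kind"):
            posthoc_label_regression(latents, labels, _split_map(10),
                                     kind="forest")


def _two_state_system():
    th = 0.15
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    A = np.stack([0.99 * R, 0.6 * np.eye(2)])
    b = np.zeros((2, 2))
    cov = np.stack([0.01 * np.eye(2), 0.2 * np.eye(2)])
    trans = np.array([[0.98, 0.02], [0.02, 0.98]])
    return A, b, cov, trans


class TestARHMM:
    def test_single_state_matches_closed_form_ar_fit(self):
        A, b, cov, trans = _two_state_system()
        x, _ = simulate_arhmm(400, A, b, cov, trans, seed=0)
        fit = fit_arhmm(x, n_states=1, n_restarts=1, n_iter=5, seed=0)
        # direct least-squares Gaussian AR(1) fit
        X = np.concatenate([x[:-1], np.ones((len(x) - 1, 1))], axis=1)
        coef, *_ = np.linalg.lstsq(X, x[1:], rcond=None)
        resid = x[1:] - X @ coef
        covd = resid.T @ resid / len(resid)
        _, logdet = np.linalg.slogdet(covd)
        quad = np.einsum("ti,ij,tj->t", resid, np.linalg.inv(covd), resid)
        ll = float(np.sum(-0.5 * (2 * np.log(2 * np.pi) + logdet + quad)))
        assert fit.train_ll == pytest.approx(ll, abs=1e-4)

    def test_em_loglik_is_monotone(self):
        A, b, cov, trans = _two_state_system()
        x, _ = simulate_arhmm(500, A, b, cov, trans, seed=1)
        fit = fit_arhmm(x, n_states=2, n_restarts=2, n_iter=60, seed=1)
        assert np.all(np.diff(fit.log_likelihoods) >= -1e-6)

    def test_recovers_simulated_states_on_held_out_data(self):
        A, b, cov, trans = _two_state_system()
        x_tr, _ = simulate_arhmm(800, A, b, cov, trans, seed=2)
        x_te, z_te = simulate_arhmm(800, A, b, cov, trans, seed=3)
        fit = fit_arhmm(x_tr, n_states=2, n_restarts=3, n_iter=80, seed=0)
        acc, conf = state_overlap(z_te[1:], arhmm_states(fit, x_te))
        assert acc >= 95.0
        assert conf.sum() == len(z_te) - 1

    def test_fit_is_deterministic_given_seed(self):
        A, b, cov, trans = _two_state_system()
        x, _ = simulate_arhmm(300, A, b, cov, trans, seed=4)
        f1 = fit_arhmm(x, n_states=2, n_restarts=2, n_iter=30, seed=9)
        f2 = fit_arhmm(x, n_states=2, n_restarts=2, n_iter=30, seed=9)
        np.testing.assert_array_equal(f1.states, f2.states)
        assert f1.train_ll == f2.train_ll

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_arhmm(np.ones((100, 2)), n_states=2)
        with pytest.raises(ValueError, match="time"):
            fit_arhmm(np.zeros((5, 2)), n_states=2)

    def test_transition_rows_sum_to_one(self):
        A, b, cov, trans = _two_state_system()
        x, _ = simulate_arhmm(300, A, b, cov, trans, seed=5)
        fit = fit_arhmm(x, n_states=2, n_restarts=1, n_iter=20, seed=0)
        np.testing.assert_allclose(fit.transitions.sum(axis=1), 1.0, atol=1e-9)


class TestStateOverlap:
    def test_identical_sequences(self):
        s = rng.integers(2, size=500)
        acc, _ = state_overlap(s, s)
        assert acc == 100.0

    def test_globally_flipped_binary_sequences(self):
        s = rng.integers(2, size=500)
        acc, _ = state_overlap(s, 1 - s)
        assert acc == 100.0

    def test_independent_binary_sequences_score_50_to_55(self):
        r = np.random.default_rng(0)
        a = r.integers(2, size=10_000)
        b = r.integers(2, size=10_000)
        acc, _ = state_overlap(a, b)
        # permutation alignment picks the better of the two labelings
        assert 50.0 <= acc <= 55.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            state_overlap([0, 1], [0, 1, 0])

    def test_many_state_alignment_uses_assignment(self):
        s = rng.integers(6, size=1000)
        perm = np.array([3, 5, 0, 1, 4, 2])
        acc, _ = state_overlap(s, perm[s])
        assert acc == 100.0


class TestMotionEnergy:
    def test_constant_trace_is_zero(self):
        assert np.all(motion_energy(np.full((10, 3), 2.5)) == 0)

    def test_ramp_has_constant_slope_energy(self):
        ramp = np.arange(0, 20, 2.0)[:, None]
        me = motion_energy(ramp)
        assert me[0, 0] == 0.0
        np.testing.assert_array_equal(me[1:, 0], 2.0)

    def test_matches_naive_loop(self):
        x = rng.normal(size=(50, 4))
        me = motion_energy(x)
        for t in range(1, 50):
            for d in range(4):
                assert me[t, d] == abs(x[t, d] - x[t - 1, d])


class TestNeuralDecode:
    def _linear_case(self, n_trials=8, T=100, n_neurons=8, n_latents=2, lag=2):
        W = rng.normal(size=((2 * lag + 1) * n_neurons, n_latents)) * 0.3
        neural, latents = [], []
        for _ in range(n_trials):
            u = rng.normal(size=(T, n_neurons))
            padded = np.pad(u, ((lag, lag), (0, 0)))
            X = np.stack([padded[t:t + 2 * lag + 1].ravel() for t in range(T)])
            latents.append(X @ W)
            neural.append(u)
        return neural, latents

    def test_default_half_window_is_sixteen(self):
        assert DecoderSpec().lag == 16

    def test_realizable_linear_mapping_is_decoded(self):
        neural, latents = self._linear_case(n_trials=14)
        res = neural_decode(neural, latents, _split_map(14),
                            specs=[DecoderSpec(hidden_layers=1,
                                               hidden_units=64, lag=2,
                                               learning_rate=3e-3,
                                               max_epochs=400)], seed=0)
        assert res["r2_mean"] >= 0.95

    def test_independent_latents_score_near_zero(self):
        neural, _ = self._linear_case()
        latents = [rng.normal(size=(100, 2)) for _ in range(8)]
        res = neural_decode(neural, latents, _split_map(8),
                            specs=[DecoderSpec(hidden_layers=1,
                                               hidden_units=16, lag=2,
                                               max_epochs=40)], seed=0)
        assert res["r2_mean"] <= 0.1

    def test_too_short_trials_rejected(self):
        neural = [rng.normal(size=(10, 4))]
        latents = [rng.normal(size=(10, 2))]
        with pytest.raises(ValueError, match="lag"):
            neural_decode(neural, latents, {0: "train"},
                          specs=[DecoderSpec(lag=16)])

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DecoderSpec(lag=-1)


class TestFinetuneDecoder:
    @pytest.fixture(scope="class")
    def trained(self):
        from psvae.model import PSVAE
        from psvae.synthgen import SceneSpec, generate_session
        from psvae.training import TrainConfig, TrialDataset, train
        trials, _ = generate_session(SceneSpec(), n_trials=10, trial_len=30,
                                     seed=6)
        ds = TrialDataset(trials)
        model = PSVAE(n_labels=4, n_unsupervised=2, channel_base=4, seed=6)
        model, _ = train(model, ds, TrainConfig(epochs=4, anneal_epochs=2,
                                                seed=6))
        from psvae.hyperopt import extract_latents
        lat = extract_latents(model, ds.trials)
        latents = [np.concatenate([d["z_s"], d["z_u"]], axis=1) for d in lat]
        frames = [t.frames for t in ds.trials]
        return model, latents, frames, ds

    def test_weight_shapes_preserved(self, trained):
        model, latents, frames, ds = trained
        tuned, _, _ = finetune_frame_decoder(
            model, latents, frames, ds.indices("train"), ds.indices("test"),
            epochs=1)
        for a, bb in zip(model.dec_dense.parameters(),
                         tuned.dec_dense.parameters()):
            assert a.data.shape == bb.data.shape

    def test_noiseless_latents_are_not_harmed(self, trained):
        # feeding the decoder the exact latents it was trained with: more
        # training from that point cannot hurt the test reconstruction
        model, latents, frames, ds = trained
        _, before, after = finetune_frame_decoder(
            model, latents, frames, ds.indices("train"), ds.indices("test"),
            epochs=5)
        assert after <= before + 1e-6

    def test_noisy_latents_benefit_from_finetuning(self, trained):
        model, latents, frames, ds = trained
        noisy = [z + np.random.default_rng(1).normal(0, 0.5, size=z.shape)
                 for z in latents]
        _, before, after = finetune_frame_decoder(
            model, noisy, frames, ds.indices("train"), ds.indices("test"),
            epochs=15, learning_rate=1e-3)
        assert after < before

    def test_dimension_mismatch_rejected(self, trained):
        model, latents, frames, ds = trained
        bad = [z[:, :3] for z in latents]
        with pytest.raises(ValueError, match="dimension"):
            finetune_frame_decoder(model, bad, frames, ds.indices("train"),
                                   ds.indices("test"))
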