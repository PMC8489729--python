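"""Annealing schedule, session pairing, and end-to-end training contracts."""
import numpy as np
import pytest

from psvae.model import PSVAE
from psvae.synthgen import SceneSpec, generate_session, generate_multisession
from psvae.training import (TrainConfig, TrialDataset, anneal_weight,
                            pair_session_batches, train)


class TestAnnealWeight:
    def test_starts_at_zero(self):
        assert anneal_weight(0, 100, 5.0) == 0.0

    def test_linear_midpoint(self):
        assert anneal_weight(50, 100, 5.0) == pytest.approx(2.5)

    def test_reaches_final_value_and_saturates(self):
        assert anneal_weight(100, 100, 5.0) == 5.0
        assert anneal_weight(250, 100, 5.0) == 5.0

    def test_zero_anneal_epochs_means_constant(self):
        assert anneal_weight(0, 0, 3.0) == 3.0

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            anneal_weight(-1, 100, 1.0)


class TestSessionPairing:
    def _items(self, n_sessions, per=4):
        return {f"S{k}": list(range(per)) for k in range(n_sessions)}

    def test_pairs_have_distinct_sessions(self):
        rng = np.random.default_rng(0)
        for (sa, _), (sb, _) in pair_session_batches(self._items(2), rng):
            assert sa != sb

    def test_all_sessions_covered_each_epoch(self):
        rng = np.random.default_rng(1)
        seen = set()
        for (sa, _), (sb, _) in pair_session_batches(self._items(4), rng):
            seen.update([sa, sb])
        assert seen == {"S0", "S1", "S2", "S3"}

    def test_seeded_order_is_reproducible(self):
        p1 = list(pair_session_batches(self._items(3), np.random.default_rng(5)))
        p2 = list(pair_session_batches(self._items(3), np.random.default_rng(5)))
        assert p1 == p2

    def test_single_session_rejected(self):
        with pytest.raises(ValueError, match="2 sessions"):
            list(pair_session_batches({"S0": [1, 2]}, np.random.default_rng(0)))


class TestTrialDataset:
    def test_labels_zscored_on_training_frames_only(self, small_session):
        trials, _ = small_session
        ds = TrialDataset(trials)
        train_labels = np.concatenate(
            [ds.trials[i].labels for i in ds.indices("train")])
        np.testing.assert_allclose(train_labels.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(train_labels.std(axis=0), 1, atol=1e-9)
        # val/test use the train statistics, so they are not exactly standard
        test_labels = np.concatenate(
            [ds.trials[i].labels for i in ds.indices("test")])
        assert not np.allclose(test_labels.mean(axis=0), 0, atol=1e-12)

    def test_multisession_scaling_is_per_session(self):
        sessions = generate_multisession(SceneSpec(), n_sessions=2,
                                         per_session_trials=10, trial_len=20,
                                         seed=0)
        ds = TrialDataset([t for _, ts, _ in sessions for t in ts])
        assert set(ds.scalers) == {"S0", "S1"}
        for sid in ("S0", "S1"):
            idx = [i for i in ds.indices("train")
                   if ds.trials[i].session_id == sid]
            labels = np.concatenate([ds.trials[i].labels for i in idx])
            np.testing.assert_allclose(labels.mean(axis=0), 0, atol=1e-9)


def _tiny_setup(n_trials=6, trial_len=30, seed=0, **spec_kw):
    trials, _ = generate_session(SceneSpec(**spec_kw), n_trials=n_trials,
                                 trial_len=trial_len, seed=seed)
    ds = TrialDataset(trials)
    model = PSVAE(n_labels=4, n_unsupervised=2, channel_base=4, seed=seed)
    return ds, model


class TestTrain:
    def test_same_seed_gives_identical_histories(self):
        cfg = TrainConfig(epochs=2, anneal_epochs=1, seed=3)
        histories = []
        for _ in range(2):
            ds, model = _tiny_setup()
            _, h = train(model, ds, cfg)
            histories.append([(e["train"].frames, e["train"].weighted_total)
                              for e in h])
        assert histories[0] == histories[1]

    def test_perturbing_masked_labels_leaves_history_bitwise_unchanged(self):
        cfg = TrainConfig(epochs=2, anneal_epochs=1, seed=1)
        ds1, model1 = _tiny_setup(n_trials=10, dropout_rate=0.3, seed=7)
        _, h1 = train(model1, ds1, cfg)

        ds2, model2 = _tiny_setup(n_trials=10, dropout_rate=0.3, seed=7)
        for t in ds2.trials:
            below = t.likelihoods < cfg.likelihood_threshold
            assert below.any()
            t.labels[below] = 1e4  # arbitrary garbage in masked entries
        _, h2 = train(model2, ds2, cfg)

        for e1, e2 in zip(h1, h2):
            for split in ("train", "val"):
                b1, b2 = e1[split], e2[split]
                for term in ("frames", "labels", "kl_s", "icmi", "tc", "dwkl",
                             "orth", "weighted_total"):
                    assert getattr(b1, term) == getattr(b2, term)

    def test_reconstruction_improves_over_training(self):
        ds, model = _tiny_setup(n_trials=8, trial_len=40)
        cfg = TrainConfig(epochs=20, anneal_epochs=10, seed=0)
        _, h = train(model, ds, cfg)
        assert h[19]["train"].mse_per_pixel < h[0]["train"].mse_per_pixel

    def test_nonfinite_loss_aborts_with_term_names(self):
        ds, model = _tiny_setup()
        for p in model.parameters():
            p.data = np.full_like(p.data, 1e30)
        cfg = TrainConfig(epochs=1, anneal_epochs=1, seed=0)
        with pytest.raises(FloatingPointError, match="epoch 0"):
            train(model, ds, cfg)

    def test_msps_needs_multiple_sessions(self):
        ds, _ = _tiny_setup()
        model = PSVAE(n_labels=4, n_unsupervised=2, n_background=3,
                      variant="msps-vae", channel_base=4, seed=0)
        cfg = TrainConfig(variant="msps-vae", epochs=1, anneal_epochs=1, seed=0)
        with pytest.raises(ValueError, match="sessions"):
            train(model, ds, cfg)

    def test_msps_smoke_run_with_triplet_term(self):
        sessions = generate_multisession(SceneSpec(), n_sessions=2,
                                         per_session_trials=10, trial_len=21,
                                         seed=0)
        ds = TrialDataset([t for _, ts, _ in sessions for t in ts])
        model = PSVAE(n_labels=4, n_unsupervised=2, n_background=3,
                      variant="msps-vae", channel_base=4, seed=0)
        cfg = TrainConfig(variant="msps-vae", epochs=2, anneal_epochs=1,
                          delta=50.0, seed=0)
        _, h = train(model, ds, cfg)
        assert np.isfinite(h[-1]["train"].triplet)
        # frozen subspace basis stays orthonormal after training steps
        basis = model.maps.full_basis()
        np.testing.assert_allclose(basis @ basis.T, np.eye(len(basis)),
                                   atol=1e-5)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(epochs=10, anneal_epochs=20)
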