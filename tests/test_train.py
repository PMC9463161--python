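"""Mini-batch pairing, optimization loops, convergence, determinism."""

import numpy as np
import pytest

import gaitgan as gg
from gaitgan.losses import LossWeights
from gaitgan.train import _pairing_index


TINY = dict(batch_pairs=8, dev_subject_count=2, seed=5)


class TestSplitDev:
    def test_subject_level_disjointness(self, small_examples, rng):
        train, dev = gg.split_dev(small_examples, 2, rng)
        assert set(train.meta.subject_id) & set(dev.meta.subject_id) == set()
        assert len(set(dev.meta.subject_id)) == 2
        assert len(train) + len(dev) == len(small_examples)

    def test_dev_zero_keeps_everything(self, small_examples, rng):
        train, dev = gg.split_dev(small_examples, 0, rng)
        assert len(dev) == 0 and len(train) == len(small_examples)

    def test_same_seed_same_split(self, small_examples):
        a = gg.split_dev(small_examples, 2, np.random.default_rng(3))
        b = gg.split_dev(small_examples, 2, np.random.default_rng(3))
        assert a[1].meta.subject_id.tolist() == b[1].meta.subject_id.tolist()

    def test_too_few_subjects_rejected(self, small_examples, rng):
        with pytest.raises(ValueError, match="subjects"):
            gg.split_dev(small_examples, len(small_examples.subjects), rng)


class TestSamplePairedBatch:
    def test_batch_size_is_twice_pairs(self, small_examples, rng):
        batch = gg.sample_paired_batch(small_examples, 7, rng)
        assert len(batch) == 14
        assert batch.x.shape == (14, 3, 384)

    def test_single_pair_same_subject_different_visits(self, small_examples, rng):
        batch = gg.sample_paired_batch(small_examples, 1, rng)
        assert len(batch) == 2
        assert batch.subject_ids[0] == batch.subject_ids[1]
        assert batch.visit_ids[0] != batch.visit_ids[1]

    def test_pairing_involution_and_visit_order(self, small_examples, rng):
        batch = gg.sample_paired_batch(small_examples, 20, rng)
        n = len(batch)
        np.testing.assert_array_equal(batch.pair_index[batch.pair_index],
                                      np.arange(n))
        assert np.all(batch.visit_order + batch.visit_order[batch.pair_index] == 1)

    def test_single_visit_subject_rejected(self, small_examples):
        one_visit = small_examples.subset(
            (small_examples.meta.visit_id == "V0").to_numpy())
        with pytest.raises(ValueError, match="2 visits"):
            _pairing_index(one_visit)


class TestCheckConvergence:
    def test_constant_trace_converged(self):
        assert gg.check_convergence([3.0] * 25, window=20)

    def test_geometric_decay_not_converged(self):
        trace = [100.0 * 0.9 ** i for i in range(50)]
        assert not gg.check_convergence(trace, window=40)

    def test_flat_tail_within_tolerance(self):
        trace = [100.0 / (1 + i) for i in range(80)] + [1.0, 1.005, 0.995] * 7
        assert gg.check_convergence(trace, window=20, tol=0.05)

    def test_short_trace_not_converged(self):
        assert not gg.check_convergence([1.0] * 5, window=20)

    def test_trace_range_reference(self):
        trace = [100.0] + [1.0 + 0.01 * (i % 3) for i in range(30)]
        assert gg.check_convergence(trace, 20, tol=0.05,
                                    relative_to="trace_range")


class TestTrainCnn:
    def test_loss_decreases_on_tiny_cohort(self, small_examples):
        cfg = gg.TrainConfig(mode="cnn", epochs=30, **TINY)
        state = gg.train_cnn(cfg, small_examples)
        tr = np.array(state.traces["train_loss"])
        smooth = np.convolve(tr, np.ones(5) / 5, mode="valid")
        assert smooth[15] < smooth[0]
        assert state.traces["dev_mse"][-1] < state.traces["dev_mse"][0]

    def test_seed_determinism(self, small_examples):
        cfg = gg.TrainConfig(mode="cnn", epochs=3, **TINY)
        a = gg.train_cnn(cfg, small_examples)
        b = gg.train_cnn(cfg, small_examples)
        for k in a.discriminator.params:
            np.testing.assert_array_equal(a.discriminator.params[k],
                                          b.discriminator.params[k])
        assert a.traces == b.traces

    def test_wrong_mode_rejected(self, small_examples):
        with pytest.raises(ValueError, match="mode"):
            gg.train_cnn(gg.TrainConfig(mode="gan"), small_examples)

    def test_dev_subjects_stay_fixed(self, small_examples):
        cfg = gg.TrainConfig(mode="cnn", epochs=2, **TINY)
        state = gg.train_cnn(cfg, small_examples)
        train_subjects = set(small_examples.subjects) - set(state.dev_subjects)
        assert len(state.dev_subjects) == 2
        assert len(train_subjects) == len(small_examples.subjects) - 2


class TestTrainGan:
    def test_delta_zero_reproduces_cnn_trajectory(self, small_examples):
        """With no adversarial term the discriminator's updates must equal
        plain CNN training step for step (matched random streams)."""
        gan_cfg = gg.TrainConfig(mode="gan", epochs=4,
                                 weights=LossWeights(1, 1, 1, 0), **TINY)
        cnn_cfg = gg.TrainConfig(mode="cnn", epochs=4,
                                 weights=LossWeights(1, 1, 1, 0), **TINY)
        g = gg.train_gan(gan_cfg, small_examples)
        c = gg.train_cnn(cnn_cfg, small_examples)
        for k in c.discriminator.params:
            np.testing.assert_array_equal(g.discriminator.params[k],
                                          c.discriminator.params[k])
        assert g.traces["dev_mse"] == c.traces["dev_mse"]

    def test_generator_improves_against_discriminator(self, small_examples):
        """After training, fakes fool the discriminator more than at init."""
        cfg = gg.TrainConfig(mode="gan", epochs=8, **TINY)
        rngs = np.random.SeedSequence(cfg.seed).spawn(10)
        init_gen = gg.Generator(np.random.default_rng(rngs[2]))
        state = gg.train_gan(cfg, small_examples)
        noise = gg.sample_noise(64, np.random.default_rng(99))
        _, d_init = state.discriminator.forward(init_gen.forward(noise))
        _, d_trained = state.discriminator.forward(state.generator.forward(noise))
        assert d_trained.mean() > d_init.mean()

    def test_seed_determinism(self, small_examples):
        cfg = gg.TrainConfig(mode="gan", epochs=2, **TINY)
        a = gg.train_gan(cfg, small_examples)
        b = gg.train_gan(cfg, small_examples)
        for k in a.generator.params:
            np.testing.assert_array_equal(a.generator.params[k],
                                          b.generator.params[k])
        assert a.traces == b.traces

    def test_records_all_traces(self, small_examples):
        cfg = gg.TrainConfig(mode="gan", epochs=3, **TINY)
        state = gg.train_gan(cfg, small_examples)
        for key in ("train_loss", "loss_disc", "loss_gen", "dev_mse"):
            assert len(state.traces[key]) == 3


class TestAdam:
    def test_matches_reference_formula_on_scalar(self):
        """One-parameter Adam against the published update rule."""
        params = {"w": np.array([1.0])}
        opt = gg.Adam(params, lr=0.1, beta1=0.9, beta2=0.999, eps=1e-8)
        g = 0.5
        opt.step(params, {"w": np.array([g])})
        m = 0.1 * g
        v = 0.001 * g * g
        expected = 1.0 - 0.1 * (m / 0.1) / (np.sqrt(v / 0.001) + 1e-8)
        np.testing.assert_allclose(params["w"], [expected], rtol=1e-6)

    def test_zero_gradient_no_update(self):
        params = {"w": np.arange(5, dtype=float)}
        opt = gg.Adam(params, lr=0.1)
        opt.step(params, {"w": np.zeros(5)})
        np.testing.assert_allclose(params["w"], np.arange(5), atol=1e-12)


class TestCheckpoint:
    def test_round_trip_preserves_params(self, small_examples, tmp_path):
        cfg = gg.TrainConfig(mode="gan", epochs=1, **TINY)
        state = gg.train_gan(cfg, small_examples)
        path = tmp_path / "ckpt.npz"
        gg.save_checkpoint(state, path)
        disc, gen, header = gg.load_checkpoint(path)
        assert header["mode"] == "gan" and header["seed"] == 5
        for k in state.discriminator.params:
            np.testing.assert_array_equal(disc.params[k],
                                          state.discriminator.params[k])
        for k in state.generator.params:
            np.testing.assert_array_equal(gen.params[k],
                                          state.generator.params[k])

    def test_corrupted_architecture_detected(self, small_examples, tmp_path):
        cfg = gg.TrainConfig(mode="cnn", epochs=1, **TINY)
        state = gg.train_cnn(cfg, small_examples)
        path = tmp_path / "ckpt.npz"
        gg.save_checkpoint(state, path)
        import numpy as _np, json as _json
        data = dict(_np.load(path))
        header = _json.loads(bytes(data["__header__"]).decode())
        header["disc_hash"] = "0" * 16
        data["__header__"] = _np.frombuffer(_json.dumps(header).encode(),
                                            dtype=_np.uint8)
        _np.savez(path, **data)
        with pytest.raises(ValueError, match="hash"):
            gg.load_checkpoint(path)
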