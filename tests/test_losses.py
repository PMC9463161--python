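"""Loss definitions vs. independent double-loop oracles and hand values."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gaitgan as gg
from gaitgan.losses import (HistoricalAverage, LossWeights,
                            historical_average_penalty, loss_disc_grad,
                            loss_gen_grad, loss_train_grad)
from conftest import random_paired_batch


# ---------------------------------------------------------------------------
# Independent oracles: explicit loops, no vectorization shared with the
# implementation.

def oracle_loss_train(batch, alpha, beta):
    n = len(batch)
    t1 = sum((batch.preds[i] - batch.truths[i]) ** 2 for i in range(n)) / n
    t2 = 0.0
    for i in range(n):
        j = batch.pair_index[i]
        if batch.visit_order[i] == 0:
            y1, y2 = batch.preds[i], batch.preds[j]
            t1_, t2_ = batch.truths[i], batch.truths[j]
        else:
            y1, y2 = batch.preds[j], batch.preds[i]
            t1_, t2_ = batch.truths[j], batch.truths[i]
        t2 += ((y1 - y2) - (t1_ - t2_)) ** 2
    return alpha * t1 + beta * t2 / n


def oracle_loss_disc(batch, d_real, d_fake, w):
    n = len(d_real)
    adv = (sum((d_real[i] - 1) ** 2 for i in range(n)) / n
           + sum(d_fake[i] ** 2 for i in range(n)) / n)
    return w.gamma * oracle_loss_train(batch, w.alpha, w.beta) + w.delta * adv


def oracle_loss_gen(d_fake):
    return sum((d - 1) ** 2 for d in d_fake) / len(d_fake)


def oracle_hist_penalty(cur, avg, coef):
    total = 0.0
    for k in cur:
        for c, a in zip(cur[k].ravel(), avg[k].ravel()):
            total += (float(c) - float(a)) ** 2
    return coef * total


class TestLossTrainHandValues:
    def test_perfect_predictions_give_zero(self, rng):
        b = random_paired_batch(5, rng)
        b.preds = b.truths.copy()
        assert gg.loss_train(b, alpha=2.0, beta=3.0) == 0.0

    def test_alpha_term_hand_value(self):
        """One pair, preds (2,1) vs truths (0,0): (4+1)/2 = 2.5."""
        b = gg.PairedBatch(truths=np.array([0.0, 0.0]),
                           pair_index=np.array([1, 0]),
                           visit_order=np.array([0, 1]),
                           preds=np.array([2.0, 1.0]))
        assert gg.loss_train(b, alpha=1.0, beta=0.0) == pytest.approx(2.5)

    def test_both_terms_hand_value(self):
        """preds (3,1), truths (2,2): MSE term 1, pair-difference term 4."""
        b = gg.PairedBatch(truths=np.array([2.0, 2.0]),
                           pair_index=np.array([1, 0]),
                           visit_order=np.array([0, 1]),
                           preds=np.array([3.0, 1.0]))
        assert gg.loss_train(b, alpha=1.0, beta=1.0) == pytest.approx(5.0)
        assert oracle_loss_train(b, 1.0, 1.0) == pytest.approx(5.0)

    def test_odd_batch_rejected(self):
        with pytest.raises(ValueError, match="even"):
            gg.PairedBatch(truths=np.zeros(3), pair_index=np.array([1, 0, 2]),
                           visit_order=np.array([0, 1, 0]))

    def test_broken_involution_rejected(self):
        with pytest.raises(ValueError, match="involution"):
            gg.PairedBatch(truths=np.zeros(4), pair_index=np.array([1, 0, 0, 2]),
                           visit_order=np.array([0, 1, 0, 1]))


class TestLossDiscHandValues:
    def test_gamma_only_reduces_to_loss_train(self, rng):
        b = random_paired_batch(4, rng)
        w = LossWeights(alpha=1.0, beta=1.0, gamma=1.0, delta=0.0)
        d = rng.uniform(0.1, 0.9, size=len(b))
        assert gg.loss_disc(b, d, d, w) == pytest.approx(
            gg.loss_train(b, 1.0, 1.0), abs=1e-12)

    def test_adversarial_optimum_is_zero(self, rng):
        b = random_paired_batch(2, rng)
        b.preds = b.truths.copy()
        w = LossWeights(gamma=0.0, delta=1.0)
        assert gg.loss_disc(b, np.ones(4), np.zeros(4), w) == 0.0

    def test_half_half_hand_value(self, rng):
        """d_real = d_fake = 0.5 with delta=1: 0.25 + 0.25 = 0.5."""
        b = random_paired_batch(1, rng)
        b.preds = b.truths.copy()
        w = LossWeights(gamma=0.0, delta=1.0)
        assert gg.loss_disc(b, np.array([0.5, 0.5]), np.array([0.5, 0.5]), w) \
            == pytest.approx(0.5)

    def test_length_mismatch_rejected(self, rng):
        b = random_paired_batch(2, rng)
        with pytest.raises(ValueError, match="d_real|d_fake"):
            gg.loss_disc(b, np.full(3, 0.5), np.full(4, 0.5), LossWeights())


class TestLossGenHandValues:
    @pytest.mark.parametrize("d_fake,expected", [
        (np.ones(5), 0.0),
        (np.zeros(5), 1.0),
        (np.array([0.5, 0.5]), 0.25),
    ])
    def test_hand_values(self, d_fake, expected):
        assert gg.loss_gen(d_fake) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gg.loss_gen(np.array([]))


class TestHistoricalAveraging:
    def test_zero_at_average(self, rng):
        params = {"a": rng.normal(size=(3, 3)), "b": rng.normal(size=4)}
        avg = {k: v.copy() for k, v in params.items()}
        assert historical_average_penalty(params, avg, 1e-3) == 0.0

    def test_scalar_hand_value(self):
        assert historical_average_penalty(
            {"w": np.array([2.0])}, {"w": np.array([0.0])}, 1.0) == 4.0

    def test_zero_coefficient(self, rng):
        params = {"a": rng.normal(size=5)}
        avg = {"a": rng.normal(size=5)}
        assert historical_average_penalty(params, avg, 0.0) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            historical_average_penalty({"a": np.zeros(3)}, {"a": np.zeros(4)}, 1.0)

    def test_ema_update_rule(self):
        h = HistoricalAverage(decay=0.9, coefficient=1.0)
        h.initialize({"w": np.array([1.0])})
        h.update({"w": np.array([2.0])})
        np.testing.assert_allclose(h.average["w"], [1.1])


class TestOracleEquivalence:
    """Vectorized losses match loop-based oracles on random batches."""

    def test_loss_train_matches_oracle_on_many_batches(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            b = random_paired_batch(int(rng.integers(1, 33)), rng)
            alpha, beta = rng.uniform(0, 3, size=2)
            assert gg.loss_train(b, alpha, beta) == pytest.approx(
                oracle_loss_train(b, alpha, beta), abs=1e-10)

    def test_loss_disc_and_gen_match_oracles(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            b = random_paired_batch(int(rng.integers(1, 17)), rng)
            w = LossWeights(*rng.uniform(0, 2, size=4))
            d_real = rng.uniform(1e-3, 1 - 1e-3, size=len(b))
            d_fake = rng.uniform(1e-3, 1 - 1e-3, size=len(b))
            assert gg.loss_disc(b, d_real, d_fake, w) == pytest.approx(
                oracle_loss_disc(b, d_real, d_fake, w), abs=1e-10)
            assert gg.loss_gen(d_fake) == pytest.approx(
                oracle_loss_gen(d_fake), abs=1e-10)

    def test_hist_penalty_matches_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            cur = {"a": rng.normal(size=(4, 5)), "b": rng.normal(size=7)}
            avg = {"a": rng.normal(size=(4, 5)), "b": rng.normal(size=7)}
            coef = float(rng.uniform(0, 2))
            assert historical_average_penalty(cur, avg, coef) == pytest.approx(
                oracle_hist_penalty(cur, avg, coef), abs=1e-10)


class TestLossProperties:
    @given(st.integers(1, 16), st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_non_negative_and_pair_symmetric(self, n_pairs, seed):
        """loss_train >= 0 and invariant under swapping pair members."""
        rng = np.random.default_rng(seed)
        b = random_paired_batch(n_pairs, rng)
        val = gg.loss_train(b, 1.0, 1.0)
        assert val >= 0.0

        # swap each pair's two members wholesale
        perm = b.pair_index.copy()
        swapped = gg.PairedBatch(truths=b.truths[perm],
                                 pair_index=b.pair_index,
                                 visit_order=b.visit_order[perm],
                                 preds=b.preds[perm])
        assert gg.loss_train(swapped, 1.0, 1.0) == pytest.approx(val, abs=1e-10)

    def test_gradient_matches_finite_differences(self, rng):
        b = random_paired_batch(6, rng)
        _, grad = loss_train_grad(b, 1.3, 0.7)
        for i in range(len(b)):
            eps = 1e-6
            bp = b.preds.copy(); bp[i] += eps
            bm = b.preds.copy(); bm[i] -= eps
            b1 = gg.PairedBatch(b.truths, b.pair_index, b.visit_order, preds=bp)
            b2 = gg.PairedBatch(b.truths, b.pair_index, b.visit_order, preds=bm)
            fd = (gg.loss_train(b1, 1.3, 0.7) - gg.loss_train(b2, 1.3, 0.7)) / (2 * eps)
            assert grad[i] == pytest.approx(fd, abs=1e-6)

    def test_gradients_vanish_at_optima(self, rng):
        b = random_paired_batch(4, rng)
        b.preds = b.truths.copy()
        _, grad = loss_train_grad(b, 1.0, 1.0)
        np.testing.assert_allclose(grad, 0.0, atol=1e-12)

        _, _, dd_real, dd_fake = loss_disc_grad(
            b, np.ones(len(b)), np.zeros(len(b)), LossWeights(gamma=0.0))
        np.testing.assert_allclose(dd_real, 0.0)
        np.testing.assert_allclose(dd_fake, 0.0)

        _, dg = loss_gen_grad(np.ones(6))
        np.testing.assert_allclose(dg, 0.0)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=-0.1)
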