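"""Optimization loops: paired mini-batches, Adam, CNN and GAN training.

Training follows the two-visit pairing scheme: each step draws examples
uniformly from the training split and joins every one with a uniformly drawn
example from the same subject's opposite visit, giving mini-batches of
2 * batch_pairs examples.  The plain CNN minimizes the paired regression
loss with the score head only; adversarial (GAN) training alternates one
discriminator update (regression + real/fake least-squares terms) with one
generator update per step.  A fixed development split of whole subjects is
scored every epoch with an unweighted MSE; training is considered converged
once that trace is steady over a trailing window.

All randomness flows through named child streams of one seed so that CNN
and GAN runs consume real-batch randomness identically (adversarial
training with delta = 0 reproduces the CNN trajectory exactly).
"""

from __future__ import annotations

import json
import logging
import math
import pathlib
from dataclasses import dataclass, field

import numpy as np

from .losses import (HistoricalAverage, LossWeights, PairedBatch,
                     loss_disc_grad, loss_gen_grad, loss_train_grad)
from .networks import Discriminator, Generator, sample_noise
from .preprocess import ExampleSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters; defaults follow the published training recipe
    (400-example paired batches, Adam at learning rate 0.01, 100 epochs,
    alpha = beta = 1, a 10-subject development split, 20-epoch convergence
    window)."""

    mode: str = "cnn"                # "cnn" | "gan"
    batch_pairs: int = 200           # paired selections per step -> N = 400
    learning_rate: float = 0.01
    epochs: int = 100
    weights: LossWeights = field(default_factory=LossWeights)
    dev_subject_count: int = 10
    convergence_window: int = 20
    convergence_tol: float = 0.05
    hist_decay: float = 0.999
    hist_coef: float = 1e-3
    gen_l2: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.mode not in ("cnn", "gan"):
            raise ValueError("mode must be 'cnn' or 'gan'")
        if self.batch_pairs < 1:
            raise ValueError("batch_pairs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainState:
    """Everything a run produces: networks, optimizer state, loss traces."""

    config: TrainConfig
    discriminator: Discriminator
    generator: Generator | None
    traces: dict[str, list[float]]
    epoch: int
    dev_subjects: list[str]


class Adam:
    """Standard Adam over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        # Moments live in the parameter dtype: adequate precision, half the
        # memory traffic of float64 on the 6.3M-parameter discriminator.
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, p in params.items():
            g = np.asarray(grads[k], dtype=p.dtype)
            m, v = self.m[k], self.v[k]
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def split_dev(examples: ExampleSet, dev_subject_count: int,
              rng: np.random.Generator) -> tuple[ExampleSet, ExampleSet]:
    """Subject-level split: dev subjects are chosen once and removed whole."""
    subjects = examples.subjects
    if dev_subject_count < 0:
        raise ValueError("dev_subject_count must be >= 0")
    if dev_subject_count >= len(subjects) and dev_subject_count > 0:
        raise ValueError(f"need at least {dev_subject_count + 1} subjects, "
                         f"have {len(subjects)}")
    dev = sorted(rng.choice(subjects, size=dev_subject_count, replace=False).tolist())
    dev_set = set(dev)
    train_subjects = [s for s in subjects if s not in dev_set]
    return examples.for_subjects(train_subjects), examples.for_subjects(dev)


def _pairing_index(train_set: ExampleSet) -> dict[str, dict[str, np.ndarray]]:
    """subject -> visit -> example indices; validates the two-visit precondition."""
    index: dict[str, dict[str, list[int]]] = {}
    meta = train_set.meta
    for i, (sid, vid) in enumerate(zip(meta["subject_id"], meta["visit_id"])):
        index.setdefault(sid, {}).setdefault(vid, []).append(i)
    bad = [s for s, visits in index.items() if len(visits) < 2]
    if bad:
        raise ValueError(f"training subjects need examples from >= 2 visits; "
                         f"violated by {bad[:5]}")
    return {s: {v: np.asarray(ix) for v, ix in visits.items()}
            for s, visits in index.items()}


def sample_paired_batch(train_set: ExampleSet, batch_pairs: int,
                        rng: np.random.Generator,
                        index: dict | None = None) -> PairedBatch:
    """Draw ``batch_pairs`` examples and join each with a uniformly chosen
    example from the same subject's opposite visit (subjects may repeat)."""
    if index is None:
        index = _pairing_index(train_set)
    n = len(train_set)
    meta = train_set.meta
    anchors = rng.choice(n, size=batch_pairs, replace=batch_pairs > n)
    sel: list[int] = []
    for a in anchors:
        sid = meta["subject_id"].iat[int(a)]
        vid = meta["visit_id"].iat[int(a)]
        visits = index[sid]
        others = [v for v in visits if v != vid]
        partner_visit = others[rng.integers(len(others))]
        partner = int(visits[partner_visit][rng.integers(visits[partner_visit].size)])
        sel.extend((int(a), partner))
    sel_arr = np.asarray(sel)
    order = np.empty(sel_arr.size, dtype=int)
    for j in range(0, sel_arr.size, 2):
        va = meta["visit_id"].iat[sel_arr[j]]
        vb = meta["visit_id"].iat[sel_arr[j + 1]]
        order[j], order[j + 1] = (0, 1) if va < vb else (1, 0)
    pair = np.arange(sel_arr.size)
    pair[0::2] += 1
    pair[1::2] -= 1
    return PairedBatch(
        truths=train_set.labels[sel_arr],
        pair_index=pair,
        visit_order=order,
        x=train_set.logspec[sel_arr],
        subject_ids=meta["subject_id"].to_numpy()[sel_arr],
        visit_ids=meta["visit_id"].to_numpy()[sel_arr],
    )


def check_convergence(trace, window: int, tol: float = 0.05,
                      relative_to: str = "window_max") -> bool:
    """Steady-state test: the trailing ``window`` entries fluctuate by less
    than ``tol`` of the reference scale (the window's max, or the whole
    trace's range)."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < window:
        return False
    tail = trace[-window:]
    spread = tail.max() - tail.min()
    if relative_to == "window_max":
        ref = abs(tail.max())
    elif relative_to == "trace_range":
        ref = trace.max() - trace.min()
    else:
        raise ValueError("relative_to must be 'window_max' or 'trace_range'")
    if ref == 0:
        return spread == 0
    return bool(spread / ref < tol)


def _dev_mse(disc: Discriminator, dev_set: ExampleSet, batch: int = 512) -> float:
    if len(dev_set) == 0:
        return float("nan")
    preds = predict_scores(disc, dev_set, batch)
    return float(np.mean((preds - dev_set.labels) ** 2))


def predict_scores(disc: Discriminator, examples: ExampleSet,
                   batch: int = 512) -> np.ndarray:
    """Score-head predictions in inference mode (dropout off)."""
    out = []
    for i in range(0, len(examples), batch):
        scores, _ = disc.forward(examples.logspec[i:i + batch], training=False)
        out.append(scores)
    return np.concatenate(out) if out else np.zeros(0)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    names = ("split", "init_disc", "init_gen", "data", "noise",
             "drop_real", "drop_fake")
    return {name: np.random.default_rng(child)
            for name, child in zip(names, root.spawn(len(names)))}


def _prepare(config: TrainConfig, examples: ExampleSet):
    rngs = _streams(config.seed)
    train_set, dev_set = split_dev(examples, config.dev_subject_count, rngs["split"])
    index = _pairing_index(train_set)
    dtype = np.dtype(config.dtype).type
    disc = Discriminator(rngs["init_disc"], dtype=dtype)
    steps = max(1, math.ceil(len(train_set) / (2 * config.batch_pairs)))
    return rngs, train_set, dev_set, index, disc, steps


def train_cnn(config: TrainConfig, examples: ExampleSet) -> TrainState:
    """Plain supervised training of the convolutional regressor.

    The real/fake head is present but unused; only the score head receives
    gradient.  Historical averaging regularizes the parameters throughout.
    """
    if config.mode != "cnn":
        raise ValueError("config.mode must be 'cnn'")
    rngs, train_set, dev_set, index, disc, steps = _prepare(config, examples)
    opt = Adam(disc.params, config.learning_rate, config.adam_beta1,
               config.adam_beta2, config.adam_eps)
    hist = HistoricalAverage(config.hist_decay, config.hist_coef)
    hist.initialize(disc.params)
    traces: dict[str, list[float]] = {"train_loss": [], "dev_mse": []}
    w = config.weights

    for epoch in range(config.epochs):
        epoch_loss = 0.0
        for _ in range(steps):
            batch = sample_paired_batch(train_set, config.batch_pairs,
                                        rngs["data"], index)
            scores, _, cache = disc.forward(batch.x, training=True,
                                            rng=rngs["drop_real"], want_cache=True)
            batch.preds = scores.astype(float)
            value, dpred = loss_train_grad(batch, w.alpha, w.beta)
            if not np.isfinite(value):
                raise RuntimeError(f"training diverged at epoch {epoch}: "
                                   f"loss_train={value}")
            grads, _ = disc.backward(cache, dpred.astype(disc.dtype),
                                     np.zeros_like(scores))
            _add_grads(grads, hist.grad(disc.params))
            opt.step(disc.params, grads)
            hist.update(disc.params)
            epoch_loss += value
        traces["train_loss"].append(epoch_loss / steps)
        traces["dev_mse"].append(_dev_mse(disc, dev_set))
    return TrainState(config, disc, None, traces, config.epochs,
                      sorted(dev_set.meta["subject_id"].unique().tolist()))


def train_gan(config: TrainConfig, examples: ExampleSet) -> TrainState:
    """Adversarial training: one discriminator step then one generator step.

    The discriminator sees a paired real batch plus an equal-size batch of
    generated examples; the generator is then updated against the refreshed
    discriminator on the same noise draw.
    """
    if config.mode != "gan":
        raise ValueError("config.mode must be 'gan'")
    rngs, train_set, dev_set, index, disc, steps = _prepare(config, examples)
    dtype = np.dtype(config.dtype).type
    gen = Generator(rngs["init_gen"], l2_coef=config.gen_l2, dtype=dtype)
    opt_d = Adam(disc.params, config.learning_rate, config.adam_beta1,
                 config.adam_beta2, config.adam_eps)
    opt_g = Adam(gen.params, config.learning_rate, config.adam_beta1,
                 config.adam_beta2, config.adam_eps)
    hist = HistoricalAverage(config.hist_decay, config.hist_coef)
    hist.initialize(disc.params)
    traces: dict[str, list[float]] = {"train_loss": [], "loss_disc": [],
                                      "loss_gen": [], "dev_mse": []}
    w = config.weights

    for epoch in range(config.epochs):
        ep_train = ep_disc = ep_gen = 0.0
        for _ in range(steps):
            batch = sample_paired_batch(train_set, config.batch_pairs,
                                        rngs["data"], index)
            n = len(batch)
            noise = sample_noise(n, rngs["noise"], dtype)

            # --- discriminator update ---
            scores_r, probs_r, cache_r = disc.forward(
                batch.x, training=True, rng=rngs["drop_real"], want_cache=True)
            fake = gen.forward(noise)
            _, probs_f, cache_f = disc.forward(
                fake, training=True, rng=rngs["drop_fake"], want_cache=True)
            batch.preds = scores_r.astype(float)
            value_d, dpred, dd_real, dd_fake = loss_disc_grad(
                batch, probs_r.astype(float), probs_f.astype(float), w)
            reg_value, _ = loss_train_grad(batch, w.alpha, w.beta)
            if not np.isfinite(value_d):
                raise RuntimeError(f"training diverged at epoch {epoch}: "
                                   f"loss_disc={value_d}")
            grads_r, _ = disc.backward(cache_r, dpred.astype(disc.dtype),
                                       dd_real.astype(disc.dtype))
            grads_f, _ = disc.backward(cache_f, np.zeros(n, dtype=disc.dtype),
                                       dd_fake.astype(disc.dtype))
            _add_grads(grads_r, grads_f)
            _add_grads(grads_r, hist.grad(disc.params))
            opt_d.step(disc.params, grads_r)
            hist.update(disc.params)

            # --- generator update (against the updated discriminator) ---
            fake, cache_g = gen.forward(noise, want_cache=True)
            _, probs_g, cache_fd = disc.forward(
                fake, training=True, rng=rngs["drop_fake"], want_cache=True)
            value_g, dd = loss_gen_grad(probs_g.astype(float))
            _, dfake = disc.backward(cache_fd, np.zeros(n, dtype=disc.dtype),
                                     dd.astype(disc.dtype), want_dx=True)
            grads_g = gen.backward(cache_g, dfake)
            opt_g.step(gen.params, grads_g)

            ep_train += reg_value
            ep_disc += value_d
            ep_gen += value_g
        traces["train_loss"].append(ep_train / steps)
        traces["loss_disc"].append(ep_disc / steps)
        traces["loss_gen"].append(ep_gen / steps)
        traces["dev_mse"].append(_dev_mse(disc, dev_set))
    return TrainState(config, disc, gen, traces, config.epochs,
                      sorted(dev_set.meta["subject_id"].unique().tolist()))


def train(config: TrainConfig, examples: ExampleSet) -> TrainState:
    return train_cnn(config, examples) if config.mode == "cnn" \
        else train_gan(config, examples)


def _add_grads(into: dict[str, np.ndarray], other: dict[str, np.ndarray]) -> None:
    for k in into:
        into[k] = into[k] + other[k]


# ---------------------------------------------------------------------------
# Checkpointing: one .npz container with a JSON header.

def save_checkpoint(state: TrainState, path: str | pathlib.Path) -> None:
    arrays = {f"disc/{k}": v for k, v in state.discriminator.params.items()}
    if state.generator is not None:
        arrays.update({f"gen/{k}": v for k, v in state.generator.params.items()})
    header = {
        "disc_hash": state.discriminator.architecture_hash(),
        "gen_hash": state.generator.architecture_hash() if state.generator else None,
        "seed": state.config.seed,
        "epoch": state.epoch,
        "mode": state.config.mode,
        "dev_subjects": state.dev_subjects,
    }
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | pathlib.Path
                    ) -> tuple[Discriminator, Generator | None, dict]:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        rng = np.random.default_rng(0)
        disc = Discriminator(rng)
        for k in disc.params:
            disc.params[k] = data[f"disc/{k}"]
        if disc.architecture_hash() != header["disc_hash"]:
            raise ValueError("checkpoint architecture hash mismatch (discriminator)")
        gen = None
        if header["gen_hash"] is not None:
            gen = Generator(rng)
            for k in gen.params:
                gen.params[k] = data[f"gen/{k}"]
            if gen.architecture_hash() != header["gen_hash"]:
                raise ValueError("checkpoint architecture hash mismatch (generator)")
    return disc, gen, header
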