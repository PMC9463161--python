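"""Training objectives.

The regression loss combines a plain MSE on predicted PIGD scores with an
MSE on within-subject between-visit score differences, so the network is
rewarded for ordering a subject's two visits correctly and not only for
matching absolute scores:

    loss_train = alpha * (1/N) sum_i (y_i - t_i)^2
               + beta  * (1/N) sum_i ((y_i1 - y_i2) - (t_i1 - t_i2))^2

where (i1, i2) are example i's own and its partner's values ordered by visit
(both members of a pair contribute the same squared difference, keeping the
1/N normalization uniform over examples).  The adversarial pieces are
least-squares objectives on the discriminator's sigmoid head:

    loss_disc = gamma * loss_train
              + delta * (mean (D(x)-1)^2 + mean D(G(z))^2)
    loss_gen  = mean (D(G(z)) - 1)^2

Fake examples are unlabeled and never enter loss_train.  Historical
averaging adds an L2 pull of the parameters toward an exponential moving
average of their recent values, a standard stabilizer for adversarial
training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class LossWeights:
    """Non-negative weights of the loss terms: alpha/beta for the regression
    parts, gamma/delta balancing regression against the adversarial game."""

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    delta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "delta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")


@dataclass
class PairedBatch:
    """A mini-batch in which every example is paired with one from the same
    subject's opposite visit.

    ``pair_index[i]`` is the partner of example ``i`` (an involution);
    ``visit_order[i]`` is 0 if example ``i`` belongs to the subject's first
    visit and 1 for the second.
    """

    truths: np.ndarray                    # (N,) clinician scores
    pair_index: np.ndarray                # (N,) partner indices
    visit_order: np.ndarray               # (N,) 0 | 1
    preds: Optional[np.ndarray] = None    # (N,) network scores, filled at use
    x: Optional[np.ndarray] = None        # (N, 3, 384) feature tensors
    subject_ids: Optional[np.ndarray] = None
    visit_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.truths = np.asarray(self.truths, dtype=float)
        self.pair_index = np.asarray(self.pair_index, dtype=int)
        self.visit_order = np.asarray(self.visit_order, dtype=int)
        n = self.truths.size
        if n % 2:
            raise ValueError("paired batch size must be even")
        if self.pair_index.shape != (n,) or self.visit_order.shape != (n,):
            raise ValueError("pair_index/visit_order must match batch size")
        idx = np.arange(n)
        if np.any(self.pair_index[self.pair_index] != idx) or np.any(self.pair_index == idx):
            raise ValueError("pairing must be an involution without fixed points")
        if np.any(self.visit_order + self.visit_order[self.pair_index] != 1):
            raise ValueError("each pair must contain one first- and one second-visit member")
        if self.subject_ids is not None:
            sid = np.asarray(self.subject_ids)
            if np.any(sid != sid[self.pair_index]):
                raise ValueError("paired examples must share subject_id")
        if self.visit_ids is not None:
            vid = np.asarray(self.visit_ids)
            if np.any(vid == vid[self.pair_index]):
                raise ValueError("paired examples must come from different visits")

    def __len__(self) -> int:
        return self.truths.size


def _ordered_diff(values: np.ndarray, pair_index: np.ndarray,
                  visit_order: np.ndarray) -> np.ndarray:
    """Per example: (first-visit value - second-visit value) of its pair."""
    sign = np.where(visit_order == 0, 1.0, -1.0)
    return sign * (values - values[pair_index])


def loss_train(batch: PairedBatch, alpha: float, beta: float) -> float:
    """Paired regression loss; requires ``batch.preds``."""
    value, _ = loss_train_grad(batch, alpha, beta)
    return value


def loss_train_grad(batch: PairedBatch, alpha: float, beta: float
                    ) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the predictions."""
    if batch.preds is None:
        raise ValueError("batch.preds must be set")
    preds = np.asarray(batch.preds, dtype=float)
    if preds.shape != batch.truths.shape:
        raise ValueError("preds and truths must have matching shape")
    n = len(batch)
    resid = preds - batch.truths
    term1 = alpha * np.mean(resid ** 2)

    d_pred = _ordered_diff(preds, batch.pair_index, batch.visit_order)
    d_true = _ordered_diff(batch.truths, batch.pair_index, batch.visit_order)
    e = d_pred - d_true
    term2 = beta * np.mean(e ** 2)

    sign = np.where(batch.visit_order == 0, 1.0, -1.0)
    # y_i enters its own pair term and its partner's (equal) term, each with sign s_i.
    grad = (2.0 * alpha / n) * resid + (4.0 * beta / n) * e * sign
    return float(term1 + term2), grad


def loss_disc(batch: PairedBatch, d_real: np.ndarray, d_fake: np.ndarray,
              weights: LossWeights) -> float:
    value, _, _, _ = loss_disc_grad(batch, d_real, d_fake, weights)
    return value


def loss_disc_grad(batch: PairedBatch, d_real: np.ndarray, d_fake: np.ndarray,
                   weights: LossWeights
                   ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Discriminator loss and gradients (w.r.t. preds, d_real, d_fake).

    The adversarial term pushes D(x) toward 1 on real examples and D(G(z))
    toward 0 on generated ones.
    """
    d_real = np.asarray(d_real, dtype=float)
    d_fake = np.asarray(d_fake, dtype=float)
    if d_real.shape != (len(batch),):
        raise ValueError("d_real must have one value per real example")
    if d_fake.shape != d_real.shape:
        raise ValueError("d_fake length must match d_real")
    reg, dpred = loss_train_grad(batch, weights.alpha, weights.beta)
    n = d_real.size
    adv = np.mean((d_real - 1.0) ** 2) + np.mean(d_fake ** 2)
    value = weights.gamma * reg + weights.delta * adv
    dd_real = weights.delta * 2.0 / n * (d_real - 1.0)
    dd_fake = weights.delta * 2.0 / n * d_fake
    return float(value), weights.gamma * dpred, dd_real, dd_fake


def loss_gen(d_fake: np.ndarray) -> float:
    value, _ = loss_gen_grad(d_fake)
    return value


def loss_gen_grad(d_fake: np.ndarray) -> tuple[float, np.ndarray]:
    """Generator loss: push the discriminator's real-probability on fakes to 1."""
    d_fake = np.asarray(d_fake, dtype=float)
    if d_fake.size == 0:
        raise ValueError("loss_gen requires at least one fake example")
    value = float(np.mean((d_fake - 1.0) ** 2))
    grad = 2.0 / d_fake.size * (d_fake - 1.0)
    return value, grad


def historical_average_penalty(current: dict[str, np.ndarray],
                               running_average: dict[str, np.ndarray],
                               coefficient: float) -> float:
    """L2 distance of the parameters from their running historical average."""
    if set(current) != set(running_average):
        raise ValueError("parameter containers must hold the same keys")
    total = 0.0
    for k, cur in current.items():
        avg = running_average[k]
        if cur.shape != avg.shape:
            raise ValueError(f"shape mismatch for parameter {k}")
        diff = cur.astype(np.float64) - avg.astype(np.float64)
        total += float((diff * diff).sum())
    return coefficient * total


def historical_average_grad(current: dict[str, np.ndarray],
                            running_average: dict[str, np.ndarray],
                            coefficient: float) -> dict[str, np.ndarray]:
    return {k: 2.0 * coefficient * (current[k] - running_average[k])
            for k in current}


@dataclass
class HistoricalAverage:
    """Exponential moving average of parameters with an L2 pull toward it.

    ``decay`` controls the memory of the average; the penalty coefficient
    weights the L2 cost added to the objective.  Updated after each
    optimizer step.
    """

    decay: float = 0.999
    coefficient: float = 1e-3
    average: dict[str, np.ndarray] = field(default_factory=dict)

    def initialize(self, params: dict[str, np.ndarray]) -> None:
        self.average = {k: v.copy() for k, v in params.items()}

    def update(self, params: dict[str, np.ndarray]) -> None:
        for k, v in params.items():
            self.average[k] = self.decay * self.average[k] + (1.0 - self.decay) * v

    def penalty(self, params: dict[str, np.ndarray]) -> float:
        return historical_average_penalty(params, self.average, self.coefficient)

    def grad(self, params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        return historical_average_grad(params, self.average, self.coefficient)
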