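"""The two networks, written directly in NumPy with explicit backprop.

Discriminator / CNN regressor (shared architecture):
    conv1d(3->32, k=3, s=1, p=1) + ReLU + dropout(0.5)
    conv1d(32->32, k=3, s=1, p=1) + ReLU + dropout(0.5)
    flatten -> dense(512) + ReLU + dropout(0.5)
    dense(2): unit 0 = unbounded PIGD score, unit 1 -> sigmoid = P(real)

Generator:
    dense(100->512) + ReLU, dense(512->512) + ReLU,
    dense(512->1152) linear, reshaped to (batch, 3, 384).

Hidden layers use weight normalization (w = g * v / ||v||, one scale g per
output unit) instead of batch normalization; output layers are plain dense.
Convolutional weights start orthogonal, dense weights He-uniform, biases 0,
weight-norm scales 1.  Dropout masks are drawn only in training mode and all
sampling goes through injected ``numpy.random.Generator`` objects, so every
forward pass is reproducible.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import numpy as np

NOISE_DIM = 100
INPUT_CHANNELS = 3
INPUT_LENGTH = 384
FLAT_DIM = INPUT_CHANNELS * INPUT_LENGTH  # 1152


# ---------------------------------------------------------------------------
# Initializers

def orthogonal_init(shape: tuple[int, int], rng: np.random.Generator,
                    dtype=np.float64) -> np.ndarray:
    """Orthogonal matrix init: the smaller dimension becomes orthonormal."""
    rows, cols = shape
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    d = np.sign(np.diag(r))
    q *= np.where(d == 0, 1.0, d)  # fix the sign ambiguity for determinism
    if rows < cols:
        q = q.T
    return np.ascontiguousarray(q[:rows, :cols], dtype=dtype)


def he_uniform_init(shape: tuple[int, ...], fan_in: int, rng: np.random.Generator,
                    dtype=np.float64) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


# ---------------------------------------------------------------------------
# Weight normalization helpers.  v is stored with output units along axis 0.

def _wn_effective(v: np.ndarray, g: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Effective weight w = g * v/||v|| (row-wise); returns (w, norm, unit)."""
    flat = v.reshape(v.shape[0], -1)
    norm = np.sqrt(np.einsum("ij,ij->i", flat, flat))
    unit = flat / norm[:, None]
    return g[:, None] * unit, norm, unit


def _wn_backward(dw: np.ndarray, v_shape: tuple, g: np.ndarray,
                 norm: np.ndarray, unit: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    dg = np.einsum("ij,ij->i", dw, unit)
    dv = (g / norm)[:, None] * (dw - dg[:, None] * unit)
    return dv.reshape(v_shape), dg


# ---------------------------------------------------------------------------
# im2col for 1-D convolution (stride 1, symmetric zero padding)

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B, C, L) -> (B, L, C*k) patch matrix."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (B, C, L, k)
    b, c, l, _ = win.shape
    return np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(b, l, c * k)


def _col2im(dcols: np.ndarray, c: int, k: int, pad: int, length: int) -> np.ndarray:
    b, l, _ = dcols.shape
    d = dcols.reshape(b, l, c, k)
    dxp = np.zeros((b, c, length + 2 * pad), dtype=dcols.dtype)
    for j in range(k):
        dxp[:, :, j:j + l] += d[:, :, :, j].transpose(0, 2, 1)
    return dxp[:, :, pad:length + pad]


class Discriminator:
    """Two-head convolutional regressor: PIGD score and real/fake probability."""

    def __init__(self, rng: np.random.Generator, n_filters: int = 32,
                 filter_size: int = 3, fc_units: int = 512,
                 dropout: float = 0.5, dtype=np.float32):
        self.n_filters = n_filters
        self.filter_size = filter_size
        self.fc_units = fc_units
        self.dropout = dropout
        self.dtype = dtype
        nf, k = n_filters, filter_size
        flat1 = INPUT_CHANNELS * k
        flat2 = nf * k
        fcin = nf * INPUT_LENGTH
        self.params: dict[str, np.ndarray] = {
            "conv1.v": orthogonal_init((nf, flat1), rng, dtype).reshape(nf, INPUT_CHANNELS, k),
            "conv1.g": np.ones(nf, dtype=dtype),
            "conv1.b": np.zeros(nf, dtype=dtype),
            "conv2.v": orthogonal_init((nf, flat2), rng, dtype).reshape(nf, nf, k),
            "conv2.g": np.ones(nf, dtype=dtype),
            "conv2.b": np.zeros(nf, dtype=dtype),
            "fc1.v": he_uniform_init((fc_units, fcin), fcin, rng, dtype),
            "fc1.g": np.ones(fc_units, dtype=dtype),
            "fc1.b": np.zeros(fc_units, dtype=dtype),
            "out.w": he_uniform_init((2, fc_units), fc_units, rng, dtype),
            "out.b": np.zeros(2, dtype=dtype),
        }

    # -- plumbing ----------------------------------------------------------
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def architecture_hash(self) -> str:
        spec = {k: list(v.shape) for k, v in sorted(self.params.items())}
        return hashlib.sha256(json.dumps(spec).encode()).hexdigest()[:16]

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None,
                want_cache: bool = False):
        """Returns (scores, real_probs[, cache]).

        ``scores`` is the unbounded regression head; ``real_probs`` the
        sigmoid of the second output unit.  Dropout (p=0.5 on conv1, conv2
        and fc1 outputs) is active only in training mode and requires ``rng``.
        """
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 3 or x.shape[1:] != (INPUT_CHANNELS, INPUT_LENGTH):
            raise ValueError(f"input must be (batch, {INPUT_CHANNELS}, {INPUT_LENGTH})")
        if not np.all(np.isfinite(x)):
            raise ValueError("input must be finite")
        if training and rng is None:
            raise ValueError("training mode requires an rng for dropout")
        p = self.params
        k, pad = self.filter_size, self.filter_size // 2
        cache: dict = {"x": x}

        cols1 = _im2col(x, k, pad)
        w1, n1, u1 = _wn_effective(p["conv1.v"], p["conv1.g"])
        z1 = cols1 @ w1.T + p["conv1.b"]
        a1 = np.maximum(z1, 0)
        a1, m1 = self._drop(a1, training, rng)

        cols2 = _im2col(a1.transpose(0, 2, 1), k, pad)
        w2, n2, u2 = _wn_effective(p["conv2.v"], p["conv2.g"])
        z2 = cols2 @ w2.T + p["conv2.b"]
        a2 = np.maximum(z2, 0)
        a2, m2 = self._drop(a2, training, rng)

        flat = a2.transpose(0, 2, 1).reshape(x.shape[0], -1)
        w3, n3, u3 = _wn_effective(p["fc1.v"], p["fc1.g"])
        z3 = flat @ w3.T + p["fc1.b"]
        a3 = np.maximum(z3, 0)
        a3, m3 = self._drop(a3, training, rng)

        out = a3 @ p["out.w"].T + p["out.b"]
        scores = out[:, 0]
        probs = _sigmoid(out[:, 1])

        if want_cache:
            cache.update(cols1=cols1, w1=w1, n1=n1, u1=u1, z1=z1, m1=m1,
                         cols2=cols2, w2=w2, n2=n2, u2=u2, z2=z2, m2=m2,
                         flat=flat, w3=w3, n3=n3, u3=u3, z3=z3, m3=m3, a3=a3,
                         probs=probs)
            return scores, probs, cache
        return scores, probs

    def _drop(self, a, training, rng):
        if not training or self.dropout <= 0:
            return a, None
        mask = (rng.random(a.shape, dtype=np.float32)
                >= self.dropout).astype(self.dtype)
        return a * (mask * self.dtype(1.0 / (1.0 - self.dropout))), mask

    # -- backward ----------------------------------------------------------
    def backward(self, cache: dict, dscores: np.ndarray, dprobs: np.ndarray,
                 want_dx: bool = False
                 ) -> tuple[dict[str, np.ndarray], np.ndarray | None]:
        """Gradients of a scalar loss given d loss/d scores and d loss/d probs.

        Returns (param gradients, gradient w.r.t. the input batch).
        """
        p = self.params
        k, pad = self.filter_size, self.filter_size // 2
        b = cache["x"].shape[0]
        probs = cache["probs"]

        dout = np.empty((b, 2), dtype=self.dtype)
        dout[:, 0] = dscores
        dout[:, 1] = dprobs * probs * (1.0 - probs)  # through the sigmoid

        grads: dict[str, np.ndarray] = {}
        grads["out.w"] = dout.T @ cache["a3"]
        grads["out.b"] = dout.sum(axis=0)
        da3 = dout @ p["out.w"]

        da3 = self._drop_back(da3, cache["m3"])
        dz3 = da3 * (cache["z3"] > 0)
        dw3 = dz3.T @ cache["flat"]
        grads["fc1.v"], grads["fc1.g"] = _wn_backward(
            dw3, p["fc1.v"].shape, p["fc1.g"], cache["n3"], cache["u3"])
        grads["fc1.b"] = dz3.sum(axis=0)
        dflat = dz3 @ cache["w3"]

        da2 = dflat.reshape(b, self.n_filters, INPUT_LENGTH).transpose(0, 2, 1)
        da2 = self._drop_back(da2, cache["m2"])
        dz2 = da2 * (cache["z2"] > 0)
        dw2 = dz2.reshape(-1, dz2.shape[-1]).T @ cache["cols2"].reshape(
            -1, cache["cols2"].shape[-1])
        grads["conv2.v"], grads["conv2.g"] = _wn_backward(
            dw2, p["conv2.v"].shape, p["conv2.g"], cache["n2"], cache["u2"])
        grads["conv2.b"] = dz2.sum(axis=(0, 1))
        dcols2 = dz2 @ cache["w2"]
        da1 = _col2im(dcols2, self.n_filters, k, pad, INPUT_LENGTH).transpose(0, 2, 1)

        da1 = self._drop_back(da1, cache["m1"])
        dz1 = da1 * (cache["z1"] > 0)
        dw1 = dz1.reshape(-1, dz1.shape[-1]).T @ cache["cols1"].reshape(
            -1, cache["cols1"].shape[-1])
        grads["conv1.v"], grads["conv1.g"] = _wn_backward(
            dw1, p["conv1.v"].shape, p["conv1.g"], cache["n1"], cache["u1"])
        grads["conv1.b"] = dz1.sum(axis=(0, 1))
        if not want_dx:
            return grads, None
        dcols1 = dz1 @ cache["w1"]
        dx = _col2im(dcols1, INPUT_CHANNELS, k, pad, INPUT_LENGTH)
        return grads, dx

    def _drop_back(self, da, mask):
        if mask is None:
            return da
        return da * (mask * self.dtype(1.0 / (1.0 - self.dropout)))


class Generator:
    """Fully connected generator: 100-d uniform noise -> fake 3 x 384 log spectrum."""

    def __init__(self, rng: np.random.Generator, hidden: int = 512,
                 l2_coef: float = 1e-4, dtype=np.float32):
        self.hidden = hidden
        self.l2_coef = l2_coef  # L2 penalty on the linear output layer
        self.dtype = dtype
        self.params: dict[str, np.ndarray] = {
            "fc1.v": he_uniform_init((hidden, NOISE_DIM), NOISE_DIM, rng, dtype),
            "fc1.g": np.ones(hidden, dtype=dtype),
            "fc1.b": np.zeros(hidden, dtype=dtype),
            "fc2.v": he_uniform_init((hidden, hidden), hidden, rng, dtype),
            "fc2.g": np.ones(hidden, dtype=dtype),
            "fc2.b": np.zeros(hidden, dtype=dtype),
            "out.w": he_uniform_init((FLAT_DIM, hidden), hidden, rng, dtype),
            "out.b": np.zeros(FLAT_DIM, dtype=dtype),
        }

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def architecture_hash(self) -> str:
        spec = {k: list(v.shape) for k, v in sorted(self.params.items())}
        return hashlib.sha256(json.dumps(spec).encode()).hexdigest()[:16]

    def forward(self, noise: np.ndarray, want_cache: bool = False):
        noise = np.asarray(noise, dtype=self.dtype)
        if noise.ndim != 2 or noise.shape[1] != NOISE_DIM:
            raise ValueError(f"noise must be (batch, {NOISE_DIM})")
        p = self.params
        w1, n1, u1 = _wn_effective(p["fc1.v"], p["fc1.g"])
        z1 = noise @ w1.T + p["fc1.b"]
        a1 = np.maximum(z1, 0)
        w2, n2, u2 = _wn_effective(p["fc2.v"], p["fc2.g"])
        z2 = a1 @ w2.T + p["fc2.b"]
        a2 = np.maximum(z2, 0)
        flat = a2 @ p["out.w"].T + p["out.b"]
        y = flat.reshape(-1, INPUT_CHANNELS, INPUT_LENGTH)
        if want_cache:
            return y, {"noise": noise, "w1": w1, "n1": n1, "u1": u1, "z1": z1,
                       "a1": a1, "w2": w2, "n2": n2, "u2": u2, "z2": z2, "a2": a2}
        return y

    def backward(self, cache: dict, dy: np.ndarray) -> dict[str, np.ndarray]:
        """Parameter gradients given d loss / d output (batch, 3, 384).

        Includes the L2 penalty gradient on the output-layer weights.
        """
        p = self.params
        dflat = dy.reshape(dy.shape[0], -1).astype(self.dtype)
        grads: dict[str, np.ndarray] = {}
        grads["out.w"] = dflat.T @ cache["a2"] + 2.0 * self.l2_coef * p["out.w"]
        grads["out.b"] = dflat.sum(axis=0)
        da2 = dflat @ p["out.w"]
        dz2 = da2 * (cache["z2"] > 0)
        dw2 = dz2.T @ cache["a1"]
        grads["fc2.v"], grads["fc2.g"] = _wn_backward(
            dw2, p["fc2.v"].shape, p["fc2.g"], cache["n2"], cache["u2"])
        grads["fc2.b"] = dz2.sum(axis=0)
        da1 = dz2 @ cache["w2"]
        dz1 = da1 * (cache["z1"] > 0)
        dw1 = dz1.T @ cache["noise"]
        grads["fc1.v"], grads["fc1.g"] = _wn_backward(
            dw1, p["fc1.v"].shape, p["fc1.g"], cache["n1"], cache["u1"])
        grads["fc1.b"] = dz1.sum(axis=0)
        return grads


def sample_noise(batch: int, rng: np.random.Generator,
                 dtype=np.float32) -> np.ndarray:
    """Generator input: ``batch`` x 100 values uniform on [0, 1)."""
    return rng.random((batch, NOISE_DIM)).astype(dtype)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
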