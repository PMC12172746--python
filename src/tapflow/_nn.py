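"""Minimal NumPy sequence models: Conv1D, bidirectional LSTM, Adam.

Small trainable building blocks for the two sequence tasks in this
package — force regression from kinematic features and touch-event
labeling.  Everything is plain NumPy with manual backpropagation so the
models run single-threaded and bit-reproducibly from a seed; layer
gradients are verified against finite differences in the test suite.

Shapes: sequences are (batch, time, features).
"""

from __future__ import annotations

import hashlib

import numpy as np


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


# ---------------------------------------------------------------------------
# layers (functional: forward returns a cache consumed by backward)


def conv1d_init(rng, c_in, c_out, k):
    s = 1.0 / np.sqrt(k * c_in)
    return {"W": rng.uniform(-s, s, (k * c_in, c_out)), "b": np.zeros(c_out)}


def conv1d_forward(p, x):
    """Same-padded 1-D convolution; x (B,T,Cin) -> (B,T,Cout)."""
    k = p["W"].shape[0] // x.shape[2]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, k - 1 - pad), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # B,T,Cin,k
    win = np.ascontiguousarray(win.transpose(0, 1, 3, 2))          # B,T,k,Cin
    B, T = x.shape[:2]
    flat = win.reshape(B, T, -1)
    y = flat @ p["W"] + p["b"]
    return y, (flat, x.shape, k, pad)


def conv1d_backward(p, cache, dy):
    flat, xshape, k, pad = cache
    B, T, c_in = xshape
    grads = {"W": flat.reshape(-1, flat.shape[-1]).T @ dy.reshape(-1, dy.shape[-1]),
             "b": dy.sum(axis=(0, 1))}
    dflat = dy @ p["W"].T                      # B,T,k*Cin
    dwin = dflat.reshape(B, T, k, c_in)
    dxp = np.zeros((B, T + k - 1, c_in))
    for j in range(k):
        dxp[:, j : j + T] += dwin[:, :, j]
    return grads, dxp[:, pad : pad + T]


def lstm_init(rng, d, h):
    # gate layout along the 4h axis: [input | forget | output] (sigmoid), then
    # [candidate] (tanh) — one activation call per block in the hot loop
    s = 1.0 / np.sqrt(d + h)
    p = {
        "Wx": rng.uniform(-s, s, (d, 4 * h)),
        "Wh": rng.uniform(-s, s, (h, 4 * h)),
        "b": np.zeros(4 * h),
    }
    p["b"][h : 2 * h] = 1.0  # forget-gate bias
    return p


def lstm_forward(p, x, reverse=False):
    B, T, _ = x.shape
    H = p["Wh"].shape[0]
    hs = np.empty((B, T, H))
    gates = np.empty((B, T, 4 * H))
    cs = np.empty((B, T, H))
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    order = range(T - 1, -1, -1) if reverse else range(T)
    xw = x @ p["Wx"] + p["b"]
    Wh = p["Wh"]
    H3 = 3 * H
    with np.errstate(over="ignore"):
        for t in order:
            z = xw[:, t] + h @ Wh
            z[:, :H3] = 1.0 / (1.0 + np.exp(-z[:, :H3]))
            np.tanh(z[:, H3:], out=z[:, H3:])
            c = z[:, H : 2 * H] * c + z[:, :H] * z[:, H3:]
            h = z[:, 2 * H : H3] * np.tanh(c)
            gates[:, t] = z
            cs[:, t] = c
            hs[:, t] = h
    return hs, (x, gates, cs, hs, reverse)


def lstm_backward(p, cache, dhs):
    x, gates, cs, hs, reverse = cache
    B, T, _ = x.shape
    H = p["Wh"].shape[0]
    H3 = 3 * H
    steps = list(range(T - 1, -1, -1) if reverse else range(T))
    # state of the previous step in *processing* order, vectorized
    c_prev = np.zeros_like(cs)
    h_prev = np.zeros_like(hs)
    if T > 1:
        c_prev[:, steps[1:]] = cs[:, steps[:-1]]
        h_prev[:, steps[1:]] = hs[:, steps[:-1]]
    tanh_c = np.tanh(cs)
    dZ = np.empty_like(gates)
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    WhT = p["Wh"].T
    for k in range(T - 1, -1, -1):
        t = steps[k]
        g = gates[:, t]
        i, f, o, cand = g[:, :H], g[:, H : 2 * H], g[:, 2 * H : H3], g[:, H3:]
        dh = dhs[:, t] + dh_next
        dc = dh * o * (1 - tanh_c[:, t] ** 2) + dc_next
        dz = dZ[:, t]
        dz[:, :H] = dc * cand * i * (1 - i)
        dz[:, H : 2 * H] = dc * c_prev[:, t] * f * (1 - f)
        dz[:, 2 * H : H3] = dh * tanh_c[:, t] * o * (1 - o)
        dz[:, H3:] = dc * i * (1 - cand**2)
        dh_next = dz @ WhT
        dc_next = dc * f
    flatZ = dZ.reshape(-1, 4 * H)
    grads = {
        "Wx": x.reshape(-1, x.shape[-1]).T @ flatZ,
        "Wh": h_prev.reshape(-1, H).T @ flatZ,
        "b": flatZ.sum(axis=0),
    }
    return grads, dZ @ p["Wx"].T


def dense_init(rng, d, h):
    s = 1.0 / np.sqrt(d)
    return {"W": rng.uniform(-s, s, (d, h)), "b": np.zeros(h)}


def dense_forward(p, x):
    return x @ p["W"] + p["b"], x


def dense_backward(p, x, dy):
    grads = {"W": x.reshape(-1, x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1]),
             "b": dy.sum(axis=tuple(range(dy.ndim - 1)))}
    return grads, dy @ p["W"].T


# ---------------------------------------------------------------------------
# losses (mean over all elements; return loss and d/dpred)


def mse_loss(pred, target):
    d = pred - target
    return float(np.mean(d**2)), 2.0 * d / d.size


def bce_loss(prob, target, eps=1e-7):
    p = np.clip(prob, eps, 1 - eps)
    loss = -np.mean(target * np.log(p) + (1 - target) * np.log(1 - p))
    grad = (p - target) / (p * (1 - p)) / p.size
    return float(loss), grad


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    def __init__(self, params: dict, lr=3e-3, beta1=0.9, beta2=0.999, eps=1e-8,
                 clip=5.0):
        self.lr = lr
        self.b1, self.b2, self.eps, self.clip = beta1, beta2, eps, clip
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict):
        self.t += 1
        norm = np.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
        scale = min(1.0, self.clip / (norm + 1e-12))
        for k in params:
            g = grads[k] * scale
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


# ---------------------------------------------------------------------------
# models


class _SequenceModel:
    """Shared plumbing: parameter flattening, hashing, batched inference."""

    params: dict[str, dict[str, np.ndarray]]

    def flat_params(self):
        return {f"{ln}.{pn}": arr for ln, layer in self.params.items()
                for pn, arr in layer.items()}

    def state_hash(self) -> str:
        h = hashlib.sha256()
        for k in sorted(self.flat_params()):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.flat_params()[k]).tobytes())
        return h.hexdigest()

    def predict(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        outs = []
        for i in range(0, x.shape[0], batch):
            outs.append(self.forward(x[i : i + batch], train=False)[0])
        return np.concatenate(outs, axis=0)


class BiLSTMRegressor(_SequenceModel):
    """Stacked bidirectional LSTM with a linear head (force regression)."""

    def __init__(self, n_features: int, hidden: int = 16, n_layers: int = 2,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.hidden, self.n_layers = hidden, n_layers
        self.params = {}
        d = n_features
        for l in range(n_layers):
            self.params[f"fw{l}"] = lstm_init(rng, d, hidden)
            self.params[f"bw{l}"] = lstm_init(rng, d, hidden)
            d = 2 * hidden
        self.params["head"] = dense_init(rng, d, 1)

    def forward(self, x, train=False, rng=None):
        caches = []
        h = x
        for l in range(self.n_layers):
            hf, cf = lstm_forward(self.params[f"fw{l}"], h)
            hb, cb = lstm_forward(self.params[f"bw{l}"], h, reverse=True)
            caches.append((cf, cb))
            h = np.concatenate([hf, hb], axis=2)
        y, dc = dense_forward(self.params["head"], h)
        caches.append(dc)
        return y[..., 0], caches

    def backward(self, caches, dy):
        grads = {}
        g_head, dh = dense_backward(self.params["head"], caches[-1], dy[..., None])
        grads["head"] = g_head
        H = self.hidden
        for l in range(self.n_layers - 1, -1, -1):
            cf, cb = caches[l]
            gf, dxf = lstm_backward(self.params[f"fw{l}"], cf, dh[:, :, :H])
            gb, dxb = lstm_backward(self.params[f"bw{l}"], cb, dh[:, :, H:])
            grads[f"fw{l}"], grads[f"bw{l}"] = gf, gb
            dh = dxf + dxb
        return grads, dh


class ConvBiLSTMClassifier(_SequenceModel):
    """1-D conv feature extractor + stacked BiLSTM + sigmoid head.

    The architecture used for touch-event labeling: a convolutional
    layer (default 100 kernels) for automatic feature extraction,
    bidirectional LSTM layers (default 3) with dropout between them, and
    a time-distributed sigmoid unit.
    """

    def __init__(self, n_kernels: int = 100, kernel_size: int = 9,
                 hidden: int = 16, n_layers: int = 3, dropout: float = 0.5,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.hidden, self.n_layers, self.dropout = hidden, n_layers, dropout
        self.params = {"conv": conv1d_init(rng, 1, n_kernels, kernel_size)}
        d = n_kernels
        for l in range(n_layers):
            self.params[f"fw{l}"] = lstm_init(rng, d, hidden)
            self.params[f"bw{l}"] = lstm_init(rng, d, hidden)
            d = 2 * hidden
        self.params["head"] = dense_init(rng, d, 1)

    def forward(self, x, train=False, rng=None):
        if x.ndim == 2:
            x = x[..., None]
        caches = {}
        h, caches["conv"] = conv1d_forward(self.params["conv"], x)
        relu_mask = h > 0
        h = h * relu_mask
        caches["relu"] = relu_mask
        caches["drop"] = []
        for l in range(self.n_layers):
            hf, cf = lstm_forward(self.params[f"fw{l}"], h)
            hb, cb = lstm_forward(self.params[f"bw{l}"], h, reverse=True)
            caches[f"lstm{l}"] = (cf, cb)
            h = np.concatenate([hf, hb], axis=2)
            if train and self.dropout > 0 and l < self.n_layers - 1:
                mask = (rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
                h = h * mask
                caches["drop"].append(mask)
            else:
                caches["drop"].append(None)
        z, caches["head"] = dense_forward(self.params["head"], h)
        prob = _sigmoid(z[..., 0])
        caches["prob"] = prob
        return prob, caches

    def backward(self, caches, dprob):
        grads = {}
        p = caches["prob"]
        dz = (dprob * p * (1 - p))[..., None]
        grads["head"], dh = dense_backward(self.params["head"], caches["head"], dz)
        H = self.hidden
        for l in range(self.n_layers - 1, -1, -1):
            if caches["drop"][l] is not None:
                dh = dh * caches["drop"][l]
            cf, cb = caches[f"lstm{l}"]
            gf, dxf = lstm_backward(self.params[f"fw{l}"], cf, dh[:, :, :H])
            gb, dxb = lstm_backward(self.params[f"bw{l}"], cb, dh[:, :, H:])
            grads[f"fw{l}"], grads[f"bw{l}"] = gf, gb
            dh = dxf + dxb
        dh = dh * caches["relu"]
        grads["conv"], _ = conv1d_backward(self.params["conv"], caches["conv"], dh)
        return grads


def numeric_gradient(loss_fn, arr, eps=1e-6):
    """Central finite differences of ``loss_fn()`` w.r.t. ``arr`` (in place)."""
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + eps
        lp = loss_fn()
        arr[idx] = orig - eps
        lm = loss_fn()
        arr[idx] = orig
        g[idx] = (lp - lm) / (2 * eps)
        it.iternext()
    return g
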