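"""Device-to-laboratory clock alignment via force regression.

The smartphone touch log lives on the device clock; the force and
movement sensors live on the laboratory clock.  Since no trigger can be
injected into the phone, alignment is data-driven: a regressor learns to
predict the force-sensor trace from movement-sensor features, and the
constant delay between logged touches and the predicted-force peaks is
estimated by cross-correlation and subtracted from the touch log.

Two regressors sit behind the same contract: a windowed linear (ridge)
model — fast, deterministic, the default — and a stacked bidirectional
LSTM trained on random 1000-sample windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import correlate

from ._nn import Adam, BiLSTMRegressor, mse_loss
from .containers import EventSet

N_LAGS = 100          # lagged moving-average features
MA_WINDOW = 10        # samples (= ms at 1 kHz)


@dataclass
class FeatureMatrix:
    """Per-millisecond features: raw movement value + 100 lagged 10 ms means.

    Column 0 is the raw trace; column k (k = 1..100) is the causal 10 ms
    equally-weighted moving average evaluated k-1 ms before the current
    sample, edges replicated.  Normalization statistics, when set, come
    from the training split only.
    """

    X: np.ndarray
    x_mean: np.ndarray | None = None
    x_std: np.ndarray | None = None

    def __post_init__(self):
        if self.X.ndim != 2 or self.X.shape[1] != N_LAGS + 1:
            raise ValueError(f"feature matrix must have {N_LAGS + 1} columns")


@dataclass
class AlignmentReport:
    mse_train: float
    mse_val: float
    mse_test: float
    delay_ms: float | None = None
    peak_corr: float | None = None
    passed: bool | None = None
    qc_threshold: float = 0.2


def extract_alignment_features(movement: np.ndarray, srate: float = 1000.0
                               ) -> FeatureMatrix:
    """Build the 101-column alignment feature matrix from a 1 kHz trace."""
    if srate != 1000.0:
        raise ValueError("alignment features are defined on 1 kHz traces")
    x = np.asarray(movement, dtype=float)
    n = x.size
    if n < 110:
        raise ValueError("trace shorter than 110 samples")
    # causal 10-sample moving average with edge replication
    xp = np.concatenate([np.full(MA_WINDOW - 1, x[0]), x])
    ma = np.convolve(xp, np.full(MA_WINDOW, 1.0 / MA_WINDOW), mode="valid")
    idx = np.arange(n)[:, None] - np.arange(N_LAGS)[None, :]
    np.clip(idx, 0, None, out=idx)
    X = np.empty((n, N_LAGS + 1), dtype=np.float32)
    X[:, 0] = x
    X[:, 1:] = ma.astype(np.float32)[idx]
    return FeatureMatrix(X)


def _contiguous_splits(n: int, fractions=(0.8, 0.1, 0.1)):
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return slice(0, n_train), slice(n_train, n_train + n_val), \
        slice(n_train + n_val, n)


class LinearForceRegressor:
    """Ridge regression on the 101 windowed features (z-scored)."""

    def __init__(self, ridge: float = 1e-3):
        self.ridge = ridge
        self.coef_: np.ndarray | None = None

    def fit(self, Xz: np.ndarray, yz: np.ndarray):
        X64 = Xz.astype(float)
        gram = X64.T @ X64
        gram[np.diag_indices_from(gram)] += self.ridge * len(yz)
        self.coef_ = np.linalg.solve(gram, X64.T @ yz)
        return self

    def predict(self, Xz: np.ndarray) -> np.ndarray:
        return Xz.astype(float) @ self.coef_


class RecurrentForceRegressor:
    """Two bidirectional LSTM layers + linear head on z-scored features."""

    def __init__(self, hidden: int = 16, seed: int = 0, window: int = 1000,
                 batch_size: int = 10, max_epochs: int = 10, patience: int = 3,
                 lr: float = 3e-3):
        self.net = BiLSTMRegressor(N_LAGS + 1, hidden=hidden, seed=seed)
        self.window, self.batch_size = window, batch_size
        self.max_epochs, self.patience, self.lr = max_epochs, patience, lr
        self.seed = seed

    def fit(self, Xz, yz, Xval=None, yval=None):
        rng = np.random.default_rng(self.seed + 1)
        opt = Adam(self.net.flat_params(), lr=self.lr)
        n = len(yz)
        steps = max(1, n // (self.window * self.batch_size))
        best, best_state, wait = np.inf, None, 0
        for _ in range(self.max_epochs):
            for _ in range(steps):
                starts = rng.integers(0, n - self.window, self.batch_size)
                xb = np.stack([Xz[s : s + self.window] for s in starts]).astype(float)
                yb = np.stack([yz[s : s + self.window] for s in starts])
                pred, cache = self.net.forward(xb, train=True, rng=rng)
                _, dpred = mse_loss(pred, yb)
                grads, _ = self.net.backward(cache, dpred)
                opt.step(self.net.flat_params(),
                         {f"{l}.{p}": grads[l][p] for l in grads for p in grads[l]})
            if Xval is not None and len(yval):
                v = float(np.mean((self.predict(Xval) - yval) ** 2))
                if v < best - 1e-6:
                    best, wait = v, 0
                    best_state = {k: a.copy()
                                  for k, a in self.net.flat_params().items()}
                else:
                    wait += 1
                    if wait >= self.patience:
                        break
        if best_state is not None:
            for k, a in self.net.flat_params().items():
                a[...] = best_state[k]
        return self

    def predict(self, Xz) -> np.ndarray:
        n, w = len(Xz), self.window
        out = np.empty(n)
        for s in range(0, n, w):
            seg = Xz[s : min(s + w, n)].astype(float)
            out[s : s + len(seg)] = self.net.predict(seg[None])[0]
        return out


def train_force_regressor(features: FeatureMatrix, force: np.ndarray,
                          seed: int = 0, model: str = "linear",
                          fractions=(0.8, 0.1, 0.1), **model_kw):
    """Fit a force regressor on contiguous train/validation/test splits.

    Returns ``(regressor, report, predicted_force)`` where the predicted
    force covers the full recording and is in z-scored force units, and
    the report carries the MSE on each split.
    """
    X, y = features.X, np.asarray(force, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in features or force")
    if len(X) != len(y):
        raise ValueError("feature/force length mismatch")
    if np.all(y == 0):
        warnings.warn("force trace is identically zero; model will fit a constant")
    tr, va, te = _contiguous_splits(len(y), fractions)
    x_mean = X[tr].mean(axis=0)
    x_std = np.maximum(X[tr].std(axis=0), 1e-12)
    y_mean = y[tr].mean()
    y_std = max(y[tr].std(), 1e-12)
    features.x_mean, features.x_std = x_mean, x_std
    Xz = (X - x_mean.astype(np.float32)) / x_std.astype(np.float32)
    yz = (y - y_mean) / y_std

    if model == "linear":
        reg = LinearForceRegressor(**model_kw).fit(Xz[tr], yz[tr])
    elif model == "bilstm":
        reg = RecurrentForceRegressor(seed=seed, **model_kw)
        reg.fit(Xz[tr], yz[tr], Xz[va], yz[va])
    else:
        raise ValueError(f"unknown model {model!r}")
    pred = reg.predict(Xz)
    report = AlignmentReport(
        mse_train=float(np.mean((pred[tr] - yz[tr]) ** 2)),
        mse_val=float(np.mean((pred[va] - yz[va]) ** 2)) if yz[va].size else np.nan,
        mse_test=float(np.mean((pred[te] - yz[te]) ** 2)) if yz[te].size else np.nan,
    )
    return reg, report, pred


def estimate_delay(pred_force: np.ndarray, touch_device_ms: np.ndarray,
                   srate: float = 1000.0, search_ms=(-5000.0, 5000.0),
                   smooth_ms: float = 25.0, qc_threshold: float = 0.2):
    """Delay (ms) maximizing the cross-correlation between the predicted
    force and an impulse train at the logged (device-clock) touch times.

    Returns ``(delay_ms, peak_corr, passed)``; ``passed`` is False when
    the normalized correlation peak falls below ``qc_threshold`` (the
    subject should then be excluded as misaligned).
    """
    touch = np.asarray(touch_device_ms, dtype=float)
    if touch.size == 0:
        raise ValueError("touch log is empty; delay undefined")
    n = len(pred_force)
    sm = smooth_ms * srate / 1000.0
    a = gaussian_filter1d(np.asarray(pred_force, dtype=float), sm)
    a = (a - a.mean()) / max(a.std(), 1e-12)
    b = np.zeros(n)
    idx = np.round(touch * srate / 1000.0).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    if idx.size == 0:
        raise ValueError("no touch events fall inside the recording")
    np.add.at(b, idx, 1.0)
    b = gaussian_filter1d(b, sm)
    b = (b - b.mean()) / max(b.std(), 1e-12)
    c = correlate(b, a, mode="full", method="fft") / n
    lags = np.arange(-(n - 1), n)
    lag_ms = lags * 1000.0 / srate
    keep = (lag_ms >= search_ms[0]) & (lag_ms <= search_ms[1])
    c, lag_ms = c[keep], lag_ms[keep]
    best = int(np.argmax(c))
    peak = float(c[best])
    return float(lag_ms[best]), peak, peak >= qc_threshold


def align_touch_log(touch_device_ms: np.ndarray, delay_ms: float) -> EventSet:
    """Shift the device-clock touch log onto the laboratory clock."""
    if not np.isfinite(delay_ms):
        raise ValueError("delay must be finite")
    t = np.asarray(touch_device_ms, dtype=float) - delay_ms
    return EventSet({"touch": t},
                    {"touch": f"device touch log shifted by -{delay_ms} ms"})


def align_session(movement: np.ndarray, force: np.ndarray,
                  touch_device_ms: np.ndarray, seed: int = 0,
                  model: str = "linear", search_ms=(-5000.0, 5000.0),
                  qc_threshold: float = 0.2, **model_kw):
    """Full alignment: features -> regressor -> delay -> lab-clock touches."""
    feats = extract_alignment_features(movement)
    reg, report, pred = train_force_regressor(feats, force, seed=seed,
                                              model=model, **model_kw)
    delay, peak, passed = estimate_delay(pred, touch_device_ms,
                                         search_ms=search_ms,
                                         qc_threshold=qc_threshold)
    report.delay_ms, report.peak_corr, report.passed = delay, peak, passed
    report.qc_threshold = qc_threshold
    return align_touch_log(touch_device_ms, delay), report, reg
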