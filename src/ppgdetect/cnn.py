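"""Dual-branch CNN for scalogram classification, implemented in numpy.

Each arrhythmia (bradycardia, tachycardia) gets its own small binary
network: two convolutional layers with 32 kernels (13x13 for the
bradycardia branch, whose discriminative energy sits at lower frequencies;
5x5 for tachycardia), stride 1, each followed by ReLU and 2x2 average
pooling with stride 2, then a 256-unit fully connected layer and a 2-unit
softmax output.  Dropout (rate 0.5) is applied after each pooling stage
and after the dense layer.  Training uses Adam (learning rate 0.01),
cross-entropy loss, class balancing by under-sampling the majority class,
a stratified 70/30 train/validation split, and early stopping when
validation accuracy stops improving.

The implementation is a compact im2col/GEMM CNN: convolution is performed
per image as a single matrix product, which keeps memory bounded and hits
BLAS for the heavy lifting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import fft as sfft

from ppgdetect.config import CNNConfig, derive_rng
from ppgdetect.scalogram import Scalogram

ARRHYTHMIA = "arrhythmia"
OTHER = "other"

_F32 = np.float32


@dataclass
class ModelSpec:
    """Architecture of one branch."""

    branch: str                     # {"brady", "tachy"}
    kernel: int = 0                 # 0 -> branch default (13 brady / 5 tachy)
    n_kernels: int = 32
    n_conv: int = 2
    dense_units: int = 256
    dropout: float = 0.5
    input_shape: tuple[int, int] = (500, 61)

    def __post_init__(self) -> None:
        if self.branch not in ("brady", "tachy"):
            raise ValueError("branch must be 'brady' or 'tachy'")
        if self.kernel == 0:
            self.kernel = 13 if self.branch == "brady" else 5

    def layer_shapes(self) -> dict[str, tuple]:
        """Output shape after each stage (valid convolution, stride 1)."""
        h, w = self.input_shape
        shapes = {}
        c = 1
        for i in range(self.n_conv):
            h, w = h - self.kernel + 1, w - self.kernel + 1
            c = self.n_kernels
            shapes[f"conv{i + 1}"] = (h, w, c)
            h, w = h // 2, w // 2
            shapes[f"pool{i + 1}"] = (h, w, c)
        shapes["flatten"] = (h * w * c,)
        shapes["dense1"] = (self.dense_units,)
        shapes["dense2"] = (2,)
        return shapes

    def n_parameters(self) -> int:
        k, f = self.kernel, self.n_kernels
        n = k * k * 1 * f + f          # conv1
        n += k * k * f * f + f         # conv2
        flat = self.layer_shapes()["flatten"][0]
        n += flat * self.dense_units + self.dense_units
        n += self.dense_units * 2 + 2
        return n


@dataclass
class TrainConfig:
    learning_rate: float = CNNConfig.learning_rate
    batch_size: int = CNNConfig.batch_size
    max_epochs: int = CNNConfig.max_epochs
    patience: int = CNNConfig.patience
    train_fraction: float = CNNConfig.train_fraction
    seed: int = 0


# ---------------------------------------------------------------- layers
#
# Valid cross-correlation is evaluated in the frequency domain: with the
# FFT taken at (at least) the input size, corr(x, w) = ifft(X * conj(W)),
# the weight gradient is corr(x, dout) and the input gradient the full
# convolution conv(dout, w) — all products become one small complex GEMM
# per frequency bin (batch x channel x filter), which is far cheaper than
# materializing im2col matrices at these image sizes.


def _fft_sizes(h: int, w: int) -> tuple[int, int]:
    return sfft.next_fast_len(h, real=True), sfft.next_fast_len(w, real=True)


_IM2COL_MAX_K = 600  # patch length below which plain GEMM beats the FFT route


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x: (B, H, W, C); W: (kh, kw, C, F).  Returns (out, cache)."""
    kh, kw, cin, f = W.shape
    if kh * kw * cin <= _IM2COL_MAX_K:
        return _conv_forward_gemm(x, W, b)
    return _conv_forward_fft(x, W, b)


def _conv_backward(cache: dict, dout: np.ndarray, need_dx: bool = True):
    if cache["method"] == "gemm":
        return _conv_backward_gemm(cache, dout, need_dx)
    return _conv_backward_fft(cache, dout, need_dx)


def _im2col_one(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(H, W, C) -> (hs*ws, kh*kw*C) patch matrix for one image (copies)."""
    from numpy.lib.stride_tricks import sliding_window_view

    h, w, cin = x.shape
    hs, ws = h - kh + 1, w - kw + 1
    if cin == 1:
        v = sliding_window_view(x[:, :, 0], (kh, kw))      # (hs, ws, kh, kw)
        return np.ascontiguousarray(v).reshape(hs * ws, kh * kw)
    v = sliding_window_view(x, (kh, kw), axis=(0, 1))      # (hs, ws, C, kh, kw)
    v = v.transpose(0, 1, 3, 4, 2)                         # (..., kh, kw, C)
    return np.ascontiguousarray(v).reshape(hs * ws, kh * kw * cin)


def _conv_forward_gemm(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    kh, kw, cin, f = W.shape
    bsz, h, w, _ = x.shape
    hs, ws = h - kh + 1, w - kw + 1
    wm = W.reshape(kh * kw * cin, f)
    out = np.empty((bsz, hs, ws, f), dtype=_F32)
    for i in range(bsz):                 # per image: bounded copies, one GEMM
        out[i] = (_im2col_one(x[i], kh, kw) @ wm + b).reshape(hs, ws, f)
    cache = {"method": "gemm", "x": x, "W": W}
    return out, cache


def _conv_backward_gemm(cache: dict, dout: np.ndarray, need_dx: bool = True):
    x, W = cache["x"], cache["W"]
    kh, kw, cin, f = W.shape
    bsz, h, w, _ = x.shape
    hs, ws = h - kh + 1, w - kw + 1
    wm = W.reshape(kh * kw * cin, f)
    dW = np.zeros((kh * kw * cin, f), dtype=_F32)
    db = dout.sum(axis=(0, 1, 2))
    dx = np.zeros((bsz, h, w, cin), dtype=_F32) if need_dx else None
    for i in range(bsz):
        cols = _im2col_one(x[i], kh, kw)
        do = dout[i].reshape(hs * ws, f)
        dW += cols.T @ do
        if need_dx:
            dcols = (do @ wm.T).reshape(hs, ws, kh, kw, cin)
            for a in range(kh):
                for c in range(kw):
                    dx[i, a : a + hs, c : c + ws, :] += dcols[:, :, a, c, :]
    return dW.reshape(W.shape), db.astype(_F32), dx


def _conv_forward_fft(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    kh, kw, cin, f = W.shape
    bsz, h, w, _ = x.shape
    hs, ws = h - kh + 1, w - kw + 1
    fh, fw = _fft_sizes(h, w)
    xf = sfft.rfft2(x.transpose(0, 3, 1, 2), s=(fh, fw))          # (B, C, fh, fwr)
    wf = sfft.rfft2(W.transpose(2, 3, 0, 1), s=(fh, fw))          # (C, F, fh, fwr)
    nbin = xf.shape[2] * xf.shape[3]
    xs = np.ascontiguousarray(xf.reshape(bsz, cin, nbin).transpose(2, 0, 1))   # (nbin, B, C)
    ws_ = np.ascontiguousarray(wf.reshape(cin, f, nbin).transpose(2, 0, 1))    # (nbin, C, F)
    ys = xs @ np.conj(ws_)                                        # (nbin, B, F)
    yf = ys.transpose(1, 2, 0).reshape(bsz, f, xf.shape[2], xf.shape[3])
    y = sfft.irfft2(yf, s=(fh, fw))[:, :, :hs, :ws]
    out = np.ascontiguousarray(y.transpose(0, 2, 3, 1), dtype=_F32) + b
    cache = {"method": "fft", "xs": xs, "ws": ws_, "shape": (bsz, h, w, cin),
             "k": (kh, kw, f), "fft": (fh, fw, xf.shape[2], xf.shape[3])}
    return out, cache


def _conv_backward_fft(cache: dict, dout: np.ndarray, need_dx: bool = True):
    bsz, h, w, cin = cache["shape"]
    kh, kw, f = cache["k"]
    fh, fw, nh, nw = cache["fft"]
    xs, ws_ = cache["xs"], cache["ws"]
    nbin = nh * nw
    df = sfft.rfft2(dout.transpose(0, 3, 1, 2), s=(fh, fw))       # (B, F, nh, nw)
    ds = np.ascontiguousarray(df.reshape(bsz, f, nbin).transpose(2, 0, 1))     # (nbin, B, F)
    # dW = corr(x, dout), cropped to the kernel support
    dwf = xs.transpose(0, 2, 1) @ np.conj(ds)                     # (nbin, C, F)
    dwf = dwf.transpose(1, 2, 0).reshape(cin, f, nh, nw)
    dW = sfft.irfft2(dwf, s=(fh, fw))[:, :, :kh, :kw].transpose(2, 3, 0, 1)
    db = dout.sum(axis=(0, 1, 2))
    dx = None
    if need_dx:
        # dx = full conv(dout, w); the FFT size >= h avoids wrap-around
        dxs = ds @ ws_.transpose(0, 2, 1)                          # (nbin, B, C)
        dxf = dxs.transpose(1, 2, 0).reshape(bsz, cin, nh, nw)
        dx = sfft.irfft2(dxf, s=(fh, fw))[:, :, :h, :w]
        dx = np.ascontiguousarray(dx.transpose(0, 2, 3, 1), dtype=_F32)
    return np.ascontiguousarray(dW, dtype=_F32), db.astype(_F32), dx


def _pool_forward(x: np.ndarray) -> np.ndarray:
    bsz, h, w, c = x.shape
    hh, ww = h // 2, w // 2
    return x[:, : hh * 2, : ww * 2].reshape(bsz, hh, 2, ww, 2, c).mean(axis=(2, 4))


def _pool_backward(dout: np.ndarray, in_shape: tuple) -> np.ndarray:
    bsz, h, w, c = in_shape
    hh, ww = h // 2, w // 2
    core = np.empty((bsz, hh * 2, ww * 2, c), dtype=_F32)
    core.reshape(bsz, hh, 2, ww, 2, c)[:] = dout[:, :, None, :, None, :]
    core *= 0.25
    if (h, w) == (hh * 2, ww * 2):
        return core
    dx = np.zeros(in_shape, dtype=_F32)
    dx[:, : hh * 2, : ww * 2] = core
    return dx


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class TrainedModel:
    """Weights + architecture + training history of one branch."""

    def __init__(self, spec: ModelSpec, params: dict[str, np.ndarray], history: dict | None = None):
        self.spec = spec
        self.params = params
        self.history = history or {}

    # -- initialization ------------------------------------------------
    @classmethod
    def initialize(cls, spec: ModelSpec, seed: int = 0) -> "TrainedModel":
        rng = derive_rng(seed, 101)
        k, f = spec.kernel, spec.n_kernels
        flat = spec.layer_shapes()["flatten"][0]

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(_F32)

        params = {
            "W1": he((k, k, 1, f), k * k),
            "b1": np.zeros(f, dtype=_F32),
            "W2": he((k, k, f, f), k * k * f),
            "b2": np.zeros(f, dtype=_F32),
            "Wd1": he((flat, spec.dense_units), flat),
            "bd1": np.zeros(spec.dense_units, dtype=_F32),
            # zero-initialized head: logits start at 0, so the first Adam
            # steps (large relative to He-scale weights at this learning
            # rate) ramp up gradually instead of shocking the ReLU stack
            "Wd2": np.zeros((spec.dense_units, 2), dtype=_F32),
            "bd2": np.zeros(2, dtype=_F32),
        }
        return cls(spec, params)

    # -- forward / backward --------------------------------------------
    def _forward(self, x: np.ndarray, drop_rng=None):
        """x: (B, H, W) float; returns probabilities and, in training mode
        (``drop_rng`` given), the cache needed for backprop."""
        p = self.params
        rate = self.spec.dropout
        x = x[..., None].astype(_F32)
        cache: dict = {"x": x}

        a1, cv1 = _conv_forward(x, p["W1"], p["b1"])
        r1 = np.maximum(a1, 0)
        pl1 = _pool_forward(r1)
        if drop_rng is not None:
            m1 = (drop_rng.random(pl1.shape, dtype=np.float32) >= rate).astype(_F32)
            m1 *= 1.0 / (1 - rate)
            pl1 = pl1 * m1
            cache.update(m1=m1, cv1=cv1)
        a2, cv2 = _conv_forward(pl1, p["W2"], p["b2"])
        r2 = np.maximum(a2, 0)
        pl2 = _pool_forward(r2)
        if drop_rng is not None:
            m2 = (drop_rng.random(pl2.shape, dtype=np.float32) >= rate).astype(_F32)
            m2 *= 1.0 / (1 - rate)
            pl2 = pl2 * m2
            cache.update(m2=m2, cv2=cv2)
        flat = pl2.reshape(len(pl2), -1)
        z1 = flat @ p["Wd1"] + p["bd1"]
        h1 = np.maximum(z1, 0)
        if drop_rng is not None:
            m3 = (drop_rng.random(h1.shape, dtype=np.float32) >= rate).astype(_F32)
            m3 *= 1.0 / (1 - rate)
            h1 = h1 * m3
            cache.update(m3=m3)
        z2 = h1 @ p["Wd2"] + p["bd2"]
        probs = _softmax(z2.astype(np.float64))
        if drop_rng is None:
            return probs, None
        cache.update(a1=a1, r1=r1, pl1=pl1, a2=a2, r2=r2, pl2_shape=pl2.shape,
                     flat=flat, z1=z1, h1=h1)
        return probs, cache

    def _backward(self, probs: np.ndarray, y: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        p = self.params
        bsz = len(y)
        dz2 = probs.copy()
        dz2[np.arange(bsz), y] -= 1.0
        dz2 = (dz2 / bsz).astype(_F32)

        grads = {}
        grads["Wd2"] = cache["h1"].T @ dz2
        grads["bd2"] = dz2.sum(axis=0)
        dh1 = dz2 @ p["Wd2"].T
        dh1 *= cache["m3"]
        dz1 = dh1 * (cache["z1"] > 0)
        grads["Wd1"] = cache["flat"].T @ dz1
        grads["bd1"] = dz1.sum(axis=0)
        dflat = dz1 @ p["Wd1"].T
        dpl2 = dflat.reshape(cache["pl2_shape"])
        dpl2 = dpl2 * cache["m2"]
        dr2 = _pool_backward(dpl2, cache["r2"].shape)
        da2 = dr2 * (cache["a2"] > 0)
        grads["W2"], grads["b2"], dpl1 = _conv_backward(cache["cv2"], da2)
        dpl1 *= cache["m1"]
        dr1 = _pool_backward(dpl1, cache["r1"].shape)
        da1 = dr1 * (cache["a1"] > 0)
        grads["W1"], grads["b1"], _ = _conv_backward(cache["cv1"], da1, need_dx=False)
        return grads

    # -- inference ------------------------------------------------------
    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Probability of the arrhythmia class for (N, H, W) or (H, W) input."""
        x = np.asarray(x, dtype=_F32)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.shape[1:] != tuple(self.spec.input_shape):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model input {self.spec.input_shape}"
            )
        out = np.empty(len(x))
        for i in range(0, len(x), batch_size):
            probs, _ = self._forward(x[i : i + batch_size], drop_rng=None)
            out[i : i + batch_size] = probs[:, 1]
        return float(out[0]) if single else out

    # -- persistence ----------------------------------------------------
    def save(self, path: str) -> None:
        meta = {"spec": asdict(self.spec), "history": self.history}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            params = {k: z[k] for k in z.files if k != "__meta__"}
        spec_d = meta["spec"]
        spec_d["input_shape"] = tuple(spec_d["input_shape"])
        return cls(ModelSpec(**spec_d), params, meta.get("history"))


# ---------------------------------------------------------------- data prep

def prepare_training_data(
    scalograms: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    train_fraction: float = 0.70,
):
    """Balance by under-sampling the majority class, then split 70/30.

    ``labels`` is binary (1 = arrhythmia segment for this branch).  Returns
    ((X_train, y_train), (X_val, y_val)); deterministic per seed.
    """
    from sklearn.model_selection import train_test_split

    scalograms = np.asarray(scalograms)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 examples of each class")
    rng = derive_rng(seed, 211)
    n_keep = min(n_pos, n_neg)
    idx_pos = np.flatnonzero(labels == 1)
    idx_neg = np.flatnonzero(labels == 0)
    keep = np.concatenate([
        rng.choice(idx_pos, n_keep, replace=False),
        rng.choice(idx_neg, n_keep, replace=False),
    ])
    X, y = scalograms[keep], labels[keep]
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y,
        train_size=train_fraction,
        stratify=y,
        random_state=int(derive_rng(seed, 212).integers(2**31)),
    )
    return (X_tr, y_tr), (X_val, y_val)


# ---------------------------------------------------------------- training

class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1c = 1 - self.b1**self.t
        b2c = 1 - self.b2**self.t
        for k in params:
            g = grads[k].astype(params[k].dtype, copy=False)
            m, v = self.m[k], self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * np.square(g)
            denom = np.sqrt(v)
            denom *= 1.0 / np.sqrt(b2c)
            denom += self.eps
            update = m / denom
            update *= self.lr / b1c
            params[k] -= update


def train(spec: ModelSpec, data, cfg: TrainConfig | None = None) -> TrainedModel:
    """Train one branch on prepared data.

    ``data`` is ((X_train, y_train), (X_val, y_val)) from
    :func:`prepare_training_data`.  Early stopping restores the weights of
    the best validation-accuracy epoch.  At this learning rate a session
    occasionally collapses into a dead constant-class state it cannot
    leave; such chance-level sessions are restarted with a fresh
    initialization stream (up to ``_MAX_RESTARTS`` times, deterministic
    per seed).  A divergence warning is raised if the final attempt still
    never beats chance.
    """
    cfg = cfg or TrainConfig()
    model = None
    for attempt in range(_MAX_RESTARTS + 1):
        model = _train_once(spec, data, cfg, attempt)
        best = max(model.history["val_accuracy"])
        if best > 0.55 or cfg.learning_rate == 0:
            return model
    if cfg.learning_rate > 0:
        warnings.warn(
            f"{spec.branch} branch failed to beat chance after "
            f"{_MAX_RESTARTS + 1} attempts (best validation accuracy "
            f"{max(model.history['val_accuracy']):.3f}); history attached",
            RuntimeWarning,
        )
    return model


_MAX_RESTARTS = 2


def _train_once(spec: ModelSpec, data, cfg: TrainConfig, attempt: int = 0) -> TrainedModel:
    (x_tr, y_tr), (x_val, y_val) = data
    x_tr = np.asarray(x_tr, dtype=_F32)
    x_val = np.asarray(x_val, dtype=_F32)
    y_tr = np.asarray(y_tr, dtype=int)
    y_val = np.asarray(y_val, dtype=int)

    salt = 7919 * attempt
    model = TrainedModel.initialize(spec, seed=cfg.seed + salt)
    opt = _Adam(model.params, cfg.learning_rate)
    shuffle_rng = derive_rng(cfg.seed + salt, 103)
    drop_rng = derive_rng(cfg.seed + salt, 104)

    history = {"train_loss": [], "val_accuracy": []}
    best_acc = -1.0
    best_params = {k: v.copy() for k, v in model.params.items()}
    stall = 0

    for epoch in range(cfg.max_epochs):
        order = shuffle_rng.permutation(len(x_tr))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            probs, cache = model._forward(xb, drop_rng=drop_rng)
            loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12))
            grads = model._backward(probs, yb, cache)
            if cfg.learning_rate > 0:
                opt.step(model.params, grads)
            losses.append(loss)
        val_pred = model.predict_proba(x_val) > 0.5
        acc = float(np.mean(val_pred == (y_val == 1)))
        history["train_loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(acc)
        if acc > best_acc:
            best_acc = acc
            best_params = {k: v.copy() for k, v in model.params.items()}
            stall = 0
        else:
            stall += 1
        if stall >= cfg.patience or best_acc == 1.0:
            break

    model.params = best_params
    model.history = history
    return model


def predict(model: TrainedModel, s) -> float | np.ndarray:
    """Arrhythmia-class probability for a Scalogram or raw image array."""
    if isinstance(s, Scalogram):
        s = s.normalized()
    return model.predict_proba(np.asarray(s))


def detect(p, threshold: float = 0.5):
    """Threshold probabilities: arrhythmia iff p > threshold (strict)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    arr = np.asarray(p)
    labels = np.where(arr > threshold, ARRHYTHMIA, OTHER)
    return str(labels[()]) if arr.ndim == 0 else labels
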