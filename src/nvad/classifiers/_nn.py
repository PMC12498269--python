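"""Minimal numpy neural-network kernels for the frame-wise VAD classifiers.

Contains exactly what the two network architectures need: an Adam optimizer,
softmax cross-entropy, same-padded 3x3 convolution with 2x2 max pooling
(LeNet-like CNN), and a two-layer LSTM with truncated backpropagation
through time.  Everything is seeded and pure numpy, so training is
bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "softmax", "softmax_ce", "CNNNet", "LSTMNet"]


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1 ** self.t)
            v_hat = self.v[k] / (1 - self.b2 ** self.t)
            self.params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_ce(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over rows plus gradient w.r.t. logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = -float(np.mean(np.log(probs[np.arange(n), targets] + 1e-12)))
    dlogits = probs.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return loss, dlogits / n


# ---------------------------------------------------------------------------
# convolution helpers (stride 1, 'same' 3x3, pad 1)

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H*W, C*k*k) patches for stride-1 same conv."""
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (B, C, H, W, k, k) -> (B, H, W, C, k, k)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * W, C * k * k)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int], k: int, pad: int) -> np.ndarray:
    B, C, H, W = shape
    dxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad))
    d = dcols.reshape(B, H, W, C, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + H, j:j + W] += d[:, :, :, :, i, j]
    return dxp[:, :, pad:pad + H, pad:pad + W]


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded 3x3 conv.  W: (F, C*9), b: (F,)."""
    B, C, H, Wd = x.shape
    cols = _im2col(x, 3, 1)
    out = cols @ W.T + b  # (B, HW, F)
    out = out.transpose(0, 2, 1).reshape(B, W.shape[0], H, Wd)
    return out, (cols, x.shape)


def _conv_backward(dout: np.ndarray, W: np.ndarray, cache):
    cols, x_shape = cache
    B, F, H, Wd = dout.shape
    dflat = dout.reshape(B, F, H * Wd).transpose(0, 2, 1)  # (B, HW, F)
    dW = np.einsum("bpf,bpc->fc", dflat, cols)
    db = dflat.sum(axis=(0, 1))
    dcols = dflat @ W  # (B, HW, C*9)
    dx = _col2im(dcols, x_shape, 3, 1)
    return dx, dW, db


def _pool_forward(x: np.ndarray):
    """2x2 max pool, stride 2, floor on odd sizes."""
    B, C, H, W = x.shape
    H2, W2 = H // 2, W // 2
    xc = x[:, :, :H2 * 2, :W2 * 2]
    windows = xc.reshape(B, C, H2, 2, W2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H2, W2, 4)
    arg = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, arg[..., None], axis=-1)[..., 0]
    return out, (arg, x.shape)


def _pool_backward(dout: np.ndarray, cache):
    arg, x_shape = cache
    B, C, H, W = x_shape
    H2, W2 = H // 2, W // 2
    dwin = np.zeros((B, C, H2, W2, 4))
    np.put_along_axis(dwin, arg[..., None], dout[..., None], axis=-1)
    dx = np.zeros(x_shape)
    dx[:, :, :H2 * 2, :W2 * 2] = dwin.reshape(B, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5) \
        .reshape(B, C, H2 * 2, W2 * 2)
    return dx


class CNNNet:
    """LeNet-like net: two (conv 3x3 -> tanh -> maxpool 2x2) stages with 32
    then 64 feature maps, followed by fully-connected 128 -> 64 -> n_out
    layers with tanh activations and a softmax readout."""

    def __init__(self, in_shape: tuple[int, int], n_out: int, rng: np.random.Generator):
        H, W = in_shape
        self.in_shape = in_shape
        H2, W2 = H // 2, W // 2
        H4, W4 = H2 // 2, W2 // 2
        if H4 < 1 or W4 < 1:
            raise ValueError(f"input {in_shape} too small for two 2x2 pools")
        flat = 64 * H4 * W4

        def uni(shape, fan_in):
            k = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-k, k, shape)

        self.params = {
            "c1W": uni((32, 1 * 9), 9), "c1b": uni((32,), 9),
            "c2W": uni((64, 32 * 9), 32 * 9), "c2b": uni((64,), 32 * 9),
            "f1W": uni((flat, 128), flat), "f1b": uni((128,), flat),
            "f2W": uni((128, 64), 128), "f2b": uni((64,), 128),
            "f3W": uni((64, n_out), 64), "f3b": uni((n_out,), 64),
        }

    def forward(self, x: np.ndarray, want_cache: bool = False):
        p = self.params
        z1, cc1 = _conv_forward(x, p["c1W"], p["c1b"])
        a1 = np.tanh(z1)
        p1, cp1 = _pool_forward(a1)
        z2, cc2 = _conv_forward(p1, p["c2W"], p["c2b"])
        a2 = np.tanh(z2)
        p2, cp2 = _pool_forward(a2)
        flat = p2.reshape(x.shape[0], -1)
        h1 = np.tanh(flat @ p["f1W"] + p["f1b"])
        h2 = np.tanh(h1 @ p["f2W"] + p["f2b"])
        logits = h2 @ p["f3W"] + p["f3b"]
        if not want_cache:
            return logits, None
        return logits, (x, a1, cc1, cp1, p1, a2, cc2, cp2, p2, flat, h1, h2)

    def backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        p = self.params
        x, a1, cc1, cp1, p1, a2, cc2, cp2, p2, flat, h1, h2 = cache
        g = {}
        g["f3W"] = h2.T @ dlogits
        g["f3b"] = dlogits.sum(0)
        dh2 = (dlogits @ p["f3W"].T) * (1 - h2 * h2)
        g["f2W"] = h1.T @ dh2
        g["f2b"] = dh2.sum(0)
        dh1 = (dh2 @ p["f2W"].T) * (1 - h1 * h1)
        g["f1W"] = flat.T @ dh1
        g["f1b"] = dh1.sum(0)
        dflat = dh1 @ p["f1W"].T
        dp2 = dflat.reshape(p2.shape)
        da2 = _pool_backward(dp2, cp2) * (1 - a2 * a2)
        dp1, g["c2W"], g["c2b"] = _conv_backward(da2, p["c2W"], cc2)
        da1 = _pool_backward(dp1, cp1) * (1 - a1 * a1)
        _, g["c1W"], g["c1b"] = _conv_backward(da1, p["c1W"], cc1)
        return g


class LSTMNet:
    """Two stacked LSTM layers (100 units each by default) plus a linear
    output layer.  Gate order inside the packed weight matrices: i, f, g, o."""

    def __init__(self, n_in: int, n_out: int, hidden: int = 100,
                 rng: np.random.Generator | None = None):
        self.n_in, self.n_out, self.hidden = n_in, n_out, hidden
        rng = rng or np.random.default_rng(0)

        def uni(shape, fan):
            k = 1.0 / np.sqrt(fan)
            return rng.uniform(-k, k, shape)

        H = hidden
        self.params = {
            "Wx1": uni((n_in, 4 * H), H), "Wh1": uni((H, 4 * H), H), "b1": uni((4 * H,), H),
            "Wx2": uni((H, 4 * H), H), "Wh2": uni((H, 4 * H), H), "b2": uni((4 * H,), H),
            "Wo": uni((H, n_out), H), "bo": uni((n_out,), H),
        }

    def init_state(self, batch: int = 1) -> dict[str, np.ndarray]:
        H = self.hidden
        return {k: np.zeros((batch, H)) for k in ("h1", "c1", "h2", "c2")}

    @staticmethod
    def _sigmoid(x):
        return 1.0 / (1.0 + np.exp(-x))

    def _cell(self, x, h, c, Wx, Wh, b):
        H = self.hidden
        a = x @ Wx + h @ Wh + b
        i = self._sigmoid(a[:, :H])
        f = self._sigmoid(a[:, H:2 * H])
        g = np.tanh(a[:, 2 * H:3 * H])
        o = self._sigmoid(a[:, 3 * H:])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        return h_new, c_new, (x, h, c, i, f, g, o, c_new, tanh_c)

    def step(self, x: np.ndarray, state: dict[str, np.ndarray]):
        """One timestep; ``x`` has shape (batch, n_in)."""
        p = self.params
        h1, c1, _ = self._cell(x, state["h1"], state["c1"], p["Wx1"], p["Wh1"], p["b1"])
        h2, c2, _ = self._cell(h1, state["h2"], state["c2"], p["Wx2"], p["Wh2"], p["b2"])
        logits = h2 @ p["Wo"] + p["bo"]
        return logits, {"h1": h1, "c1": c1, "h2": h2, "c2": c2}

    def forward_chunk(self, xs: np.ndarray, state: dict[str, np.ndarray]):
        """Forward over a (T, batch, n_in) chunk, keeping caches for BPTT.

        Returns per-step logits (T, batch, n_out), the carried-out state
        (detached: treated as a constant by the next chunk's backward pass),
        and the cache list.
        """
        p = self.params
        h1, c1, h2, c2 = state["h1"], state["c1"], state["h2"], state["c2"]
        caches = []
        logits_seq = np.empty((xs.shape[0], xs.shape[1], self.n_out))
        for t in range(xs.shape[0]):
            h1, c1, k1 = self._cell(xs[t], h1, c1, p["Wx1"], p["Wh1"], p["b1"])
            h2, c2, k2 = self._cell(h1, h2, c2, p["Wx2"], p["Wh2"], p["b2"])
            logits_seq[t] = h2 @ p["Wo"] + p["bo"]
            caches.append((k1, k2, h2))
        out_state = {"h1": h1, "c1": c1, "h2": h2, "c2": c2}
        return logits_seq, out_state, caches

    def _cell_backward(self, dh, dc_next, cache, Wx, Wh):
        x, h_prev, c_prev, i, f, g, o, c_new, tanh_c = cache
        do = dh * tanh_c
        dc = dh * o * (1 - tanh_c * tanh_c) + dc_next
        di, df, dg = dc * g, dc * c_prev, dc * i
        da = np.concatenate([
            di * i * (1 - i),
            df * f * (1 - f),
            dg * (1 - g * g),
            do * o * (1 - o),
        ], axis=1)
        grads = (x.T @ da, h_prev.T @ da, da.sum(axis=0))
        dx = da @ Wx.T
        dh_prev = da @ Wh.T
        dc_prev = dc * f
        return dx, dh_prev, dc_prev, grads

    def backward_chunk(self, dlogits: np.ndarray, caches) -> dict[str, np.ndarray]:
        """BPTT over one chunk; the chunk's initial state is a constant."""
        p = self.params
        g = {k: np.zeros_like(v) for k, v in p.items()}
        B = dlogits.shape[1]
        H = self.hidden
        dh1_next = np.zeros((B, H))
        dc1_next = np.zeros((B, H))
        dh2_next = np.zeros((B, H))
        dc2_next = np.zeros((B, H))
        for t in range(dlogits.shape[0] - 1, -1, -1):
            k1, k2, h2 = caches[t]
            g["Wo"] += h2.T @ dlogits[t]
            g["bo"] += dlogits[t].sum(axis=0)
            dh2 = dlogits[t] @ p["Wo"].T + dh2_next
            dx2, dh2_next, dc2_next, (gWx2, gWh2, gb2) = self._cell_backward(
                dh2, dc2_next, k2, p["Wx2"], p["Wh2"])
            g["Wx2"] += gWx2
            g["Wh2"] += gWh2
            g["b2"] += gb2
            dh1 = dx2 + dh1_next
            _, dh1_next, dc1_next, (gWx1, gWh1, gb1) = self._cell_backward(
                dh1, dc1_next, k1, p["Wx1"], p["Wh1"])
            g["Wx1"] += gWx1
            g["Wh1"] += gWh1
            g["b1"] += gb1
        return g

    def predict_sequence(self, xs: np.ndarray, state: dict[str, np.ndarray]):
        """Classes for a (T, batch, n_in) sequence; returns (T, batch) argmax."""
        out = np.empty((xs.shape[0], xs.shape[1]), dtype=np.int64)
        for t in range(xs.shape[0]):
            logits, state = self.step(xs[t], state)
            out[t] = logits.argmax(axis=-1)
        return out, state
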