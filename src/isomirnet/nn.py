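"""A self-contained numpy implementation of the two-branch CNN+BLSTM net.

The network scores a (small RNA, target site) sequence pair for
interaction. Each one-hot encoded input (4 x L) passes through its own
1-D convolution (valid padding, stride 1, rectifier) and 1-D max pooling
(stride 1); the two branches are concatenated along the position axis,
passed through a bidirectional LSTM returning per-position states,
flattened, and fed to a rectified dense layer and a single sigmoid
output. Dropout is active only during training; an L1 penalty applies to
the convolutional kernels and the dense-layer weight matrices (never to
biases or the recurrent weights). Training minimizes binary cross-entropy
with Adam on mini-batches.

Everything here — forward pass, backpropagation through time, Adam — is
implemented directly on numpy arrays in float64, so training is exactly
reproducible under a fixed seed and gradients can be verified against
finite differences.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ParameterError


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int, m: int):
    a = rng.standard_normal((max(n, m), min(n, m)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    return q[:n, :m] if q.shape == (max(n, m), min(n, m)) and n >= m else q.T[:n, :m]


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-7)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.001):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-7
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


class InteractionNet:
    """Two-branch CNN + BLSTM interaction classifier on numpy arrays.

    Parameters mirror the published architecture: 10 kernels of size 4 x 8
    per branch, pooling size 4 (stride 1), 10 LSTM units per direction,
    a 100-unit dense layer, dropout 0.25 after the merge and 0.5 after the
    BLSTM and dense layers, L1 0.01 on convolution and dense weights.
    """

    def __init__(
        self,
        mirna_len: int = 30,
        site_len: int = 60,
        n_kernels: int = 10,
        kernel_len: int = 8,
        pool_size: int = 4,
        lstm_units: int = 10,
        dense_units: int = 100,
        dropout_merge: float = 0.25,
        dropout_lstm: float = 0.50,
        dropout_dense: float = 0.50,
        l1_penalty: float = 0.01,
        batchnorm_after_conv: bool = False,
        seed: int = 0,
    ):
        if mirna_len < kernel_len or site_len < kernel_len:
            raise ParameterError("input lengths must be >= kernel_len")
        for rate in (dropout_merge, dropout_lstm, dropout_dense):
            if not 0.0 <= rate < 1.0:
                raise ParameterError("dropout rates must be in [0, 1)")
        conv_m = mirna_len - kernel_len + 1
        conv_s = site_len - kernel_len + 1
        if pool_size > conv_m or pool_size > conv_s:
            raise ParameterError("pool_size exceeds post-convolution width")
        self.mirna_len, self.site_len = mirna_len, site_len
        self.n_kernels, self.kernel_len, self.pool_size = n_kernels, kernel_len, pool_size
        self.lstm_units, self.dense_units = lstm_units, dense_units
        self.dropouts = (dropout_merge, dropout_lstm, dropout_dense)
        self.l1_penalty = l1_penalty
        self.batchnorm = batchnorm_after_conv
        self.seed = seed

        self.pool_m = conv_m - pool_size + 1
        self.pool_s = conv_s - pool_size + 1
        self.merged_len = self.pool_m + self.pool_s
        self.flat_len = 2 * lstm_units * self.merged_len

        rng = np.random.default_rng(seed)
        K, C, J, H, D = n_kernels, 4, kernel_len, lstm_units, dense_units
        p: dict[str, np.ndarray] = {}
        for br in ("m", "s"):
            p[f"convW_{br}"] = _glorot_uniform(rng, (K, C, J), C * J, K)
            p[f"convb_{br}"] = np.zeros(K)
            if self.batchnorm:
                p[f"bn_gamma_{br}"] = np.ones(K)
                p[f"bn_beta_{br}"] = np.zeros(K)
        for dr in ("f", "b"):
            p[f"lstmW_{dr}"] = _glorot_uniform(rng, (K, 4 * H), K, 4 * H)
            p[f"lstmU_{dr}"] = np.concatenate(
                [_orthogonal(rng, H, H) for _ in range(4)], axis=1
            )
            bias = np.zeros(4 * H)
            bias[H:2 * H] = 1.0  # forget-gate bias
            p[f"lstmb_{dr}"] = bias
        p["denseW"] = _glorot_uniform(rng, (self.flat_len, D), self.flat_len, D)
        p["denseb"] = np.zeros(D)
        p["outW"] = _glorot_uniform(rng, (D, 1), D, 1)
        p["outb"] = np.zeros(1)
        self.params = p
        if self.batchnorm:
            self.bn_running = {
                br: (np.zeros(n_kernels), np.ones(n_kernels)) for br in ("m", "s")
            }
            self.bn_momentum, self.bn_eps = 0.99, 1e-3
        self._dropout_rng = np.random.default_rng(rng.integers(2 ** 31))

    # -- shapes --------------------------------------------------------------

    def shape_chain(self) -> dict[str, tuple[int, ...]]:
        """Intermediate tensor shapes (channels x positions), batch omitted."""
        return {
            "conv_mirna": (self.n_kernels, self.mirna_len - self.kernel_len + 1),
            "conv_site": (self.n_kernels, self.site_len - self.kernel_len + 1),
            "pool_mirna": (self.n_kernels, self.pool_m),
            "pool_site": (self.n_kernels, self.pool_s),
            "merged": (self.n_kernels, self.merged_len),
            "blstm": (2 * self.lstm_units, self.merged_len),
            "flatten": (self.flat_len,),
            "dense": (self.dense_units,),
            "output": (1,),
        }

    # -- forward -------------------------------------------------------------

    def _conv_forward(self, x, br, train):
        W, b = self.params[f"convW_{br}"], self.params[f"convb_{br}"]
        xw = sliding_window_view(x, self.kernel_len, axis=2)  # (B,4,T,J)
        z = np.einsum("bctj,kcj->bkt", xw, W) + b[None, :, None]
        cache = {"xw": xw, "x_shape": x.shape}
        if self.batchnorm:
            z, bn_cache = self._bn_forward(z, br, train)
            cache["bn"] = bn_cache
        a = np.maximum(z, 0.0)
        cache["z"] = z
        return a, cache

    def _bn_forward(self, z, br, train):
        gamma = self.params[f"bn_gamma_{br}"][None, :, None]
        beta = self.params[f"bn_beta_{br}"][None, :, None]
        if train:
            mean = z.mean(axis=(0, 2))
            var = z.var(axis=(0, 2))
            rm, rv = self.bn_running[br]
            m = self.bn_momentum
            self.bn_running[br] = (m * rm + (1 - m) * mean, m * rv + (1 - m) * var)
        else:
            mean, var = self.bn_running[br]
        inv = 1.0 / np.sqrt(var[None, :, None] + self.bn_eps)
        xhat = (z - mean[None, :, None]) * inv
        out = gamma * xhat + beta
        return out, {"xhat": xhat, "inv": inv, "gamma": gamma, "train": train}

    def _pool_forward(self, a):
        win = sliding_window_view(a, self.pool_size, axis=2)  # (B,K,P,S)
        idx = win.argmax(axis=3)
        out = np.take_along_axis(win, idx[..., None], axis=3)[..., 0]
        return out, idx

    def _lstm_forward(self, X, direction):
        """X: (B, T, F) time-major input; returns states (B, T, H) + cache."""
        W = self.params[f"lstmW_{direction}"]
        U = self.params[f"lstmU_{direction}"]
        b = self.params[f"lstmb_{direction}"]
        B, T, _F = X.shape
        H = self.lstm_units
        order = range(T) if direction == "f" else range(T - 1, -1, -1)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        states = np.zeros((B, T, H))
        cache = []
        for t in order:
            z = X[:, t, :] @ W + h @ U + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append({"t": t, "x": X[:, t, :], "h_prev": h, "c_prev": c,
                          "i": i, "f": f, "g": g, "o": o, "tanh_c": tanh_c})
            h, c = h_new, c_new
            states[:, t, :] = h
        return states, cache

    def _dropout(self, a, rate, train):
        if not train or rate == 0.0:
            return a, None
        mask = (self._dropout_rng.random(a.shape) >= rate) / (1.0 - rate)
        return a * mask, mask

    def forward(self, x_m, x_s, train: bool = False):
        """Probability for each pair; returns (prob (B,), cache)."""
        a_m, cm = self._conv_forward(x_m, "m", train)
        a_s, cs = self._conv_forward(x_s, "s", train)
        p_m, idx_m = self._pool_forward(a_m)
        p_s, idx_s = self._pool_forward(a_s)
        merged = np.concatenate([p_m, p_s], axis=2)            # (B, K, 70)
        merged_d, mask_merge = self._dropout(merged, self.dropouts[0], train)
        X = merged_d.transpose(0, 2, 1)                        # (B, 70, K)
        st_f, cache_f = self._lstm_forward(X, "f")
        st_b, cache_b = self._lstm_forward(X, "b")
        blstm = np.concatenate([st_f, st_b], axis=2)           # (B, 70, 2H)
        blstm_d, mask_lstm = self._dropout(blstm, self.dropouts[1], train)
        flat = blstm_d.reshape(blstm_d.shape[0], -1)           # (B, 1400)
        dz = flat @ self.params["denseW"] + self.params["denseb"]
        da = np.maximum(dz, 0.0)
        da_d, mask_dense = self._dropout(da, self.dropouts[2], train)
        logits = (da_d @ self.params["outW"] + self.params["outb"])[:, 0]
        prob = _sigmoid(logits)
        cache = {
            "cm": cm, "cs": cs, "idx_m": idx_m, "idx_s": idx_s,
            "a_m_shape": a_m.shape, "a_s_shape": a_s.shape,
            "mask_merge": mask_merge, "X": X,
            "cache_f": cache_f, "cache_b": cache_b,
            "blstm_shape": blstm.shape, "mask_lstm": mask_lstm,
            "flat": flat, "dz": dz, "da_d": da_d, "mask_dense": mask_dense,
            "prob": prob,
        }
        return prob, cache

    # -- backward ------------------------------------------------------------

    def _pool_backward(self, dout, idx, a_shape):
        da = np.zeros(a_shape)
        P = dout.shape[2]
        for w in range(self.pool_size):
            sel = idx == w
            contrib = np.where(sel, dout, 0.0)
            da[:, :, w:w + P] += contrib
        return da

    def _lstm_backward(self, dstates, cache, direction):
        W = self.params[f"lstmW_{direction}"]
        U = self.params[f"lstmU_{direction}"]
        B = dstates.shape[0]
        H = self.lstm_units
        T = dstates.shape[1]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params[f"lstmb_{direction}"])
        dX = np.zeros((B, T, W.shape[0]))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for step in reversed(cache):
            t = step["t"]
            dh = dstates[:, t, :] + dh_next
            do = dh * step["tanh_c"]
            dc = dh * step["o"] * (1.0 - step["tanh_c"] ** 2) + dc_next
            di = dc * step["g"]
            dg = dc * step["i"]
            df = dc * step["c_prev"]
            dc_next = dc * step["f"]
            dzi = di * step["i"] * (1 - step["i"])
            dzf = df * step["f"] * (1 - step["f"])
            dzg = dg * (1 - step["g"] ** 2)
            dzo = do * step["o"] * (1 - step["o"])
            dzcat = np.concatenate([dzi, dzf, dzg, dzo], axis=1)
            dW += step["x"].T @ dzcat
            dU += step["h_prev"].T @ dzcat
            db += dzcat.sum(axis=0)
            dX[:, t, :] = dzcat @ W.T
            dh_next = dzcat @ U.T
        return dX, dW, dU, db

    def _conv_backward(self, da, cache, br):
        z = cache["z"]
        dz = da * (z > 0)
        if self.batchnorm:
            dz = self._bn_backward(dz, cache["bn"], br)
        xw = cache["xw"]
        dW = np.einsum("bkt,bctj->kcj", dz, xw)
        db = dz.sum(axis=(0, 2))
        dx = np.zeros(cache["x_shape"])
        W = self.params[f"convW_{br}"]
        T = dz.shape[2]
        for j in range(self.kernel_len):
            dx[:, :, j:j + T] += np.einsum("bkt,kc->bct", dz, W[:, :, j])
        self._grads[f"convW_{br}"] = dW + self.l1_penalty * np.sign(W)
        self._grads[f"convb_{br}"] = db
        return dx

    def _bn_backward(self, dout, bn_cache, br):
        xhat, inv, gamma = bn_cache["xhat"], bn_cache["inv"], bn_cache["gamma"]
        n = dout.shape[0] * dout.shape[2]
        self._grads[f"bn_gamma_{br}"] = (dout * xhat).sum(axis=(0, 2))
        self._grads[f"bn_beta_{br}"] = dout.sum(axis=(0, 2))
        dxhat = dout * gamma
        if not bn_cache["train"]:
            return dxhat * inv
        sum_dxhat = dxhat.sum(axis=(0, 2), keepdims=True)
        sum_dxhat_x = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv / n) * (n * dxhat - sum_dxhat - xhat * sum_dxhat_x)

    def backward(self, cache, y):
        """Gradients of mean BCE + L1 w.r.t. all parameters.

        ``y`` are 0/1 labels; the sigmoid+BCE combination gives the output
        pre-activation gradient (p - y) / B directly.
        """
        self._grads: dict[str, np.ndarray] = {}
        B = y.shape[0]
        prob = cache["prob"]
        dlogits = ((prob - y) / B)[:, None]
        self._grads["outW"] = cache["da_d"].T @ dlogits \
            + self.l1_penalty * np.sign(self.params["outW"])
        self._grads["outb"] = dlogits.sum(axis=0)
        dda = dlogits @ self.params["outW"].T
        if cache["mask_dense"] is not None:
            dda = dda * cache["mask_dense"]
        ddz = dda * (cache["dz"] > 0)
        self._grads["denseW"] = cache["flat"].T @ ddz \
            + self.l1_penalty * np.sign(self.params["denseW"])
        self._grads["denseb"] = ddz.sum(axis=0)
        dflat = ddz @ self.params["denseW"].T
        dblstm = dflat.reshape(cache["blstm_shape"])
        if cache["mask_lstm"] is not None:
            dblstm = dblstm * cache["mask_lstm"]
        H = self.lstm_units
        dX_f, dWf, dUf, dbf = self._lstm_backward(dblstm[:, :, :H], cache["cache_f"], "f")
        dX_b, dWb, dUb, dbb = self._lstm_backward(dblstm[:, :, H:], cache["cache_b"], "b")
        self._grads["lstmW_f"], self._grads["lstmU_f"], self._grads["lstmb_f"] = dWf, dUf, dbf
        self._grads["lstmW_b"], self._grads["lstmU_b"], self._grads["lstmb_b"] = dWb, dUb, dbb
        dX = dX_f + dX_b
        dmerged = dX.transpose(0, 2, 1)
        if cache["mask_merge"] is not None:
            dmerged = dmerged * cache["mask_merge"]
        d_pm = dmerged[:, :, : self.pool_m]
        d_ps = dmerged[:, :, self.pool_m:]
        da_m = self._pool_backward(d_pm, cache["idx_m"], cache["a_m_shape"])
        da_s = self._pool_backward(d_ps, cache["idx_s"], cache["a_s_shape"])
        self._conv_backward(da_m, cache["cm"], "m")
        self._conv_backward(da_s, cache["cs"], "s")
        return self._grads

    # -- loss ----------------------------------------------------------------

    def loss(self, prob, y):
        eps = 1e-12
        bce = -np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps))
        l1 = self.l1_penalty * sum(
            np.abs(self.params[k]).sum()
            for k in ("convW_m", "convW_s", "denseW", "outW")
        )
        return bce + l1
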