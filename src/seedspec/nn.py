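"""A compact NumPy CNN: mapping layer, five 3x3 convolutions, global max pool.

The network turns a length-F feature-band vector into a small
3-channel square "image" and classifies it:

    affine F -> D  ->  reshape (3, s, s)  ->  5 x [conv3x3 + ReLU]
    -> global max pool -> affine -> softmax

Convolutions use padding 1 so only the stride (2 at layer 3, 1
elsewhere) changes the spatial size.  Forward/backward passes are
written as nine shifted GEMMs per convolution (one per kernel offset),
which keeps all heavy arithmetic inside BLAS; activations use the
layout (channels, batch, height, width) so each shifted slice
flattens into a single large matrix product.

Training is plain SGD with momentum on the full batch (or minibatches)
under a caller-supplied learning-rate schedule.  All parameters are
float32; initialization is uniform +-1/sqrt(fan_in) per layer, drawn
from a single integer seed, so runs are exactly reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SeedCNN", "softmax", "log_softmax"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def _uniform_init(rng, shape, fan_in, dtype, gain=1.0):
    """Uniform(+-sqrt(gain/fan_in)); gain 6 is He-style for ReLU layers.

    The small default bound is fine for the output layer, but the
    hidden layers need the He scale: under global max pooling a
    too-small initialization leaves most ReLU units dead and SGD sits
    on a near-flat plateau for hundreds of epochs.
    """
    bound = np.sqrt(gain / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class SeedCNN:
    """Mapping-reshape CNN classifier over selected feature bands.

    Parameters
    ----------
    n_input_bands : int
        Number of selected wavelengths F.
    map_dim : int
        Dimension D of the learned high-dimensional mapping; must be
        3*s*s with s even (reshaped to a 3-channel s x s image).
    widths : sequence of 5 ints
        Output channels of the five convolution layers.
    n_classes : int
        Number of varieties q.
    seed : int
        Initialization seed.
    """

    STRIDES = (1, 1, 2, 1, 1)

    def __init__(self, n_input_bands, map_dim, widths, n_classes, seed=0, dtype=np.float32):
        s2 = map_dim // 3
        s = int(round(s2**0.5))
        if 3 * s * s != map_dim or s % 2 != 0 or s <= 0:
            raise ValueError(f"map_dim {map_dim} is not 3*s^2 with s even")
        if len(widths) != 5:
            raise ValueError("widths must list 5 channel counts")
        self.n_input_bands = int(n_input_bands)
        self.map_dim = int(map_dim)
        self.side = s
        self.widths = tuple(int(w) for w in widths)
        self.n_classes = int(n_classes)
        self.seed = int(seed)
        self.dtype = dtype

        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        self.params["Wmap"] = _uniform_init(rng, (n_input_bands, map_dim), n_input_bands, dtype, gain=6.0)
        self.params["bmap"] = _uniform_init(rng, (map_dim,), n_input_bands, dtype)
        c_in = 3
        for layer, c_out in enumerate(self.widths, start=1):
            fan = c_in * 9
            self.params[f"W{layer}"] = _uniform_init(rng, (c_out, c_in, 3, 3), fan, dtype, gain=6.0)
            self.params[f"b{layer}"] = _uniform_init(rng, (c_out,), fan, dtype)
            c_in = c_out
        self.params["Whead"] = _uniform_init(rng, (self.widths[-1], n_classes), self.widths[-1], dtype)
        self.params["bhead"] = _uniform_init(rng, (n_classes,), self.widths[-1], dtype)
        self._velocity = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._buffers: dict[str, np.ndarray] = {}

    # -- introspection --------------------------------------------------
    @property
    def n_params(self) -> int:
        """Total trainable parameter count, from the weight arrays."""
        return int(sum(v.size for v in self.params.values()))

    def spatial_sizes(self) -> list[int]:
        """Output side length after each conv layer."""
        s = self.side
        out = []
        for stride in self.STRIDES:
            s = (s - 1) // stride + 1  # pad 1, kernel 3
            out.append(s)
        return out

    # -- conv primitives (im2col + one GEMM per layer) ------------------
    def _buffer(self, key, shape):
        buf = self._buffers.get(key)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, dtype=self.dtype)
            self._buffers[key] = buf
        return buf

    def _im2col(self, xp, stride, h_out, w_out, key):
        """Gather the 9 shifted views of a padded (C,N,Hp,Wp) input.

        Returns a (9*C, N*h_out*w_out) matrix in (offset, channel)
        row order, matching the kernel flattening used below.
        """
        c_in, n = xp.shape[0], xp.shape[1]
        col = self._buffer(key, (3, 3, c_in, n, h_out, w_out))
        for di in range(3):
            for dj in range(3):
                col[di, dj] = xp[
                    :, :, di : di + stride * h_out : stride, dj : dj + stride * w_out : stride
                ]
        return col.reshape(9 * c_in, n * h_out * w_out)

    @staticmethod
    def _kernel_matrix(W):
        """(C_out, C_in, 3, 3) -> (C_out, 9*C_in) in (offset, channel) order."""
        return np.ascontiguousarray(W.transpose(2, 3, 1, 0).reshape(-1, W.shape[0]).T)

    def _conv_forward(self, col, W, b):
        return self._kernel_matrix(W) @ col + b[:, None]

    def _conv_backward(self, col, W, dy, xp_shape, stride, h_out, w_out, key):
        """Gradients for one conv layer from its cached im2col matrix.

        dy: (C_out, N*h_out*w_out).  Returns (dW, db, dx) with dx
        unpadded, shaped like the layer input.
        """
        c_out = W.shape[0]
        c_in, n = xp_shape[0], xp_shape[1]
        db = dy.sum(axis=1)
        dWt = dy @ col.T  # (C_out, 9*C_in)
        dW = dWt.reshape(c_out, 3, 3, c_in).transpose(0, 3, 1, 2).copy()
        if stride == 1:
            # dx is a full 3x3 convolution of dy with the flipped,
            # channel-transposed kernel -> one well-shaped GEMM
            dyp = np.zeros((c_out, n, h_out + 2, w_out + 2), dtype=self.dtype)
            dyp[:, :, 1:-1, 1:-1] = dy.reshape(c_out, n, h_out, w_out)
            colb = self._im2col(dyp, 1, h_out, w_out, key)
            flipped = W[:, :, ::-1, ::-1]
            Wb = np.ascontiguousarray(
                flipped.transpose(2, 3, 0, 1).reshape(-1, c_in).T
            )  # (C_in, 9*C_out), column order (di, dj, c_out)
            dx = (Wb @ colb).reshape(c_in, n, h_out, w_out)
        else:
            dcol = (self._kernel_matrix(W).T @ dy).reshape(3, 3, c_in, n, h_out, w_out)
            dxp = np.zeros(xp_shape, dtype=self.dtype)
            for di in range(3):
                for dj in range(3):
                    dxp[
                        :, :, di : di + stride * h_out : stride, dj : dj + stride * w_out : stride
                    ] += dcol[di, dj]
            dx = dxp[:, :, 1:-1, 1:-1]
        return dW, db, dx

    # -- forward / backward ---------------------------------------------
    def forward(self, X, want_cache=False):
        """X: (N, F) float array -> logits (N, q); optionally a cache."""
        X = np.ascontiguousarray(X, dtype=self.dtype)
        if X.ndim != 2 or X.shape[1] != self.n_input_bands:
            raise ValueError(
                f"expected (N, {self.n_input_bands}) input, got {X.shape}"
            )
        n = X.shape[0]
        p = self.params
        mapped = X @ p["Wmap"] + p["bmap"]  # (N, D)
        # channel-major reshape: (N, 3, s, s) -> layout (3, N, s, s)
        act = mapped.reshape(n, 3, self.side, self.side).transpose(1, 0, 2, 3)
        cache = {"X": X, "cols": [], "xp_shapes": [], "masks": []} if want_cache else None
        sizes = self.spatial_sizes()
        h_in = self.side
        for layer, (c_out, stride, h_out) in enumerate(
            zip(self.widths, self.STRIDES, sizes), start=1
        ):
            xp = np.zeros((act.shape[0], n, h_in + 2, h_in + 2), dtype=self.dtype)
            xp[:, :, 1:-1, 1:-1] = act
            col = self._im2col(xp, stride, h_out, h_out, f"col{layer}")
            y = self._conv_forward(col, p[f"W{layer}"], p[f"b{layer}"])
            mask = y > 0
            y *= mask
            if want_cache:
                cache["cols"].append(col)
                cache["xp_shapes"].append(xp.shape)
                cache["masks"].append(mask)
            act = y.reshape(c_out, n, h_out, h_out)
            h_in = h_out
        flat = act.reshape(self.widths[-1], n, -1)
        pool_idx = flat.argmax(axis=2)  # (C, N)
        pooled = np.take_along_axis(flat, pool_idx[:, :, None], axis=2)[:, :, 0]  # (C, N)
        logits = pooled.T @ p["Whead"] + p["bhead"]
        if want_cache:
            cache.update(pooled=pooled, pool_idx=pool_idx, last_spatial=h_in, n=n)
            return logits, cache
        return logits

    def backward(self, cache, dlogits):
        """Gradients of a scalar loss given d(loss)/d(logits), (N, q)."""
        p = self.params
        n = cache["n"]
        grads = {}
        dlogits = dlogits.astype(self.dtype)
        grads["Whead"] = cache["pooled"] @ dlogits
        grads["bhead"] = dlogits.sum(axis=0)
        dpooled = p["Whead"] @ dlogits.T  # (C, N)
        c_last = self.widths[-1]
        hw = cache["last_spatial"] ** 2
        dflat = np.zeros((c_last, n, hw), dtype=self.dtype)
        np.put_along_axis(dflat, cache["pool_idx"][:, :, None], dpooled[:, :, None], axis=2)
        dy = dflat.reshape(c_last, -1)
        sizes = self.spatial_sizes()
        for layer in range(5, 0, -1):
            dy = dy * cache["masks"][layer - 1].reshape(dy.shape)
            h_out = sizes[layer - 1]
            dW, db, dx = self._conv_backward(
                cache["cols"][layer - 1],
                p[f"W{layer}"],
                dy,
                cache["xp_shapes"][layer - 1],
                self.STRIDES[layer - 1],
                h_out,
                h_out,
                f"colb{layer}",
            )
            grads[f"W{layer}"] = dW
            grads[f"b{layer}"] = db
            dy = dx.reshape(dx.shape[0], -1)
        # dx now holds gradient w.r.t. the reshaped mapping, layout (3, N, s, s)
        dmapped = dy.reshape(3, n, self.side, self.side).transpose(1, 0, 2, 3).reshape(n, -1)
        grads["Wmap"] = cache["X"].T @ dmapped
        grads["bmap"] = dmapped.sum(axis=0)
        return grads

    # -- prediction / optimisation --------------------------------------
    def predict_proba(self, X, batch_size=512) -> np.ndarray:
        out = []
        for lo in range(0, len(X), batch_size):
            out.append(softmax(self.forward(X[lo : lo + batch_size])))
        return np.concatenate(out, axis=0).astype(float)

    def loss_and_grads(self, X, labels):
        """Mean softmax cross-entropy and parameter gradients."""
        logits, cache = self.forward(X, want_cache=True)
        n = len(X)
        logp = log_softmax(logits)
        loss = float(-logp[np.arange(n), labels].mean())
        dlogits = softmax(logits)
        dlogits[np.arange(n), labels] -= 1.0
        dlogits /= n
        return loss, self.backward(cache, dlogits)

    def sgd_step(self, grads, lr, momentum=0.9, weight_decay=0.0):
        for k, g in grads.items():
            if weight_decay:
                g = g + weight_decay * self.params[k]
            v = self._velocity[k]
            v *= momentum
            v += g
            self.params[k] -= (lr * v).astype(self.dtype)

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state) -> None:
        for k, v in state.items():
            self.params[k] = np.asarray(v, dtype=self.dtype).copy()
        self._velocity = {k: np.zeros_like(v) for k, v in self.params.items()}
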