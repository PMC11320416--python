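"""3D layers with analytic forward/backward passes.

Conventions
-----------
* Activations are ``(C, N, D, H, W)`` float32 arrays (channel-first so that a
  convolution is a stack of GEMMs over the channel axis).
* Spatial padding is "same"-style with ceil-mode output sizes: a dimension of
  length ``n`` convolved at stride ``s`` yields ``ceil(n / s)`` samples, with
  the required zero padding split (floor, ceil) around the axis.
* ``forward(x, retain=...)`` caches what backward needs only when ``retain``
  is true, so inference on large volumes carries no training memory cost.
"""

from __future__ import annotations

import math

import numpy as np

DTYPE = np.float32


def same_geometry(n: int, k: int, stride: int, dilation: int = 1) -> tuple[int, int, int]:
    """Ceil-mode output length and (low, high) zero padding for one axis."""
    out = -(-n // stride)
    eff = (k - 1) * dilation + 1
    total = max(0, (out - 1) * stride + eff - n)
    return out, total // 2, total - total // 2


def _axis_slice(offset: int, dilation: int, stride: int, length: int) -> slice:
    start = offset * dilation
    return slice(start, start + stride * (length - 1) + 1, stride)


class Layer:
    """Base: parameters and matching gradient buffers keyed by name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for key, value in self.params.items():
            self.grads[key] = np.zeros_like(value)

    def forward(self, x: np.ndarray, retain: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, same-padded, optional stride/dilation, no bias by default.

    The kernel loop runs one GEMM per kernel offset, accumulating
    ``W[:, :, a, b, c] @ x_shifted`` — this keeps peak memory at one shifted
    copy of the input instead of a full im2col matrix.  For single-channel
    inputs with large kernels (the stem) an im2col path chunked over output
    depth is used instead, which is bandwidth-friendlier.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        dilation: int = 1,
        bias: bool = False,
        init: str = "he",
        rng: np.random.Generator | None = None,
        input_grad: bool = True,
    ) -> None:
        super().__init__()
        self.cin, self.cout = in_channels, out_channels
        self.k, self.stride, self.dilation = kernel, stride, dilation
        # first layer of a network: dL/dx is never consumed, skip computing it
        self.input_grad = input_grad
        fan_in = in_channels * kernel**3
        if init == "zero":
            weight = np.zeros((out_channels, in_channels, kernel, kernel, kernel), DTYPE)
        else:
            if rng is None:
                rng = np.random.default_rng(0)
            weight = rng.normal(
                0.0, math.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel, kernel, kernel)
            ).astype(DTYPE)
        self.params["weight"] = weight
        if bias:
            self.params["bias"] = np.zeros(out_channels, DTYPE)
        self.zero_grad()
        self._cache: tuple | None = None

    def _pad(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, ...], tuple[tuple[int, int], ...]]:
        k, s, d = self.k, self.stride, self.dilation
        geoms = [same_geometry(n, k, s, d) for n in x.shape[2:]]
        out_shape = tuple(g[0] for g in geoms)
        pads = tuple((g[1], g[2]) for g in geoms)
        if any(p != (0, 0) for p in pads):
            xp = np.pad(x, ((0, 0), (0, 0)) + pads)
        else:
            xp = x
        return xp, out_shape, pads

    def forward(self, x: np.ndarray, retain: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, DTYPE)
        cin, n = x.shape[:2]
        if cin != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {cin}")
        k, s, d = self.k, self.stride, self.dilation
        if k == 1 and s == 1:
            w2 = self.params["weight"].reshape(self.cout, self.cin)
            out2 = w2 @ x.reshape(cin, -1)
            out = out2.reshape((self.cout,) + x.shape[1:])
            if retain:
                self._cache = ("1x1", x)
        elif cin == 1 and s == 2 and d == 1:
            out, cache = self._forward_parity(x, n, retain)
            if retain:
                self._cache = cache
        else:
            xp, out_shape, pads = self._pad(x)
            do, ho, wo = out_shape
            nvox = n * do * ho * wo
            w = self.params["weight"]
            offsets = [
                (_axis_slice(a, d, s, do), _axis_slice(b, d, s, ho), _axis_slice(c, d, s, wo))
                for a in range(k)
                for b in range(k)
                for c in range(k)
            ]
            if retain and cin * k**3 * nvox * 4 < 3e8:
                # training-size tensors: materialize im2col once, reuse in backward
                cols = np.empty((k**3 * cin, nvox), DTYPE)
                for r, (sz, sy, sx) in enumerate(offsets):
                    cols[r * cin : (r + 1) * cin] = xp[:, :, sz, sy, sx].reshape(cin, nvox)
                w2 = w.transpose(0, 2, 3, 4, 1).reshape(self.cout, -1)
                out2 = w2 @ cols
                out = out2.reshape(self.cout, n, do, ho, wo)
                self._cache = ("cols", cols, offsets, x.shape, xp.shape, pads, out_shape)
            else:
                out2 = np.zeros((self.cout, nvox), DTYPE)
                for (sz, sy, sx), wo_ in zip(
                    offsets, w.reshape(self.cout, cin, -1).transpose(2, 0, 1)
                ):
                    sl = xp[:, :, sz, sy, sx].reshape(cin, nvox)
                    out2 += wo_ @ sl
                out = out2.reshape(self.cout, n, do, ho, wo)
                if retain:
                    self._cache = ("gen", xp, x.shape, pads, out_shape)
        if "bias" in self.params:
            out += self.params["bias"].reshape(-1, 1, 1, 1, 1)
        return out

    # -- stride-2 single-channel fast path (the stem) -------------------------
    #
    # A stride-2 gather has no contiguous runs, which makes naive im2col
    # memory-bound.  Splitting the padded volume into its 8 stride-2 parity
    # sub-volumes once turns every kernel-offset slice into a unit-stride
    # view with runs of full row length, after which column assembly and the
    # single (cout x k^3) GEMM run near memcpy speed.

    def _parity_views(self, xp: np.ndarray, out_shape: tuple[int, ...]):
        par = {}
        for pz in range(2):
            for py in range(2):
                for px in range(2):
                    par[(pz, py, px)] = np.ascontiguousarray(xp[:, pz::2, py::2, px::2])
        return par

    def _forward_parity(self, x: np.ndarray, n: int, retain: bool):
        k = self.k
        xp, out_shape, pads = self._pad(x)
        do, ho, wo = out_shape
        xp0 = xp[0]
        par = self._parity_views(xp0, out_shape)
        nvox = n * do * ho * wo
        wmat = self.params["weight"].reshape(self.cout, k**3)
        if retain:
            # keep full columns for the weight-gradient GEMM in backward
            cols = np.empty((k**3, nvox), DTYPE)
            row = 0
            for a in range(k):
                for b in range(k):
                    for c in range(k):
                        v = par[(a % 2, b % 2, c % 2)]
                        cols[row] = v[
                            :, a // 2 : a // 2 + do, b // 2 : b // 2 + ho, c // 2 : c // 2 + wo
                        ].reshape(nvox)
                        row += 1
            out = (wmat @ cols).reshape(self.cout, n, do, ho, wo)
            return out, ("par", cols, xp0.shape, x.shape, pads, out_shape)
        # inference: chunk over output depth to bound the column buffer
        out = np.empty((self.cout, n, do, ho, wo), DTYPE)
        chunk = max(1, int(2.5e8 / (k**3 * n * ho * wo * 4)))
        cols = np.empty((k**3, n * min(chunk, do) * ho * wo), DTYPE)
        for z0 in range(0, do, chunk):
            z1 = min(do, z0 + chunk)
            nv = n * (z1 - z0) * ho * wo
            row = 0
            for a in range(k):
                for b in range(k):
                    for c in range(k):
                        v = par[(a % 2, b % 2, c % 2)]
                        zlo = a // 2 + z0
                        cols[row, :nv] = v[
                            :, zlo : zlo + (z1 - z0), b // 2 : b // 2 + ho, c // 2 : c // 2 + wo
                        ].reshape(nv)
                        row += 1
            out[:, :, z0:z1] = (wmat @ cols[:, :nv]).reshape(
                self.cout, n, z1 - z0, ho, wo
            )
        return out, None

    def _backward_parity(self, dout: np.ndarray) -> np.ndarray:
        _, cols, xp_shape, x_shape, pads, out_shape = self._cache
        k = self.k
        do, ho, wo = out_shape
        n = x_shape[1]
        nvox = n * do * ho * wo
        dout2 = dout.reshape(self.cout, nvox)
        self.grads["weight"] += (dout2 @ cols.T).reshape(self.params["weight"].shape)
        if not self.input_grad:
            return np.zeros(x_shape, DTYPE)
        wmat = self.params["weight"].reshape(self.cout, k**3)
        dcols = wmat.T @ dout2
        # scatter back through the parity decomposition
        dpar = {
            key: np.zeros(
                (n,) + tuple(-(-(m - p) // 2) for m, p in zip(xp_shape[1:], key)), DTYPE
            )
            for key in [(pz, py, px) for pz in range(2) for py in range(2) for px in range(2)]
        }
        row = 0
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    dpar[(a % 2, b % 2, c % 2)][
                        :, a // 2 : a // 2 + do, b // 2 : b // 2 + ho, c // 2 : c // 2 + wo
                    ] += dcols[row].reshape(n, do, ho, wo)
                    row += 1
        dxp = np.zeros(xp_shape, DTYPE)
        for (pz, py, px), buf in dpar.items():
            dxp[:, pz::2, py::2, px::2] += buf
        sl = tuple(slice(p[0], p[0] + dim) for p, dim in zip(pads, x_shape[2:]))
        return dxp[None][(slice(None), slice(None)) + sl]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without retained forward")
        if "bias" in self.params:
            self.grads["bias"] += dout.sum(axis=(1, 2, 3, 4))
        if self._cache[0] == "par":
            return self._backward_parity(dout)
        if self._cache[0] == "cols":
            _, cols, offsets, x_shape, xp_shape, pads, out_shape = self._cache
            cin, n = x_shape[:2]
            k = self.k
            nvox = n * int(np.prod(out_shape))
            dout2 = dout.reshape(self.cout, nvox)
            dw2 = dout2 @ cols.T  # (cout, k^3 * cin)
            self.grads["weight"] += (
                dw2.reshape(self.cout, k, k, k, cin).transpose(0, 4, 1, 2, 3)
            )
            if not self.input_grad:
                return np.zeros(x_shape, DTYPE)
            w2 = self.params["weight"].transpose(0, 2, 3, 4, 1).reshape(self.cout, -1)
            dcols = w2.T @ dout2
            dxp = np.zeros(xp_shape, DTYPE)
            do, ho, wo = out_shape
            for r, (sz, sy, sx) in enumerate(offsets):
                dxp[:, :, sz, sy, sx] += dcols[r * cin : (r + 1) * cin].reshape(
                    cin, n, do, ho, wo
                )
            sl = tuple(slice(p[0], p[0] + dim) for p, dim in zip(pads, x_shape[2:]))
            return dxp[(slice(None), slice(None)) + sl]
        if self._cache[0] == "1x1":
            _, x = self._cache
            cin, n = x.shape[:2]
            dout2 = dout.reshape(self.cout, -1)
            x2 = x.reshape(cin, -1)
            self.grads["weight"] += (dout2 @ x2.T).reshape(self.params["weight"].shape)
            dx = (self.params["weight"].reshape(self.cout, cin).T @ dout2).reshape(x.shape)
            return dx
        _, xp, x_shape, pads, out_shape = self._cache
        cin, n = x_shape[:2]
        k, s, d = self.k, self.stride, self.dilation
        do, ho, wo = out_shape
        nvox = n * do * ho * wo
        dout2 = dout.reshape(self.cout, nvox)
        w = self.params["weight"]
        dxp = np.zeros_like(xp)
        for a in range(k):
            sz = _axis_slice(a, d, s, do)
            for b in range(k):
                sy = _axis_slice(b, d, s, ho)
                for c in range(k):
                    sx = _axis_slice(c, d, s, wo)
                    sl = xp[:, :, sz, sy, sx].reshape(cin, nvox)
                    self.grads["weight"][:, :, a, b, c] += dout2 @ sl.T
                    dxp[:, :, sz, sy, sx] += (w[:, :, a, b, c].T @ dout2).reshape(
                        cin, n, do, ho, wo
                    )
        sl = tuple(
            slice(p[0], p[0] + dim) for p, dim in zip(pads, x_shape[2:])
        )
        return dxp[(slice(None), slice(None)) + sl]


class BatchNorm3d(Layer):
    """Per-channel batch normalization with running statistics.

    Training mode (``retain=True``) normalizes by the current batch's
    (sample x spatial) statistics and updates exponential running averages;
    inference applies the frozen running statistics as a fixed affine map.
    The fixed inference affine matters here: per-sample normalization
    (instance norm) would erase absolute intensity scale, which carries part
    of the class signal this pipeline classifies on.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels, DTYPE)
        self.params["beta"] = np.zeros(channels, DTYPE)
        # state, not parameters: checkpointed but untouched by the optimizer
        self.running_mean = np.zeros(channels, DTYPE)
        self.running_var = np.ones(channels, DTYPE)
        self.zero_grad()
        self._cache = None

    def forward(self, x: np.ndarray, retain: bool = False) -> np.ndarray:
        g = self.params["gamma"].reshape(-1, 1, 1, 1, 1)
        b = self.params["beta"].reshape(-1, 1, 1, 1, 1)
        if retain:
            mean = x.mean(axis=(1, 2, 3, 4), keepdims=True)
            var = x.var(axis=(1, 2, 3, 4), keepdims=True)
            self.running_mean += self.momentum * (
                mean.ravel() - self.running_mean
            ).astype(DTYPE)
            self.running_var += self.momentum * (
                var.ravel() - self.running_var
            ).astype(DTYPE)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv
            self._cache = (xhat, inv)
            out = g * xhat + b
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            scale = (self.params["gamma"] * inv).reshape(-1, 1, 1, 1, 1)
            shift = b - scale * self.running_mean.reshape(-1, 1, 1, 1, 1)
            out = scale * x + shift
        return out.astype(DTYPE, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        g = self.params["gamma"].reshape(-1, 1, 1, 1, 1)
        self.grads["gamma"] += (dout * xhat).sum(axis=(1, 2, 3, 4))
        self.grads["beta"] += dout.sum(axis=(1, 2, 3, 4))
        dxhat = dout * g
        m1 = dxhat.mean(axis=(1, 2, 3, 4), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(1, 2, 3, 4), keepdims=True)
        return ((dxhat - m1 - xhat * m2) * inv).astype(DTYPE, copy=False)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray, retain: bool = False) -> np.ndarray:
        out = np.maximum(x, 0)
        if retain:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool3d(Layer):
    """3x3x3 max pooling at stride 2 (ceil mode, -inf padding)."""

    def __init__(self, kernel: int = 3, stride: int = 2) -> None:
        super().__init__()
        self.k, self.stride = kernel, stride
        self._cache = None

    def forward(self, x: np.ndarray, retain: bool = False) -> np.ndarray:
        k, s = self.k, self.stride
        geoms = [same_geometry(n, k, s) for n in x.shape[2:]]
        out_shape = tuple(g[0] for g in geoms)
        pads = tuple((g[1], g[2]) for g in geoms)
        xp = np.pad(x, ((0, 0), (0, 0)) + pads, constant_values=-np.inf)
        do, ho, wo = out_shape
        out = np.full(x.shape[:2] + out_shape, -np.inf, DTYPE)
        arg = np.zeros(out.shape, np.uint8)
        idx = 0
        for a in range(k):
            sz = _axis_slice(a, 1, s, do)
            for b in range(k):
                sy = _axis_slice(b, 1, s, ho)
                for c in range(k):
                    sx = _axis_slice(c, 1, s, wo)
                    sl = xp[:, :, sz, sy, sx]
                    better = sl > out
                    out[better] = sl[better]
                    arg[better] = idx
                    idx += 1
        if retain:
            self._cache = (arg, xp.shape, pads, x.shape, out_shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        arg, xp_shape, pads, x_shape, out_shape = self._cache
        k, s = self.k, self.stride
        do, ho, wo = out_shape
        dxp = np.zeros(xp_shape, DTYPE)
        idx = 0
        for a in range(k):
            sz = _axis_slice(a, 1, s, do)
            for b in range(k):
                sy = _axis_slice(b, 1, s, ho)
                for c in range(k):
                    sx = _axis_slice(c, 1, s, wo)
                    dxp[:, :, sz, sy, sx] += dout * (arg == idx)
                    idx += 1
        sl = tuple(slice(p[0], p[0] + dim) for p, dim in zip(pads, x_shape[2:]))
        return dxp[(slice(None), slice(None)) + sl]


def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Linear-interpolation matrix mapping ``n_in`` samples onto ``n_out``.

    Output sample centres are placed at ``(i + 0.5) * n_in / n_out - 0.5`` in
    input coordinates (half-pixel alignment), clamped at the boundary.
    """
    mat = np.zeros((n_out, n_in), DTYPE)
    scale = n_in / n_out
    for i in range(n_out):
        src = min(max((i + 0.5) * scale - 0.5, 0.0), n_in - 1.0)
        f = int(math.floor(src))
        w = src - f
        mat[i, f] += 1.0 - w
        if w > 0:
            mat[i, f + 1] += w
    return mat


class TrilinearResize(Layer):
    """Separable trilinear resize of (C, N, D, H, W) to a target spatial grid."""

    def __init__(self, target_shape: tuple[int, int, int]) -> None:
        super().__init__()
        self.target_shape = tuple(target_shape)
        self._mats: dict[tuple[int, int], np.ndarray] = {}
        self._in_shape = None

    def _mat(self, n_in: int, n_out: int) -> np.ndarray:
        key = (n_in, n_out)
        if key not in self._mats:
            self._mats[key] = _resize_matrix(n_in, n_out)
        return self._mats[key]

    @staticmethod
    def _apply_axis(x: np.ndarray, mat: np.ndarray, axis: int) -> np.ndarray:
        moved = np.moveaxis(x, axis, -1)
        out = moved @ mat.T
        return np.moveaxis(out, -1, axis)

    def forward(self, x: np.ndarray, retain: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        out = x
        for axis, n_out in zip((2, 3, 4), self.target_shape):
            mat = self._mat(x.shape[axis], n_out)
            out = self._apply_axis(out, mat, axis)
        return np.ascontiguousarray(out, DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        out = dout
        for axis, n_in in zip((4, 3, 2), self._in_shape[4:1:-1]):
            mat = self._mat(n_in, self.target_shape[axis - 2])
            out = self._apply_axis(out, mat.T, axis)
        return np.ascontiguousarray(out, DTYPE)


def softmax2(logits: np.ndarray) -> np.ndarray:
    """Two-channel softmax along axis 0, numerically stabilized."""
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, target: np.ndarray, pos_weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Mean voxelwise 2-class cross entropy and its gradient w.r.t. logits.

    ``target`` is a binary (N, D, H, W) array; ``pos_weight`` rescales the
    lesion class to counter the foreground/background voxel imbalance.
    """
    probs = softmax2(logits)
    t = target.astype(DTYPE)
    w = np.where(t > 0, pos_weight, 1.0).astype(DTYPE)
    eps = 1e-12
    per_vox = -(t * np.log(probs[1] + eps) + (1 - t) * np.log(probs[0] + eps)) * w
    denom = w.size
    loss = float(per_vox.sum() / denom)
    onehot = np.stack([1 - t, t])
    dlogits = (probs - onehot) * w[None] / denom
    return loss, dlogits.astype(DTYPE, copy=False)


def soft_dice_loss(logits: np.ndarray, target: np.ndarray, eps: float = 1.0) -> tuple[float, np.ndarray]:
    """1 - soft Dice of the lesion-channel probability against a binary target."""
    probs = softmax2(logits)
    p = probs[1]
    t = target.astype(DTYPE)
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum()) + eps
    dice = (2 * inter + eps) / denom
    # d dice / d p, then softmax jacobian back to the two logit channels
    ddice_dp = (2 * t * denom - (2 * inter + eps)) / denom**2
    dloss_dp = -ddice_dp
    dlogits = np.empty_like(logits)
    jac = p * (1 - p) * dloss_dp
    dlogits[1] = jac
    dlogits[0] = -jac
    return 1.0 - dice, dlogits.astype(DTYPE, copy=False)
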