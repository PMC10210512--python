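"""Layers and optimizer built on the :mod:`ocra.autodiff` engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = ["Module", "Linear", "LSTMCell", "conv2d", "maxpool2d", "Adam"]


class Module:
    """Parameter container with recursive discovery, ``pytorch``-style."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out[name] = val
            elif isinstance(val, Module):
                for sub, p in val.parameters().items():
                    out[f"{name}.{sub}"] = p
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters().values())

    def zero_grad(self):
        for p in self.parameters().values():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data[...] = arr


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    """Affine map ``y = x W + b`` with weight shape (in, out)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = Tensor(_glorot(rng, n_in, n_out, (n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y if self.bias is None else y + self.bias


class LSTMCell(Module):
    """LSTM with a single combined bias vector for the four gate blocks."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_in = n_in
        self.n_hidden = n_hidden
        self.weight = Tensor(
            _glorot(rng, n_in + n_hidden, 4 * n_hidden,
                    (n_in + n_hidden, 4 * n_hidden)),
            requires_grad=True,
        )
        bias = np.zeros(4 * n_hidden)
        bias[n_hidden:2 * n_hidden] = 1.0  # forget-gate bias
        self.bias = Tensor(bias, requires_grad=True)

    def __call__(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        z = concat([x, h], axis=-1) @ self.weight + self.bias
        n = self.n_hidden
        i = z[..., 0 * n:1 * n].sigmoid()
        f = z[..., 1 * n:2 * n].sigmoid()
        g = z[..., 2 * n:3 * n].tanh()
        o = z[..., 3 * n:4 * n].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, padding: int) -> Tensor:
    """2-D convolution (cross-correlation), stride 1, via im2col.

    ``x``: (B, C_in, H, W); ``weight``: (C_in, C_out, k, k); output keeps
    H × W under same-padding (padding = k // 2 for odd k).
    """
    k = weight.shape[-1]
    c_out = weight.shape[1]
    xd = x.data
    if padding:
        xd = np.pad(xd, [(0, 0), (0, 0), (padding, padding), (padding, padding)])
    B, C, H, W = xd.shape
    Ho, Wo = H - k + 1, W - k + 1
    windows = np.lib.stride_tricks.sliding_window_view(xd, (k, k), axis=(2, 3))
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * k * k)
    w_mat = weight.data.transpose(0, 2, 3, 1).reshape(C * k * k, c_out)
    out_data = (cols @ w_mat).reshape(B, Ho, Wo, c_out).transpose(0, 3, 1, 2)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, -1, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g_mat = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, c_out)
        if weight.requires_grad:
            gw = (cols.T @ g_mat).reshape(C, k, k, c_out).transpose(0, 3, 1, 2)
            weight._accumulate(gw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            g_cols = (g_mat @ w_mat.T).reshape(B, Ho, Wo, C, k, k)
            gx = np.zeros((B, C, H, W))
            for di in range(k):
                for dj in range(k):
                    gx[:, :, di:di + Ho, dj:dj + Wo] += \
                        g_cols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            x._accumulate(gx)

    return Tensor._make(out_data, parents, backward)


def maxpool2d(x: Tensor, k: int = 2, stride: int = 2) -> Tensor:
    """Max pooling with floor-division output size (trailing rows dropped)."""
    assert k == stride == 2, "only 2x2/2 pooling is used"
    B, C, H, W = x.shape
    Ho, Wo = H // 2, W // 2
    x = x[:, :, : Ho * 2, : Wo * 2]
    x = x.reshape(B, C, Ho, 2, Wo, 2)
    return x.max(axis=5).max(axis=3)


class Adam:
    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()
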