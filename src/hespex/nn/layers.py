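"""Network building blocks: linear / convolutional layers, pooling,
upsampling, multi-head cross-attention and masked per-nucleus pooling.

Layers follow the familiar Module pattern: a :class:`Module` owns named
:class:`Tensor` parameters, ``parameters()`` walks the tree, and weights are
initialised with He (fan-in) initialisation for every layer followed by a
ReLU, zero biases throughout.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat

__all__ = [
    "Module", "Linear", "Conv2d", "max_pool2d", "upsample_nearest",
    "label_pool", "MultiheadCrossAttention", "cross_entropy_logits",
    "he_normal",
]


def he_normal(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    """He et al. fan-in normal initialisation: std = sqrt(2 / fan_in)."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Module:
    """Minimal parameter container with recursive traversal."""

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def state_dict(self, prefix: str = "") -> dict:
        state = {}
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                state[prefix + k] = v.data.copy()
            elif isinstance(v, Module):
                state.update(v.state_dict(prefix + k + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        state.update(item.state_dict(f"{prefix}{k}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        state[f"{prefix}{k}.{i}"] = item.data.copy()
        return state

    def load_state_dict(self, state: dict, prefix: str = ""):
        for k, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                v.data = np.array(state[prefix + k], dtype=np.float64)
            elif isinstance(v, Module):
                v.load_state_dict(state, prefix + k + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_dict(state, f"{prefix}{k}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        item.data = np.array(state[f"{prefix}{k}.{i}"], dtype=np.float64)

    def to_dtype(self, dtype):
        """Cast every parameter in place (e.g. float32 for training speed)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Tensor(he_normal(rng, n_in, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """2-D convolution on NCHW tensors via im2col, 'same' padding for odd kernels."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        fan_in = c_in * kernel * kernel
        self.weight = Tensor(he_normal(rng, fan_in, (c_out, c_in, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.kernel = kernel
        self.pad = kernel // 2

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.pad)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, pad: int) -> Tensor:
    """Stride-1 convolution; x (N,C,H,W), weight (O,C,kh,kw)."""
    n, c, h, w = x.data.shape
    o, _, kh, kw = weight.data.shape
    if kh == 1 and kw == 1:
        return _conv1x1(x, weight, bias)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    # (N, C, H, W, kh, kw) view, no copy
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * kh * kw)
    wmat = weight.data.reshape(o, c * kh * kw).T
    out_data = (cols @ wmat).reshape(n, h, w, o).transpose(0, 3, 1, 2) \
        + bias.data[None, :, None, None]

    def bwd(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * h * w, o)
        if bias.requires_grad:
            bias._accum(gmat.sum(axis=0))
        if weight.requires_grad:
            weight._accum((cols.T @ gmat).T.reshape(o, c, kh, kw))
        if x.requires_grad:
            dcols = (gmat @ wmat.T).reshape(n, h, w, c, kh * kw)
            dcols = np.ascontiguousarray(dcols.transpose(0, 3, 4, 1, 2))
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + h, j:j + w] += dcols[:, :, i * kw + j]
            x._accum(dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp)

    return Tensor._result(out_data, (x, weight, bias), bwd)


def _conv1x1(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Pointwise convolution: a pure channel projection, no im2col."""
    n, c, h, w = x.data.shape
    o = weight.data.shape[0]
    xm = x.data.reshape(n, c, h * w)
    wm = weight.data.reshape(o, c)
    out_data = np.matmul(wm, xm).reshape(n, o, h, w) \
        + bias.data[None, :, None, None]

    def bwd(g):
        gm = g.reshape(n, o, h * w)
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            dw = np.matmul(gm, xm.transpose(0, 2, 1)).sum(axis=0)
            weight._accum(dw.reshape(o, c, 1, 1))
        if x.requires_grad:
            x._accum(np.matmul(wm.T, gm).reshape(n, c, h, w))

    return Tensor._result(out_data, (x, weight, bias), bwd)


def max_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k x k max pooling; spatial dims must divide by k."""
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims ({h},{w}) not divisible by pool size {k}")
    h2, w2 = h // k, w // k
    blocks = x.data.reshape(n, c, h2, k, w2, k).transpose(0, 1, 2, 4, 3, 5) \
        .reshape(n, c, h2, w2, k * k)
    idx = blocks.argmax(axis=-1)
    out_data = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        db = np.zeros((n, c, h2, w2, k * k))
        np.put_along_axis(db, idx[..., None], g[..., None], axis=-1)
        x._accum(db.reshape(n, c, h2, w2, k, k).transpose(0, 1, 2, 4, 3, 5)
                 .reshape(n, c, h, w))

    return Tensor._result(out_data, (x,), bwd)


def upsample_nearest(x: Tensor, f: int) -> Tensor:
    """Nearest-neighbour upsampling by integer factor f."""
    n, c, h, w = x.data.shape
    out_data = np.repeat(np.repeat(x.data, f, axis=2), f, axis=3)

    def bwd(g):
        x._accum(g.reshape(n, c, h, f, w, f).sum(axis=(3, 5)))

    return Tensor._result(out_data, (x,), bwd)


def label_pool(feat: Tensor, labels: np.ndarray, ids: np.ndarray) -> Tensor:
    """Mask-pool a (C,H,W) feature volume over nucleus instances.

    For each id in ``ids``, output the per-channel sum of features over the
    pixels with that label, divided by the pixel area of the instance —
    the size-normalised nuclei-level feature of the morphology branch.
    Returns (len(ids), C).
    """
    c = feat.data.shape[0]
    lab = np.asarray(labels).ravel()
    ids = np.asarray(ids, dtype=np.int64)
    if ids.size == 0:
        raise ValueError("label_pool requires at least one nucleus id")
    kmax = int(max(lab.max(initial=0), ids.max())) + 1
    areas = np.bincount(lab, minlength=kmax)[ids]
    if np.any(areas == 0):
        missing = ids[areas == 0]
        raise KeyError(f"nucleus ids absent from instance map: {missing.tolist()}")
    dtype = feat.data.dtype
    flat = feat.data.reshape(c, -1)
    sums = np.empty((ids.size, c), dtype=dtype)
    for ch in range(c):
        sums[:, ch] = np.bincount(lab, weights=flat[ch], minlength=kmax)[ids]
    out_data = sums / areas[:, None].astype(dtype)

    def bwd(g):
        # scatter: d feat[ch, pixel] = g[row(label), ch] / area(label)
        row_of = np.full(kmax, -1, dtype=np.int64)
        row_of[ids] = np.arange(ids.size)
        rows = row_of[lab]
        valid = rows >= 0
        gflat = np.zeros((c, lab.size), dtype=dtype)
        scaled = (g / areas[:, None]).astype(dtype)
        gflat[:, valid] = scaled[rows[valid]].T
        feat._accum(gflat.reshape(feat.data.shape))

    return Tensor._result(out_data, (feat,), bwd)


class MultiheadCrossAttention(Module):
    """Multi-head cross-attention with a single query token per item.

    Queries, keys and values arrive as (B, Tq, D) / (B, Tk, D); scaled
    dot-product attention runs independently per head, heads are concatenated
    and passed through an output projection.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must divide by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def forward(self, query: Tensor, keyval: Tensor) -> Tensor:
        b, tq, d = query.data.shape
        tk = keyval.data.shape[1]
        h, dh = self.n_heads, self.d_head
        q = self.wq(query).reshape(b, tq, h, dh).transpose(0, 2, 1, 3)
        k = self.wk(keyval).reshape(b, tk, h, dh).transpose(0, 2, 1, 3)
        v = self.wv(keyval).reshape(b, tk, h, dh).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, tq, d)
        return self.wo(ctx)


def cross_entropy_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy between logits (N, M) and integer targets (N,)."""
    targets = np.asarray(targets, dtype=np.int64)
    n = logits.data.shape[0]
    logp = logits.log_softmax(axis=-1)
    picked = logp[np.arange(n), targets]
    return -picked.mean()
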