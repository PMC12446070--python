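"""UNet3+-style backbone for joint nuclei segmentation and per-pixel
cell-type classification.

The network has an encoding and a decoding branch over five feature scales
(by default) with full-scale skip connections: every decoder stage
aggregates features from *all* scales — encoder maps max-pooled down,
decoder maps upsampled — each reduced to ``skip_width`` channels, then fused
by a convolution.  Deep supervision is not used.  The per-pixel class
probabilities (cell types plus background) come from a 1x1 classifier on
the full-resolution decoder stage.

Two feature volumes are exported for downstream heads: the output of the
first convolutional layer (``base_width`` channels) and of the last decoder
fusion (``levels * skip_width`` channels), both at input resolution — with
the default widths their concatenation is the 384-dimensional per-pixel
feature used for nucleus pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, Module, Tensor, concat, max_pool2d, upsample_nearest

__all__ = ["BackboneConfig", "SegOutput", "UNet3PlusBackbone",
           "forward_backbone", "morphology_loss"]

EPS_PROB = 1e-8  # clamp inside logs


@dataclass
class BackboneConfig:
    """Architecture hyperparameters.

    ``levels`` feature scales, ``base_width`` channels of the first
    convolution, ``skip_width`` channels contributed by each scale to every
    full-scale skip aggregation, ``n_classes`` output classes (cell types
    plus background).  Encoder widths double per level.
    """

    levels: int = 5
    base_width: int = 64
    skip_width: int = 64
    n_classes: int = 9

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("need at least 2 levels")
        if min(self.base_width, self.skip_width, self.n_classes) < 1:
            raise ValueError("widths and class count must be >= 1")

    @property
    def encoder_widths(self) -> list[int]:
        return [self.base_width * 2 ** i for i in range(self.levels)]

    @property
    def last_width(self) -> int:
        return self.levels * self.skip_width

    @property
    def pooled_dim(self) -> int:
        return self.base_width + self.last_width


@dataclass
class SegOutput:
    """Backbone outputs for a batch of patches (NCHW tensors).

    ``class_probs``: (N, n_classes, H, W), per-pixel probability simplex;
    ``first_features``: (N, base_width, H, W);
    ``last_features``: (N, levels * skip_width, H, W).
    ``logits`` is kept for numerically stable losses.
    """

    class_probs: Tensor
    first_features: Tensor
    last_features: Tensor
    logits: Tensor


class UNet3PlusBackbone(Module):
    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        self.cfg = cfg
        L = cfg.levels
        widths = cfg.encoder_widths
        self.enc = [Conv2d(3 if i == 0 else widths[i - 1], widths[i], 3, rng)
                    for i in range(L)]
        # decoder stages d = L-2 .. 0; each aggregates L sources
        self.skip_convs = []   # skip_convs[d][s]: source scale s -> skip_width
        self.fusions = []
        dec_width = cfg.last_width
        for d in range(L - 2, -1, -1):
            per_source = []
            for s in range(L):
                c_in = widths[s] if s <= d else (widths[L - 1] if s == L - 1 else dec_width)
                # pointwise channel projections; spatial mixing happens in
                # the 3x3 encoder convs and the 3x3 fusion conv below
                per_source.append(Conv2d(c_in, cfg.skip_width, 1, rng))
            self.skip_convs.append(per_source)
            self.fusions.append(Conv2d(dec_width, dec_width, 3, rng))
        self.classifier = Conv2d(dec_width, cfg.n_classes, 1, rng)

    def forward(self, x: Tensor) -> SegOutput:
        cfg = self.cfg
        L = cfg.levels
        n, c, h, w = x.data.shape
        div = 2 ** (L - 1)
        if h % div or w % div:
            raise ValueError(
                f"input spatial dims ({h},{w}) must be divisible by {div}; "
                f"pad or crop the patch to a multiple of {div}")
        encs = []
        cur = x
        for i, conv in enumerate(self.enc):
            if i > 0:
                cur = max_pool2d(cur, 2)
            cur = conv(cur).relu()
            encs.append(cur)
        decs = {L - 1: encs[L - 1]}
        for stage, d in enumerate(range(L - 2, -1, -1)):
            parts = []
            for s in range(L):
                if s < d:
                    src = max_pool2d(encs[s], 2 ** (d - s))
                elif s == d:
                    src = encs[s]
                else:
                    src = upsample_nearest(decs[s], 2 ** (s - d))
                parts.append(self.skip_convs[stage][s](src).relu())
            fused = self.fusions[stage](concat(parts, axis=1)).relu()
            decs[d] = fused
        last = decs[0]
        logits = self.classifier(last)
        return SegOutput(class_probs=logits.softmax(axis=1),
                         first_features=encs[0], last_features=last,
                         logits=logits)


def forward_backbone(patch: np.ndarray | Tensor, net: UNet3PlusBackbone) -> SegOutput:
    """Run the backbone on a standardized patch.

    Accepts (H, W, 3) / (3, H, W) single patches or (N, 3, H, W) batches.
    """
    if isinstance(patch, Tensor):
        x = patch
    else:
        arr = np.asarray(patch, dtype=np.float64)
        if arr.ndim == 3 and arr.shape[2] == 3:
            arr = arr.transpose(2, 0, 1)
        if arr.ndim == 3:
            arr = arr[None]
        x = Tensor(arr)
    return net(x)


def morphology_loss(class_probs: Tensor | np.ndarray, target: np.ndarray) -> Tensor:
    """Per-pixel cross-entropy of the segmentation/classification map.

    ``-1/N sum_i sum_j I_ij log p_ij`` over all N pixels of the batch, with
    probabilities clamped at 1e-8 inside the log.  ``target`` holds integer
    class indices (background 0) shaped (N, H, W) or (H, W).
    """
    probs = class_probs if isinstance(class_probs, Tensor) else Tensor(class_probs)
    target = np.asarray(target, dtype=np.int64)
    if target.ndim == 2:
        target = target[None]
    n, m = probs.data.shape[0], probs.data.shape[1]
    if target.shape != (n,) + probs.data.shape[2:]:
        raise ValueError("target shape must match the probability map")
    if target.min() < 0 or target.max() >= m:
        raise ValueError(f"targets must lie in 0..{m - 1}")
    flat = probs.transpose(0, 2, 3, 1).reshape(-1, m)
    picked = flat[np.arange(flat.data.shape[0]), target.ravel()]
    return -(picked.clip_min(EPS_PROB).log()).mean()
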