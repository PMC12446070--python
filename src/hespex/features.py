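"""Per-nucleus morphology embeddings from backbone feature volumes.

Nuclei-level features are obtained by masking the first and last backbone
feature volumes with each nucleus, summing over the nucleus pixels and
dividing by its pixel area (countering nucleus-size variability); with the
default widths this yields a 384-dimensional vector.  Patch-level features
are the spatial mean of the same two volumes.  The concatenation of the two
is mapped by two fully connected layers with ReLU to the final 256-d
embedding ``x_nucleus`` consumed by every prediction head.
"""

from __future__ import annotations

import numpy as np

from .backbone import SegOutput
from .core import InstanceMap
from .nn import Linear, Module, Tensor, concat, label_pool

__all__ = ["pool_nucleus_features", "patch_feature_vector", "NucleusEmbedder",
           "embed_nucleus"]

EMBED_DIM = 256


def pool_nucleus_features(seg: SegOutput, imap: InstanceMap,
                          batch_index: int = 0, ids=None) -> Tensor:
    """Mask-pooled, area-normalised per-nucleus features, shape (n_ids, D).

    D = base_width + levels * skip_width (384 with default widths).  ``ids``
    defaults to the instance map's valid ids in increasing order; an id
    absent from the map raises ``KeyError``.
    """
    if ids is None:
        ids = np.array(sorted(imap.valid_ids), dtype=np.int64)
    else:
        ids = np.asarray(ids, dtype=np.int64)
    if ids.size == 0:
        raise ValueError("no valid nuclei to pool")
    feat = concat([seg.first_features[batch_index],
                   seg.last_features[batch_index]], axis=0)
    return label_pool(feat, imap.labels, ids)


def patch_feature_vector(seg: SegOutput, batch_index: int = 0) -> Tensor:
    """Spatial mean of the first and last feature volumes, concatenated."""
    feat = concat([seg.first_features[batch_index],
                   seg.last_features[batch_index]], axis=0)
    return feat.mean(axis=(1, 2))


class NucleusEmbedder(Module):
    """Two fully connected layers with ReLU mapping the concatenated
    nucleus-level and patch-level features to the 256-d embedding."""

    def __init__(self, pooled_dim: int, rng: np.random.Generator,
                 hidden: int = EMBED_DIM, out: int = EMBED_DIM):
        self.fc1 = Linear(2 * pooled_dim, hidden, rng)
        self.fc2 = Linear(hidden, out, rng)

    def forward(self, pooled: Tensor, patch_vec: Tensor) -> Tensor:
        """pooled (n, D), patch_vec (D,) -> x_nucleus (n, 256)."""
        n = pooled.data.shape[0]
        tiled = patch_vec.reshape(1, -1) * Tensor(np.ones((n, 1),
                                                          dtype=pooled.data.dtype))
        x = concat([pooled, tiled], axis=1)
        return self.fc2(self.fc1(x).relu())


def embed_nucleus(pooled: Tensor | np.ndarray, patch_vec: Tensor | np.ndarray,
                  embedder: NucleusEmbedder) -> Tensor:
    """Embed pooled per-nucleus features (n, D) with their patch vector (D,)."""
    pooled = pooled if isinstance(pooled, Tensor) else Tensor(pooled)
    patch_vec = patch_vec if isinstance(patch_vec, Tensor) else Tensor(patch_vec)
    if pooled.data.shape[1] != patch_vec.data.shape[0]:
        raise ValueError("pooled and patch feature dimensions disagree")
    return embedder(pooled, patch_vec)
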