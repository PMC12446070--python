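"""Assembly of the full multitask network.

One :class:`MultitaskNetwork` owns the segmentation backbone, the nucleus
embedder, the cell-type head, the expression-consistency head, the
neighborhood-composition head, the expression predictor and any
cell-type-specific adjusted expression heads.  A forward pass over a batch
of patches produces every prediction and every training loss in one graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import BackboneConfig, UNet3PlusBackbone, morphology_loss
from .celltype import (CellTypeHead, ExpressionConsistencyHead,
                       NeighborhoodHead, celltype_class_loss,
                       consistency_losses, nc_losses)
from .core import InstanceMap
from .expression import (ExpressionPredictor, adjusted_expression_loss,
                         expression_loss)
from .features import NucleusEmbedder
from .nn import Module, Tensor, concat, label_pool

__all__ = ["NetworkConfig", "PatchSample", "MultitaskNetwork", "BatchOutput"]


@dataclass
class NetworkConfig:
    """Widths and heads of the multitask network."""

    n_types: int
    n_genes: int
    levels: int = 5
    base_width: int = 64
    skip_width: int = 64
    d_model: int = 512
    n_heads: int = 8
    embed_dim: int = 256
    adjusted_types: tuple[int, ...] = ()

    def backbone_config(self) -> BackboneConfig:
        return BackboneConfig(levels=self.levels, base_width=self.base_width,
                              skip_width=self.skip_width,
                              n_classes=self.n_types + 1)


@dataclass
class PatchSample:
    """One training/inference patch and its aligned annotations.

    ``image``: standardized (3, H, W) float array; ``labels``: nuclei
    instance map; ``ids``: the valid nucleus ids (ascending); training-only
    fields: ``type_idx`` per nucleus, ``y_log`` log-normalised expression
    rows, ``q`` ground-truth composition, ``target_map`` per-pixel class
    grid (background 0, type t -> t+1).
    """

    image: np.ndarray
    labels: np.ndarray
    ids: np.ndarray
    type_idx: np.ndarray | None = None
    y_log: np.ndarray | None = None
    q: np.ndarray | None = None
    target_map: np.ndarray | None = None

    @staticmethod
    def rasterize_types(labels: np.ndarray, ids: np.ndarray,
                        type_idx: np.ndarray) -> np.ndarray:
        """Per-pixel class targets: background 0, nucleus of type t -> t+1."""
        lut = np.zeros(int(labels.max(initial=0)) + 1, dtype=np.int64)
        lut[np.asarray(ids, dtype=np.int64)] = np.asarray(type_idx) + 1
        return lut[labels]


@dataclass
class BatchOutput:
    """Everything one forward pass produces for a batch of patches."""

    losses: dict[str, Tensor] = field(default_factory=dict)
    ct_logits: Tensor | None = None          # (total cells, n_types)
    y_prime: Tensor | None = None            # (total cells, n_genes), log scale
    y_adjusted: dict[int, Tensor] = field(default_factory=dict)
    p_est: list[np.ndarray] = field(default_factory=list)   # per patch
    x_nucleus: Tensor | None = None
    cells_per_patch: list[int] = field(default_factory=list)


class MultitaskNetwork(Module):
    """The full multitask stack.  Parameters and activations are held in
    float32 by default (float64 via ``dtype``); losses involving small
    per-cell tensors are unaffected in their contract."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator,
                 reference_log: np.ndarray | None = None,
                 dtype=np.float32):
        self.cfg = cfg
        self.dtype = np.dtype(dtype)
        self.backbone = UNet3PlusBackbone(cfg.backbone_config(), rng)
        pooled_dim = self.backbone.cfg.pooled_dim
        self.embedder = NucleusEmbedder(pooled_dim, rng, out=cfg.embed_dim)
        self.ct_head = CellTypeHead(cfg.n_types, rng, in_dim=cfg.embed_dim)
        self.cons_head = ExpressionConsistencyHead(cfg.n_genes, cfg.n_types, rng)
        self.nc_head = NeighborhoodHead(cfg.n_types, rng, in_dim=cfg.embed_dim)
        self.expr = ExpressionPredictor(cfg.n_genes, cfg.n_types, rng,
                                        reference=reference_log,
                                        d_model=cfg.d_model, n_heads=cfg.n_heads,
                                        in_dim=cfg.embed_dim)
        self.adj_heads = [ExpressionPredictor(cfg.n_genes, cfg.n_types, rng,
                                              reference=reference_log,
                                              d_model=cfg.d_model,
                                              n_heads=cfg.n_heads,
                                              in_dim=cfg.embed_dim)
                          for _ in cfg.adjusted_types]
        self.to_dtype(self.dtype)

    # ------------------------------------------------------------------
    def forward_batch(self, samples: list[PatchSample],
                      training: bool = True) -> BatchOutput:
        """Run the whole multitask stack on a batch of patches.

        With ``training=True`` all nine loss components are populated from
        the samples' annotations; otherwise only predictions are computed.
        """
        imgs = np.stack([s.image for s in samples]).astype(self.dtype)
        seg = self.backbone(Tensor(imgs))
        out = BatchOutput()

        x_all, pest_rows = [], []
        pest_tensors = []
        for b, s in enumerate(samples):
            feat = concat([seg.first_features[b], seg.last_features[b]], axis=0)
            pooled = label_pool(feat, s.labels, s.ids)
            patch_vec = feat.mean(axis=(1, 2))
            x_nuc = self.embedder(pooled, patch_vec)
            x_all.append(x_nuc)
            p_est = self.nc_head(x_nuc.mean(axis=0))
            pest_tensors.append(p_est)
            out.p_est.append(p_est.data.copy())
            pest_rows.append(p_est.reshape(1, -1)
                             * Tensor(np.ones((len(s.ids), 1),
                                              dtype=p_est.data.dtype)))
            out.cells_per_patch.append(len(s.ids))
        x = concat(x_all, axis=0)
        pest_cells = concat(pest_rows, axis=0)
        out.x_nucleus = x
        ct_logits = self.ct_head(x)
        out.ct_logits = ct_logits
        expr_out = self.expr(x, pest_cells)
        out.y_prime = expr_out.y_prime
        for t, head in zip(self.cfg.adjusted_types, self.adj_heads):
            out.y_adjusted[t] = head(x, pest_cells).y_prime

        if not training:
            return out

        types = np.concatenate([s.type_idx for s in samples])
        y_log = np.vstack([s.y_log for s in samples])
        targets = np.stack([s.target_map for s in samples])

        losses = out.losses
        losses["morph"] = morphology_loss(seg.class_probs, targets)
        losses["ct_class"] = celltype_class_loss(ct_logits, types)
        l_expr, l_embed, l_logits = consistency_losses(
            expr_out.y_prime, y_log, types, self.cons_head)
        losses["ct_expr"] = l_expr
        losses["ct_embed"] = l_embed
        losses["ct_logits"] = l_logits

        # per-patch composition losses, averaged over the batch
        ct_soft = ct_logits.softmax(axis=-1)
        nc_est_terms, nc_pr_terms = [], []
        start = 0
        for b, s in enumerate(samples):
            n = len(s.ids)
            p_ct_soft = ct_soft[np.arange(start, start + n)].mean(axis=0)
            l_est, l_pr = nc_losses(pest_tensors[b], p_ct_soft, s.q)
            nc_est_terms.append(l_est)
            nc_pr_terms.append(l_pr)
            start += n
        losses["nc_est"] = sum(nc_est_terms[1:], nc_est_terms[0]) * (1.0 / len(samples))
        losses["nc_pr"] = sum(nc_pr_terms[1:], nc_pr_terms[0]) * (1.0 / len(samples))

        losses["ge"] = expression_loss(expr_out.y_prime, y_log)
        if self.cfg.adjusted_types:
            adj_terms = [adjusted_expression_loss(out.y_adjusted[t], y_log, types, t)
                         for t in self.cfg.adjusted_types]
            total_adj = adj_terms[0]
            for term in adj_terms[1:]:
                total_adj = total_adj + term
            losses["ge_adj"] = total_adj
        else:
            losses["ge_adj"] = Tensor(0.0)
        return out

    # ------------------------------------------------------------------
    @staticmethod
    def make_sample(image_std: np.ndarray, imap: InstanceMap,
                    ids: np.ndarray, type_idx=None, y_log=None,
                    q=None) -> PatchSample:
        img = image_std.transpose(2, 0, 1) if image_std.shape[-1] == 3 else image_std
        ids = np.asarray(ids, dtype=np.int64)
        tmap = None
        if type_idx is not None:
            tmap = PatchSample.rasterize_types(imap.labels, ids,
                                               np.asarray(type_idx))
        return PatchSample(image=img, labels=imap.labels, ids=ids,
                           type_idx=None if type_idx is None
                           else np.asarray(type_idx, dtype=np.int64),
                           y_log=y_log, q=q, target_map=tmap)
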