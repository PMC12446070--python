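"""Per-cell gene expression prediction.

In reference mode the model predicts, for each nucleus embedding, a softmax
weight vector ``W`` over the averaged cell-type profiles ``R`` and forms the
base prediction ``S = W R`` — a convex combination of reference profiles.
In direct mode ``S`` comes from a plain two-layer regression of the
embedding.  Neighborhood information then enters through multi-head
cross-attention (eight heads): the patch's estimated composition ``p_est``
forms the query, ``S`` forms the key and value (one token per gene, a
learned gene-identity embedding scaled and shifted by that gene's ``S``
value); a linear layer on the attention output gives a residual ``b`` over
genes, and the prediction is ``y' = ReLU(S + b)`` (reference mode) or
``ReLU(b)`` (direct mode).  A per-type copy of the same stack provides the
adjusted predictions used for cells reassigned by the recovery mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ReferenceProfiles
from .nn import Linear, Module, MultiheadCrossAttention, Tensor

__all__ = [
    "ExpressionPredictor", "ExpressionOutput", "predict_weights",
    "weighted_profile", "attention_residual", "finalize_expression",
    "adjusted_expression_loss", "spot_aggregate", "expression_loss",
]

HIDDEN = 256


@dataclass
class ExpressionOutput:
    """Per-cell outputs: profile weights ``W`` (reference mode), base
    prediction ``S``, attention residual ``b`` and final ``y_prime``."""

    W: Tensor | None
    S: Tensor
    b: Tensor
    y_prime: Tensor


class ExpressionPredictor(Module):
    """Reference-profile regression with cross-attention (one instance also
    serves as a cell-type-specific adjusted head)."""

    def __init__(self, n_genes: int, n_types: int, rng: np.random.Generator,
                 reference: np.ndarray | None = None,
                 d_model: int = 512, n_heads: int = 8, in_dim: int = 256):
        self.n_genes = n_genes
        self.reference = None if reference is None else np.asarray(reference, float)
        if self.reference is not None and self.reference.shape[1] != n_genes:
            raise ValueError("reference gene dimension mismatch")
        n_out = self.reference.shape[0] if self.reference is not None else n_genes
        self.fc1 = Linear(in_dim, HIDDEN, rng)
        self.fc2 = Linear(HIDDEN, n_out, rng)
        # gene-identity embeddings: token_j = g_j * S_j + h_j
        self.gene_scale = Tensor(rng.normal(0, 1.0 / np.sqrt(d_model),
                                            (n_genes, d_model)), requires_grad=True)
        self.gene_shift = Tensor(np.zeros((n_genes, d_model)), requires_grad=True)
        self.query_proj = Linear(n_types, d_model, rng)
        self.attn = MultiheadCrossAttention(d_model, n_heads, rng)
        self.out_proj = Linear(d_model, n_genes, rng)

    @property
    def reference_mode(self) -> bool:
        return self.reference is not None

    def head(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())

    def forward(self, x_nucleus: Tensor, p_est: Tensor) -> ExpressionOutput:
        """x_nucleus (n, 256); p_est (n, n_types), each cell's patch
        composition (cells of one patch share rows)."""
        if self.reference_mode:
            w = self.head(x_nucleus).softmax(axis=-1)
            s = w @ Tensor(self.reference.astype(x_nucleus.data.dtype, copy=False))
        else:
            w = None
            s = self.head(x_nucleus)
        b = attention_residual(p_est, s, self)
        y = (s + b).relu() if self.reference_mode else b.relu()
        return ExpressionOutput(W=w, S=s, b=b, y_prime=y)


def predict_weights(x_nucleus: Tensor | np.ndarray,
                    predictor: ExpressionPredictor) -> Tensor:
    """Softmax profile weights on the reference simplex, shape (n, n_profiles)."""
    if not predictor.reference_mode:
        raise ValueError("profile weights require reference mode")
    x = x_nucleus if isinstance(x_nucleus, Tensor) else Tensor(np.atleast_2d(x_nucleus))
    return predictor.head(x).softmax(axis=-1)


def weighted_profile(W: Tensor | np.ndarray,
                     ref: ReferenceProfiles | np.ndarray) -> Tensor:
    """S_j = sum_k W_k R_kj — the weighted sum of reference profiles."""
    W = W if isinstance(W, Tensor) else Tensor(np.atleast_2d(W))
    R = ref.R if isinstance(ref, ReferenceProfiles) else np.asarray(ref, float)
    if W.data.shape[-1] != R.shape[0]:
        raise ValueError("weight length must equal the number of profiles")
    return W @ Tensor(R.astype(W.data.dtype, copy=False))


def attention_residual(p_est: Tensor | np.ndarray, S: Tensor | np.ndarray,
                       predictor: ExpressionPredictor) -> Tensor:
    """Cross-attention residual b (n, n_genes): query from the patch
    composition, keys/values are per-gene tokens built from S."""
    p = p_est if isinstance(p_est, Tensor) else Tensor(np.atleast_2d(p_est))
    s = S if isinstance(S, Tensor) else Tensor(np.atleast_2d(S))
    n = s.data.shape[0]
    d = predictor.gene_scale.data.shape[1]
    # (n, n_genes, d_model) tokens
    kv = predictor.gene_scale.reshape(1, predictor.n_genes, d) \
        * s.reshape(n, predictor.n_genes, 1) \
        + predictor.gene_shift.reshape(1, predictor.n_genes, d)
    q = predictor.query_proj(p).reshape(n, 1, d)
    ctx = predictor.attn(q, kv)
    return predictor.out_proj(ctx).reshape(n, predictor.n_genes)


def finalize_expression(S: Tensor | np.ndarray, b: Tensor | np.ndarray,
                        mode: str = "reference") -> Tensor:
    """y' = ReLU(S + b) in reference mode, ReLU(b) in direct mode."""
    s = S if isinstance(S, Tensor) else Tensor(S)
    bb = b if isinstance(b, Tensor) else Tensor(b)
    if s.data.shape != bb.data.shape:
        raise ValueError("S and b shapes disagree")
    if mode == "reference":
        return (s + bb).relu()
    if mode == "direct":
        return bb.relu()
    raise ValueError("mode must be 'reference' or 'direct'")


def expression_loss(pred: Tensor | np.ndarray, truth: np.ndarray) -> Tensor:
    """Mean over cells (or spots) of the squared error, averaged over genes."""
    p = pred if isinstance(pred, Tensor) else Tensor(pred)
    t = np.asarray(truth, dtype=np.float64)
    if p.data.shape != t.shape:
        raise ValueError("prediction and truth are misaligned")
    return ((p - Tensor(t.astype(p.data.dtype, copy=False))) ** 2).mean(axis=1).mean()


def adjusted_expression_loss(y_adj: Tensor | np.ndarray, y_true: np.ndarray,
                             true_types: np.ndarray, t: int) -> Tensor:
    """Masked squared-error loss of a cell-type-specific head: the mean
    squared error (over genes then cells) restricted to cells whose true
    type is ``t``; zero when the batch holds no such cell."""
    y_adj = y_adj if isinstance(y_adj, Tensor) else Tensor(y_adj)
    y_true = np.asarray(y_true, dtype=np.float64)
    true_types = np.asarray(true_types)
    if y_adj.data.shape != y_true.shape or len(true_types) != y_true.shape[0]:
        raise ValueError("rows of y_adj, y_true and true_types are misaligned")
    mask = np.flatnonzero(true_types == t)
    if mask.size == 0:
        return Tensor(0.0)
    truth = Tensor(y_true[mask].astype(y_adj.data.dtype, copy=False))
    return ((y_adj[mask] - truth) ** 2).mean(axis=1).mean()


def spot_aggregate(y_prime: Tensor | np.ndarray,
                   membership: np.ndarray, n_spots: int | None = None) -> Tensor:
    """Sum per-cell predictions within each spot patch (weak supervision).

    ``membership[i]`` is the spot index of cell i; spots without cells get a
    zero vector.  Returns (n_spots, n_genes).
    """
    y = y_prime if isinstance(y_prime, Tensor) else Tensor(np.atleast_2d(y_prime))
    membership = np.asarray(membership, dtype=np.int64)
    if n_spots is None:
        n_spots = int(membership.max(initial=-1)) + 1
    onehot = np.zeros((n_spots, membership.size), dtype=y.data.dtype)
    onehot[membership, np.arange(membership.size)] = 1.0
    return Tensor(onehot) @ y
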