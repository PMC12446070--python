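"""Cell-type prediction, expression-consistency and neighborhood-composition
heads, their losses, and the composition-guided recovery mechanism.

The recovery mechanism addresses cell types that are morphologically nearly
indistinguishable in H&E (e.g. B versus T lymphocytes): at inference the
estimated neighborhood composition ``p_est`` is compared with the
composition implied by the predicted classes ``p_CT``, and under-represented
target types receive a stochastic logit boost
``v_t = alpha * n_cells * (p_est_t - p_CT_t) * |Phi_t|`` with
``Phi_t ~ N(p_est_t, 1)`` drawn once per patch per type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Linear, Module, Tensor, cross_entropy_logits

__all__ = [
    "CellTypeHead", "ExpressionConsistencyHead", "NeighborhoodHead",
    "RecoveryParams", "predict_celltype", "celltype_class_loss",
    "consistency_losses", "estimate_nc", "nc_losses", "recover_celltypes",
    "kl_divergence",
]

EPS = 1e-8
HIDDEN = 256


class CellTypeHead(Module):
    """FC(256) -> ReLU -> FC(M): cell-type logits from x_nucleus."""

    def __init__(self, n_types: int, rng: np.random.Generator,
                 in_dim: int = 256, hidden: int = HIDDEN):
        self.fc1 = Linear(in_dim, hidden, rng)
        self.fc2 = Linear(hidden, n_types, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


def predict_celltype(x_nucleus: Tensor | np.ndarray,
                     head: CellTypeHead) -> tuple[Tensor, np.ndarray]:
    """Logits and argmax classes for embeddings (n, 256).

    Ties in the argmax resolve to the lowest class index.
    """
    x = x_nucleus if isinstance(x_nucleus, Tensor) else Tensor(np.atleast_2d(x_nucleus))
    logits = head(x)
    return logits, logits.data.argmax(axis=1)


def celltype_class_loss(logits: Tensor | np.ndarray, true_types: np.ndarray) -> Tensor:
    """Mean cross-entropy over cells between type logits and integer labels."""
    logits = logits if isinstance(logits, Tensor) else Tensor(logits)
    true_types = np.asarray(true_types, dtype=np.int64)
    m = logits.data.shape[1]
    if true_types.min(initial=0) < 0 or true_types.max(initial=0) >= m:
        raise ValueError(f"class labels must lie in 0..{m - 1}")
    return cross_entropy_logits(logits, true_types)


class ExpressionConsistencyHead(Module):
    """Shared head mapping an expression vector to a 256-d embedding and
    cell-type logits; applied to both predicted and measured expression."""

    def __init__(self, n_genes: int, n_types: int, rng: np.random.Generator,
                 hidden: int = HIDDEN):
        self.fc1 = Linear(n_genes, hidden, rng)
        self.fc2 = Linear(hidden, n_types, rng)

    def forward(self, y: Tensor) -> tuple[Tensor, Tensor]:
        embed = self.fc1(y).relu()
        return embed, self.fc2(embed)


def _cosine_rows(a: Tensor, b: Tensor) -> Tensor:
    """Row-wise cosine similarity with epsilon-regularised norms."""
    num = (a * b).sum(axis=1)
    na = ((a * a).sum(axis=1) + EPS ** 2).sqrt()
    nb = ((b * b).sum(axis=1) + EPS ** 2).sqrt()
    return num / (na * nb)


def consistency_losses(y_pred: Tensor | np.ndarray, y_true: Tensor | np.ndarray,
                       true_types: np.ndarray,
                       head: ExpressionConsistencyHead) -> tuple[Tensor, Tensor, Tensor]:
    """(L_CT_expr, L_CT_embed, L_CT_logits) for aligned expression rows.

    The shared head embeds predicted and measured expression; the
    cross-entropy term is computed exclusively on the predicted-expression
    logits, the embedding term is the mean of ``1 - cos`` between the two
    embeddings, and the logit term the mean squared logit difference
    (averaged over types and cells).
    """
    y_pred = y_pred if isinstance(y_pred, Tensor) else Tensor(y_pred)
    if not isinstance(y_true, Tensor):
        y_true = Tensor(np.asarray(y_true).astype(y_pred.data.dtype, copy=False))
    if y_pred.data.shape != y_true.data.shape:
        raise ValueError("predicted and measured expression are misaligned")
    x_pr, p_pr = head(y_pred)
    x_gt, p_gt = head(y_true)
    l_expr = celltype_class_loss(p_pr, true_types)
    l_embed = (1.0 - _cosine_rows(x_pr, x_gt)).mean()
    l_logits = ((p_pr - p_gt) ** 2).mean(axis=1).mean()
    return l_expr, l_embed, l_logits


class NeighborhoodHead(Module):
    """FC -> ReLU -> FC -> softmax over cell types; input is the mean
    nucleus embedding of a patch."""

    def __init__(self, n_types: int, rng: np.random.Generator,
                 in_dim: int = 256, hidden: int = HIDDEN):
        self.fc1 = Linear(in_dim, hidden, rng)
        self.fc2 = Linear(hidden, n_types, rng)

    def forward(self, mean_embed: Tensor) -> Tensor:
        return self.fc2(self.fc1(mean_embed).relu()).softmax(axis=-1)


def estimate_nc(x_nuclei: Tensor | np.ndarray, head: NeighborhoodHead) -> Tensor:
    """Estimated cell-type composition of a patch from its nucleus
    embeddings (n, 256); softmax output sums to 1."""
    x = x_nuclei if isinstance(x_nuclei, Tensor) else Tensor(np.atleast_2d(x_nuclei))
    if x.data.shape[0] == 0:
        raise ValueError("patch has no nuclei; exclude it from composition losses")
    return head(x.mean(axis=0))


def kl_divergence(p: Tensor | np.ndarray, q: np.ndarray) -> Tensor:
    """KL(P || Q) in nats with ratio clamped at 1e-8."""
    p = p if isinstance(p, Tensor) else Tensor(p)
    q = np.maximum(np.asarray(q, dtype=p.data.dtype), EPS)
    ratio = p.clip_min(EPS) / Tensor(q)
    return (p * ratio.log()).sum()


def nc_losses(p_est: Tensor | np.ndarray, p_ct: Tensor | np.ndarray,
              q_true: np.ndarray) -> tuple[Tensor, Tensor]:
    """(KL(p_est || q), KL(p_ct || q)) for one patch."""
    return kl_divergence(p_est, q_true), kl_divergence(p_ct, q_true)


@dataclass
class RecoveryParams:
    """Settings of the recovery mechanism.

    ``alpha`` scales the logit boost (2 by default, matching immune-type
    recovery); ``confidence_mask_threshold`` exempts cells predicted as a
    protected type with softmax probability above it; ``target_types`` are
    the class indices subject to recovery; ``protected_types`` generalises
    the original single protected type to any subset.
    """

    alpha: float = 2.0
    confidence_mask_threshold: float = 0.6
    target_types: tuple[int, ...] = ()
    protected_types: tuple[int, ...] = ()
    rng_seed: int = 0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0.0 <= self.confidence_mask_threshold <= 1.0:
            raise ValueError("confidence threshold must lie in [0, 1]")


def recover_celltypes(logits: np.ndarray, p_est: np.ndarray, p_ct: np.ndarray,
                      rp: RecoveryParams,
                      rng: np.random.Generator | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Revise the predicted classes of one patch using estimated composition.

    Per target type ``t``: ``v_t = alpha * n_cells * (p_est_t - p_ct_t) *
    |Phi_t|``, ``Phi_t ~ N(p_est_t, 1)`` drawn once per patch per type; the
    revised logit is ``v_t + logit_t``.  Cells confidently predicted as a
    protected type are exempt.  The final class is the argmax over the
    current class plus the target types on revised logits; classes outside
    the target set are never introduced.

    Returns (revised class indices, revised logits).  Deterministic for a
    fixed ``rp.rng_seed``.
    """
    logits = np.asarray(logits, dtype=np.float64)
    n_cells, m = logits.shape
    p_est = np.asarray(p_est, dtype=np.float64)
    p_ct = np.asarray(p_ct, dtype=np.float64)
    targets = [t for t in rp.target_types]
    if any(t < 0 or t >= m for t in targets):
        raise ValueError("target types outside known classes")
    current = logits.argmax(axis=1)
    revised = logits.copy()
    if rng is None:
        rng = np.random.default_rng(rp.rng_seed)
    for t in targets:
        phi = rng.normal(p_est[t], 1.0)
        v_t = rp.alpha * n_cells * (p_est[t] - p_ct[t]) * abs(phi)
        revised[:, t] = v_t + logits[:, t]
    if n_cells == 0 or not targets:
        return current, revised
    # exemption: confidently predicted protected cells keep their class
    z = logits - logits.max(axis=1, keepdims=True)
    probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    exempt = np.zeros(n_cells, dtype=bool)
    for pt in rp.protected_types:
        exempt |= (current == pt) & (probs[:, pt] > rp.confidence_mask_threshold)
    # argmax over {current class} union target_types on revised logits
    final = current.copy()
    cand_cols = np.array(sorted(set(targets)), dtype=np.int64)
    for i in range(n_cells):
        if exempt[i]:
            continue
        cands = np.unique(np.append(cand_cols, current[i]))
        final[i] = cands[np.argmax(revised[i, cands])]
    return final, revised
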