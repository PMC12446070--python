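"""Training: total-loss assembly, on-the-fly augmentation, the optimisation
loop and checkpoint selection.

The nine loss components are summed with two fixed scalings — the embedding
consistency term is scaled by 100 (it is numerically small) and the
adjusted-expression term is inversely scaled by the number of cell types in
the auxiliary prediction.  Optimisation uses AdamW at a fixed learning rate
of 1e-3 (moment decays 0.9/0.999, weight decay 1e-4), batch size 8, with
He-initialised weights, per-channel input standardisation, log-normalised
expression targets and random flip/right-angle-rotation augmentation.  One
checkpoint is kept per epoch; the deployed checkpoint is the epoch with the
best average rank of validation F1 (cell-type head) and validation mean
per-gene Pearson correlation (expression head).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import f1_score

from .network import MultitaskNetwork, PatchSample
from .nn import AdamW, no_grad

__all__ = ["TrainConfig", "total_loss", "augment", "train_model",
           "select_checkpoint", "LOSS_COMPONENTS"]

LOSS_COMPONENTS = ("morph", "ct_class", "ct_embed", "ct_logits", "ct_expr",
                   "nc_est", "nc_pr", "ge_adj", "ge")


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 8
    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.0001
    embed_loss_scale: float = 100.0
    seed: int = 0
    augmentation: bool = True

    def __post_init__(self):
        for name in ("epochs", "batch_size", "lr", "beta1", "beta2",
                     "weight_decay", "embed_loss_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def total_loss(components: dict, n_ct_aux: int,
               embed_loss_scale: float = 100.0):
    """Sum of all nine loss components with the fixed scalings.

    ``L = L_morph + L_ct_class + scale * L_ct_embed + L_ct_logits +
    L_ct_expr + L_nc_est + L_nc_pr + (1/N_CT) * L_ge_adj + L_ge``.
    """
    if n_ct_aux < 1:
        raise ValueError("n_ct_aux must be >= 1")
    missing = [k for k in LOSS_COMPONENTS if k not in components]
    if missing:
        raise KeyError(f"missing loss components: {missing}")
    c = components
    return (c["morph"] + c["ct_class"] + embed_loss_scale * c["ct_embed"]
            + c["ct_logits"] + c["ct_expr"] + c["nc_est"] + c["nc_pr"]
            + (1.0 / n_ct_aux) * c["ge_adj"] + c["ge"])


def _apply_transform(arr: np.ndarray, flip: int, rot: int) -> np.ndarray:
    """Apply flip (0 none, 1 horizontal, 2 vertical) then k*90deg rotation
    to the leading two (spatial) axes."""
    if flip == 1:
        arr = arr[:, ::-1]
    elif flip == 2:
        arr = arr[::-1, :]
    if rot:
        arr = np.rot90(arr, k=rot, axes=(0, 1))
    return np.ascontiguousarray(arr)


def augment(image: np.ndarray, label_maps: list[np.ndarray],
            rng: np.random.Generator) -> tuple[np.ndarray, list[np.ndarray]]:
    """Random flip (horizontal or vertical) and right-angle rotation (90,
    180 or 270 degrees), identical across the image and all label maps.
    Identity is included in both draws.  Spatial axes are the first two.
    """
    flip = int(rng.integers(0, 3))
    rot = int(rng.integers(0, 4))
    return (_apply_transform(image, flip, rot),
            [_apply_transform(m, flip, rot) for m in label_maps])


def _augment_sample(s: PatchSample, rng: np.random.Generator) -> PatchSample:
    img_hwc = s.image.transpose(1, 2, 0)
    img2, (labels2, tmap2) = augment(img_hwc, [s.labels, s.target_map], rng)
    return PatchSample(image=img2.transpose(2, 0, 1), labels=labels2,
                       ids=s.ids, type_idx=s.type_idx, y_log=s.y_log,
                       q=s.q, target_map=tmap2)


def _validation_metrics(net: MultitaskNetwork,
                        samples: list[PatchSample],
                        batch_size: int) -> tuple[float, float]:
    """(macro F1 of the cell-type head, mean per-gene PCC of expression)."""
    preds, trues, yps, yts = [], [], [], []
    with no_grad():
        for i in range(0, len(samples), batch_size):
            chunk = samples[i:i + batch_size]
            out = net.forward_batch(chunk, training=False)
            preds.append(out.ct_logits.data.argmax(axis=1))
            trues.append(np.concatenate([s.type_idx for s in chunk]))
            yps.append(out.y_prime.data)
            yts.append(np.vstack([s.y_log for s in chunk]))
    pred = np.concatenate(preds)
    true = np.concatenate(trues)
    f1 = f1_score(true, pred, average="macro", zero_division=0)
    yp, yt = np.vstack(yps), np.vstack(yts)
    pccs = []
    for j in range(yt.shape[1]):
        if yp[:, j].std() > 0 and yt[:, j].std() > 0:
            pccs.append(np.corrcoef(yp[:, j], yt[:, j])[0, 1])
    mean_pcc = float(np.mean(pccs)) if pccs else 0.0
    return float(f1), mean_pcc


def train_model(train_samples: list[PatchSample],
                val_samples: list[PatchSample],
                net: MultitaskNetwork,
                cfg: TrainConfig,
                verbose: bool = False) -> tuple[list[dict], pd.DataFrame]:
    """Minimise the total loss with AdamW; returns one parameter snapshot
    per epoch and a metric log (train loss, validation F1 and mean PCC).

    The order of training samples is randomised once before training; data
    augmentation is applied on the fly each epoch.  Fully reproducible for
    a fixed ``cfg.seed``.
    """
    if not train_samples:
        raise ValueError("no training samples")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(train_samples))
    samples = [train_samples[i] for i in order]
    opt = AdamW(net.parameters(), lr=cfg.lr, betas=(cfg.beta1, cfg.beta2),
                weight_decay=cfg.weight_decay)
    n_ct = net.cfg.n_types
    checkpoints, rows = [], []
    for epoch in range(cfg.epochs):
        epoch_losses = []
        for i in range(0, len(samples), cfg.batch_size):
            batch = samples[i:i + cfg.batch_size]
            if cfg.augmentation:
                batch = [_augment_sample(s, rng) for s in batch]
            out = net.forward_batch(batch, training=True)
            loss = total_loss(out.losses, n_ct, cfg.embed_loss_scale)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        val_f1, val_pcc = (_validation_metrics(net, val_samples, cfg.batch_size)
                           if val_samples else (np.nan, np.nan))
        checkpoints.append(net.state_dict())
        rows.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                     "val_f1": val_f1, "val_pcc": val_pcc})
        if verbose:
            import sys
            print(f"epoch {epoch}: loss={rows[-1]['train_loss']:.4f} "
                  f"val_f1={val_f1:.3f} val_pcc={val_pcc:.3f}", file=sys.stderr)
    return checkpoints, pd.DataFrame(rows)


def select_checkpoint(val_f1, val_pcc) -> int:
    """Epoch (0-based) with the best average of the F1 rank and PCC rank.

    Rank 1 is the best (highest) value of each metric; ties in the average
    rank resolve to the earliest epoch.
    """
    f1 = np.asarray(val_f1, dtype=np.float64)
    pcc = np.asarray(val_pcc, dtype=np.float64)
    if f1.size == 0 or f1.shape != pcc.shape:
        raise ValueError("need equal-length, non-empty metric sequences")
    r1 = rankdata(-f1, method="average")
    r2 = rankdata(-pcc, method="average")
    return int(np.argmin((r1 + r2) / 2.0))
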