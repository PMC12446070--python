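"""Whole-image prediction: overlapping tiling, largest-area nucleus
assignment, checkpoint ensembling and domain-shift knowledge injection.

An image larger than the training patch size is divided into overlapping
tiles (30-pixel overlap by default, roughly the width of the largest
nuclei); every nucleus is predicted exactly once, from the tile containing
the largest share of its pixels (ties broken by earliest tile in scan
order).  Ensembling averages post-softmax cell-type probabilities and
expression elementwise across checkpoints before the argmax/recovery step.
Knowledge injection re-runs the recovery mechanism with a very large alpha
and the predicted composition of selected types forced to zero, pushing
cells of known-present types back into the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .celltype import RecoveryParams, recover_celltypes
from .core import CellTable, ExpressionMatrix, InstanceMap
from .network import MultitaskNetwork, PatchSample
from .nn import no_grad
from .preprocess import tile_patches

__all__ = ["InferenceConfig", "predict_image", "ensemble_predict",
           "apply_knowledge_injection", "assign_nuclei_to_tiles"]


@dataclass
class InferenceConfig:
    tile_size: int = 256
    tile_overlap: int = 30
    batch_size: int = 8
    recovery: RecoveryParams | None = None
    injection_alpha: float | None = None      # e.g. 1e4 in domain-shift mode
    injection_zero_types: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.tile_overlap < self.tile_size:
            raise ValueError("require 0 <= overlap < tile_size")


def assign_nuclei_to_tiles(imap: InstanceMap,
                           origins: list[tuple[int, int]],
                           size: int) -> dict[int, list[int]]:
    """Map tile index -> nucleus ids predicted from that tile.

    Each nucleus goes to the tile containing its largest pixel area; ties
    resolve to the earliest tile in scan order.  The clamped tiling covers
    every pixel, so every nucleus is assigned exactly once.
    """
    best_area: dict[int, int] = {}
    best_tile: dict[int, int] = {}
    for t, (r0, c0) in enumerate(origins):
        crop = imap.labels[r0:r0 + size, c0:c0 + size]
        ids, counts = np.unique(crop[crop > 0], return_counts=True)
        for nid, cnt in zip(ids, counts):
            nid = int(nid)
            if nid not in imap.valid_ids:
                continue
            if cnt > best_area.get(nid, 0):
                best_area[nid] = int(cnt)
                best_tile[nid] = t
    assignment: dict[int, list[int]] = {}
    for nid, t in best_tile.items():
        assignment.setdefault(t, []).append(nid)
    for t in assignment:
        assignment[t].sort()
    total = sum(len(v) for v in assignment.values())
    assert total == len(imap.valid_ids), "tiling failed to cover some nucleus"
    return assignment


def _forward_tiles(image_std: np.ndarray, imap: InstanceMap,
                   net: MultitaskNetwork, cfg: InferenceConfig):
    """Run the network tile-by-tile; returns per-nucleus raw outputs.

    Gives (ids, ct_probs, y_prime, y_adjusted, per-tile info list) where the
    tile info carries (nucleus row indices, p_est) for recovery.
    """
    h, w = imap.shape
    origins = tile_patches((h, w), cfg.tile_size, cfg.tile_overlap)
    assignment = assign_nuclei_to_tiles(imap, origins, cfg.tile_size)
    all_ids, probs_rows, y_rows = [], [], []
    adj_rows: dict[int, list[np.ndarray]] = {t: [] for t in net.cfg.adjusted_types}
    tile_info = []
    tiles = sorted(assignment)
    with no_grad():
        for i in range(0, len(tiles), cfg.batch_size):
            chunk = tiles[i:i + cfg.batch_size]
            samples = []
            for t in chunk:
                r0, c0 = origins[t]
                img = image_std[r0:r0 + cfg.tile_size, c0:c0 + cfg.tile_size]
                labels = imap.labels[r0:r0 + cfg.tile_size, c0:c0 + cfg.tile_size]
                samples.append(PatchSample(
                    image=img.transpose(2, 0, 1), labels=labels,
                    ids=np.asarray(assignment[t], dtype=np.int64)))
            out = net.forward_batch(samples, training=False)
            start = 0
            z = out.ct_logits.data
            probs = np.exp(z - z.max(axis=1, keepdims=True))
            probs /= probs.sum(axis=1, keepdims=True)
            for j, t in enumerate(chunk):
                n = len(assignment[t])
                offset = sum(len(v) for v in all_ids)
                tile_info.append((np.arange(offset, offset + n), out.p_est[j]))
                all_ids.append(assignment[t])
                probs_rows.append(probs[start:start + n])
                y_rows.append(out.y_prime.data[start:start + n])
                for tt in net.cfg.adjusted_types:
                    adj_rows[tt].append(out.y_adjusted[tt].data[start:start + n])
                start += n
    ids = np.concatenate([np.asarray(v) for v in all_ids])
    ct_probs = np.vstack(probs_rows)
    y_prime = np.vstack(y_rows)
    y_adj = {t: np.vstack(v) for t, v in adj_rows.items() if v}
    return ids, ct_probs, y_prime, y_adj, tile_info


def _finalize(ids, ct_probs, y_prime, y_adj, tile_info, imap, net, cfg,
              gene_names, type_names, mpp) -> tuple[CellTable, ExpressionMatrix]:
    """Recovery / injection, adjusted-expression substitution, assembly."""
    classes = ct_probs.argmax(axis=1)
    rp = cfg.recovery
    if cfg.injection_alpha is not None:
        rp = RecoveryParams(alpha=cfg.injection_alpha,
                            confidence_mask_threshold=(
                                rp.confidence_mask_threshold if rp else 0.6),
                            target_types=tuple(cfg.injection_zero_types),
                            protected_types=rp.protected_types if rp else (),
                            rng_seed=cfg.seed)
    if rp is not None and rp.target_types:
        rng = np.random.default_rng(rp.rng_seed)
        logits = np.log(np.maximum(ct_probs, 1e-12))
        for rows, p_est in tile_info:
            p_ct = np.bincount(classes[rows],
                               minlength=net.cfg.n_types).astype(float)
            p_ct /= max(p_ct.sum(), 1)
            if cfg.injection_alpha is not None:
                p_ct[list(cfg.injection_zero_types)] = 0.0
            new_cls, _ = recover_celltypes(logits[rows], p_est, p_ct, rp, rng=rng)
            classes[rows] = new_cls
        for t, y_t in y_adj.items():
            moved = classes == t
            y_prime[moved] = y_t[moved]

    areas = imap.areas()
    centroids = _centroids(imap)
    order = np.argsort(ids)
    ids_sorted = ids[order]
    df = pd.DataFrame({
        "id": ids_sorted,
        "row": [centroids[i][0] for i in ids_sorted],
        "col": [centroids[i][1] for i in ids_sorted],
        "area_px": [areas[i] for i in ids_sorted],
        "type_pred": [type_names[c] for c in classes[order]],
    })
    table = CellTable(df, mpp=mpp)
    expr = ExpressionMatrix(np.maximum(y_prime[order], 0.0), gene_names,
                            scale="log_normalized")
    return table, expr


def _centroids(imap: InstanceMap) -> dict[int, tuple[float, float]]:
    rr, cc = np.nonzero(imap.labels)
    lab = imap.labels[rr, cc]
    out = {}
    for nid in imap.valid_ids:
        sel = lab == nid
        out[nid] = (float(rr[sel].mean()), float(cc[sel].mean()))
    return out


def predict_image(image: np.ndarray, imap: InstanceMap, net: MultitaskNetwork,
                  channel_mean, channel_std, cfg: InferenceConfig,
                  gene_names: list[str], type_names: list[str],
                  mpp: float = 0.5) -> tuple[CellTable, ExpressionMatrix]:
    """Predict cell types and expression for every valid nucleus of a
    (possibly large) image; each nucleus is predicted once, from the tile
    holding its largest area."""
    image_std = (np.asarray(image, dtype=np.float64)
                 - np.asarray(channel_mean).reshape(1, 1, 3)) \
        / np.asarray(channel_std).reshape(1, 1, 3)
    ids, ct_probs, y_prime, y_adj, tile_info = _forward_tiles(
        image_std, imap, net, cfg)
    return _finalize(ids, ct_probs, y_prime, y_adj, tile_info, imap, net,
                     cfg, gene_names, type_names, mpp)


def ensemble_predict(image: np.ndarray, imap: InstanceMap,
                     net: MultitaskNetwork, checkpoints: list[dict],
                     channel_mean, channel_std, cfg: InferenceConfig,
                     gene_names: list[str], type_names: list[str],
                     mpp: float = 0.5) -> tuple[CellTable, ExpressionMatrix]:
    """Average per-cell expression, cell-type probabilities and estimated
    compositions elementwise across checkpoints, then argmax/recover."""
    if not checkpoints:
        raise ValueError("need at least one checkpoint")
    image_std = (np.asarray(image, dtype=np.float64)
                 - np.asarray(channel_mean).reshape(1, 1, 3)) \
        / np.asarray(channel_std).reshape(1, 1, 3)
    acc = None
    for state in checkpoints:
        net.load_state_dict(state)
        ids, ct_probs, y_prime, y_adj, tile_info = _forward_tiles(
            image_std, imap, net, cfg)
        if acc is None:
            acc = [ids, ct_probs, y_prime,
                   {t: v.copy() for t, v in y_adj.items()},
                   [(rows, p.copy()) for rows, p in tile_info]]
        else:
            if not np.array_equal(acc[0], ids):
                raise ValueError("checkpoints disagree on nucleus assignment")
            acc[1] += ct_probs
            acc[2] += y_prime
            for t in acc[3]:
                acc[3][t] += y_adj[t]
            for k in range(len(tile_info)):
                acc[4][k][1][:] += tile_info[k][1]
    k = float(len(checkpoints))
    acc[1] /= k
    acc[2] /= k
    for t in acc[3]:
        acc[3][t] /= k
    for rows, p in acc[4]:
        p /= k
    return _finalize(acc[0], acc[1], acc[2], acc[3], acc[4], imap, net, cfg,
                     gene_names, type_names, mpp)


def apply_knowledge_injection(logits: np.ndarray, p_est: np.ndarray,
                              zero_types: tuple[int, ...], alpha: float = 1e4,
                              seed: int = 0,
                              confidence_mask_threshold: float = 0.6,
                              protected_types: tuple[int, ...] = ()
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Recovery with a very large alpha and the predicted composition of the
    injected types treated as zero; other types' logits are untouched."""
    n_types = logits.shape[1]
    p_ct = np.bincount(logits.argmax(axis=1), minlength=n_types).astype(float)
    p_ct /= max(p_ct.sum(), 1)
    p_ct[list(zero_types)] = 0.0
    rp = RecoveryParams(alpha=alpha, target_types=tuple(zero_types),
                        confidence_mask_threshold=confidence_mask_threshold,
                        protected_types=protected_types, rng_seed=seed)
    return recover_celltypes(logits, p_est, p_ct, rp)
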