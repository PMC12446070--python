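"""Model/Results interface over the multitask framework.

:class:`HistoExpressionModel` is constructed from a paired dataset (H&E
patches, nuclei instance maps, a cell table with type labels, a raw count
matrix and optional averaged reference profiles); :meth:`fit` trains the
multitask network end-to-end and returns a :class:`HistoExpressionResults`
carrying the per-epoch metric log, the selected checkpoint, held-out
diagnostics and prediction methods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, ReferenceProfiles, log_normalize
from .evaluation import celltype_metrics, per_gene_pcc, variance_ranked_genes
from .inference import InferenceConfig, ensemble_predict, predict_image
from .network import MultitaskNetwork, NetworkConfig
from .nn import no_grad
from .synthetic import SimulatedDataset
from .training import TrainConfig, select_checkpoint, train_model

__all__ = ["HistoExpressionModel", "HistoExpressionResults",
           "save_checkpoint", "load_checkpoint"]


class HistoExpressionModel:
    """Multitask histology-to-expression model bound to a dataset.

    Parameters
    ----------
    dataset : SimulatedDataset (or an object with the same fields)
        Paired patches, instance maps, cell table (with ``type_true`` and
        ``patch`` columns), raw count matrix and per-patch compositions.
    reference : ReferenceProfiles or None
        Averaged cell-type profiles; ``None`` switches the expression head
        to direct-regression mode.
    net_config, train_config : optional overrides of the architecture and
        optimisation settings.
    """

    def __init__(self, dataset: SimulatedDataset,
                 reference: ReferenceProfiles | None = None,
                 net_config: NetworkConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.dataset = dataset
        self.reference = reference
        self.type_names = sorted(dataset.cells.df["type_true"].unique())
        self.type_index = {t: i for i, t in enumerate(self.type_names)}
        self.gene_names = dataset.expression.gene_names
        if net_config is None:
            net_config = NetworkConfig(n_types=len(self.type_names),
                                       n_genes=len(self.gene_names))
        self.net_config = net_config
        self.train_config = train_config or TrainConfig()
        self.expr_log = log_normalize(dataset.expression)
        self.reference_log = (None if reference is None
                              else np.log1p(reference.R))

    @classmethod
    def from_dataset(cls, dataset: SimulatedDataset, **kwargs):
        return cls(dataset, reference=dataset.reference, **kwargs)

    # ------------------------------------------------------------------
    def _build_samples(self, patch_indices, channel_mean, channel_std):
        from .network import MultitaskNetwork as MN
        samples = []
        df = self.dataset.cells.df
        for p in patch_indices:
            rows = df.index[df["patch"] == p].to_numpy()
            if rows.size == 0:
                continue
            sub = df.loc[rows]
            ids = sub["id"].to_numpy()
            # ids in the instance map are local (1..n); recover local ids
            local = ids - ids.min() + 1 if ids.min() > 0 else ids
            imap = self.dataset.instance_maps[p]
            present = np.isin(local, list(imap.valid_ids))
            if not present.any():
                continue
            type_idx = sub["type_true"].map(self.type_index).to_numpy()
            q = np.bincount(type_idx, minlength=len(self.type_names)).astype(float)
            q /= q.sum()
            img = (self.dataset.patches[p].pixels.astype(np.float64)
                   - channel_mean.reshape(1, 1, 3)) / channel_std.reshape(1, 1, 3)
            samples.append(MN.make_sample(
                img, imap, local[present], type_idx=type_idx[present],
                y_log=self.expr_log.values[rows[present]], q=q))
        return samples

    def _channel_stats(self, patch_indices):
        pix = np.stack([self.dataset.patches[p].pixels for p in patch_indices])
        mean = pix.mean(axis=(0, 1, 2)).astype(np.float64)
        std = pix.std(axis=(0, 1, 2)).astype(np.float64)
        std[std == 0] = 1.0
        return mean, std

    # ------------------------------------------------------------------
    def fit(self, train_frac: float = 0.7, val_frac: float = 0.1,
            verbose: bool = False) -> "HistoExpressionResults":
        """Train end-to-end; the patch list is split into train/validation/
        test blocks by the given fractions."""
        n = self.dataset.n_patches
        n_train = max(int(round(train_frac * n)), 1)
        n_val = max(int(round(val_frac * n)), 1)
        train_idx = list(range(0, n_train))
        val_idx = list(range(n_train, min(n_train + n_val, n)))
        test_idx = list(range(min(n_train + n_val, n), n))
        return self.fit_split(train_idx, val_idx, test_idx, verbose=verbose)

    def fit_split(self, train_idx, val_idx, test_idx,
                  verbose: bool = False) -> "HistoExpressionResults":
        mean, std = self._channel_stats(train_idx)
        train_s = self._build_samples(train_idx, mean, std)
        val_s = self._build_samples(val_idx, mean, std)
        test_s = self._build_samples(test_idx, mean, std)
        rng = np.random.default_rng(self.train_config.seed)
        net = MultitaskNetwork(self.net_config, rng,
                               reference_log=self.reference_log)
        checkpoints, log = train_model(train_s, val_s, net,
                                       self.train_config, verbose=verbose)
        best = select_checkpoint(log["val_f1"].to_numpy(),
                                 log["val_pcc"].to_numpy()) \
            if val_s else len(checkpoints) - 1
        net.load_state_dict(checkpoints[best])
        res = HistoExpressionResults(
            model=self, network=net, checkpoints=checkpoints,
            metric_log=log, best_epoch=best,
            channel_mean=mean, channel_std=std,
            split={"train": list(train_idx), "val": list(val_idx),
                   "test": list(test_idx)})
        if test_s:
            res._evaluate_holdout(test_s)
        return res


@dataclass
class HistoExpressionResults:
    """Fitted model: selected checkpoint, training history, diagnostics."""

    model: HistoExpressionModel
    network: MultitaskNetwork
    checkpoints: list[dict]
    metric_log: pd.DataFrame
    best_epoch: int
    channel_mean: np.ndarray
    channel_std: np.ndarray
    split: dict
    holdout: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    def _evaluate_holdout(self, test_samples):
        preds, trues, yps, yts = [], [], [], []
        with no_grad():
            bs = self.model.train_config.batch_size
            for i in range(0, len(test_samples), bs):
                chunk = test_samples[i:i + bs]
                out = self.network.forward_batch(chunk, training=False)
                preds.append(out.ct_logits.data.argmax(axis=1))
                trues.append(np.concatenate([s.type_idx for s in chunk]))
                yps.append(out.y_prime.data)
                yts.append(np.vstack([s.y_log for s in chunk]))
        pred = np.concatenate(preds)
        true = np.concatenate(trues)
        names = self.model.type_names
        ct = celltype_metrics([names[i] for i in pred], [names[i] for i in true])
        yp = ExpressionMatrix(np.maximum(np.vstack(yps), 0),
                              self.model.gene_names, scale="log_normalized")
        yt = ExpressionMatrix(np.vstack(yts), self.model.gene_names,
                              scale="log_normalized")
        pcc = per_gene_pcc(yp, yt)
        ranked = variance_ranked_genes(yt)
        self.holdout = {
            "n_cells": int(len(true)),
            "celltype_accuracy": ct["accuracy"],
            "macro_f1": ct["macro_f1"],
            "per_gene_pcc": pcc,
            "mean_pcc": float(pcc.dropna().mean()),
            "variance_ranked_genes": ranked,
            "expression_pred": yp,
            "expression_true": yt,
            "types_pred": pred,
            "types_true": true,
        }

    def top_gene_pcc(self, k: int = 5) -> float:
        """Mean held-out PCC of the k highest-variance genes."""
        genes = self.holdout["variance_ranked_genes"][:k]
        return float(self.holdout["per_gene_pcc"].loc[genes].dropna().mean())

    # ------------------------------------------------------------------
    def predict(self, image: np.ndarray, imap, cfg: InferenceConfig | None = None):
        """Whole-image prediction with the selected checkpoint."""
        cfg = cfg or InferenceConfig(
            tile_size=self.model.dataset.cfg.patch_size, tile_overlap=30)
        return predict_image(image, imap, self.network, self.channel_mean,
                             self.channel_std, cfg, self.model.gene_names,
                             self.model.type_names,
                             mpp=self.model.dataset.cfg.mpp)

    def predict_ensemble(self, image, imap, epochs: list[int],
                         cfg: InferenceConfig | None = None):
        """Ensemble prediction averaging the listed epoch checkpoints."""
        cfg = cfg or InferenceConfig(
            tile_size=self.model.dataset.cfg.patch_size, tile_overlap=30)
        states = [self.checkpoints[e] for e in epochs]
        out = ensemble_predict(image, imap, self.network, states,
                               self.channel_mean, self.channel_std, cfg,
                               self.model.gene_names, self.model.type_names,
                               mpp=self.model.dataset.cfg.mpp)
        self.network.load_state_dict(self.checkpoints[self.best_epoch])
        return out

    def summary(self) -> str:
        lines = [
            "Histology-to-expression multitask model",
            "=" * 46,
            f"patches (train/val/test): {len(self.split['train'])}/"
            f"{len(self.split['val'])}/{len(self.split['test'])}",
            f"cell types: {len(self.model.type_names)}   "
            f"genes: {len(self.model.gene_names)}",
            f"epochs trained: {len(self.checkpoints)}   "
            f"selected epoch: {self.best_epoch}",
            f"final train loss: {self.metric_log['train_loss'].iloc[-1]:.4f}",
        ]
        if self.holdout:
            lines += [
                "-" * 46,
                f"held-out cells: {self.holdout['n_cells']}",
                f"cell-type accuracy: {self.holdout['celltype_accuracy']:.3f}",
                f"macro F1: {self.holdout['macro_f1']:.3f}",
                f"mean per-gene PCC: {self.holdout['mean_pcc']:.3f}",
                f"mean PCC, top-5 variance genes: {self.top_gene_pcc(5):.3f}",
            ]
        return "\n".join(lines)

    def plot_training(self, ax=None):
        """Training-loss and validation-metric curves (requires matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.metric_log["epoch"], self.metric_log["train_loss"],
                label="train loss")
        ax2 = ax.twinx()
        ax2.plot(self.metric_log["epoch"], self.metric_log["val_f1"],
                 color="C1", label="val F1")
        ax2.plot(self.metric_log["epoch"], self.metric_log["val_pcc"],
                 color="C2", label="val PCC")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax2.set_ylabel("validation metric")
        ax.axvline(self.best_epoch, ls="--", color="grey")
        return ax

    def save(self, path: str):
        save_checkpoint(path, self)


def save_checkpoint(path: str, results: HistoExpressionResults):
    """Single-file parameter archive plus a JSON manifest sidecar."""
    state = results.network.state_dict()
    np.savez_compressed(path, **state)
    manifest = {
        "net_config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(results.network.cfg).items()},
        "channel_mean": results.channel_mean.tolist(),
        "channel_std": results.channel_std.tolist(),
        "gene_names": results.model.gene_names,
        "type_names": results.model.type_names,
        "best_epoch": int(results.best_epoch),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_checkpoint(path: str, reference_log: np.ndarray | None = None):
    """Restore (network, manifest) from a saved checkpoint."""
    with open(str(path) + ".json") as fh:
        manifest = json.load(fh)
    cfgd = dict(manifest["net_config"])
    cfgd["adjusted_types"] = tuple(cfgd.get("adjusted_types", ()))
    cfg = NetworkConfig(**cfgd)
    rng = np.random.default_rng(0)
    net = MultitaskNetwork(cfg, rng, reference_log=reference_log)
    archive = np.load(str(path) if str(path).endswith(".npz")
                      else str(path) + ".npz")
    net.load_state_dict({k: archive[k] for k in archive.files})
    return net, manifest
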