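"""Evaluation metrics: per-gene Pearson correlation, SSIM on rasterised
expression images, cell-type accuracy/F1 and composition concordance,
variance-stratified correlation summaries, and the spot-mode averaging
convention (per image, then per individual, then per gene).

Undefined correlations (constant vectors) are reported as NaN sentinels and
excluded from medians, never imputed as zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity
from sklearn.metrics import accuracy_score, f1_score

from .core import CellTable, ExpressionMatrix, NCVector

__all__ = [
    "per_gene_pcc", "rasterize_expression", "ssim_per_gene",
    "celltype_metrics", "variance_ranked_genes", "stratified_correlation",
    "spot_metric_rollup",
]


def per_gene_pcc(pred: ExpressionMatrix, truth: ExpressionMatrix) -> pd.Series:
    """Pearson correlation across cells for every gene.

    Genes whose predicted or measured vector is constant get NaN.
    Requires at least two cells.
    """
    if pred.gene_names != truth.gene_names:
        raise ValueError("gene panels disagree")
    if pred.n_cells != truth.n_cells:
        raise ValueError("cell counts disagree")
    if pred.n_cells < 2:
        raise ValueError("need at least two cells for a correlation")
    x, y = pred.values, truth.values
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).sum(axis=0) / (sx * sy)
    r[(sx == 0) | (sy == 0)] = np.nan
    return pd.Series(r, index=pred.gene_names, name="pcc")


def rasterize_expression(expr: ExpressionMatrix, cells: CellTable,
                         extent: tuple[int, int], bin_size: int = 16) -> np.ndarray:
    """Per-gene spatial expression images: cell values summed per spatial
    bin, so pixel intensities equal the total expression in the bin.
    Returns (n_genes, H_bins, W_bins)."""
    h, w = extent
    hb, wb = (h + bin_size - 1) // bin_size, (w + bin_size - 1) // bin_size
    r = (cells.df["row"].to_numpy() // bin_size).astype(int).clip(0, hb - 1)
    c = (cells.df["col"].to_numpy() // bin_size).astype(int).clip(0, wb - 1)
    flat = r * wb + c
    out = np.zeros((expr.n_genes, hb * wb))
    for j in range(expr.n_genes):
        out[j] = np.bincount(flat, weights=expr.values[:, j], minlength=hb * wb)
    return out.reshape(expr.n_genes, hb, wb)


def ssim_per_gene(pred_raster: np.ndarray, truth_raster: np.ndarray,
                  gaussian: bool = True) -> np.ndarray:
    """SSIM per gene between predicted and measured expression rasters.

    Standard SSIM with a Gaussian window (``gaussian=False`` switches to a
    uniform window) and the conventional constants; the dynamic range is the
    max-minus-min of the truth raster per gene.  Zero-range (degenerate)
    truth rasters give NaN.
    """
    if pred_raster.shape != truth_raster.shape:
        raise ValueError("raster shapes disagree")
    n_genes = pred_raster.shape[0]
    out = np.full(n_genes, np.nan)
    for j in range(n_genes):
        t = truth_raster[j]
        rng = t.max() - t.min()
        if rng <= 0:
            continue
        win = min(7, (min(t.shape) // 2) * 2 - 1)
        if win < 3:
            continue
        out[j] = structural_similarity(pred_raster[j], t, data_range=rng,
                                       gaussian_weights=gaussian, win_size=win)
    return out


def celltype_metrics(pred_types, true_types) -> dict:
    """Accuracy, per-class F1, macro F1 and the two composition vectors.

    Label sets are aligned on their union (absent classes count zero).
    """
    pred = np.asarray(pred_types)
    true = np.asarray(true_types)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth lengths disagree")
    labels = sorted(set(pred.tolist()) | set(true.tolist()))
    acc = accuracy_score(true, pred)
    per_class = f1_score(true, pred, labels=labels, average=None, zero_division=0)
    macro = f1_score(true, pred, labels=labels, average="macro", zero_division=0)
    comp_pred = np.array([(pred == lab).mean() for lab in labels])
    comp_true = np.array([(true == lab).mean() for lab in labels])
    return {
        "accuracy": float(acc),
        "f1_per_class": dict(zip(labels, per_class.astype(float))),
        "macro_f1": float(macro),
        "composition_pred": NCVector(comp_pred),
        "composition_true": NCVector(comp_true),
    }


def variance_ranked_genes(expr: ExpressionMatrix) -> list[str]:
    """Genes ranked by decreasing variance of log1p values — the built-in
    fallback when no external spatially/highly-variable ranking is given."""
    values = np.log1p(expr.values) if expr.scale == "raw_counts" else expr.values
    var = values.var(axis=0)
    order = np.argsort(-var, kind="stable")
    return [expr.gene_names[j] for j in order]


def stratified_correlation(metric: pd.Series,
                           gene_lists: dict[str, list[str]]) -> pd.DataFrame:
    """Median and quartiles of a per-gene metric within named gene lists
    (e.g. top-k spatially variable genes); NaN entries are excluded."""
    rows = []
    panel = set(metric.index)
    for name, genes in gene_lists.items():
        if len(genes) > len(panel):
            raise ValueError(f"list '{name}' exceeds panel size")
        missing = [g for g in genes if g not in panel]
        if missing:
            raise ValueError(f"genes not in panel: {missing[:5]}")
        vals = metric.loc[genes].dropna()
        rows.append({"stratum": name, "n_genes": len(genes),
                     "n_defined": len(vals),
                     "median": vals.median(),
                     "q1": vals.quantile(0.25), "q3": vals.quantile(0.75)})
    return pd.DataFrame(rows)


def spot_metric_rollup(per_image: pd.DataFrame,
                       image_to_individual: dict) -> pd.DataFrame:
    """Average per-gene metrics per image, then per individual, then per
    gene — individuals weigh equally regardless of their image count.

    ``per_image``: rows = images, columns = genes.  Returns a frame with a
    per-gene mean over individuals and an overall mean.
    """
    unmapped = [img for img in per_image.index if img not in image_to_individual]
    if unmapped:
        raise ValueError(f"images without an individual: {unmapped[:5]}")
    groups = per_image.groupby(per_image.index.map(image_to_individual))
    per_individual = groups.mean()          # image-level -> individual-level
    per_gene = per_individual.mean(axis=0)  # individual-level -> gene-level
    out = per_gene.to_frame("mean_over_individuals")
    out.loc["__overall__"] = per_gene.mean()
    return out
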