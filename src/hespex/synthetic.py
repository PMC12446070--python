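"""Synthetic H&E-like data with fully known ground truth.

Real training data for histology-to-expression models pairs an H&E image
with subcellular spatial transcriptomics measurements of the same tissue.
This module emulates the parts of that pairing the model learns from:

* elliptical nuclei of several cell types rendered into RGB patches on a
  pink-white eosin-like background, each type with its own chromatin colour
  (plus a "hard" palette where two types are nearly indistinguishable);
* spatially clustered cell-type neighbourhoods — each patch draws one
  attractor point per type and assigns types by proximity, blended with a
  uniform draw by ``neighborhood_mixing`` (1 = fully mixed, i.i.d. types);
* per-cell expression counts drawn from type-specific reference profiles
  with multiplicative log-normal gene noise: ``Poisson(s * R[type] * e^eps)``
  with ``eps ~ N(0, noise_sd)`` per cell and gene and ``s`` a global size
  factor (1 by default).

All randomness flows through three independent substreams (layout,
rendering, expression) spawned from one seed, so e.g. changing the gene
panel never perturbs nucleus geometry.  Identical seeds give byte-identical
outputs.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .core import (CellTable, ExpressionMatrix, HEPatch, InstanceMap,
                   NCVector, ReferenceProfiles)

__all__ = ["SimConfig", "SimulatedDataset", "generate_reference_profiles",
           "render_patch", "generate_dataset"]

BACKGROUND_RGB = np.array([243.0, 228.0, 234.0])  # pale eosin pink


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults define the desk-scale study conditions: 4 cell types with a
    24-gene panel (4 marker genes each), 200 patches of 128 x 128 pixels at
    0.5 um/px, 8-20 nuclei per patch with radii 4-7 px, moderately clustered
    neighbourhoods (mixing 0.5) and log-normal expression noise of 0.15.
    """

    n_types: int = 4
    n_genes: int = 24
    markers_per_type: int = 4
    patch_size: int = 128
    n_patches: int = 200
    nuclei_per_patch: tuple[int, int] = (8, 20)
    nucleus_radius: tuple[float, float] = (4.0, 7.0)
    neighborhood_mixing: float = 0.5
    noise_sd: float = 0.15
    seed: int = 0
    mpp: float = 0.5
    size_factor: float = 1.0
    palette: str = "easy"  # "easy": well-separated colours; "hard": two near-twins

    def __post_init__(self):
        if self.n_genes < self.n_types * self.markers_per_type:
            raise ValueError("n_genes must be >= n_types * markers_per_type")
        for name in ("n_types", "n_genes", "markers_per_type", "patch_size", "n_patches"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.neighborhood_mixing <= 1.0:
            raise ValueError("neighborhood_mixing must lie in [0, 1]")
        if self.palette not in ("easy", "hard"):
            raise ValueError("palette must be 'easy' or 'hard'")

    def type_names(self) -> list[str]:
        return [f"type{t}" for t in range(self.n_types)]

    def substreams(self) -> tuple[np.random.Generator, ...]:
        """(layout, render, expression, profiles) independent generators."""
        seq = np.random.SeedSequence(self.seed)
        return tuple(np.random.default_rng(s) for s in seq.spawn(4))


def _type_colors(cfg: SimConfig) -> np.ndarray:
    """Base RGB per type: haematoxylin-like hues spread around blue-purple."""
    hues = 0.55 + 0.35 * np.arange(cfg.n_types) / max(cfg.n_types, 1)
    colors = np.array([colorsys.hsv_to_rgb(h % 1.0, 0.55, 0.62) for h in hues]) * 255
    if cfg.palette == "hard" and cfg.n_types >= 2:
        colors[-1] = colors[-2] + 3.0  # two nearly identical types
    return colors


def generate_reference_profiles(cfg: SimConfig) -> ReferenceProfiles:
    """Averaged expression profile per cell type with disjoint marker blocks.

    Marker genes of a type have mean expression at least five times the
    off-marker baseline, mimicking the contrast of averaged cell-type
    profiles from an annotated single-cell reference.
    """
    rng = cfg.substreams()[3]
    baseline = rng.uniform(0.4, 1.2, size=(cfg.n_types, cfg.n_genes))
    for t in range(cfg.n_types):
        lo = t * cfg.markers_per_type
        hi = lo + cfg.markers_per_type
        baseline[t, lo:hi] = rng.uniform(8.0, 16.0, size=cfg.markers_per_type)
    genes = [f"g{j:03d}" for j in range(cfg.n_genes)]
    return ReferenceProfiles(baseline, cfg.type_names(), genes)


def _assign_types(cfg: SimConfig, centers: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Spatial blob type assignment.

    Each patch draws skewed type propensities (Dirichlet) and one attractor
    point per type; a nucleus prefers types that are both locally dominant
    and spatially near, blended with a uniform draw by
    ``neighborhood_mixing`` (1 = i.i.d. uniform types).
    """
    n = len(centers)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    propensity = rng.dirichlet(np.full(cfg.n_types, 0.8))
    attractors = rng.uniform(0, cfg.patch_size, size=(cfg.n_types, 2))
    sigma = 0.25 * cfg.patch_size
    d2 = ((centers[:, None, :] - attractors[None, :, :]) ** 2).sum(axis=2)
    w = propensity[None, :] * np.exp(-d2 / (2 * sigma ** 2))
    w /= w.sum(axis=1, keepdims=True)
    probs = (cfg.neighborhood_mixing / cfg.n_types
             + (1 - cfg.neighborhood_mixing) * w)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(n)
    return (probs.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(np.int64)


def render_patch(cfg: SimConfig, layout_rng: np.random.Generator,
                 render_rng: np.random.Generator,
                 id_offset: int = 0) -> tuple[HEPatch, InstanceMap, CellTable]:
    """Render one patch: place non-overlapping ellipses by rejection sampling,
    assign spatially clustered types, paint each type in its base colour with
    texture jitter on a pink-white background.

    If placement keeps failing the patch simply carries fewer nuclei.
    """
    size = cfg.patch_size
    labels = np.zeros((size, size), dtype=np.int64)
    n_target = int(layout_rng.integers(cfg.nuclei_per_patch[0],
                                       cfg.nuclei_per_patch[1] + 1))
    rows, cols, areas, axes_list = [], [], [], []
    nucleus_id = 0
    for _ in range(n_target):
        placed = False
        for _attempt in range(40):
            a = layout_rng.uniform(*cfg.nucleus_radius)
            b = layout_rng.uniform(*cfg.nucleus_radius)
            theta = layout_rng.uniform(0, np.pi)
            rmax = max(a, b) + 1
            cy = layout_rng.uniform(rmax, size - rmax)
            cx = layout_rng.uniform(rmax, size - rmax)
            rr, cc = draw_ellipse(cy, cx, a, b, shape=(size, size), rotation=theta)
            if rr.size == 0 or labels[rr, cc].any():
                continue
            nucleus_id += 1
            labels[rr, cc] = nucleus_id
            rows.append(cy)
            cols.append(cx)
            areas.append(rr.size)
            axes_list.append((a, b))
            placed = True
            break
        if not placed:
            continue
    centers = np.column_stack([rows, cols]) if rows else np.zeros((0, 2))
    types = _assign_types(cfg, centers, layout_rng)

    # painting: background + per-type chromatin colour + texture noise
    img = BACKGROUND_RGB[None, None, :] + render_rng.normal(0, 4.0, (size, size, 3))
    colors = _type_colors(cfg)
    for nid in range(1, nucleus_id + 1):
        mask = labels == nid
        base = colors[types[nid - 1]]
        jitter = render_rng.normal(0, 7.0, (int(mask.sum()), 3))
        img[mask] = base[None, :] + jitter
    pixels = np.clip(img, 0, 255).astype(np.uint8)

    ids = np.arange(1, nucleus_id + 1)
    table = pd.DataFrame({
        "id": ids + id_offset,
        "row": np.asarray(rows),
        "col": np.asarray(cols),
        "area_px": np.asarray(areas, dtype=np.int64),
        "type_true": [f"type{t}" for t in types],
    })
    patch = HEPatch(pixels, origin=(0, 0), mpp=cfg.mpp)
    imap = InstanceMap(labels)
    return patch, imap, CellTable(table, mpp=cfg.mpp)


@dataclass
class SimulatedDataset:
    """A fully known synthetic study: images, labels, cells and expression."""

    cfg: SimConfig
    patches: list[HEPatch]
    instance_maps: list[InstanceMap]
    cells: CellTable            # includes 'patch' column and global ids
    expression: ExpressionMatrix  # raw counts, rows aligned to cells
    reference: ReferenceProfiles
    compositions: list[NCVector] = field(default_factory=list)

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    def cells_in_patch(self, p: int) -> pd.DataFrame:
        return self.cells.df[self.cells.df["patch"] == p]


def generate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate the full paired dataset under one seed.

    Per-cell expression: ``Poisson(size_factor * R[type_j] * exp(eps_j))``
    with ``eps_j ~ Normal(0, noise_sd)`` i.i.d. per cell and gene.  Per-patch
    composition vectors are the empirical type frequencies.
    """
    layout_rng, render_rng, expr_rng, _ = cfg.substreams()
    reference = generate_reference_profiles(cfg)
    type_index = {name: t for t, name in enumerate(cfg.type_names())}

    patches, imaps, frames, comps = [], [], [], []
    id_offset = 0
    for p in range(cfg.n_patches):
        patch, imap, table = render_patch(cfg, layout_rng, render_rng, id_offset)
        id_offset += len(table)
        df = table.df.assign(patch=p)
        patches.append(patch)
        imaps.append(imap)
        frames.append(df)
        tvec = np.zeros(cfg.n_types)
        for name in df["type_true"]:
            tvec[type_index[name]] += 1
        comps.append(NCVector(tvec / tvec.sum()) if tvec.sum() > 0
                     else NCVector(np.full(cfg.n_types, 1.0 / cfg.n_types)))

    cells_df = pd.concat(frames, ignore_index=True)
    t_idx = cells_df["type_true"].map(type_index).to_numpy()
    eps = expr_rng.normal(0.0, cfg.noise_sd, size=(len(cells_df), cfg.n_genes))
    rates = cfg.size_factor * reference.R[t_idx] * np.exp(eps)
    counts = expr_rng.poisson(rates).astype(np.float64)
    expr = ExpressionMatrix(counts, reference.gene_names, scale="raw_counts")
    return SimulatedDataset(cfg, patches, imaps, CellTable(cells_df, mpp=cfg.mpp),
                            expr, reference, comps)


def write_dataset(ds: SimulatedDataset, outdir: str) -> None:
    """Write a simulated dataset to ``outdir`` in the package's standard formats."""
    import os

    from . import io as hio
    os.makedirs(outdir, exist_ok=True)
    for p, (patch, imap) in enumerate(zip(ds.patches, ds.instance_maps)):
        hio.write_patch(os.path.join(outdir, f"patch{p:04d}.tif"), patch)
        hio.write_instance_map(os.path.join(outdir, f"labels{p:04d}.tif"), imap)
    hio.write_cell_table(os.path.join(outdir, "cells.csv"), ds.cells)
    hio.write_expression_csv(os.path.join(outdir, "expression.csv"),
                             ds.expression, cell_ids=ds.cells.ids)
    hio.write_reference_profiles(os.path.join(outdir, "reference.csv"), ds.reference)
    comp = pd.DataFrame([c.probs for c in ds.compositions],
                        columns=ds.reference.profile_names)
    comp.to_csv(os.path.join(outdir, "compositions.csv"), index_label="patch")
    import dataclasses
    import json
    with open(os.path.join(outdir, "simconfig.json"), "w") as fh:
        json.dump(dataclasses.asdict(ds.cfg), fh, indent=1)
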