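"""Data preparation: transcript QC, cross-modality nucleus matching, cell
filtering, Macenko stain normalisation, image tiling, cross-validation
splits and spot-mode patch/gene preparation.

These are the deterministic steps that turn raw paired inputs (H&E image,
nuclei label maps from an external segmenter, transcript tables or spot
tables from the spatial platform) into the aligned training containers of
:mod:`hespex.core`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize as sk_resize

from .core import CellTable, ExpressionMatrix, HEPatch, InstanceMap

__all__ = [
    "MatchResult", "filter_transcripts", "match_nuclei", "filter_cells",
    "macenko_normalize", "tile_patches", "make_cv_splits",
    "make_spot_patches", "select_spot_genes",
]

CONTROL_PREFIXES = ("NegControl", "BLANK", "Blank", "antisense", "DeprecatedCodeword")


@dataclass
class MatchResult:
    """Pairing of H&E nuclei with spatial-transcriptomics objects.

    ``pairs`` maps each matched H&E nucleus id to the id of the overlapping
    object in the other modality; ``overlap_fraction`` records, per H&E id,
    overlap pixels divided by the H&E nucleus area (always >= 0.5 for a
    stored pair).
    """

    pairs: dict[int, int] = field(default_factory=dict)
    overlap_fraction: dict[int, float] = field(default_factory=dict)


def filter_transcripts(transcripts: pd.DataFrame, qv_min: float = 20.0,
                       control_prefixes=CONTROL_PREFIXES) -> pd.DataFrame:
    """Remove low-quality and control transcripts.

    Rows with phred-scaled quality below ``qv_min`` are dropped (a value of
    exactly ``qv_min`` is retained), as are negative-control / blank /
    antisense codewords identified by gene-name prefix.
    """
    for col in ("gene", "qv"):
        if col not in transcripts.columns:
            raise ValueError(f"transcripts table missing column '{col}'")
    keep = transcripts["qv"] >= qv_min
    gene = transcripts["gene"].astype(str)
    for prefix in control_prefixes:
        keep &= ~gene.str.startswith(prefix)
    return transcripts[keep].reset_index(drop=True)


def match_nuclei(he_map: InstanceMap, sst_map: InstanceMap,
                 min_overlap: float = 0.5) -> MatchResult:
    """Match H&E nuclei to spatial-transcriptomics objects by pixel overlap.

    For each H&E nucleus the candidate is the object with maximal overlap;
    the pair is stored iff the overlap covers at least ``min_overlap`` of
    the H&E nucleus area (inclusive).  Ties on overlap are broken by the
    smaller object id.  Each H&E nucleus maps to at most one object.
    """
    if he_map.shape != sst_map.shape:
        raise ValueError("instance maps must share shape")
    he = he_map.labels.ravel()
    sst = sst_map.labels.ravel()
    sel = he > 0
    he_areas = np.bincount(he[sel])
    both = sel & (sst > 0)
    result = MatchResult()
    if not both.any():
        return result
    # joint histogram of (he id, sst id) over co-labelled pixels
    pair_df = pd.DataFrame({"he": he[both], "sst": sst[both]})
    counts = pair_df.groupby(["he", "sst"]).size().reset_index(name="n")
    counts = counts.sort_values(["he", "n", "sst"],
                                ascending=[True, False, True])
    best = counts.drop_duplicates("he", keep="first")
    for he_id, sst_id, n in best[["he", "sst", "n"]].itertuples(index=False):
        frac = n / he_areas[he_id]
        if frac >= min_overlap:
            result.pairs[int(he_id)] = int(sst_id)
            result.overlap_fraction[int(he_id)] = float(frac)
    return result


def filter_cells(cells: CellTable, expr: ExpressionMatrix,
                 min_area_um2: float = 10.0) -> tuple[CellTable, ExpressionMatrix]:
    """Drop unusable cells: zero total counts, 'unassigned' type, or a
    nucleus smaller than ``min_area_um2`` square microns (strict)."""
    if len(cells) != expr.n_cells:
        raise ValueError("cell table and expression matrix are misaligned")
    df = cells.df
    keep = expr.values.sum(axis=1) > 0
    if "type_true" in df.columns:
        keep &= (df["type_true"].astype(str) != "unassigned").to_numpy()
    keep &= (df["area_um2"] >= min_area_um2).to_numpy()
    return (CellTable(df[keep].reset_index(drop=True), mpp=cells.mpp),
            ExpressionMatrix(expr.values[keep], expr.gene_names, scale=expr.scale))


# ---------------------------------------------------------------------------
# Macenko stain normalisation
# ---------------------------------------------------------------------------

def _stain_decompose(pixels: np.ndarray, io_intensity: float, beta: float,
                     alpha: float, conc_pct: float):
    """Estimate the 2-stain basis and concentrations of an RGB image.

    Returns (stain_matrix (3,2), conc_percentiles (2,)) or None when fewer
    than two pixels carry enough optical density.
    """
    od = -np.log10((pixels.reshape(-1, 3).astype(np.float64) + 1) / io_intensity)
    fg = od[(od > beta).all(axis=1)]
    if fg.shape[0] < 2:
        return None
    cov = np.cov(fg.T)
    evals, evecs = np.linalg.eigh(cov)
    basis = evecs[:, [1, 2]]  # two leading eigenvectors of the OD cloud
    proj = fg @ basis
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    a_min, a_max = np.percentile(angles, alpha), np.percentile(angles, 100 - alpha)
    v1 = basis @ np.array([np.cos(a_min), np.sin(a_min)])
    v2 = basis @ np.array([np.cos(a_max), np.sin(a_max)])
    if (v1 < 0).all():
        v1 = -v1
    if (v2 < 0).all():
        v2 = -v2
    # haematoxylin first (more blue -> larger first component by convention)
    stains = np.column_stack([v1, v2]) if v1[0] > v2[0] else np.column_stack([v2, v1])
    stains /= np.linalg.norm(stains, axis=0, keepdims=True)
    conc = np.linalg.lstsq(stains, od.T, rcond=None)[0]
    return stains, np.percentile(conc, conc_pct, axis=1), conc


def macenko_normalize(patch: HEPatch, reference: HEPatch,
                      io_intensity: float = 240.0, beta: float = 0.15,
                      alpha: float = 1.0, conc_pct: float = 99.0) -> HEPatch:
    """Standardise stain colours of ``patch`` to match ``reference``.

    Pixels are converted to optical density ``OD = -log10((I+1)/Io)``;
    near-transparent pixels (all channels below ``beta`` OD) are excluded
    from stain estimation; the two stain vectors come from the ``alpha`` /
    ``100-alpha`` angle percentiles in the leading OD eigenplane, and
    concentrations are rescaled so their ``conc_pct`` percentile matches the
    reference's before reconstruction to 8-bit RGB.

    Degenerate inputs (fewer than two foreground-OD pixels, e.g. a pure
    white patch) are returned unchanged with ``degenerate_stain`` set in the
    returned patch's pixel array metadata via an attribute on the HEPatch.
    """
    dec = _stain_decompose(patch.pixels, io_intensity, beta, alpha, conc_pct)
    ref_dec = _stain_decompose(reference.pixels, io_intensity, beta, alpha, conc_pct)
    if dec is None or ref_dec is None:
        out = HEPatch(patch.pixels.copy(), origin=patch.origin, mpp=patch.mpp)
        out.degenerate_stain = True
        return out
    stains, conc_ref_pct, conc = dec[0], ref_dec[1], dec[2]
    conc_pcts = np.percentile(conc, conc_pct, axis=1)
    scale = np.divide(conc_ref_pct, conc_pcts,
                      out=np.ones_like(conc_ref_pct), where=conc_pcts > 0)
    conc_scaled = conc * scale[:, None]
    od_new = (ref_dec[0] @ conc_scaled).T
    rgb = io_intensity * np.power(10.0, -od_new) - 1
    pixels = np.clip(rgb, 0, 255).reshape(patch.pixels.shape).astype(np.uint8)
    out = HEPatch(pixels, origin=patch.origin, mpp=patch.mpp)
    out.degenerate_stain = False
    return out


# ---------------------------------------------------------------------------
# Tiling and cross-validation
# ---------------------------------------------------------------------------

def _axis_origins(extent: int, size: int, overlap: int) -> list[int]:
    stride = size - overlap
    origins = list(range(0, max(extent - size, 0) + 1, stride))
    if origins[-1] + size < extent:
        origins.append(extent - size)
    return origins


def tile_patches(image_extent: tuple[int, int], size: int,
                 overlap: int = 0) -> list[tuple[int, int]]:
    """Patch origins on a stride of ``size - overlap``; the final origin per
    axis is clamped so the last patch ends exactly at the image border, so
    every pixel is covered at least once and all tiles are full-sized."""
    h, w = image_extent
    if not size > overlap >= 0:
        raise ValueError("require size > overlap >= 0")
    if size > h or size > w:
        raise ValueError(f"tile size {size} exceeds image extent {image_extent}")
    return [(r, c) for r in _axis_origins(h, size, overlap)
            for c in _axis_origins(w, size, overlap)]


@dataclass
class FoldSplit:
    """Row ranges (half-open) of one cross-validation fold."""

    test: tuple[int, int]
    val: tuple[int, int]
    train: list[tuple[int, int]]


def make_cv_splits(image_extent: tuple[int, int], k: int = 5) -> list[FoldSplit]:
    """Horizontal-band cross-validation over a whole image.

    The image is sectioned into ``k`` nearly equal horizontal bands; fold
    ``f`` tests on band ``f``, holds out a validation strip one tenth of the
    image height (at least one row) from the top of the remaining region,
    and trains on the rest.  Bands are disjoint and exhaustive.
    """
    h, _ = image_extent
    if k < 2:
        raise ValueError("need at least 2 folds")
    if h < k:
        raise ValueError("image height must be at least the number of folds")
    edges = np.linspace(0, h, k + 1).astype(int)
    folds = []
    for f in range(k):
        test = (int(edges[f]), int(edges[f + 1]))
        remaining = [(int(edges[i]), int(edges[i + 1])) for i in range(k) if i != f]
        lo0, hi0 = remaining[0]
        # validation: a strip of height floor(H/10), at least 1 row, carved
        # from the top of the remaining region (never the whole first band)
        val_h = min(max(h // 10, 1), hi0 - lo0 - 1) if hi0 - lo0 > 1 else 1
        val = (lo0, lo0 + val_h)
        train = ([(lo0 + val_h, hi0)] if lo0 + val_h < hi0 else []) + remaining[1:]
        folds.append(FoldSplit(test=test, val=val, train=train))
    return folds


# ---------------------------------------------------------------------------
# Spot mode (spot-based spatial transcriptomics)
# ---------------------------------------------------------------------------

def make_spot_patches(image: np.ndarray, spots: pd.DataFrame,
                      crop: int = 224, center: int = 112,
                      out_size: int = 256, mpp: float = 0.5) -> list[HEPatch]:
    """Extract one patch per sequencing spot.

    Per spot: a ``crop`` x ``crop`` window centred on the spot (reflect-
    padded near borders), centre-cropped to ``center`` x ``center`` and
    bilinearly resized to ``out_size`` x ``out_size``.
    """
    for col in ("row", "col"):
        if col not in spots.columns:
            raise ValueError(f"spot table missing column '{col}'")
    h, w = image.shape[:2]
    half = crop // 2
    pad = half + 1
    padded = np.pad(image, ((pad, pad), (pad, pad), (0, 0)), mode="reflect")
    off = (crop - center) // 2
    patches = []
    for r, c in spots[["row", "col"]].itertuples(index=False):
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"spot centre ({r},{c}) outside image")
        r0, c0 = int(round(r)) + pad - half, int(round(c)) + pad - half
        window = padded[r0:r0 + crop, c0:c0 + crop]
        central = window[off:off + center, off:off + center]
        resized = sk_resize(central.astype(np.float64), (out_size, out_size, 3),
                            order=1, mode="reflect", anti_aliasing=False)
        patches.append(HEPatch(np.clip(resized, 0, 255).astype(np.uint8), mpp=mpp))
    return patches


def select_spot_genes(sections: list[ExpressionMatrix], top_k: int = 1000,
                      min_spots: int = 1000) -> list[str]:
    """Union of each section's ``top_k`` most variable genes, minus genes
    expressed (count > 0) in fewer than ``min_spots`` spots pooled over all
    sections.

    Variability ranks use the per-gene variance of log1p-transformed values,
    a self-contained stand-in for external highly-variable-gene rankings.
    """
    if not sections:
        raise ValueError("need at least one section")
    genes = sections[0].gene_names
    for s in sections[1:]:
        if s.gene_names != genes:
            raise ValueError("sections must share a gene panel")
    chosen: set[str] = set()
    for s in sections:
        var = np.log1p(s.values).var(axis=0)
        k = min(top_k, len(genes))
        top = np.argsort(-var, kind="stable")[:k]
        chosen.update(genes[j] for j in top)
    pooled_nonzero = sum((s.values > 0).sum(axis=0) for s in sections)
    expressed = {genes[j] for j in range(len(genes)) if pooled_nonzero[j] >= min_spots}
    return [g for g in genes if g in chosen and g in expressed]
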