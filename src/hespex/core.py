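"""Shared domain types and normalisation transforms.

The package revolves around five containers: an :class:`HEPatch` (an RGB
histology tile), an :class:`InstanceMap` (integer nuclei label image aligned
to a patch), a :class:`CellTable` (per-nucleus records), an
:class:`ExpressionMatrix` (cells x genes values, raw counts or
log-normalised) and :class:`ReferenceProfiles` (averaged expression profiles
of cell types from an external single-cell reference).  Coordinates are
0-based row-major; a patch occupies the half-open window
``[r0, r0+h) x [c0, c0+w)`` of its parent image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HEPatch", "InstanceMap", "CellTable", "ExpressionMatrix",
    "ReferenceProfiles", "NCVector", "log_normalize", "standardize_patch",
]

RAW_COUNTS = "raw_counts"
LOG_NORMALIZED = "log_normalized"


@dataclass
class HEPatch:
    """8-bit RGB image tile with its origin in the parent image and pixel size.

    Attributes
    ----------
    pixels : (h, w, 3) uint8 array
    origin : (row, col) offset of the tile in the parent image, 0-based
    mpp : microns per pixel (> 0)
    """

    pixels: np.ndarray
    origin: tuple[int, int] = (0, 0)
    mpp: float = 0.5

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be (h, w, 3)")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("patch must be at least 1 x 1")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class InstanceMap:
    """Integer nuclei label image; 0 is background, positive ids are nuclei."""

    labels: np.ndarray
    valid_ids: set[int] = field(default_factory=set)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        if (self.labels < 0).any():
            raise ValueError("labels must be non-negative")
        if not self.valid_ids:
            self.valid_ids = set(int(i) for i in np.unique(self.labels) if i > 0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def areas(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts) if i > 0}


@dataclass
class CellTable:
    """Per-cell records backed by a DataFrame.

    Required columns: ``id`` (unique int), ``row``, ``col`` (centroid),
    ``area_px``.  Derived: ``area_um2 = area_px * mpp**2``.  Optional:
    ``type_true``, ``type_pred``, ``fold``, ``patch``.
    """

    df: pd.DataFrame
    mpp: float = 0.5

    def __post_init__(self):
        df = self.df
        for col in ("id", "row", "col", "area_px"):
            if col not in df.columns:
                raise ValueError(f"CellTable missing required column '{col}'")
        if df["id"].duplicated().any():
            raise ValueError("cell ids must be unique")
        if (df["area_px"] < 1).any():
            raise ValueError("area_px must be >= 1")
        if "area_um2" not in df.columns:
            df = df.assign(area_um2=df["area_px"] * self.mpp ** 2)
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> np.ndarray:
        return self.df["id"].to_numpy()


@dataclass
class ExpressionMatrix:
    """Cells x genes non-negative expression values with a scale flag."""

    values: np.ndarray
    gene_names: list[str]
    scale: str = RAW_COUNTS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_names = list(self.gene_names)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x genes)")
        if self.values.shape[1] != len(self.gene_names):
            raise ValueError("gene_names length must match number of columns")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("gene names must be unique")
        if (self.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.scale not in (RAW_COUNTS, LOG_NORMALIZED):
            raise ValueError(f"unknown scale '{self.scale}'")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class ReferenceProfiles:
    """Averaged expression profiles of cell types: (n_profiles, n_genes)."""

    R: np.ndarray
    profile_names: list[str]
    gene_names: list[str]

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=np.float64)
        if self.R.ndim != 2:
            raise ValueError("R must be 2-D")
        if self.R.shape != (len(self.profile_names), len(self.gene_names)):
            raise ValueError("R shape must be (n_profiles, n_genes)")
        if (self.R < 0).any():
            raise ValueError("reference profiles must be non-negative")

    @property
    def n_profiles(self) -> int:
        return self.R.shape[0]


@dataclass
class NCVector:
    """Cell-type composition of a patch; lives on the probability simplex."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if (self.probs < 0).any():
            raise ValueError("composition entries must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError("composition must sum to 1")


def log_normalize(expr: ExpressionMatrix, transform=None) -> ExpressionMatrix:
    """Log-normalise raw counts: elementwise natural log(1 + count).

    ``transform`` may override the default recipe with any monotone map of
    raw counts (e.g. a library-size-scaled variant); it receives and returns
    the raw values array.
    """
    if expr.scale != RAW_COUNTS:
        raise ValueError("input must be raw counts")
    values = expr.values if transform is None else np.asarray(transform(expr.values))
    if (values < 0).any():
        raise ValueError("negative values cannot be log-normalised")
    return ExpressionMatrix(np.log1p(values), expr.gene_names, scale=LOG_NORMALIZED)


def standardize_patch(patch: HEPatch, channel_mean, channel_std) -> np.ndarray:
    """Standardise an RGB patch with per-channel training mean and std.

    Returns a float (h, w, 3) array ``(pixels - mean) / std``.
    """
    mean = np.asarray(channel_mean, dtype=np.float64).reshape(1, 1, 3)
    std = np.asarray(channel_std, dtype=np.float64).reshape(1, 1, 3)
    if (std <= 0).any():
        raise ValueError("channel std must be positive")
    return (patch.pixels.astype(np.float64) - mean) / std
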