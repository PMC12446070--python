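"""Round-trip a simulated dataset directory (as written by
:func:`hespex.synthetic.write_dataset`) back into memory."""

from __future__ import annotations

import glob
import json
import os

import pandas as pd

from . import io as hio
from .core import NCVector
from .synthetic import SimConfig, SimulatedDataset

__all__ = ["read_dataset"]


def read_dataset(datadir: str) -> SimulatedDataset:
    patch_files = sorted(glob.glob(os.path.join(datadir, "patch*.tif")))
    label_files = sorted(glob.glob(os.path.join(datadir, "labels*.tif")))
    if not patch_files or len(patch_files) != len(label_files):
        raise FileNotFoundError(f"no paired patch/label TIFFs in {datadir}")
    patches = [hio.read_patch(f) for f in patch_files]
    imaps = [hio.read_instance_map(f) for f in label_files]
    cells = hio.read_cell_table(os.path.join(datadir, "cells.csv"))
    expr = hio.read_expression_csv(os.path.join(datadir, "expression.csv"))
    ref = hio.read_reference_profiles(os.path.join(datadir, "reference.csv"))
    comp_df = pd.read_csv(os.path.join(datadir, "compositions.csv"), index_col=0)
    comps = [NCVector(row) for row in comp_df.to_numpy()]
    cfg_path = os.path.join(datadir, "simconfig.json")
    if os.path.exists(cfg_path):
        with open(cfg_path) as fh:
            raw = json.load(fh)
        for key in ("nuclei_per_patch", "nucleus_radius"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = SimConfig(**raw)
    else:
        cfg = SimConfig(n_types=ref.n_profiles, n_genes=len(ref.gene_names),
                        markers_per_type=max(len(ref.gene_names) // ref.n_profiles // 2, 1),
                        patch_size=patches[0].pixels.shape[0],
                        n_patches=len(patches))
    return SimulatedDataset(cfg, patches, imaps, cells, expr, ref, comps)
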