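"""Data preparation: transcript QC, nucleus matching (vs a brute-force
pixel-counting oracle), cell filtering, Macenko normalisation, tiling,
cross-validation splits and spot-mode preparation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hespex.core import CellTable, ExpressionMatrix, HEPatch, InstanceMap
from hespex.preprocess import (filter_cells, filter_transcripts,
                               macenko_normalize, make_cv_splits,
                               make_spot_patches, match_nuclei, select_spot_genes,
                               tile_patches)


class TestFilterTranscripts:
    def test_qv_boundary_inclusive(self):
        df = pd.DataFrame({"gene": ["A", "B", "C"], "qv": [19.9, 20.0, 35.0]})
        out = filter_transcripts(df)
        assert out["gene"].tolist() == ["B", "C"]

    def test_control_prefixes_removed(self):
        df = pd.DataFrame({"gene": ["ACTB", "NegControlProbe_1", "BLANK_3",
                                    "antisense_X"], "qv": [30.0] * 4})
        assert filter_transcripts(df)["gene"].tolist() == ["ACTB"]

    def test_empty_and_missing_columns(self):
        empty = pd.DataFrame({"gene": [], "qv": []})
        assert len(filter_transcripts(empty)) == 0
        with pytest.raises(ValueError):
            filter_transcripts(pd.DataFrame({"gene": ["A"]}))


def brute_force_match(he, sst, min_overlap=0.5):
    """Exhaustive pixel-count oracle for nucleus matching."""
    pairs = {}
    for he_id in np.unique(he):
        if he_id == 0:
            continue
        mask = he == he_id
        area = mask.sum()
        best, best_n = None, 0
        for sst_id in sorted(np.unique(sst[mask])):
            if sst_id == 0:
                continue
            n = int((sst[mask] == sst_id).sum())
            if n > best_n:
                best, best_n = int(sst_id), n
        if best is not None and best_n >= min_overlap * area:
            pairs[int(he_id)] = best
    return pairs


class TestMatchNuclei:
    def test_full_containment_and_boundary(self):
        he = np.zeros((8, 8), dtype=int)
        he[1:3, 1:3] = 1       # 4 px
        he[5:7, 5:7] = 2       # 4 px
        sst = np.zeros((8, 8), dtype=int)
        sst[0:4, 0:4] = 7      # covers nucleus 1 fully
        sst[5:7, 5:6] = 9      # covers exactly half of nucleus 2
        res = match_nuclei(InstanceMap(he), InstanceMap(sst))
        assert res.pairs == {1: 7, 2: 9}
        assert res.overlap_fraction[1] == pytest.approx(1.0)
        assert res.overlap_fraction[2] == pytest.approx(0.5)  # inclusive

    def test_below_half_not_matched(self):
        he = np.zeros((4, 4), dtype=int)
        he[0:2, 0:2] = 1
        sst = np.zeros((4, 4), dtype=int)
        sst[0, 0] = 3          # 25% overlap
        assert match_nuclei(InstanceMap(he), InstanceMap(sst)).pairs == {}

    def test_max_overlap_candidate_chosen(self):
        he = np.zeros((2, 10), dtype=int)
        he[:, 0:5] = 1         # 10 px
        sst = np.zeros((2, 10), dtype=int)
        sst[:, 0:3] = 4        # 6 px overlap (60%)
        sst[:, 3:5] = 2        # 4 px overlap (40%)
        res = match_nuclei(InstanceMap(he), InstanceMap(sst))
        assert res.pairs == {1: 4}

    def test_matches_brute_force_on_random_maps(self, rng):
        for _ in range(100):
            he = rng.integers(0, 5, size=(12, 12))
            sst = rng.integers(0, 5, size=(12, 12))
            got = match_nuclei(InstanceMap(he), InstanceMap(sst)).pairs
            assert got == brute_force_match(he, sst)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match_nuclei(InstanceMap(np.zeros((2, 2), dtype=int)),
                         InstanceMap(np.zeros((3, 3), dtype=int)))


class TestFilterCells:
    @staticmethod
    def _table(areas_um2, types):
        n = len(areas_um2)
        df = pd.DataFrame({"id": np.arange(n) + 1, "row": np.zeros(n),
                           "col": np.zeros(n), "area_px": np.full(n, 50),
                           "area_um2": areas_um2, "type_true": types})
        return CellTable(df)

    def test_all_three_rules(self):
        cells = self._table([9.99, 10.0, 25.0, 25.0],
                            ["a", "a", "unassigned", "b"])
        expr = ExpressionMatrix(np.array([[5.0], [5.0], [5.0], [0.0]]), ["g"])
        out_cells, out_expr = filter_cells(cells, expr)
        # 9.99 um2 dropped (strict), unassigned dropped, zero-count dropped
        assert out_cells.df["id"].tolist() == [2]
        assert out_expr.values.shape == (1, 1)

    def test_identity_when_nothing_matches(self):
        cells = self._table([12.0, 15.0], ["a", "b"])
        expr = ExpressionMatrix(np.ones((2, 2)), ["g1", "g2"])
        out_cells, out_expr = filter_cells(cells, expr)
        assert out_cells.df.equals(cells.df)
        assert np.array_equal(out_expr.values, expr.values)

    def test_misaligned_rejected(self):
        cells = self._table([12.0], ["a"])
        with pytest.raises(ValueError):
            filter_cells(cells, ExpressionMatrix(np.ones((2, 1)), ["g"]))


def _two_stain_patch(rng, h=64, w=64, io_intensity=240.0):
    """Synthetic patch built from two known stain vectors in OD space."""
    v1 = np.array([0.65, 0.70, 0.29])   # haematoxylin-like
    v2 = np.array([0.07, 0.99, 0.11])   # eosin-like
    v1, v2 = v1 / np.linalg.norm(v1), v2 / np.linalg.norm(v2)
    c1 = rng.uniform(0.05, 1.2, size=(h * w))
    c2 = rng.uniform(0.05, 1.2, size=(h * w))
    od = np.outer(c1, v1) + np.outer(c2, v2)
    rgb = io_intensity * 10.0 ** (-od) - 1
    return HEPatch(np.clip(rgb, 0, 255).reshape(h, w, 3).astype(np.uint8)), v1, v2


class TestMacenko:
    def test_self_reference_near_identity(self, rng):
        patch, _, _ = _two_stain_patch(rng)
        out = macenko_normalize(patch, patch)
        diff = np.abs(out.pixels.astype(float) - patch.pixels.astype(float))
        assert diff.mean() < 2.0

    def test_white_patch_degenerate_path(self):
        white = HEPatch(np.full((16, 16, 3), 255, dtype=np.uint8))
        ref, _, _ = _two_stain_patch(np.random.default_rng(0))
        out = macenko_normalize(white, ref)
        assert np.array_equal(out.pixels, white.pixels)
        assert out.degenerate_stain

    def test_recovers_known_stain_vectors(self, rng):
        from hespex.preprocess import _stain_decompose
        patch, v1, v2 = _two_stain_patch(rng)
        stains, _, _ = _stain_decompose(patch.pixels, 240.0, 0.15, 1.0, 99.0)
        got = [stains[:, 0], stains[:, 1]]
        for v in (v1, v2):
            angles = [np.degrees(np.arccos(np.clip(np.dot(v, g), -1, 1)))
                      for g in got]
            assert min(angles) < 5.0  # angular tolerance


class TestTiling:
    def test_basic_counts_and_strides(self):
        assert len(tile_patches((512, 512), 256, 0)) == 4
        cols = sorted({c for _, c in tile_patches((256, 482), 256, 30)})
        assert cols == [0, 226]

    def test_errors(self):
        with pytest.raises(ValueError):
            tile_patches((100, 100), 50, 50)
        with pytest.raises(ValueError):
            tile_patches((100, 100), 128, 0)

    @given(st.integers(20, 90), st.integers(20, 90), st.integers(5, 19),
           st.integers(0, 4))
    @settings(max_examples=60, deadline=None)
    def test_full_coverage_and_clamped_last(self, h, w, size, overlap):
        origins = tile_patches((h, w), size, overlap)
        covered = np.zeros((h, w), dtype=bool)
        for r, c in origins:
            assert 0 <= r <= h - size and 0 <= c <= w - size
            covered[r:r + size, c:c + size] = True
        assert covered.all()
        rows = sorted({r for r, _ in origins})
        assert rows[-1] == h - size  # final patch abuts the border
        assert all(b > a for a, b in zip(rows, rows[1:]))


class TestCVSplits:
    def test_band_heights_and_validation(self):
        folds = make_cv_splits((1000, 500), k=5)
        assert len(folds) == 5
        for f in folds:
            assert f.test[1] - f.test[0] == 200
            assert f.val[1] - f.val[0] == 100  # a tenth of the height

    def test_partition_property(self):
        for k in (2, 3, 5):
            folds = make_cv_splits((97, 40), k=k)
            for f in folds:
                rows = np.zeros(97, dtype=int)
                rows[f.test[0]:f.test[1]] += 1
                rows[f.val[0]:f.val[1]] += 1
                for lo, hi in f.train:
                    rows[lo:hi] += 1
                assert (rows == 1).all()

    def test_tiny_image_validation_at_least_one_row(self):
        folds = make_cv_splits((8, 10), k=2)
        for f in folds:
            assert f.val[1] - f.val[0] >= 1


class TestSpotMode:
    def test_patch_geometry(self, rng):
        image = rng.integers(0, 256, size=(300, 300, 3)).astype(np.uint8)
        spots = pd.DataFrame({"row": [150.0, 2.0], "col": [150.0, 295.0]})
        patches = make_spot_patches(image, spots)
        assert len(patches) == 2
        for p in patches:
            assert p.pixels.shape == (256, 256, 3)
        # centre crop offset: (224 - 112) / 2 = 56 px per side
        assert (224 - 112) // 2 == 56

    def test_center_crop_content(self, rng):
        image = np.zeros((301, 301, 3), dtype=np.uint8)
        image[150, 150] = 255  # bright pixel at the spot centre
        patches = make_spot_patches(image, pd.DataFrame({"row": [150.0],
                                                         "col": [150.0]}))
        h, w = np.unravel_index(patches[0].pixels[:, :, 0].argmax(), (256, 256))
        assert abs(h - 128) <= 3 and abs(w - 128) <= 3

    def test_outside_spot_rejected(self, rng):
        image = np.zeros((50, 50, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            make_spot_patches(image, pd.DataFrame({"row": [60.0], "col": [0.0]}))

    def test_select_spot_genes_toy(self):
        genes = ["g0", "g1", "g2", "g3", "g4"]
        # g0 variable + common; g1 variable but only 2 nonzero spots;
        # g2 constant; g3 variable + common; g4 zero
        sec = ExpressionMatrix(np.array([
            [9, 5, 1, 0, 0],
            [0, 0, 1, 8, 0],
            [5, 0, 1, 4, 0],
            [1, 0, 1, 9, 0],
        ], dtype=float), genes)
        out = select_spot_genes([sec], top_k=3, min_spots=3)
        # brute-force set algebra: top-3 variable = {g0, g1, g3};
        # expressed in >= 3 spots = {g0, g3}
        assert out == ["g0", "g3"]
        # top_k exceeding panel uses all genes
        out_all = select_spot_genes([sec], top_k=99, min_spots=1)
        assert "g2" in out_all and "g4" not in out_all
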