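"""Metrics: per-gene PCC against the covariance formula, SSIM against a
hand-written sliding-window oracle, cell-type metrics, stratified summaries
and the spot-mode rollup convention."""

import numpy as np
import pandas as pd
import pytest

from hespex.core import CellTable, ExpressionMatrix
from hespex.evaluation import (celltype_metrics, per_gene_pcc,
                               rasterize_expression, spot_metric_rollup,
                               ssim_per_gene, stratified_correlation,
                               variance_ranked_genes)


def make_expr(values, scale="log_normalized"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(values, [f"g{i}" for i in range(values.shape[1])],
                            scale=scale)


class TestPerGenePCC:
    def test_perfect_and_sign(self, rng):
        x = rng.uniform(0, 5, size=(10, 3))
        assert np.allclose(per_gene_pcc(make_expr(x), make_expr(x)), 1.0)
        inv = per_gene_pcc(make_expr(x.max() - x), make_expr(x))
        assert np.allclose(inv, -1.0)

    def test_matches_covariance_oracle(self, rng):
        for _ in range(30):
            x = rng.uniform(0, 5, size=(8, 4))
            y = rng.uniform(0, 5, size=(8, 4))
            got = per_gene_pcc(make_expr(x), make_expr(y))
            for j in range(4):
                cov = np.mean((x[:, j] - x[:, j].mean())
                              * (y[:, j] - y[:, j].mean()))
                oracle = cov / (x[:, j].std() * y[:, j].std())
                assert got.iloc[j] == pytest.approx(oracle, abs=1e-9)

    def test_constant_gene_is_nan_sentinel(self, rng):
        x = rng.uniform(0, 5, size=(6, 2))
        x[:, 1] = 2.0
        out = per_gene_pcc(make_expr(x), make_expr(rng.uniform(0, 5, (6, 2))))
        assert np.isnan(out.iloc[1])
        assert not np.isnan(out.iloc[0])

    def test_too_few_cells_rejected(self):
        one = make_expr([[1.0, 2.0]])
        with pytest.raises(ValueError):
            per_gene_pcc(one, one)


def uniform_ssim_oracle(a, b, data_range, win=7):
    """Direct sliding-window SSIM with a uniform window."""
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    h, w = a.shape
    r = win // 2
    vals = []
    for i in range(r, h - r):
        for j in range(r, w - r):
            wa = a[i - r:i + r + 1, j - r:j + r + 1].ravel()
            wb = b[i - r:i + r + 1, j - r:j + r + 1].ravel()
            mu_a, mu_b = wa.mean(), wb.mean()
            # unbiased (n-1) moments, matching the conventional formulation
            va, vb = wa.var(ddof=1), wb.var(ddof=1)
            cab = ((wa - mu_a) * (wb - mu_b)).sum() / (wa.size - 1)
            vals.append(((2 * mu_a * mu_b + c1) * (2 * cab + c2))
                        / ((mu_a ** 2 + mu_b ** 2 + c1) * (va + vb + c2)))
    return float(np.mean(vals))


class TestSSIM:
    def test_identical_rasters_give_one(self, rng):
        raster = rng.uniform(0, 10, size=(1, 16, 16))
        out = ssim_per_gene(raster, raster)
        assert out[0] == pytest.approx(1.0, abs=1e-9)

    def test_at_most_one_and_degenerate_nan(self, rng):
        a = rng.uniform(0, 10, size=(2, 16, 16))
        b = rng.uniform(0, 10, size=(2, 16, 16))
        b[1] = 5.0  # zero-range truth raster
        out = ssim_per_gene(a, b)
        assert out[0] <= 1.0
        assert np.isnan(out[1])

    def test_matches_sliding_window_oracle(self, rng):
        a = rng.uniform(0, 10, size=(16, 16))
        b = rng.uniform(0, 10, size=(16, 16))
        got = ssim_per_gene(a[None], b[None], gaussian=False)[0]
        oracle = uniform_ssim_oracle(a, b, data_range=b.max() - b.min())
        assert got == pytest.approx(oracle, abs=1e-6)

    def test_rasterization_sums_expression_per_bin(self):
        df = pd.DataFrame({"id": [1, 2, 3], "row": [1.0, 2.0, 20.0],
                           "col": [1.0, 3.0, 20.0], "area_px": [4, 4, 4]})
        cells = CellTable(df)
        expr = make_expr([[1.0], [2.0], [5.0]])
        raster = rasterize_expression(expr, cells, extent=(32, 32), bin_size=16)
        assert raster.shape == (1, 2, 2)
        assert raster[0, 0, 0] == 3.0   # two cells in the first bin
        assert raster[0, 1, 1] == 5.0

    def test_noise_ladder_degrades_pcc_monotonically(self, rng):
        truth = rng.uniform(0, 5, size=(200, 4))
        mean_pccs = []
        for sd in (0.1, 0.5, 1.5, 4.0):
            noisy = truth + rng.normal(0, sd, truth.shape)
            noisy -= noisy.min()
            pcc = per_gene_pcc(make_expr(noisy), make_expr(truth))
            mean_pccs.append(pcc.mean())
        assert all(a > b for a, b in zip(mean_pccs, mean_pccs[1:]))


class TestCelltypeMetrics:
    def test_perfect_agreement(self):
        types = ["a", "b", "a", "c"]
        m = celltype_metrics(types, types)
        assert m["accuracy"] == 1.0
        assert m["macro_f1"] == 1.0
        assert m["composition_pred"].probs.sum() == pytest.approx(1.0)

    def test_two_class_confusion_worked_example(self):
        # TP=3, FP=1, FN=1, TN=5 -> F1 = 2*3 / (2*3 + 1 + 1) = 0.75
        true = ["p"] * 3 + ["p"] + ["n"] * 5 + ["n"]
        pred = ["p"] * 3 + ["n"] + ["n"] * 5 + ["p"]
        m = celltype_metrics(pred, true)
        assert m["f1_per_class"]["p"] == pytest.approx(0.75)

    def test_label_union_alignment(self):
        m = celltype_metrics(["a", "a"], ["a", "b"])
        assert set(m["f1_per_class"]) == {"a", "b"}

    def test_composition_concordance_when_types_agree(self, rng):
        types = rng.choice(["a", "b", "c"], size=50).tolist()
        m = celltype_metrics(types, types)
        assert np.allclose(m["composition_pred"].probs,
                           m["composition_true"].probs)


class TestStratified:
    def test_toy_hand_computed_medians(self):
        pcc = pd.Series([0.9, 0.7, 0.5, 0.3, 0.1, -0.2],
                        index=[f"g{i}" for i in range(6)])
        out = stratified_correlation(pcc, {"top3": ["g0", "g1", "g2"],
                                           "bottom3": ["g3", "g4", "g5"]})
        top = out[out["stratum"] == "top3"].iloc[0]
        assert top["median"] == pytest.approx(0.7)
        assert top["n_genes"] == 3
        bot = out[out["stratum"] == "bottom3"].iloc[0]
        assert bot["median"] == pytest.approx(0.1)

    def test_oversized_list_rejected(self):
        pcc = pd.Series([0.5], index=["g0"])
        with pytest.raises(ValueError):
            stratified_correlation(pcc, {"big": ["g0", "g1"]})

    def test_variance_ranking_fallback(self, rng):
        values = rng.poisson(2.0, size=(50, 3)).astype(float)
        values[:, 1] = values[:, 1] * 10          # most variable after log1p?
        values[:, 2] = 1.0                        # constant
        expr = make_expr(values, scale="raw_counts")
        ranked = variance_ranked_genes(expr)
        assert ranked[-1] == "g2"


class TestSpotRollup:
    def test_one_image_per_individual_is_plain_mean(self):
        per_image = pd.DataFrame([[0.2, 0.4], [0.6, 0.8]],
                                 index=["imgA", "imgB"], columns=["g0", "g1"])
        out = spot_metric_rollup(per_image, {"imgA": "p1", "imgB": "p2"})
        assert out.loc["g0", "mean_over_individuals"] == pytest.approx(0.4)

    def test_individuals_weigh_equally_not_images(self):
        # individual 1 has one image (0.0), individual 2 has three (1.0 each)
        per_image = pd.DataFrame([[0.0], [1.0], [1.0], [1.0]],
                                 index=["a", "b", "c", "d"], columns=["g0"])
        mapping = {"a": "p1", "b": "p2", "c": "p2", "d": "p2"}
        out = spot_metric_rollup(per_image, mapping)
        # hand arithmetic: mean(0.0, 1.0) = 0.5, not image-weighted 0.75
        assert out.loc["g0", "mean_over_individuals"] == pytest.approx(0.5)

    def test_order_invariance_and_unmapped_error(self):
        per_image = pd.DataFrame([[0.1], [0.9]], index=["a", "b"],
                                 columns=["g0"])
        m = {"a": "p1", "b": "p2"}
        out1 = spot_metric_rollup(per_image, m)
        out2 = spot_metric_rollup(per_image.iloc[::-1], m)
        assert out1.loc["__overall__"].equals(out2.loc["__overall__"])
        with pytest.raises(ValueError):
            spot_metric_rollup(per_image, {"a": "p1"})
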