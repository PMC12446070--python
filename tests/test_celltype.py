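"""Cell-type head, expression-consistency losses, neighborhood composition
and the composition-guided recovery mechanism — each against direct-formula
oracles."""

import numpy as np
import pytest

from hespex.celltype import (CellTypeHead, ExpressionConsistencyHead,
                             NeighborhoodHead, RecoveryParams,
                             celltype_class_loss, consistency_losses,
                             estimate_nc, kl_divergence, nc_losses,
                             predict_celltype, recover_celltypes)
from hespex.nn import Tensor


def softmax(z, axis=-1):
    e = np.exp(z - z.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


class TestCellTypeHead:
    def test_argmax_class(self, rng):
        head = CellTypeHead(3, rng, in_dim=8)
        logits, classes = predict_celltype(rng.normal(size=(4, 8)), head)
        assert np.array_equal(classes, logits.data.argmax(axis=1))

    def test_tie_breaks_to_lowest_index(self):
        # enumeration over tied logit patterns
        for tied in ([0.5, 0.5, 0.1], [1.0, 1.0, 1.0], [0.2, 0.9, 0.9]):
            arr = np.array([tied])
            first = int(np.flatnonzero(arr[0] == arr[0].max())[0])
            assert arr.argmax(axis=1)[0] == first

    def test_class_loss_closed_forms(self, rng):
        # uniform logits over M=4 -> ln 4
        uniform = np.zeros((5, 4))
        got = float(celltype_class_loss(uniform, np.arange(5) % 4).data)
        assert got == pytest.approx(np.log(4), abs=1e-9)
        assert got == pytest.approx(1.3863, abs=1e-4)
        # strongly confident correct predictions -> ~0
        confident = np.eye(4)[np.arange(5) % 4] * 50.0
        assert float(celltype_class_loss(confident, np.arange(5) % 4).data) \
            == pytest.approx(0.0, abs=1e-12)

    def test_class_loss_matches_oracle(self, rng):
        for _ in range(100):
            logits = rng.normal(size=(6, 5))
            labels = rng.integers(0, 5, size=6)
            got = float(celltype_class_loss(logits, labels).data)
            p = softmax(logits)
            oracle = -np.mean([np.log(p[i, labels[i]]) for i in range(6)])
            assert got == pytest.approx(oracle, abs=1e-6)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            celltype_class_loss(np.zeros((2, 3)), np.array([0, 5]))


class TestConsistencyLosses:
    def test_identical_inputs_zero_embed_and_logits(self, rng):
        head = ExpressionConsistencyHead(6, 3, rng)
        y = rng.uniform(0, 2, size=(4, 6))
        _, l_embed, l_logits = consistency_losses(y, y, np.zeros(4, dtype=int),
                                                  head)
        assert float(l_embed.data) == pytest.approx(0.0, abs=1e-7)
        assert float(l_logits.data) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_embeddings_give_one(self):
        from hespex.celltype import _cosine_rows
        a = Tensor(np.array([[1.0, 0.0]]))
        b = Tensor(np.array([[0.0, 1.0]]))
        assert float((1.0 - _cosine_rows(a, b)).mean().data) \
            == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_formula_oracle(self, rng):
        head = ExpressionConsistencyHead(5, 3, rng)
        for _ in range(100):
            yp = rng.uniform(0, 3, size=(3, 5))
            yt = rng.uniform(0, 3, size=(3, 5))
            labels = rng.integers(0, 3, size=3)
            l_expr, l_embed, l_logits = consistency_losses(yp, yt, labels, head)

            def fwd(y):
                h = np.maximum(y @ head.fc1.weight.data + head.fc1.bias.data, 0)
                return h, h @ head.fc2.weight.data + head.fc2.bias.data

            xp, pp = fwd(yp)
            xg, pg = fwd(yt)
            sp = softmax(pp)
            oracle_expr = -np.mean([np.log(sp[i, labels[i]]) for i in range(3)])
            cos = np.array([xp[i] @ xg[i]
                            / (np.sqrt(xp[i] @ xp[i] + 1e-16)
                               * np.sqrt(xg[i] @ xg[i] + 1e-16))
                            for i in range(3)])
            oracle_embed = np.mean(1 - cos)
            oracle_logits = np.mean(((pp - pg) ** 2).mean(axis=1))
            assert float(l_expr.data) == pytest.approx(oracle_expr, abs=1e-6)
            assert float(l_embed.data) == pytest.approx(oracle_embed, abs=1e-6)
            assert float(l_logits.data) == pytest.approx(oracle_logits, abs=1e-6)


class TestNeighborhoodComposition:
    def test_output_on_simplex_and_permutation_invariant(self, rng):
        head = NeighborhoodHead(4, rng, in_dim=8)
        x = rng.normal(size=(6, 8))
        p = estimate_nc(x, head)
        assert float(p.data.sum()) == pytest.approx(1.0, abs=1e-9)
        perm = estimate_nc(x[rng.permutation(6)], head)
        assert np.allclose(p.data, perm.data, atol=1e-12)

    def test_single_nucleus(self, rng):
        head = NeighborhoodHead(4, rng, in_dim=8)
        x = rng.normal(size=(1, 8))
        assert np.allclose(estimate_nc(x, head).data,
                           head(Tensor(x[0])).data)

    def test_empty_patch_rejected(self, rng):
        head = NeighborhoodHead(4, rng, in_dim=8)
        with pytest.raises(ValueError):
            estimate_nc(np.zeros((0, 8)), head)

    def test_kl_worked_value_and_identity(self):
        p = np.array([0.5, 0.5])
        q = np.array([0.25, 0.75])
        got = float(kl_divergence(p, q).data)
        expected = 0.5 * np.log(2) + 0.5 * np.log(2 / 3)
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(0.1438, abs=1e-4)
        assert float(kl_divergence(q, q).data) == pytest.approx(0.0, abs=1e-9)

    def test_kl_nonnegative_on_random_simplex_pairs(self, rng):
        for _ in range(100):
            p = rng.dirichlet(np.ones(5))
            q = rng.dirichlet(np.ones(5))
            l_est, l_pr = nc_losses(p, p, q)
            assert float(l_est.data) >= -1e-9
            assert float(l_pr.data) >= -1e-9


class TestRecovery:
    def test_equal_compositions_identity(self, rng):
        logits = rng.normal(size=(10, 4))
        p = np.array([0.4, 0.3, 0.2, 0.1])
        rp = RecoveryParams(alpha=2.0, target_types=(1, 2), rng_seed=5)
        classes, revised = recover_celltypes(logits, p, p, rp)
        assert np.array_equal(classes, logits.argmax(axis=1))
        assert np.allclose(revised, logits)

    def test_alpha_zero_identity(self, rng):
        logits = rng.normal(size=(8, 3))
        rp = RecoveryParams(alpha=0.0, target_types=(0, 1, 2), rng_seed=1)
        classes, revised = recover_celltypes(
            logits, np.array([0.6, 0.3, 0.1]), np.array([0.1, 0.3, 0.6]), rp)
        assert np.array_equal(classes, logits.argmax(axis=1))
        assert np.allclose(revised, logits)

    def test_worked_logit_boost(self):
        # alpha=2, n_cells=10, p_est - p_ct = 0.2, |Phi| = 0.5 -> v = 2.0
        v = 2.0 * 10 * (0.3 - 0.1) * 0.5
        assert v == pytest.approx(2.0)
        # and through the implementation with a controlled draw
        logits = np.zeros((10, 3))
        p_est = np.array([0.3, 0.4, 0.3])
        p_ct = np.array([0.1, 0.6, 0.3])

        class FixedRng:
            def normal(self, loc, scale):
                return loc + 0.2  # |Phi_0| = 0.5 for p_est[0] = 0.3

        rp = RecoveryParams(alpha=2.0, target_types=(0,))
        _, revised = recover_celltypes(logits, p_est, p_ct, rp, rng=FixedRng())
        assert revised[0, 0] == pytest.approx(2.0, abs=1e-12)

    def test_deterministic_under_seed(self, rng):
        logits = rng.normal(size=(20, 4))
        p_est = np.array([0.4, 0.3, 0.2, 0.1])
        p_ct = np.array([0.1, 0.2, 0.3, 0.4])
        rp = RecoveryParams(alpha=2.0, target_types=(0, 1), rng_seed=42)
        out1 = recover_celltypes(logits, p_est, p_ct, rp)
        out2 = recover_celltypes(logits, p_est, p_ct, rp)
        assert np.array_equal(out1[0], out2[0])
        assert np.array_equal(out1[1], out2[1])

    def test_never_introduces_non_target_classes(self, rng):
        for trial in range(50):
            logits = rng.normal(size=(15, 5))
            p_est = rng.dirichlet(np.ones(5))
            p_ct = rng.dirichlet(np.ones(5))
            rp = RecoveryParams(alpha=3.0, target_types=(1, 3), rng_seed=trial)
            before = logits.argmax(axis=1)
            after, _ = recover_celltypes(logits, p_est, p_ct, rp)
            changed = after != before
            assert set(after[changed]).issubset({1, 3})
            # non-target logit columns are untouched
            _, revised = recover_celltypes(logits, p_est, p_ct, rp)
            for col in (0, 2, 4):
                assert np.allclose(revised[:, col], logits[:, col])

    def test_confident_protected_cells_exempt(self):
        logits = np.array([[5.0, 0.0], [0.2, 0.0]])
        p_est = np.array([0.0, 1.0])
        p_ct = np.array([1.0, 0.0])
        rp = RecoveryParams(alpha=100.0, target_types=(1,),
                            protected_types=(0,), rng_seed=0)
        after, _ = recover_celltypes(logits, p_est, p_ct, rp)
        assert after[0] == 0   # confident type-0 cell is masked from recovery
        assert after[1] == 1   # uncertain cell is recovered
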