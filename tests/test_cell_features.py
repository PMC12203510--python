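"""Cell-line features: z-scoring, PPI fusion, and the compression autoencoder."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from synfuse.cell_features import (
    Autoencoder,
    AutoencoderSpec,
    FusedCellMatrix,
    build_fused_matrix,
    embed_cell_lines,
    fuse_with_ppi,
    normalize_expression,
    train_autoencoder,
)
from synfuse.records import OmicsMatrix, PPIMatrix, SchemaError, ValidationError


def _omics(values, kind="expression", cells=None, genes=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return OmicsMatrix(
        cell_ids=cells or [f"c{i}" for i in range(n)],
        gene_ids=genes or [f"g{j}" for j in range(m)],
        values=values, kind=kind)


class TestNormalizeExpression:
    def test_closed_form_column(self):
        m = normalize_expression(_omics([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(m.values[:, 0], [-1.2247, 0.0, 1.2247],
                                   atol=1e-4)

    def test_constant_column_maps_to_zero(self):
        m = normalize_expression(_omics([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        np.testing.assert_array_equal(m.values[:, 0], np.zeros(3))

    def test_moments_after_op(self, rng):
        m = normalize_expression(_omics(rng.standard_normal((4, 6))))
        np.testing.assert_allclose(m.values.mean(axis=0), np.zeros(6), atol=1e-12)
        np.testing.assert_allclose(m.values.std(axis=0), np.ones(6), atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValidationError):
            normalize_expression(_omics([[1.0, 2.0]]))


class TestFuseWithPPI:
    def test_identity_ppi_is_noop(self, rng):
        om = _omics(rng.standard_normal((3, 4)))
        ppi = PPIMatrix(gene_ids=om.gene_ids, weights=np.eye(4))
        np.testing.assert_array_equal(fuse_with_ppi(om, ppi), om.values)

    def test_permutation_ppi_permutes_columns(self, rng):
        om = _omics(rng.standard_normal((3, 4)))
        perm = np.array([2, 0, 3, 1])
        p = np.zeros((4, 4))
        p[np.arange(4), perm] = 1.0
        sym = p + p.T  # make symmetric; single permutation matrices aren't
        ppi = PPIMatrix(gene_ids=om.gene_ids, weights=sym)
        np.testing.assert_allclose(fuse_with_ppi(om, ppi),
                                   om.values @ sym, atol=1e-12)

    def test_matches_triple_loop_product(self, rng):
        om = _omics(rng.standard_normal((3, 4)))
        w = rng.random((4, 4))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        ppi = PPIMatrix(gene_ids=om.gene_ids, weights=w)
        out = fuse_with_ppi(om, ppi)
        oracle = np.zeros((3, 4))
        for i in range(3):
            for j in range(4):
                for k in range(4):
                    oracle[i, j] += om.values[i, k] * w[k, j]
        np.testing.assert_allclose(out, oracle, atol=1e-10)

    def test_linearity(self, rng):
        x = rng.standard_normal((3, 5))
        ymat = rng.standard_normal((3, 5))
        w = rng.random((5, 5))
        w = (w + w.T) / 2
        genes = [f"g{j}" for j in range(5)]
        ppi = PPIMatrix(gene_ids=genes, weights=w)
        a, b = 0.7, -1.3
        lhs = fuse_with_ppi(_omics(a * x + b * ymat, genes=genes), ppi)
        rhs = (a * fuse_with_ppi(_omics(x, genes=genes), ppi)
               + b * fuse_with_ppi(_omics(ymat, genes=genes), ppi))
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_alignment_zero_fills_missing_genes(self, rng):
        om = _omics(rng.standard_normal((2, 3)), genes=["g0", "g1", "g2"])
        ppi = PPIMatrix(gene_ids=["g1", "gX"],
                        weights=np.array([[0.0, 0.5], [0.5, 0.0]]))
        out = fuse_with_ppi(om, ppi)
        # g1 has no surviving partner within the omics gene list
        np.testing.assert_array_equal(out, np.zeros((2, 3)))


class TestBuildFusedMatrix:
    def _inputs(self, rng):
        mut = _omics((rng.random((2, 3)) < 0.5).astype(float), kind="mutation",
                     genes=["m0", "m1", "m2"])
        expr = _omics(rng.standard_normal((2, 4)), genes=["e0", "e1", "e2", "e3"])
        genes = ["m0", "m1", "m2", "e0", "e1", "e2", "e3"]
        w = rng.random((7, 7))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        return mut, expr, PPIMatrix(gene_ids=genes, weights=w)

    def test_shape(self, rng):
        mut, expr, ppi = self._inputs(rng)
        fused = build_fused_matrix(mut, expr, ppi)
        assert fused.values.shape == (2, 7)

    def test_identity_ppi_concatenates_unchanged(self, rng):
        mut, expr, _ = self._inputs(rng)
        genes = mut.gene_ids + expr.gene_ids
        ppi = PPIMatrix(gene_ids=genes, weights=np.eye(7))
        fused = build_fused_matrix(mut, expr, ppi)
        np.testing.assert_array_equal(fused.values,
                                      np.hstack([mut.values, expr.values]))

    def test_blockwise_oracle(self, rng):
        mut, expr, ppi = self._inputs(rng)
        fused = build_fused_matrix(mut, expr, ppi)
        oracle = np.hstack([
            mut.values @ ppi.align(mut.gene_ids).weights,
            expr.values @ ppi.align(expr.gene_ids).weights,
        ])
        np.testing.assert_allclose(fused.values, oracle, atol=1e-12)

    def test_ppi_disabled_gives_standardized_concat(self, rng):
        mut, expr, ppi = self._inputs(rng)
        fused = build_fused_matrix(mut, expr, ppi, use_ppi=False)
        concat = np.hstack([mut.values, expr.values])
        mu, sd = concat.mean(axis=0), concat.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            expected = (concat - mu) / sd
        expected[:, sd == 0] = 0.0
        np.testing.assert_array_equal(fused.values, expected)

    def test_cell_order_mismatch_rejected(self, rng):
        mut, expr, ppi = self._inputs(rng)
        expr.cell_ids = list(reversed(expr.cell_ids))
        with pytest.raises(SchemaError):
            build_fused_matrix(mut, expr, ppi)


def _rank_k_data(rng, n=50, m=40, k=2):
    u = rng.standard_normal((n, k))
    v = rng.standard_normal((k, m))
    return u @ v


class TestAutoencoder:
    def test_linear_bottleneck_reaches_pca_optimum(self, rng):
        x = _rank_k_data(rng)
        spec = AutoencoderSpec(hidden=(2,), activation="linear", epochs=1500,
                               lr=1e-2, seed=0)
        ae = Autoencoder(x.shape[1], spec)
        history = ae.fit(x)
        final_mse = float(((ae.reconstruct(x) - x) ** 2).mean())
        # rank-2 data with a 2-unit linear bottleneck: the PCA optimum is ~0
        assert final_mse < 0.01 * x.var()
        assert history[-1] <= history[0]

    def test_embedding_spans_principal_subspace(self, rng):
        x = _rank_k_data(rng, k=2)
        spec = AutoencoderSpec(hidden=(2,), activation="linear", epochs=1500,
                               lr=1e-2, seed=0)
        ae = Autoencoder(x.shape[1], spec)
        ae.fit(x)
        recon = ae.reconstruct(x)
        xc = x - x.mean(axis=0)
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        angles = subspace_angles((recon - recon.mean(axis=0)).T, vt[:2].T)
        assert angles.max() < 1e-3

    def test_full_width_bottleneck_near_perfect(self, rng):
        x = rng.standard_normal((20, 6))
        spec = AutoencoderSpec(hidden=(6,), activation="linear", epochs=2000,
                               lr=1e-2, seed=0)
        ae = Autoencoder(6, spec)
        ae.fit(x)
        assert float(((ae.reconstruct(x) - x) ** 2).mean()) < 0.01 * x.var()

    def test_same_seed_identical_history(self, rng):
        x = rng.standard_normal((15, 8))
        spec = AutoencoderSpec(hidden=(8, 3), epochs=50, lr=1e-3, seed=7)
        h1 = Autoencoder(8, spec).fit(x)
        h2 = Autoencoder(8, spec).fit(x)
        assert h1 == h2

    def test_embed_cell_lines_shapes_and_determinism(self, rng):
        x = rng.standard_normal((5, 10))
        x[3] = x[1]  # duplicated profile
        fused = FusedCellMatrix(cell_ids=[f"c{i}" for i in range(5)], values=x)
        ae, _ = train_autoencoder(fused, AutoencoderSpec(hidden=(6, 3),
                                                         epochs=30, seed=0))
        embs = embed_cell_lines(fused, ae)
        assert len(embs) == 5 and all(e.vector.shape == (3,) for e in embs)
        np.testing.assert_array_equal(embs[1].vector, embs[3].vector)

    def test_rowwise_equals_batch(self, rng):
        x = rng.standard_normal((6, 9))
        ae = Autoencoder(9, AutoencoderSpec(hidden=(5, 2), epochs=20, seed=0))
        ae.fit(x)
        batch = ae.encode(x)
        rows = np.stack([ae.encode(x[i:i + 1])[0] for i in range(6)])
        np.testing.assert_allclose(batch, rows, atol=1e-6)

    def test_column_mismatch_rejected(self, rng):
        ae = Autoencoder(9, AutoencoderSpec(hidden=(5, 2), epochs=1, seed=0))
        with pytest.raises(SchemaError):
            ae.encode(rng.standard_normal((3, 8)))
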