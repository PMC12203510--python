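"""Drug feature blocks: fingerprints, Jaccard similarity, target/pathway
means and the padded 8-token combination feature."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from synfuse.drug_features import (
    DrugFeatureBlock,
    DrugFeaturizer,
    SmilesParseError,
    build_combination_feature,
    compute_fingerprint,
    jaccard_similarity,
    pathway_feature,
    pathway_tag_feature,
    similarity_vector,
    target_feature,
)
from synfuse.records import (
    DrugRecord,
    EmbeddingTable,
    SchemaError,
    ValidationError,
)

ASPIRIN = "CC(=O)OC1=CC=CC=C1C(=O)O"


class TestFingerprint:
    def test_valid_molecule_sets_bits(self):
        fp = compute_fingerprint("C")
        assert fp.shape == (1024,)
        assert set(np.unique(fp)) <= {0.0, 1.0}
        assert fp.sum() >= 1

    def test_deterministic(self):
        np.testing.assert_array_equal(compute_fingerprint(ASPIRIN),
                                      compute_fingerprint(ASPIRIN))

    def test_canonicalization_invariant(self):
        # the same molecule written differently must hash identically
        canonical = Chem.MolToSmiles(Chem.MolFromSmiles(ASPIRIN))
        assert canonical != ASPIRIN
        np.testing.assert_array_equal(compute_fingerprint(ASPIRIN),
                                      compute_fingerprint(canonical))

    def test_unparseable_smiles_names_drug(self):
        with pytest.raises(SmilesParseError, match="drugX"):
            compute_fingerprint("not_a_smiles((", drug_id="drugX")


def _bits(idx, n=16):
    v = np.zeros(n)
    v[list(idx)] = 1
    return v


class TestJaccard:
    @pytest.mark.parametrize("a, b, expected", [
        (_bits({0, 3, 7}), _bits({0, 3, 7}), 1.0),      # identical
        (_bits({0, 1}), _bits({2, 3}), 0.0),            # disjoint
        (_bits({1, 2, 3}), _bits({2, 3, 4}), 0.5),      # 2 shared / 4 union
        (_bits(()), _bits(()), 1.0),                    # both empty
        (_bits(()), _bits({1}), 0.0),                   # empty vs non-empty
    ])
    def test_examples(self, a, b, expected):
        assert jaccard_similarity(a, b) == expected

    def test_length_mismatch(self):
        with pytest.raises(SchemaError):
            jaccard_similarity(np.zeros(4), np.zeros(5))

    @settings(deadline=None, max_examples=100)
    @given(st.sets(st.integers(0, 15)), st.sets(st.integers(0, 15)))
    def test_matches_set_arithmetic_and_invariants(self, sa, sb):
        got = jaccard_similarity(_bits(sa), _bits(sb))
        union = sa | sb
        expected = 1.0 if not union else len(sa & sb) / len(union)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == jaccard_similarity(_bits(sb), _bits(sa))  # symmetry
        assert 0.0 <= got <= 1.0
        assert (got == 1.0) == (sa == sb)


class TestSimilarityVector:
    def test_self_entry_is_one(self, rng):
        fps = [(rng.random(32) < 0.3).astype(float) for _ in range(5)]
        vec = similarity_vector(fps[2], fps)
        assert vec[2] == 1.0

    def test_unseen_drug_in_range(self, rng):
        fps = [(rng.random(32) < 0.3).astype(float) for _ in range(5)]
        probe = (rng.random(32) < 0.3).astype(float)
        vec = similarity_vector(probe, fps)
        assert vec.shape == (5,)
        assert np.isfinite(vec).all() and (vec >= 0).all() and (vec <= 1).all()

    def test_matches_pairwise_loop(self, rng):
        fps = [(rng.random(64) < 0.2).astype(float) for _ in range(6)]
        vec = similarity_vector(fps[0], fps)
        oracle = np.array([jaccard_similarity(fps[0], f) for f in fps])
        np.testing.assert_array_equal(vec, oracle)

    def test_empty_reference_rejected(self, rng):
        with pytest.raises(ValidationError):
            similarity_vector(np.zeros(8), [])


class TestTargetPathwayFeatures:
    def test_single_target_returns_vector(self, small_embeddings):
        drug = DrugRecord("d", target_ids={"P3"})
        np.testing.assert_array_equal(target_feature(drug, small_embeddings),
                                      small_embeddings["P3"])

    def test_opposite_vectors_cancel(self):
        table = EmbeddingTable({"a": [1.0, -2.0], "b": [-1.0, 2.0]})
        drug = DrugRecord("d", target_ids={"a", "b"})
        np.testing.assert_array_equal(target_feature(drug, table), [0.0, 0.0])

    def test_no_targets_gives_zero_vector(self, small_embeddings):
        drug = DrugRecord("d")
        np.testing.assert_array_equal(target_feature(drug, small_embeddings),
                                      np.zeros(6))

    def test_mean_matches_loop_oracle_and_permutation_invariance(self, rng):
        table = EmbeddingTable({f"t{i}": rng.standard_normal(1024) for i in range(3)})
        drug = DrugRecord("d", target_ids={"t0", "t1", "t2"})
        acc = np.zeros(1024)
        for t in ["t2", "t0", "t1"]:  # any order
            acc += table[t]
        np.testing.assert_allclose(target_feature(drug, table), acc / 3,
                                   atol=1e-12)

    def test_pathway_tag_hand_mean(self):
        table = EmbeddingTable({"g1": [0.0, 2.0], "g2": [2.0, 0.0]})
        np.testing.assert_array_equal(
            pathway_tag_feature({"g1", "g2"}, table), [1.0, 1.0])

    def test_pathway_tag_all_unmapped_is_zero(self, small_embeddings):
        np.testing.assert_array_equal(
            pathway_tag_feature({"nope"}, small_embeddings), np.zeros(6))

    def test_pathway_feature_loop_oracle(self, rng):
        vectors = {f"pw{i}": rng.standard_normal(8) for i in range(3)}
        drug = DrugRecord("d", pathway_ids=set(vectors))
        oracle = sum(vectors.values()) / 3
        np.testing.assert_allclose(pathway_feature(drug, vectors), oracle,
                                   atol=1e-12)

    def test_pathway_feature_empty_is_zero(self, rng):
        vectors = {"pw0": rng.standard_normal(8)}
        drug = DrugRecord("d")
        np.testing.assert_array_equal(pathway_feature(drug, vectors), np.zeros(8))


def _random_block(rng, n_bits=16, n_ref=5, dim=8):
    return DrugFeatureBlock(
        fingerprint=(rng.random(n_bits) < 0.3).astype(float),
        similarity=rng.random(n_ref),
        target=rng.standard_normal(dim),
        pathway=rng.standard_normal(dim),
    )


class TestCombinationFeature:
    def test_shape_and_zero_padding(self, rng):
        a, b = _random_block(rng), _random_block(rng)
        cf = build_combination_feature(a, b, d=32)
        assert cf.tokens.shape == (8, 32)
        # similarity token zero beyond its width
        assert np.array_equal(cf.tokens[1, 5:], np.zeros(27))
        assert np.array_equal(cf.tokens[5, 5:], np.zeros(27))

    def test_swap_exchanges_token_halves(self, rng):
        a, b = _random_block(rng), _random_block(rng)
        ab = build_combination_feature(a, b, d=32).tokens
        ba = build_combination_feature(b, a, d=32).tokens
        np.testing.assert_array_equal(ab[:4], ba[4:])
        np.testing.assert_array_equal(ab[4:], ba[:4])

    def test_lossless_unpad(self, rng):
        a, b = _random_block(rng), _random_block(rng)
        cf = build_combination_feature(a, b, d=64)
        ra, rb = cf.unpad()
        for orig, rec in ((a, ra), (b, rb)):
            for x, y in zip(orig.blocks(), rec.blocks()):
                np.testing.assert_array_equal(x, y)

    def test_d_too_small_rejected(self, rng):
        a, b = _random_block(rng, n_bits=64), _random_block(rng, n_bits=64)
        with pytest.raises(ValidationError):
            build_combination_feature(a, b, d=32)


class TestDrugFeaturizer:
    @pytest.fixture
    def featurizer(self, drug_ab, small_embeddings):
        a, b = drug_ab
        pathway_genes = {"PW0": {"P5", "P6"}, "PW1": {"P7"}}
        return DrugFeaturizer({"A": a, "B": b}, small_embeddings, pathway_genes,
                              n_bits=64, d=64)

    def test_combination_token_order(self, featurizer):
        cf = featurizer.combination("A", "B")
        block_a = featurizer.block("A")
        np.testing.assert_array_equal(cf.tokens[0, :64], block_a.fingerprint)
        np.testing.assert_array_equal(cf.tokens[2, :6], block_a.target)

    def test_similarity_self_index(self, featurizer):
        # reference order is sorted drug ids: A at 0, B at 1
        assert featurizer.block("A").similarity[0] == 1.0
        assert featurizer.block("B").similarity[1] == 1.0

    def test_ablation_flags_zero_tokens(self, drug_ab, small_embeddings):
        a, b = drug_ab
        fz = DrugFeaturizer({"A": a, "B": b}, small_embeddings,
                            {"PW0": {"P5"}, "PW1": {"P7"}},
                            n_bits=64, d=64, use_targets=False)
        cf = fz.combination("A", "B")
        assert np.array_equal(cf.tokens[2], np.zeros(64))
        assert np.array_equal(cf.tokens[6], np.zeros(64))
        assert cf.tokens[3].any()  # pathway block untouched
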