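"""Build the four per-drug feature blocks and the 8-token pair feature.

Uses the SMILES-backed mode so real Morgan fingerprints are computed.
"""

from synfuse import FixtureSpec, generate_fixture
from synfuse.drug_features import DrugFeaturizer, jaccard_similarity

fixture = generate_fixture(
    FixtureSpec.small(seed=0, n_drugs=8, smiles_mode=True, n_bits=256))
drugs = fixture.drugs

featurizer = DrugFeaturizer(drugs.drugs, drugs.embeddings, drugs.pathway_genes,
                            n_bits=256, d=256)
a, b = sorted(drugs.drugs)[:2]
block_a = featurizer.block(a)
print(f"drug {a}: {drugs.drugs[a].smiles}")
print(f"  fingerprint bits set: {int(block_a.fingerprint.sum())} / 256")
print(f"  similarity vs {len(featurizer.reference_order)} reference drugs: "
      f"min {block_a.similarity.min():.2f}, max {block_a.similarity.max():.2f} "
      f"(1.00 is the drug itself)")
print(f"  target block dim: {block_a.target.shape[0]} "
      f"(mean over {len(drugs.drugs[a].target_ids)} target embeddings)")

j = jaccard_similarity(featurizer.fingerprint(a), featurizer.fingerprint(b))
print(f"Jaccard({a}, {b}) = {j:.3f}  "
      "(shared substructure bits / union of bits)")

cf = featurizer.combination(a, b)
print(f"pair feature: {cf.tokens.shape[0]} tokens x {cf.tokens.shape[1]} dims, "
      f"block widths {cf.block_widths} (zero-padded to a common width)")
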