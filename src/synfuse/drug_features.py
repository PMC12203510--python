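"""Per-drug feature blocks and the 8-token drug-combination feature.

Each drug contributes four feature blocks:

* ``fingerprint`` — Morgan circular fingerprint (radius 3, 1024 bits by
  default), the raw 0/1 substructure indicator vector;
* ``similarity``  — Jaccard similarity of the drug's fingerprint against a
  fixed, ordered reference set of training drugs (a dense low-dimensional
  surrogate for the sparse fingerprint);
* ``target``      — mean of the language-model embedding vectors of the
  drug's annotated protein targets;
* ``pathway``     — mean over the drug's pathway tags of the per-tag mean
  gene embedding.

For a drug pair (i, j) the blocks are zero-padded to a common width ``d``
and stacked in the fixed order
``[fp_i, sim_i, tgt_i, pw_i, fp_j, sim_j, tgt_j, pw_j]`` — an 8 × d token
matrix consumed by the attention encoder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .records import DrugRecord, EmbeddingTable, SchemaError, ValidationError

logger = logging.getLogger(__name__)

TOKENS_PER_PAIR = 8
BLOCK_ORDER = ("fingerprint", "similarity", "target", "pathway")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the drug id."""

    def __init__(self, smiles: str, drug_id: str | None = None):
        self.smiles = smiles
        self.drug_id = drug_id
        who = f" for drug {drug_id!r}" if drug_id else ""
        super().__init__(f"unparseable SMILES{who}: {smiles!r}")


def compute_fingerprint(
    smiles: str, radius: int = 3, n_bits: int = 1024, drug_id: str | None = None
) -> np.ndarray:
    """Morgan fingerprint of a molecule as a 0/1 vector of length ``n_bits``."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, drug_id)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=float)
    arr[list(fp.GetOnBits())] = 1.0
    return arr


def jaccard_similarity(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Intersection-over-union of two equal-length bit vectors.

    Two all-zero fingerprints are treated as identical empty substructure
    sets (similarity 1); an empty set against a non-empty one scores 0.
    """
    fp_a = np.asarray(fp_a)
    fp_b = np.asarray(fp_b)
    if fp_a.shape != fp_b.shape:
        raise SchemaError(f"fingerprint length mismatch: {fp_a.shape} vs {fp_b.shape}")
    a = fp_a != 0
    b = fp_b != 0
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    inter = int(np.count_nonzero(a & b))
    return inter / union


def similarity_vector(fp: np.ndarray, reference_fps: list[np.ndarray]) -> np.ndarray:
    """Jaccard similarities of one fingerprint against the ordered reference set."""
    if len(reference_fps) == 0:
        raise ValidationError("reference drug set is empty")
    return np.array([jaccard_similarity(fp, ref) for ref in reference_fps])


def target_feature(drug: DrugRecord, embeddings: EmbeddingTable) -> np.ndarray:
    """Mean of the embedding vectors of the drug's targets.

    Targets absent from the table are skipped (logged); a drug with no
    mapped targets gets the zero vector so it stays usable downstream.
    """
    vecs = []
    n_missing = 0
    for tid in sorted(drug.target_ids):
        if tid in embeddings:
            vecs.append(embeddings[tid])
        else:
            n_missing += 1
    if n_missing:
        logger.info("drug %s: %d target(s) missing from embedding table",
                    drug.drug_id, n_missing)
    if not vecs:
        return np.zeros(embeddings.dim)
    return np.mean(vecs, axis=0)


def pathway_tag_feature(pathway_genes, embeddings: EmbeddingTable) -> np.ndarray:
    """A pathway tag's vector: the mean embedding of its member genes."""
    vecs = [embeddings[g] for g in sorted(pathway_genes) if g in embeddings]
    if not vecs:
        logger.warning("pathway with no mapped genes → zero vector")
        return np.zeros(embeddings.dim)
    return np.mean(vecs, axis=0)


def pathway_feature(drug: DrugRecord,
                    pathway_vectors: dict[str, np.ndarray]) -> np.ndarray:
    """Mean over the drug's pathway-tag vectors; zero vector for no pathways."""
    vecs = [pathway_vectors[p] for p in sorted(drug.pathway_ids)
            if p in pathway_vectors]
    if not vecs:
        dim = len(next(iter(pathway_vectors.values()))) if pathway_vectors else 0
        return np.zeros(dim)
    return np.mean(vecs, axis=0)


@dataclass
class DrugFeatureBlock:
    """The four feature blocks of one drug, before padding."""

    fingerprint: np.ndarray
    similarity: np.ndarray
    target: np.ndarray
    pathway: np.ndarray

    def blocks(self) -> list[np.ndarray]:
        return [self.fingerprint, self.similarity, self.target, self.pathway]


@dataclass
class CombinationFeature:
    """8 × d token matrix for one drug pair, each block zero-padded to d."""

    tokens: np.ndarray
    block_widths: tuple[int, int, int, int]

    def unpad(self) -> tuple[DrugFeatureBlock, DrugFeatureBlock]:
        """Recover the original (unpadded) blocks by truncation."""
        w = self.block_widths
        rows = [self.tokens[i, : w[i % 4]] for i in range(TOKENS_PER_PAIR)]
        return (DrugFeatureBlock(*rows[:4]), DrugFeatureBlock(*rows[4:]))


def build_combination_feature(
    block_a: DrugFeatureBlock, block_b: DrugFeatureBlock, d: int
) -> CombinationFeature:
    """Stack two drugs' blocks into the 8-token matrix, zero-padded to width d."""
    widths = tuple(len(b) for b in block_a.blocks())
    widths_b = tuple(len(b) for b in block_b.blocks())
    if widths != widths_b:
        raise SchemaError(f"block widths differ between drugs: {widths} vs {widths_b}")
    if max(widths) > d:
        raise ValidationError(
            f"model dimension d={d} smaller than a block width ({max(widths)})")
    tokens = np.zeros((TOKENS_PER_PAIR, d))
    for i, block in enumerate(block_a.blocks() + block_b.blocks()):
        tokens[i, : len(block)] = block
    return CombinationFeature(tokens=tokens, block_widths=widths)


class DrugFeaturizer:
    """Builds and caches per-drug blocks against a fixed reference drug order.

    The reference set (the training drugs, in a stored order) defines the
    similarity-block coordinates, so an unseen drug in a cold-start setting
    is embedded against the same references as the training drugs were.

    Parameters
    ----------
    drugs : mapping drug_id → DrugRecord
    embeddings : EmbeddingTable for target proteins and pathway genes
    pathway_genes : mapping pathway_id → set of gene ids
    fingerprints : optional precomputed drug_id → bit vector (bypasses SMILES)
    d : common token width (pad target); defaults to 1024
    use_fingerprint / use_targets / use_pathways : ablation switches — a
        disabled family contributes all-zero tokens
    """

    def __init__(
        self,
        drugs: dict[str, DrugRecord],
        embeddings: EmbeddingTable,
        pathway_genes: dict[str, set[str]],
        reference_order: list[str] | None = None,
        fingerprints: dict[str, np.ndarray] | None = None,
        radius: int = 3,
        n_bits: int = 1024,
        d: int = 1024,
        use_fingerprint: bool = True,
        use_targets: bool = True,
        use_pathways: bool = True,
    ):
        self.drugs = drugs
        self.embeddings = embeddings
        self.pathway_genes = pathway_genes
        self.radius = radius
        self.n_bits = n_bits
        self.d = d
        self.use_fingerprint = use_fingerprint
        self.use_targets = use_targets
        self.use_pathways = use_pathways
        self.reference_order = list(reference_order or sorted(drugs))
        self._fps: dict[str, np.ndarray] = dict(fingerprints or {})
        self._pathway_vectors = {
            pw: pathway_tag_feature(genes, embeddings)
            for pw, genes in sorted(pathway_genes.items())
        }
        self._blocks: dict[str, DrugFeatureBlock] = {}

    # -- per-drug pieces ---------------------------------------------------
    def fingerprint(self, drug_id: str) -> np.ndarray:
        if drug_id not in self._fps:
            drug = self.drugs[drug_id]
            if not drug.smiles:
                raise ValidationError(
                    f"drug {drug_id!r} has neither a SMILES nor a precomputed fingerprint")
            self._fps[drug_id] = compute_fingerprint(
                drug.smiles, self.radius, self.n_bits, drug_id=drug_id)
        return self._fps[drug_id]

    def block(self, drug_id: str,
              drop_targets: frozenset[str] = frozenset(),
              drop_pathways: frozenset[str] = frozenset()) -> DrugFeatureBlock:
        """The drug's four blocks; drop sets recompute the target/pathway
        means over the remaining annotations (inference-time feature removal)."""
        cacheable = not drop_targets and not drop_pathways
        if cacheable and drug_id in self._blocks:
            return self._blocks[drug_id]
        drug = self.drugs[drug_id]
        fp = self.fingerprint(drug_id)
        sim = similarity_vector(fp, [self.fingerprint(r) for r in self.reference_order])
        if drop_targets or drop_pathways:
            drug = DrugRecord(
                drug_id=drug.drug_id, smiles=drug.smiles,
                target_ids=drug.target_ids - drop_targets,
                pathway_ids=drug.pathway_ids - drop_pathways)
        tgt = target_feature(drug, self.embeddings)
        pw = pathway_feature(drug, self._pathway_vectors)
        if pw.size == 0:
            pw = np.zeros(self.embeddings.dim)
        block = DrugFeatureBlock(
            fingerprint=fp if self.use_fingerprint else np.zeros_like(fp),
            similarity=sim,
            target=tgt if self.use_targets else np.zeros_like(tgt),
            pathway=pw if self.use_pathways else np.zeros_like(pw),
        )
        if cacheable:
            self._blocks[drug_id] = block
        return block

    def combination(self, drug_a: str, drug_b: str,
                    drop_targets: frozenset[str] = frozenset(),
                    drop_pathways: frozenset[str] = frozenset()) -> CombinationFeature:
        """The 8 × d token matrix for an (ordered) drug pair."""
        if drop_targets or drop_pathways:
            annotated_t = self.drugs[drug_a].target_ids | self.drugs[drug_b].target_ids
            annotated_p = self.drugs[drug_a].pathway_ids | self.drugs[drug_b].pathway_ids
            for tid in sorted(drop_targets - annotated_t):
                logger.warning("dropped target %s is not annotated to %s or %s",
                               tid, drug_a, drug_b)
            for pid in sorted(drop_pathways - annotated_p):
                logger.warning("dropped pathway %s is not annotated to %s or %s",
                               pid, drug_a, drug_b)
        return build_combination_feature(
            self.block(drug_a, drop_targets, drop_pathways),
            self.block(drug_b, drop_targets, drop_pathways),
            self.d,
        )

    def token_stack(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        """Token matrices for many pairs, shape (n_pairs, 8, d)."""
        return np.stack([self.combination(a, b).tokens for a, b in pairs])
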