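"""Shared record types for synergy triplets, drugs, omics matrices and embeddings.

These are the in-memory containers every stage of the pipeline exchanges:
drug annotations (:class:`DrugRecord`), measured synergy triplets
(:class:`SynergyRecord`), cell-line omics (:class:`OmicsMatrix`), the
protein-association matrix (:class:`PPIMatrix`) and precomputed protein /
gene language-model vectors (:class:`EmbeddingTable`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SCORE_TYPES = ("loewe", "bliss", "zip", "hsa")


class SchemaError(ValueError):
    """A file does not match its documented column/shape contract."""


class ValidationError(ValueError):
    """Parsed content violates a record invariant (e.g. drug paired with itself)."""


def pair_key(drug_a: str, drug_b: str) -> tuple[str, str]:
    """Canonical unordered-pair key: lexicographically sorted drug ids."""
    return (drug_a, drug_b) if drug_a <= drug_b else (drug_b, drug_a)


@dataclass
class DrugRecord:
    """One drug: identity, structure and its target / pathway annotation sets."""

    drug_id: str
    smiles: str | None = None
    target_ids: frozenset[str] = field(default_factory=frozenset)
    pathway_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValidationError("drug_id must be non-empty")
        self.target_ids = frozenset(self.target_ids)
        self.pathway_ids = frozenset(self.pathway_ids)


@dataclass
class SynergyRecord:
    """One measured triplet: two drugs, a cell line, and synergy score(s).

    ``scores`` maps synergy-type names (``loewe``/``bliss``/``zip``/``hsa``)
    to real values.  The unordered pair is the identity used for replicate
    collapsing and fold assignment.
    """

    drug_a: str
    drug_b: str
    cell_line: str
    scores: dict[str, float] = field(default_factory=dict)
    label: int | None = None

    def __post_init__(self) -> None:
        if self.drug_a == self.drug_b:
            raise ValidationError(
                f"drug paired with itself: {self.drug_a!r} (cell {self.cell_line!r})"
            )
        if not self.scores:
            raise ValidationError("at least one synergy score must be present")
        unknown = set(self.scores) - set(SCORE_TYPES)
        if unknown:
            raise ValidationError(f"unknown synergy score type(s): {sorted(unknown)}")
        if self.label is not None and self.label not in (0, 1):
            raise ValidationError(f"label must be 0/1, got {self.label!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return pair_key(self.drug_a, self.drug_b)

    def score(self, score_type: str) -> float:
        return self.scores[score_type]


@dataclass
class OmicsMatrix:
    """Cell-line × gene matrix: continuous expression or binary mutation calls."""

    cell_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    kind: str = "expression"  # "expression" | "mutation"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise SchemaError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if self.kind not in ("expression", "mutation"):
            raise ValidationError(f"unknown omics kind {self.kind!r}")
        if self.kind == "mutation":
            bad = ~np.isin(self.values, (0.0, 1.0))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValidationError(
                    f"mutation matrix must be binary; found {self.values[i, j]!r} "
                    f"at cell {self.cell_ids[i]!r}, gene {self.gene_ids[j]!r}"
                )

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class PPIMatrix:
    """Symmetric non-negative gene–gene association matrix (STRING-style)."""

    gene_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        t = len(self.gene_ids)
        if self.weights.shape != (t, t):
            raise SchemaError(f"PPI weights shape {self.weights.shape} != ({t}, {t})")
        if len(set(self.gene_ids)) != t:
            raise ValidationError("duplicate gene ids in PPI matrix")
        if not np.allclose(self.weights, self.weights.T):
            raise ValidationError("PPI weight matrix must be symmetric")
        if (self.weights < 0).any():
            raise ValidationError("PPI weights must be non-negative")

    def align(self, gene_ids: list[str]) -> "PPIMatrix":
        """Reindex to ``gene_ids``: genes absent from the network get zero
        rows/columns, genes absent from ``gene_ids`` are dropped."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        t = len(gene_ids)
        out = np.zeros((t, t))
        present = [(j, index[g]) for j, g in enumerate(gene_ids) if g in index]
        if present:
            rows = np.array([p[0] for p in present])
            cols = np.array([p[1] for p in present])
            out[np.ix_(rows, rows)] = self.weights[np.ix_(cols, cols)]
        return PPIMatrix(gene_ids=list(gene_ids), weights=out)


class EmbeddingTable:
    """Mapping from protein/gene id to a fixed-dimension real vector.

    Stands in for the output of a pretrained protein language model: each
    target protein or pathway gene is represented by one dense vector, and
    drug-level features are means over these vectors.
    """

    def __init__(self, vectors: dict[str, np.ndarray]):
        if not vectors:
            raise ValidationError("embedding table is empty")
        self._vectors: dict[str, np.ndarray] = {}
        dim = None
        for key, vec in vectors.items():
            arr = np.asarray(vec, dtype=float).ravel()
            if dim is None:
                dim = arr.size
            elif arr.size != dim:
                raise SchemaError(
                    f"embedding for {key!r} has dimension {arr.size}, expected {dim}"
                )
            if key in self._vectors:
                raise ValidationError(f"duplicate embedding key {key!r}")
            self._vectors[key] = arr
        self.dim = int(dim)

    def __contains__(self, key: str) -> bool:
        return key in self._vectors

    def __getitem__(self, key: str) -> np.ndarray:
        return self._vectors[key]

    def __len__(self) -> int:
        return len(self._vectors)

    def keys(self):
        return self._vectors.keys()

    def items(self):
        return self._vectors.items()
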