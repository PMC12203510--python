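"""Synthetic fixture generation with planted, learnable synergy structure.

The generator emulates every input the pipeline consumes — drugs with
fingerprints and target/pathway annotations, protein/gene embedding
vectors, cell-line expression and mutation matrices, a STRING-style PPI
edge list — and plants a known synergy signal:

    score(A, B, c) = w_struct·z[J(A,B)] + w_target·z[overlap(T_A, T_B)]
                   + w_pathway·z[overlap(P_A, P_B)] + w_cell·z[⟨u_c, β⟩] + ε

where J is fingerprint Jaccard similarity, overlap is the cosine
similarity of the two drugs' mean target (resp. pathway) embedding
vectors — a smooth overlap measure expressed in exactly the feature
space the model consumes, so the planted signal is by construction a
deterministic function of the generated features —
u_c is the cell line's latent expression factor,
z[·] standardises each component over its realised values, and
ε ~ N(0, σ²).  The score is symmetric in (A, B) by construction and the
true components are stored alongside for diagnostics, so recovery and
ablation behaviour can be measured against ground truth.

Everything is reproducible: a fixture regenerated from the same
(spec, seed) is byte-identical on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .drug_features import (
    compute_fingerprint,
    jaccard_similarity,
    pathway_feature,
    pathway_tag_feature,
    target_feature,
)
from .records import (
    DrugRecord,
    EmbeddingTable,
    OmicsMatrix,
    PPIMatrix,
    SynergyRecord,
    ValidationError,
)

# a small pool of valid drug-like SMILES for the chemistry-backed mode
BUILTIN_SMILES = [
    "CC(=O)OC1=CC=CC=C1C(=O)O",          # aspirin
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",      # caffeine
    "CC(C)CC1=CC=C(C=C1)C(C)C(=O)O",     # ibuprofen
    "C1=CC=C2C(=C1)C=CC=C2O",            # naphthol
    "CC(=O)NC1=CC=C(C=C1)O",             # paracetamol
    "C1=CC=C(C=C1)C(=O)O",               # benzoic acid
    "C1CCC(CC1)N",                       # cyclohexylamine
    "CCN(CC)CCNC(=O)C1=CC=C(C=C1)N",     # procainamide
    "CN1CCC[C@H]1C2=CN=CC=C2",           # nicotine
    "C1=CC(=CC=C1O)O",                   # hydroquinone
    "CC1=CC=C(C=C1)S(=O)(=O)N",          # tosylamide
    "C1=CC=C(C=C1)CC(C(=O)O)N",          # phenylalanine
    "CC(C)NCC(COC1=CC=CC2=CC=CC=C21)O",  # propranolol
    "C1=CC=C(C=C1)C2=CC=CC=C2",          # biphenyl
    "OC(=O)C1=CC=CC=C1O",                # salicylic acid
    "CCOC(=O)C1=CC=CC=C1",               # ethyl benzoate
    "NC1=CC=C(C=C1)S(=O)(=O)NC1=NC=CC=N1",  # sulfadiazine
    "CC(N)CC1=CC=CC=C1",                 # amphetamine
    "OCC1=CC=CC=C1",                     # benzyl alcohol
    "CC(=O)C1=CC=CC=C1",                 # acetophenone
]


@dataclass
class FixtureSpec:
    """Study conditions of a synthetic dataset.

    Counts, noise level and signal weights define what an end-to-end run
    can recover; ``seed`` is mandatory and every file derives from it.
    """

    seed: int
    n_drugs: int = 30
    n_cells: int = 10
    n_genes_expr: int = 60
    n_genes_mut: int = 40
    n_targets: int = 15
    n_pathways: int = 8
    embed_dim: int = 1024
    embed_latent_rank: int = 4
    n_bits: int = 1024
    fingerprint_density: float = 0.1
    n_scaffold_families: int = 6
    family_bit_density: float = 0.15
    specific_bit_density: float = 0.05
    noise_sd: float = 0.0
    w_struct: float = 1.0
    w_target: float = 1.0
    w_pathway: float = 1.0
    w_cell: float = 1.0
    expr_rank: int = 3
    expr_noise_sd: float = 0.1
    ppi_density: float = 0.15
    mutation_rate: float = 0.2
    targets_per_drug: tuple[int, int] = (2, 4)
    pathways_per_drug: tuple[int, int] = (1, 3)
    genes_per_pathway: tuple[int, int] = (3, 8)
    smiles_mode: bool = False

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_cells", "n_genes_expr", "n_genes_mut",
                     "n_pathways", "embed_dim", "n_bits", "expr_rank"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_targets < 0:
            raise ValidationError("n_targets must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be >= 0")

    @classmethod
    def small(cls, seed: int, **overrides) -> "FixtureSpec":
        """Reduced-width fixture used throughout the test suite: same
        counts and signal as the default, narrow feature vectors so model
        training stays fast on one CPU."""
        base = cls(seed=seed, embed_dim=32, n_bits=64)
        return replace(base, **overrides) if overrides else base


def _seeds(spec: FixtureSpec, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(spec.seed).spawn(n)]


def set_overlap(a: set, b: set) -> float:
    """Intersection-over-union of two finite sets; 0 when both are empty."""
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


@dataclass
class FixtureDrugs:
    drugs: dict[str, DrugRecord]
    fingerprints: dict[str, np.ndarray]
    embeddings: EmbeddingTable
    pathway_genes: dict[str, set[str]]


@dataclass
class FixtureCells:
    expression: OmicsMatrix
    mutation: OmicsMatrix
    ppi: PPIMatrix
    ppi_edges: list[tuple[str, str, float]]
    gene_map: dict[str, str]
    cell_factors: np.ndarray  # n_cells × expr_rank latent factors


@dataclass
class Fixture:
    spec: FixtureSpec
    drugs: FixtureDrugs
    cells: FixtureCells
    records: list[SynergyRecord]
    truth: pd.DataFrame
    beta: np.ndarray

    def write(self, outdir: str | Path) -> None:
        """Emit all input files in the documented delimited-text dialects."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        sio.write_synergy_table(self.records, out / "synergy.tsv")
        with open(out / "drugs.tsv", "w") as fh:
            fh.write("drug_id\tsmiles\n")
            for did, rec in sorted(self.drugs.drugs.items()):
                fh.write(f"{did}\t{rec.smiles or ''}\n")
        with open(out / "targets.tsv", "w") as fh:
            fh.write("drug_id\tprotein_id\n")
            for did, rec in sorted(self.drugs.drugs.items()):
                for tid in sorted(rec.target_ids):
                    fh.write(f"{did}\t{tid}\n")
        with open(out / "pathways.tsv", "w") as fh:
            fh.write("drug_id\tpathway_id\n")
            for did, rec in sorted(self.drugs.drugs.items()):
                for pid in sorted(rec.pathway_ids):
                    fh.write(f"{did}\t{pid}\n")
        with open(out / "pathway_genes.tsv", "w") as fh:
            fh.write("pathway_id\tgene_id\n")
            for pid, genes in sorted(self.drugs.pathway_genes.items()):
                for g in sorted(genes):
                    fh.write(f"{pid}\t{g}\n")
        sio.write_embedding_table(self.drugs.embeddings, out / "embeddings.tsv")
        fps = EmbeddingTable({d: fp for d, fp in sorted(self.drugs.fingerprints.items())})
        sio.write_embedding_table(fps, out / "fingerprints.tsv")
        sio.write_omics_matrix(self.cells.expression, out / "expression.tsv")
        sio.write_omics_matrix(self.cells.mutation, out / "mutation.tsv")
        with open(out / "ppi_edges.tsv", "w") as fh:
            fh.write("protein1\tprotein2\tcombined_score\n")
            for p1, p2, w in self.cells.ppi_edges:
                fh.write(f"{p1}\t{p2}\t{w:.17g}\n")
        with open(out / "gene_map.tsv", "w") as fh:
            fh.write("protein_id\tgene_id\n")
            for pid, gid in sorted(self.cells.gene_map.items()):
                fh.write(f"{pid}\t{gid}\n")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False,
                          float_format="%.17g")


def generate_drugs(spec: FixtureSpec) -> FixtureDrugs:
    """Drugs with fingerprints, target/pathway annotations, and embeddings.

    By default fingerprints are drawn directly as sparse random bit
    vectors (no chemistry needed); ``smiles_mode`` assigns built-in SMILES
    and computes real Morgan fingerprints instead.
    """
    rng = _seeds(spec, 3)[0]
    drug_ids = [f"D{i:03d}" for i in range(spec.n_drugs)]
    target_pool = [f"P{i:03d}" for i in range(spec.n_targets)]
    pathway_ids = [f"PW{i:02d}" for i in range(spec.n_pathways)]
    gene_pool = [f"GE{i:03d}" for i in range(spec.n_genes_expr)]

    # drug panels cluster into scaffold families: a family-core bit pattern
    # shared within the family plus drug-specific bits.  With
    # n_scaffold_families <= 1 bits are i.i.d. at fingerprint_density.
    family_cores = None
    if not spec.smiles_mode and spec.n_scaffold_families > 1:
        family_cores = (rng.random((spec.n_scaffold_families, spec.n_bits))
                        < spec.family_bit_density)
    fingerprints: dict[str, np.ndarray] = {}
    smiles_map: dict[str, str | None] = {}
    for i, did in enumerate(drug_ids):
        if spec.smiles_mode:
            smi = BUILTIN_SMILES[i % len(BUILTIN_SMILES)]
            smiles_map[did] = smi
            fingerprints[did] = compute_fingerprint(smi, n_bits=spec.n_bits)
        else:
            smiles_map[did] = None
            if family_cores is not None:
                core = family_cores[i % spec.n_scaffold_families]
                specific = rng.random(spec.n_bits) < spec.specific_bit_density
                fp = (core | specific).astype(float)
            else:
                fp = (rng.random(spec.n_bits) < spec.fingerprint_density).astype(float)
            if fp.sum() == 0:
                fp[rng.integers(spec.n_bits)] = 1.0
            fingerprints[did] = fp

    pathway_genes = {
        pid: set(rng.choice(gene_pool,
                            size=rng.integers(spec.genes_per_pathway[0],
                                              spec.genes_per_pathway[1] + 1),
                            replace=False))
        for pid in pathway_ids
    }

    drugs: dict[str, DrugRecord] = {}
    for did in drug_ids:
        if spec.n_targets > 0:
            lo, hi = spec.targets_per_drug
            k = int(rng.integers(lo, hi + 1))
            k = min(k, spec.n_targets)
            targets = frozenset(rng.choice(target_pool, size=k, replace=False))
        else:
            targets = frozenset()
        lo, hi = spec.pathways_per_drug
        kp = min(int(rng.integers(lo, hi + 1)), spec.n_pathways)
        pathways = frozenset(rng.choice(pathway_ids, size=kp, replace=False))
        drugs[did] = DrugRecord(drug_id=did, smiles=smiles_map[did],
                                target_ids=targets, pathway_ids=pathways)

    # protein-language-model embeddings are strongly anisotropic: vectors are
    # drawn from a low-rank latent subspace spanned by an orthonormal basis
    r = min(spec.embed_latent_rank, spec.embed_dim)
    basis, _ = np.linalg.qr(rng.standard_normal((spec.embed_dim, r)))
    vectors = {tid: basis @ rng.standard_normal(r) for tid in target_pool}
    vectors.update({g: basis @ rng.standard_normal(r) for g in gene_pool})
    return FixtureDrugs(drugs=drugs, fingerprints=fingerprints,
                        embeddings=EmbeddingTable(vectors),
                        pathway_genes=pathway_genes)


def generate_cells(spec: FixtureSpec) -> FixtureCells:
    """Expression (rank-r factor model + noise), mutation (sparse Bernoulli)
    and a symmetric random PPI graph with weights in [0.7, 1)."""
    rng = _seeds(spec, 3)[1]
    cell_ids = [f"C{i:02d}" for i in range(spec.n_cells)]
    expr_genes = [f"GE{i:03d}" for i in range(spec.n_genes_expr)]
    mut_genes = [f"GM{i:03d}" for i in range(spec.n_genes_mut)]

    u = rng.standard_normal((spec.n_cells, spec.expr_rank))
    v = rng.standard_normal((spec.expr_rank, spec.n_genes_expr))
    expr_values = u @ v
    if spec.expr_noise_sd > 0:
        expr_values = expr_values + spec.expr_noise_sd * rng.standard_normal(
            expr_values.shape)
    expression = OmicsMatrix(cell_ids=cell_ids, gene_ids=expr_genes,
                             values=expr_values, kind="expression")
    mutation = OmicsMatrix(
        cell_ids=cell_ids, gene_ids=mut_genes,
        values=(rng.random((spec.n_cells, spec.n_genes_mut))
                < spec.mutation_rate).astype(float),
        kind="mutation")

    all_genes = expr_genes + mut_genes
    gene_map = {f"PR{i:03d}": g for i, g in enumerate(all_genes)}
    protein_of = {g: p for p, g in gene_map.items()}
    t = len(all_genes)
    weights = np.zeros((t, t))
    edges: list[tuple[str, str, float]] = []
    for i in range(t):
        for j in range(i + 1, t):
            if rng.random() < spec.ppi_density:
                w = 0.7 + 0.3 * rng.random()
                weights[i, j] = weights[j, i] = w
                edges.append((protein_of[all_genes[i]], protein_of[all_genes[j]],
                              float(w)))
    ppi = PPIMatrix(gene_ids=list(all_genes), weights=weights)
    return FixtureCells(expression=expression, mutation=mutation, ppi=ppi,
                        ppi_edges=edges, gene_map=gene_map, cell_factors=u)


def generate_synergy(
    spec: FixtureSpec, drugs: FixtureDrugs, cells: FixtureCells
) -> tuple[list[SynergyRecord], pd.DataFrame, np.ndarray]:
    """Planted-signal synergy scores for all pairs × all cell lines.

    Returns the records, a ground-truth component table and the cell
    projection vector β.
    """
    rng = _seeds(spec, 3)[2]
    drug_ids = sorted(drugs.drugs)
    cell_ids = cells.expression.cell_ids
    pairs = [(drug_ids[i], drug_ids[j])
             for i in range(len(drug_ids)) for j in range(i + 1, len(drug_ids))]

    j_comp = np.array([
        jaccard_similarity(drugs.fingerprints[a], drugs.fingerprints[b])
        for a, b in pairs])
    # overlap measured in the embedding space the model sees: cosine of the
    # per-drug mean target / pathway vectors (the d^t and d^p feature blocks)
    tgt_vec = {d: target_feature(drugs.drugs[d], drugs.embeddings)
               for d in drug_ids}
    pw_tag = {pw: pathway_tag_feature(genes, drugs.embeddings)
              for pw, genes in sorted(drugs.pathway_genes.items())}
    pw_vec = {d: pathway_feature(drugs.drugs[d], pw_tag) for d in drug_ids}
    t_comp = np.array([_cosine(tgt_vec[a], tgt_vec[b]) for a, b in pairs])
    p_comp = np.array([_cosine(pw_vec[a], pw_vec[b]) for a, b in pairs])
    beta = rng.standard_normal(spec.expr_rank)
    c_comp = cells.cell_factors @ beta

    zj, zt, zp, zc = _zscore(j_comp), _zscore(t_comp), _zscore(p_comp), _zscore(c_comp)

    records: list[SynergyRecord] = []
    rows = []
    for pi, (a, b) in enumerate(pairs):
        for ci, cell in enumerate(cell_ids):
            signal = (spec.w_struct * zj[pi] + spec.w_target * zt[pi]
                      + spec.w_pathway * zp[pi] + spec.w_cell * zc[ci])
            eps = spec.noise_sd * rng.standard_normal() if spec.noise_sd > 0 else 0.0
            score = signal + eps
            records.append(SynergyRecord(drug_a=a, drug_b=b, cell_line=cell,
                                         scores={"loewe": float(score)}))
            rows.append({"drug_a": a, "drug_b": b, "cell_line": cell,
                         "z_struct": zj[pi], "z_target": zt[pi],
                         "z_pathway": zp[pi], "z_cell": zc[ci],
                         "score": float(score)})
    return records, pd.DataFrame(rows), beta


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """All six inputs plus ground truth, reproducible from (spec, seed)."""
    drugs = generate_drugs(spec)
    cells = generate_cells(spec)
    records, truth, beta = generate_synergy(spec, drugs, cells)
    return Fixture(spec=spec, drugs=drugs, cells=cells, records=records,
                   truth=truth, beta=beta)
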