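"""Readers and writers for every external file the pipeline touches.

All files are delimited text (tab or comma, auto-detected from the header
line, overridable via ``sep=``).  Documented dialects:

* synergy table:   columns ``drug_a, drug_b, cell_line`` plus one or more of
                   ``loewe, bliss, zip, hsa``
* drug table:      ``drug_id, smiles``
* target map:      ``drug_id, protein_id``
* pathway map:     ``drug_id, pathway_id`` (gene membership in a separate
                   ``pathway_id, gene_id`` file) or combined
                   ``drug_id, pathway_id, gene_id``
* PPI edges:       ``protein1, protein2, combined_score`` (STRING-style)
* protein→gene:    ``protein_id, gene_id``
* omics matrix:    cell × gene with id headers (``transpose=True`` for
                   gene × cell files)
* embedding table: ``id`` column followed by the vector components
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from .records import (
    SCORE_TYPES,
    EmbeddingTable,
    OmicsMatrix,
    PPIMatrix,
    SchemaError,
    SynergyRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_synergy_table",
    "write_synergy_table",
    "average_replicate_triplets",
    "read_drug_table",
    "read_target_map",
    "read_pathway_map",
    "read_pathway_genes",
    "read_gene_map",
    "read_ppi_edges",
    "read_embedding_table",
    "write_embedding_table",
    "read_omics_matrix",
    "write_omics_matrix",
]

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


class EmptyInputError(SchemaError):
    pass


def _detect_sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise EmptyInputError(f"{path}: empty file")
    return "\t" if "\t" in header else ","


def _read_table(path: str | Path, sep: str | None, required: list[str]) -> pd.DataFrame:
    sep = _detect_sep(path, sep)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty and len(df.columns) == 0:
        raise EmptyInputError(f"{path}: no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; "
                          f"found {list(df.columns)}")
    return df


# ---------------------------------------------------------------------------
# synergy triplets

def read_synergy_table(
    path: str | Path,
    score_column: str | None = None,
    sep: str | None = None,
    permissive: bool = False,
) -> list[SynergyRecord]:
    """Read a synergy triplet table into :class:`SynergyRecord` objects.

    ``score_column`` restricts parsing to one synergy type; by default every
    recognised score column present is read.  Rows violating an invariant
    (drug paired with itself, unparseable score) raise a located
    :class:`ValidationError`, or are skipped with a logged count when
    ``permissive`` is set.  Replicate rows are kept as-is; collapse them with
    :func:`average_replicate_triplets`.
    """
    df = _read_table(path, sep, ["drug_a", "drug_b", "cell_line"])
    if score_column is not None:
        if score_column not in df.columns:
            raise SchemaError(f"{path}: missing score column {score_column!r}")
        score_cols = [score_column]
    else:
        score_cols = [c for c in SCORE_TYPES if c in df.columns]
        if not score_cols:
            raise SchemaError(f"{path}: no synergy score column among {SCORE_TYPES}")
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")

    records: list[SynergyRecord] = []
    n_skipped = 0
    for idx, row in df.iterrows():
        try:
            scores = {}
            for col in score_cols:
                raw = row[col]
                if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
                    continue
                try:
                    scores[col] = float(raw)
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"{path} row {idx}: unparseable {col} score {raw!r}")
            records.append(SynergyRecord(
                drug_a=str(row["drug_a"]), drug_b=str(row["drug_b"]),
                cell_line=str(row["cell_line"]), scores=scores))
        except ValidationError as err:
            if not permissive:
                raise ValidationError(f"{path} row {idx}: {err}") from err
            n_skipped += 1
    if n_skipped:
        logger.warning("%s: skipped %d invalid row(s)", path, n_skipped)
    return records


def write_synergy_table(records: list[SynergyRecord], path: str | Path,
                        sep: str = "\t") -> None:
    score_cols = [t for t in SCORE_TYPES if any(t in r.scores for r in records)]
    with open(path, "w") as fh:
        fh.write(sep.join(["drug_a", "drug_b", "cell_line", *score_cols]) + "\n")
        for r in records:
            vals = [(_FLOAT_FMT % r.scores[t]) if t in r.scores else ""
                    for t in score_cols]
            fh.write(sep.join([r.drug_a, r.drug_b, r.cell_line, *vals]) + "\n")


def average_replicate_triplets(records: list[SynergyRecord]) -> list[SynergyRecord]:
    """Collapse replicate measurements of the same (unordered pair, cell line).

    Scores of each synergy type are averaged arithmetically over the
    replicates carrying that type; (A,B,c) and (B,A,c) collapse to one key.
    Idempotent; output ordered by first appearance of each key.
    """
    acc: dict[tuple, dict[str, list[float]]] = {}
    order: list[tuple] = []
    for r in records:
        key = (*r.pair, r.cell_line)
        if key not in acc:
            acc[key] = defaultdict(list)
            order.append(key)
        for t, v in r.scores.items():
            acc[key][t].append(v)
    return [
        SynergyRecord(
            drug_a=key[0], drug_b=key[1], cell_line=key[2],
            scores={t: float(np.mean(vs)) for t, vs in acc[key].items()},
        )
        for key in order
    ]


# ---------------------------------------------------------------------------
# drug annotation tables

def read_drug_table(path: str | Path, sep: str | None = None) -> dict[str, str]:
    """Read ``drug_id, smiles`` rows; returns drug_id → SMILES."""
    df = _read_table(path, sep, ["drug_id", "smiles"])
    out: dict[str, str] = {}
    for idx, row in df.iterrows():
        did = str(row["drug_id"])
        if did in out:
            raise ValidationError(f"{path} row {idx}: duplicate drug_id {did!r}")
        out[did] = str(row["smiles"]) if pd.notna(row["smiles"]) else ""
    return out


def read_target_map(path: str | Path, sep: str | None = None) -> dict[str, set[str]]:
    """Read ``drug_id, protein_id`` rows; returns drug_id → set of protein ids."""
    df = _read_table(path, sep, ["drug_id", "protein_id"])
    out: dict[str, set[str]] = defaultdict(set)
    for _, row in df.iterrows():
        out[str(row["drug_id"])].add(str(row["protein_id"]))
    return dict(out)


def read_pathway_map(
    path: str | Path, sep: str | None = None
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Read a drug→pathway map; returns (drug→pathway ids, pathway→gene ids).

    Accepts either ``drug_id, pathway_id`` (the second returned dict is then
    empty and membership comes from :func:`read_pathway_genes`) or the
    combined ``drug_id, pathway_id, gene_id`` shape.
    """
    df = _read_table(path, sep, ["drug_id", "pathway_id"])
    drug2pw: dict[str, set[str]] = defaultdict(set)
    pw2genes: dict[str, set[str]] = defaultdict(set)
    has_genes = "gene_id" in df.columns
    for _, row in df.iterrows():
        pw = str(row["pathway_id"])
        drug2pw[str(row["drug_id"])].add(pw)
        if has_genes and pd.notna(row["gene_id"]):
            pw2genes[pw].add(str(row["gene_id"]))
    return dict(drug2pw), dict(pw2genes)


def read_pathway_genes(path: str | Path, sep: str | None = None) -> dict[str, set[str]]:
    """Read ``pathway_id, gene_id`` membership rows."""
    df = _read_table(path, sep, ["pathway_id", "gene_id"])
    out: dict[str, set[str]] = defaultdict(set)
    for _, row in df.iterrows():
        out[str(row["pathway_id"])].add(str(row["gene_id"]))
    return dict(out)


def read_gene_map(path: str | Path, sep: str | None = None) -> dict[str, str]:
    """Read ``protein_id, gene_id`` rows (STRING protein→gene mapping)."""
    df = _read_table(path, sep, ["protein_id", "gene_id"])
    return {str(r["protein_id"]): str(r["gene_id"]) for _, r in df.iterrows()}


# ---------------------------------------------------------------------------
# PPI network

def read_ppi_edges(
    path: str | Path,
    gene_map: dict[str, str],
    score_threshold: float = 700.0,
    score_scale: float = 1000.0,
    sep: str | None = None,
    identity_fallback: bool = False,
) -> PPIMatrix:
    """Build a symmetric gene–gene association matrix from a STRING-style
    edge list ``protein1, protein2, combined_score``.

    ``score_threshold`` is on the same scale as the file (STRING's 0–999
    convention by default: threshold 700 means dropping edges whose combined
    score is below 0.7).  Stored weights are divided by ``score_scale`` so
    downstream fusion always sees the 0–1 scale; pass ``score_scale=1.0``
    for files already on the unit scale.  Edges whose proteins lack a gene
    mapping are dropped with a logged count.
    """
    df = _read_table(path, sep, ["protein1", "protein2", "combined_score"])
    weights: dict[tuple[str, str], float] = {}
    n_below, n_unmapped = 0, 0
    for idx, row in df.iterrows():
        try:
            score = float(row["combined_score"])
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path} row {idx}: unparseable combined_score {row['combined_score']!r}")
        if score < score_threshold:
            n_below += 1
            continue
        p1, p2 = str(row["protein1"]), str(row["protein2"])
        if p1 not in gene_map or p2 not in gene_map:
            n_unmapped += 1
            continue
        g1, g2 = gene_map[p1], gene_map[p2]
        if g1 == g2:
            continue
        key = (g1, g2) if g1 <= g2 else (g2, g1)
        weights[key] = max(weights.get(key, 0.0), score / score_scale)
    logger.info("%s: %d edges below threshold %.3g, %d with unmapped proteins",
                path, n_below, n_unmapped, score_threshold)
    if not weights:
        logger.warning("%s: no PPI edges survive the threshold — degenerate network",
                       path)
        if not identity_fallback:
            return PPIMatrix(gene_ids=[], weights=np.zeros((0, 0)))
        genes = sorted(set(gene_map.values()))
        return PPIMatrix(gene_ids=genes, weights=np.eye(len(genes)))
    genes = sorted({g for key in weights for g in key})
    index = {g: i for i, g in enumerate(genes)}
    mat = np.zeros((len(genes), len(genes)))
    for (g1, g2), w in weights.items():
        mat[index[g1], index[g2]] = w
        mat[index[g2], index[g1]] = w
    return PPIMatrix(gene_ids=genes, weights=mat)


# ---------------------------------------------------------------------------
# embedding tables

def read_embedding_table(path: str | Path, sep: str | None = None) -> EmbeddingTable:
    """Read an ``id, v0, v1, …`` table; all vectors must share one dimension."""
    sep = _detect_sep(path, sep)
    vectors: dict[str, np.ndarray] = {}
    dim = None
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise EmptyInputError(f"{path}: empty file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(sep)
            key = parts[0]
            if key in vectors:
                raise ValidationError(f"{path} line {lineno}: duplicate key {key!r}")
            try:
                vec = np.array([float(x) for x in parts[1:]])
            except ValueError as err:
                raise SchemaError(f"{path} line {lineno}: {err}") from err
            if dim is None:
                dim = vec.size
            elif vec.size != dim:
                raise SchemaError(
                    f"{path} line {lineno}: vector for {key!r} has {vec.size} "
                    f"components, expected {dim}")
            vectors[key] = vec
    if not vectors:
        raise EmptyInputError(f"{path}: no embedding rows")
    return EmbeddingTable(vectors)


def write_embedding_table(table: EmbeddingTable, path: str | Path,
                          sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(sep.join(["id", *[f"v{i}" for i in range(table.dim)]]) + "\n")
        for key, vec in table.items():
            fh.write(sep.join([key, *(_FLOAT_FMT % x for x in vec)]) + "\n")


# ---------------------------------------------------------------------------
# omics matrices

def read_omics_matrix(
    path: str | Path,
    kind: str,
    sep: str | None = None,
    transpose: bool = False,
) -> OmicsMatrix:
    """Read a cell × gene matrix with id headers.

    ``kind`` is ``"expression"`` (continuous, kept raw — normalisation is a
    separate step) or ``"mutation"`` (validated binary).  Files stored
    gene × cell are read with ``transpose=True``.
    """
    sep = _detect_sep(path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    if transpose:
        df = df.T
    return OmicsMatrix(
        cell_ids=[str(c) for c in df.index],
        gene_ids=[str(g) for g in df.columns],
        values=df.to_numpy(dtype=float),
        kind=kind,
    )


def write_omics_matrix(matrix: OmicsMatrix, path: str | Path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(sep.join(["cell_id", *matrix.gene_ids]) + "\n")
        for cid, row in zip(matrix.cell_ids, matrix.values):
            fh.write(sep.join([cid, *(_FLOAT_FMT % x for x in row)]) + "\n")
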