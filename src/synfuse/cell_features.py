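"""Cell-line representation: omics × PPI fusion and autoencoder compression.

A cell line is described by a gene-expression profile (z-scored per gene)
and a binary mutation profile.  Each profile is re-weighted through the
protein-association network by a matrix product with the symmetric PPI
weight matrix — every gene's value becomes a network-neighbourhood-weighted
combination — and the two fused blocks are concatenated.  An unsupervised
autoencoder then compresses each cell line's fused profile to a dense
bottleneck vector (768-d at benchmark scale) which is frozen and reused by
the synergy model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, Dense, ReLU, Sequential
from .records import OmicsMatrix, PPIMatrix, SchemaError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class FusedCellMatrix:
    """N_cell × (M_mut + M_e) fused feature matrix, rows aligned to cell_ids."""

    cell_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.cell_ids):
            raise SchemaError("row count does not match cell_ids")
        if not np.isfinite(self.values).all():
            raise ValidationError("non-finite entries in fused cell matrix")


def normalize_expression(matrix: OmicsMatrix) -> OmicsMatrix:
    """Z-score each gene (column) across cell lines.

    Zero-variance genes map to all-zero columns.  Requires at least two
    cell lines (a single row has no defined variance).
    """
    if matrix.n_cells < 2:
        raise ValidationError("expression normalisation needs >= 2 cell lines")
    x = matrix.values
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    z[:, sd == 0] = 0.0
    return OmicsMatrix(cell_ids=list(matrix.cell_ids), gene_ids=list(matrix.gene_ids),
                       values=z, kind=matrix.kind)


def fuse_with_ppi(omics: OmicsMatrix, ppi: PPIMatrix) -> np.ndarray:
    """Re-weight each cell-line profile through the PPI network.

    The (N_cell × M) omics matrix is multiplied by the (M × M) symmetric
    association matrix aligned to the same gene order, spreading each
    gene's signal over its network neighbourhood.
    """
    aligned = ppi if ppi.gene_ids == omics.gene_ids else ppi.align(omics.gene_ids)
    if aligned.gene_ids != omics.gene_ids:
        raise SchemaError("gene order mismatch between omics and PPI after alignment")
    return omics.values @ aligned.weights


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    z[:, sd == 0] = 0.0
    return z


def build_fused_matrix(
    mut: OmicsMatrix,
    expr: OmicsMatrix,
    ppi: PPIMatrix | None,
    use_ppi: bool = True,
) -> FusedCellMatrix:
    """Concatenate the PPI-fused mutation and expression blocks.

    With ``use_ppi=False`` (the network-free ablation) the PPI stage is
    skipped and the concatenated [mutation | expression] matrix is
    column-standardised instead.
    """
    if mut.cell_ids != expr.cell_ids:
        raise SchemaError("mutation and expression matrices list different cell "
                          "lines or orders")
    if use_ppi:
        if ppi is None:
            raise ValidationError("use_ppi=True but no PPI matrix supplied")
        fused = np.hstack([fuse_with_ppi(mut, ppi), fuse_with_ppi(expr, ppi)])
    else:
        fused = _standardize_columns(np.hstack([mut.values, expr.values]))
    return FusedCellMatrix(cell_ids=list(mut.cell_ids), values=fused)


@dataclass
class AutoencoderSpec:
    """Architecture and training schedule of the compression autoencoder.

    ``hidden`` lists the encoder's hidden widths ending at the bottleneck;
    the decoder mirrors it.  Defaults follow the benchmark-scale setting
    (bottleneck 768); fixture-scale runs pass smaller widths.
    """

    hidden: tuple[int, ...] = (4096, 2048, 768)
    activation: str = "relu"  # "relu" | "linear"
    epochs: int = 300
    lr: float = 1e-3
    batch_size: int | None = None  # None = full batch
    seed: int = 0

    @property
    def bottleneck(self) -> int:
        return self.hidden[-1]


class AutoencoderDivergence(RuntimeError):
    pass


class Autoencoder:
    """Symmetric encoder/decoder trained to reconstruct the fused matrix.

    Training minimises the mean squared reconstruction error with Adam and
    is deterministic given ``spec.seed``.  The encoder half is what the
    pipeline keeps: :meth:`encode` maps cell profiles to bottleneck vectors.
    """

    def __init__(self, input_dim: int, spec: AutoencoderSpec):
        if spec.bottleneck >= input_dim:
            logger.warning("bottleneck %d >= input dim %d — no compression",
                           spec.bottleneck, input_dim)
        self.spec = spec
        self.input_dim = input_dim
        rng = np.random.default_rng(spec.seed)
        act = ReLU if spec.activation == "relu" else None
        enc_layers: list = []
        widths = [input_dim, *spec.hidden]
        for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            enc_layers.append(Dense(a, b, rng))
            if act is not None and i < len(widths) - 2:
                enc_layers.append(act())
        dec_layers: list = []
        widths_dec = [*reversed(spec.hidden), input_dim]
        for i, (a, b) in enumerate(zip(widths_dec[:-1], widths_dec[1:])):
            dec_layers.append(Dense(a, b, rng))
            if act is not None and i < len(widths_dec) - 2:
                dec_layers.append(act())
        self.encoder = Sequential(enc_layers)
        self.decoder = Sequential(dec_layers)
        self._rng = rng

    def fit(self, x: np.ndarray) -> list[float]:
        """Train on the fused matrix; returns the per-epoch loss history."""
        x = np.asarray(x, dtype=float)
        spec = self.spec
        params = self.encoder.params() + self.decoder.params()
        opt = Adam(params, lr=spec.lr)
        n = x.shape[0]
        history: list[float] = []
        for epoch in range(spec.epochs):
            if spec.batch_size is None or spec.batch_size >= n:
                batches = [np.arange(n)]
            else:
                perm = self._rng.permutation(n)
                batches = np.array_split(perm, int(np.ceil(n / spec.batch_size)))
            total, count = 0.0, 0
            for idx in batches:
                xb = x[idx]
                recon = self.decoder.forward(self.encoder.forward(xb, True), True)
                diff = recon - xb
                loss = float((diff ** 2).mean())
                if not np.isfinite(loss):
                    raise AutoencoderDivergence(
                        f"non-finite reconstruction loss at epoch {epoch} "
                        f"(lr={spec.lr})")
                opt.zero_grad()
                self.encoder.backward(self.decoder.backward(2 * diff / diff.size))
                opt.step()
                total += loss * len(idx)
                count += len(idx)
            history.append(total / count)
        return history

    def encode(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.input_dim:
            raise SchemaError(
                f"input has {x.shape[-1]} columns, encoder expects {self.input_dim}")
        return self.encoder.forward(x, training=False)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self.decoder.forward(self.encode(x), training=False)


@dataclass
class CellLineEmbedding:
    cell_id: str
    vector: np.ndarray = field(repr=False)


def train_autoencoder(fused: FusedCellMatrix,
                      spec: AutoencoderSpec) -> tuple[Autoencoder, list[float]]:
    """Fit the compression autoencoder on all cell lines; returns it with
    the training-loss history."""
    ae = Autoencoder(fused.values.shape[1], spec)
    history = ae.fit(fused.values)
    return ae, history


def embed_cell_lines(fused: FusedCellMatrix,
                     encoder: Autoencoder) -> list[CellLineEmbedding]:
    """One bottleneck vector per cell line, order-aligned to ``cell_ids``."""
    z = encoder.encode(fused.values)
    return [CellLineEmbedding(cid, z[i]) for i, cid in enumerate(fused.cell_ids)]
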