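"""Synergy prediction model: attention fusion encoder plus FCNN head.

The 8-token drug-combination feature is passed through a stack of
multi-head self-attention blocks (residual + layer norm, no positional
encoding), flattened to ``f_d ∈ R^{8d}``, concatenated with the cell-line
bottleneck vector ``f_c``, and mapped to a synergy score by a three-layer
fully connected network (ReLU, batch norm, dropout between layers; linear
output for regression, sigmoid for classification).

Training follows the benchmark regimen: Adam with mini-batches, MSE loss
for regression / binary cross-entropy for classification, and early
stopping once the validation loss has not improved for ``patience``
epochs, restoring the best-validation parameters.  Defaults mirror the
benchmark setting (h=8, d=1024, batch 512, dropout 0.5, patience 20);
fixture-scale runs shrink the widths through :class:`ModelConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .drug_features import CombinationFeature, DrugFeaturizer
from .nn import (
    Adam,
    BatchNorm1d,
    Dense,
    Dropout,
    ReLU,
    Sequential,
    TransformerBlock,
)
from .records import SchemaError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Hyperparameters of the synergy model and its training regimen."""

    h: int = 8
    d: int = 1024
    n_layers: int = 2
    cell_dim: int = 768
    head_widths: tuple[int, ...] = (4096, 1024)
    dropout: float = 0.5
    batch_size: int = 512
    lr: float = 1e-3
    patience: int = 20
    max_epochs: int = 500
    task: str = "regression"  # "regression" | "classification"
    seed: int = 0
    use_attention: bool = True
    use_residual: bool = True
    symmetrize: bool = True
    augment_swap: bool = False  # also present each training pair in swapped order
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.task not in ("regression", "classification"):
            raise ValidationError(f"unknown task {self.task!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError("dropout must be in [0, 1)")
        if self.use_attention and self.d % self.h != 0:
            raise ValidationError(f"h={self.h} must divide d={self.d}")
        for name in ("h", "d", "n_layers", "cell_dim", "batch_size",
                     "patience", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def loss(y: np.ndarray, y_hat: np.ndarray, task: str = "regression") -> float:
    """Training objective on final predictions.

    Regression: mean squared error.  Classification: mean binary
    cross-entropy of predicted probabilities (clipped away from 0/1).
    """
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size == 0:
        raise ValidationError("empty target vector")
    if y.shape != y_hat.shape:
        raise SchemaError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if task == "regression":
        return float(np.mean((y - y_hat) ** 2))
    p = np.clip(y_hat, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def encode_combination(tokens: np.ndarray,
                       blocks: list[TransformerBlock]) -> np.ndarray:
    """Apply the attention blocks in order and flatten row-major to f_d."""
    x = np.asarray(tokens, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    for blk in blocks:
        x = blk.forward(x, training=False)
    flat = x.reshape(x.shape[0], -1)
    return flat[0] if single else flat


def mask_features(
    featurizer: DrugFeaturizer,
    drug_a: str,
    drug_b: str,
    drop_targets: frozenset[str] | set[str] = frozenset(),
    drop_pathways: frozenset[str] | set[str] = frozenset(),
) -> CombinationFeature:
    """Inference-time removal of named target/pathway features.

    The target/pathway tokens are recomputed as the mean over the remaining
    annotations (zero vector if none remain); fingerprint and similarity
    tokens are untouched.  Ids not annotated to either drug are warned
    about and ignored.
    """
    return featurizer.combination(
        drug_a, drug_b,
        drop_targets=frozenset(drop_targets),
        drop_pathways=frozenset(drop_pathways),
    )


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


class SynergyModel:
    """Attention fusion encoder + three-layer prediction head."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.blocks: list[TransformerBlock] = []
        if config.use_attention:
            self.blocks = [
                TransformerBlock(config.d, config.h, rng,
                                 residual=config.use_residual)
                for _ in range(config.n_layers)
            ]
        head_in = 8 * config.d + config.cell_dim
        layers: list = []
        widths = [head_in, *config.head_widths]
        for a, b in zip(widths[:-1], widths[1:]):
            layers += [Dense(a, b, rng), BatchNorm1d(b), ReLU(),
                       Dropout(config.dropout, rng)]
        layers.append(Dense(widths[-1], 1, rng))
        self.head = Sequential(layers)
        self._rng = rng

    # -- parameter plumbing ------------------------------------------------
    def _all_layers(self) -> list:
        return [*self.blocks, self.head]

    def parameters(self):
        return [p for l in self._all_layers() for p in l.params()]

    def _bn_layers(self) -> list[BatchNorm1d]:
        return [l for l in self.head.layers if isinstance(l, BatchNorm1d)]

    def snapshot(self) -> dict:
        return {
            "params": [p.value.copy() for p in self.parameters()],
            "bn": [(bn.running_mean.copy(), bn.running_var.copy())
                   for bn in self._bn_layers()],
        }

    def restore(self, snap: dict) -> None:
        for p, v in zip(self.parameters(), snap["params"]):
            p.value[...] = v
        for bn, (mu, var) in zip(self._bn_layers(), snap["bn"]):
            bn.running_mean[...] = mu
            bn.running_var[...] = var

    # -- checkpointing -----------------------------------------------------
    def save(self, path: str | Path, extra: dict | None = None) -> None:
        """Write all parameters plus the config (and any extra metadata such
        as the reference-drug order and feature-build parameters) to one
        ``.npz`` file, sufficient to reproduce predictions."""
        snap = self.snapshot()
        arrays = {f"param_{i}": v for i, v in enumerate(snap["params"])}
        for i, (mu, var) in enumerate(snap["bn"]):
            arrays[f"bn_mean_{i}"] = mu
            arrays[f"bn_var_{i}"] = var
        meta = {"config": dataclasses.asdict(self.config), "extra": extra or {}}
        arrays["meta"] = np.frombuffer(
            json.dumps(meta, default=str).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> tuple["SynergyModel", dict]:
        """Rebuild a model from a checkpoint; returns (model, extra metadata)."""
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            cfg = meta["config"]
            cfg["head_widths"] = tuple(cfg["head_widths"])
            model = cls(ModelConfig(**cfg))
            n_params = sum(1 for k in data.files if k.startswith("param_"))
            n_bn = sum(1 for k in data.files if k.startswith("bn_mean_"))
            snap = {
                "params": [data[f"param_{i}"] for i in range(n_params)],
                "bn": [(data[f"bn_mean_{i}"], data[f"bn_var_{i}"])
                       for i in range(n_bn)],
            }
        model.restore(snap)
        return model, meta["extra"]

    # -- forward / loss ----------------------------------------------------
    def forward(self, tokens: np.ndarray, cells: np.ndarray,
                training: bool = False) -> np.ndarray:
        """Raw model output (scores for regression, logits for classification)."""
        x = np.asarray(tokens, dtype=float)
        cells = np.asarray(cells, dtype=float)
        if x.shape[1] != 8 or x.shape[2] != self.config.d:
            raise SchemaError(f"token stack shape {x.shape} != (n, 8, {self.config.d})")
        if cells.shape[1] != self.config.cell_dim:
            raise SchemaError(
                f"cell embedding width {cells.shape[1]} != {self.config.cell_dim}")
        for blk in self.blocks:
            x = blk.forward(x, training)
        self._fd = x.reshape(x.shape[0], -1)
        z = np.hstack([self._fd, cells])
        return self.head.forward(z, training).ravel()

    def _backward(self, dout: np.ndarray) -> None:
        dz = self.head.backward(dout[:, None])
        dtok = dz[:, : 8 * self.config.d].reshape(-1, 8, self.config.d)
        for blk in reversed(self.blocks):
            dtok = blk.backward(dtok)

    def loss_and_grads(self, tokens, cells, y, training: bool = True) -> float:
        """One forward/backward pass; leaves gradients in the parameters."""
        y = np.asarray(y, dtype=float).ravel()
        out = self.forward(tokens, cells, training)
        n = y.size
        if self.config.task == "regression":
            diff = out - y
            value = float(np.mean(diff ** 2))
            dout = 2.0 * diff / n
        else:
            # numerically stable BCE-with-logits
            z = out
            value = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
            dout = (1.0 / (1.0 + np.exp(-z)) - y) / n
        self._backward(dout)
        return value

    # -- training ----------------------------------------------------------
    def fit(self, tokens: np.ndarray, cells: np.ndarray, y: np.ndarray,
            pair_keys: list[tuple[str, str]]) -> TrainingHistory:
        """Train with Adam mini-batches and patience-based early stopping.

        The validation split is drawn by unordered-pair key (so a drug pair
        never straddles the train/validation boundary), sized by
        ``config.val_fraction``.
        """
        cfg = self.config
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        if not (len(pair_keys) == n and tokens.shape[0] == n and cells.shape[0] == n):
            raise SchemaError("tokens, cells, y and pair_keys must align")
        uniq = sorted(set(pair_keys))
        if len(uniq) < 2:
            raise ValidationError("need >= 2 distinct pairs to form a validation split")
        split_rng = np.random.default_rng(cfg.seed)
        perm = split_rng.permutation(len(uniq))
        n_val = max(1, int(round(cfg.val_fraction * len(uniq))))
        val_pairs = {uniq[i] for i in perm[:n_val]}
        val_mask = np.array([pk in val_pairs for pk in pair_keys])
        if val_mask.all() or not val_mask.any():
            raise ValidationError("validation split is degenerate")
        tr_idx = np.flatnonzero(~val_mask)
        va_idx = np.flatnonzero(val_mask)

        opt = Adam(self.parameters(), lr=cfg.lr)
        history = TrainingHistory()
        best_val = np.inf
        best_snap = self.snapshot()
        epochs_since_best = 0
        batch_rng = np.random.default_rng(cfg.seed + 1)
        for epoch in range(cfg.max_epochs):
            order = batch_rng.permutation(tr_idx.size)
            total = 0.0
            for start in range(0, tr_idx.size, cfg.batch_size):
                idx = tr_idx[order[start:start + cfg.batch_size]]
                opt.zero_grad()
                batch_loss = self.loss_and_grads(
                    tokens[idx], cells[idx], y[idx], training=True)
                opt.step()
                total += batch_loss * idx.size
            history.train_loss.append(total / tr_idx.size)
            val_out = self.forward(tokens[va_idx], cells[va_idx], training=False)
            if cfg.task == "classification":
                val_out = 1.0 / (1.0 + np.exp(-val_out))
            val_loss = loss(y[va_idx], val_out, cfg.task)
            history.val_loss.append(val_loss)
            if val_loss < best_val:
                best_val = val_loss
                best_snap = self.snapshot()
                history.best_epoch = epoch
                epochs_since_best = 0
            else:
                epochs_since_best += 1
                if epochs_since_best >= cfg.patience:
                    logger.info("early stop at epoch %d (best %d, val %.5g)",
                                epoch, history.best_epoch, best_val)
                    break
        self.restore(best_snap)
        return history

    # -- inference ---------------------------------------------------------
    def predict(self, tokens: np.ndarray, cells: np.ndarray) -> np.ndarray:
        """Evaluation-mode predictions (probabilities for classification)."""
        out = self.forward(tokens, cells, training=False)
        if self.config.task == "classification":
            return 1.0 / (1.0 + np.exp(-out))
        return out

    def predict_symmetric(self, tokens_ab: np.ndarray, tokens_ba: np.ndarray,
                          cells: np.ndarray) -> np.ndarray:
        """Order-invariant prediction: the mean over both token orders."""
        return 0.5 * (self.predict(tokens_ab, cells) + self.predict(tokens_ba, cells))

    def predict_pairs(self, featurizer: DrugFeaturizer,
                      pairs: list[tuple[str, str]],
                      cells: np.ndarray) -> np.ndarray:
        """Predict for drug-id pairs, symmetrising over pair order if configured."""
        tokens_ab = featurizer.token_stack(pairs)
        if not self.config.symmetrize:
            return self.predict(tokens_ab, cells)
        tokens_ba = featurizer.token_stack([(b, a) for a, b in pairs])
        return self.predict_symmetric(tokens_ab, tokens_ba, cells)


def ablation_config(base: ModelConfig, variant: str) -> tuple[ModelConfig, dict]:
    """Map a named ablation variant to (model config, featurizer flags).

    ``no_target_pathway`` drops both annotation families, ``no_target`` /
    ``no_pathway`` drop one, ``no_attention`` replaces the encoder with the
    raw flattened feature, ``no_ppi`` is handled at the cell-feature stage.
    """
    flags = {"use_targets": True, "use_pathways": True, "use_fingerprint": True}
    cfg = base
    if variant == "full":
        pass
    elif variant == "no_target_pathway":
        flags["use_targets"] = flags["use_pathways"] = False
    elif variant == "no_target":
        flags["use_targets"] = False
    elif variant == "no_pathway":
        flags["use_pathways"] = False
    elif variant == "no_attention":
        cfg = replace(base, use_attention=False)
    elif variant == "no_ppi":
        pass  # acted on in build_fused_matrix(use_ppi=False)
    else:
        raise ValidationError(f"unknown ablation variant {variant!r}")
    return cfg, flags
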