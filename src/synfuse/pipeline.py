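"""End-to-end orchestration: features → cell embeddings → training → metrics.

Two entry points:

* :func:`run_experiment` — in-memory cross-validated evaluation of a
  :class:`~synfuse.simulate.Fixture` or pre-loaded inputs; what the test
  suite, the examples and the acceptance script drive.
* :func:`run_pipeline` — file-based run from a :class:`RunConfig`
  (YAML-loadable), writing per-stage artifacts, a manifest with the config
  hash and seed, predictions and a metric report.  Re-running with an
  identical config and seed reproduces the report byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import io as sio
from .cell_features import (
    AutoencoderSpec,
    build_fused_matrix,
    embed_cell_lines,
    normalize_expression,
    train_autoencoder,
)
from .drug_features import DrugFeaturizer
from .metrics import (
    classification_metrics,
    per_cell_line_report,
    regression_metrics,
    summarize_folds,
    threshold_labels,
)
from .model import ModelConfig, SynergyModel, ablation_config
from .records import DrugRecord, SynergyRecord, ValidationError
from .simulate import Fixture, FixtureSpec, generate_fixture
from .splits import FoldAssignment, make_leave_one_out_folds, make_pair_disjoint_folds

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative description of one full run."""

    seed: int
    outdir: str
    score_type: str = "loewe"
    task: str = "regression"
    label_threshold: float = 30.0
    split_strategy: str = "pair_disjoint_kfold"
    k: int = 5
    variant: str = "full"  # full | no_target | no_pathway | no_target_pathway
    #                        | no_ppi | no_attention
    fixture: FixtureSpec | None = None
    paths: dict = field(default_factory=dict)
    model: ModelConfig = field(default_factory=ModelConfig)
    autoencoder: AutoencoderSpec = field(default_factory=AutoencoderSpec)
    ppi_score_threshold: float = 700.0
    ppi_score_scale: float = 1000.0
    average_replicates: bool = True

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "fixture" in raw and raw["fixture"] is not None:
            raw["fixture"] = FixtureSpec(**raw["fixture"])
        if "model" in raw:
            mc = dict(raw["model"])
            if "head_widths" in mc:
                mc["head_widths"] = tuple(mc["head_widths"])
            raw["model"] = ModelConfig(**mc)
        if "autoencoder" in raw:
            ac = dict(raw["autoencoder"])
            if "hidden" in ac:
                ac["hidden"] = tuple(ac["hidden"])
            raw["autoencoder"] = AutoencoderSpec(**ac)
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage builders

def build_featurizer(
    drugs: dict[str, DrugRecord],
    embeddings,
    pathway_genes,
    fingerprints=None,
    d: int = 1024,
    n_bits: int = 1024,
    flags: dict | None = None,
    reference_order: list[str] | None = None,
) -> DrugFeaturizer:
    flags = flags or {}
    return DrugFeaturizer(
        drugs=drugs, embeddings=embeddings, pathway_genes=pathway_genes,
        fingerprints=fingerprints, n_bits=n_bits, d=d,
        reference_order=reference_order,
        use_fingerprint=flags.get("use_fingerprint", True),
        use_targets=flags.get("use_targets", True),
        use_pathways=flags.get("use_pathways", True),
    )


def build_cell_embeddings(
    expression, mutation, ppi, ae_spec: AutoencoderSpec, use_ppi: bool = True
) -> tuple[dict[str, np.ndarray], list[float]]:
    """Normalise expression, fuse with the PPI network, train the
    autoencoder and return cell_id → bottleneck vector."""
    expr_norm = normalize_expression(expression)
    fused = build_fused_matrix(mutation, expr_norm, ppi, use_ppi=use_ppi)
    encoder, history = train_autoencoder(fused, ae_spec)
    cells = embed_cell_lines(fused, encoder)
    return {e.cell_id: e.vector for e in cells}, history


def make_folds(records: list[SynergyRecord], strategy: str, k: int,
               seed: int) -> FoldAssignment:
    if strategy == "pair_disjoint_kfold":
        return make_pair_disjoint_folds(records, k=k, seed=seed)
    if strategy == "leave_one_drug_out":
        return make_leave_one_out_folds(records, unit="drug")
    if strategy == "leave_one_cell_line_out":
        return make_leave_one_out_folds(records, unit="cell_line")
    raise ValidationError(f"unknown split strategy {strategy!r}")


class _TokenCache:
    """Token stacks per ordered drug pair, built lazily once per pair."""

    def __init__(self, featurizer: DrugFeaturizer):
        self.featurizer = featurizer
        self._cache: dict[tuple[str, str], np.ndarray] = {}

    def get(self, a: str, b: str) -> np.ndarray:
        key = (a, b)
        if key not in self._cache:
            self._cache[key] = self.featurizer.combination(a, b).tokens
        return self._cache[key]

    def stack(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        return np.stack([self.get(a, b) for a, b in pairs])


def cross_validate(
    records: list[SynergyRecord],
    featurizer: DrugFeaturizer,
    cell_vectors: dict[str, np.ndarray],
    model_cfg: ModelConfig,
    folds: FoldAssignment,
    score_type: str = "loewe",
    folds_to_run: list[int] | None = None,
) -> dict:
    """Train one model per fold and evaluate on the held-out fold.

    Training presents each sample in canonical (sorted) pair order;
    test predictions are symmetrised over both orders when configured.
    Returns per-fold metrics, the mean/sd summary, and the pooled
    out-of-fold predictions.
    """
    cache = _TokenCache(featurizer)
    canon = [r.pair for r in records]
    cells = np.stack([cell_vectors[r.cell_line] for r in records])
    if model_cfg.task == "classification":
        y = np.array([float(r.label) for r in records])
    else:
        y = np.array([r.scores[score_type] for r in records])

    per_fold, histories = [], []
    oof_y, oof_pred, oof_idx = [], [], []
    run_folds = folds_to_run if folds_to_run is not None else list(range(folds.n_folds))
    for fold in run_folds:
        tr = folds.train_indices(records, fold)
        te = folds.test_indices(records, fold)
        if tr.size == 0 or te.size == 0:
            logger.warning("fold %d is empty; skipped", fold)
            continue
        model = SynergyModel(replace(model_cfg, seed=model_cfg.seed + fold))
        tr_pairs = [canon[i] for i in tr]
        tr_tokens = cache.stack(tr_pairs)
        tr_cells, tr_y, tr_keys = cells[tr], y[tr], tr_pairs
        if model_cfg.augment_swap:
            tr_tokens = np.concatenate(
                [tr_tokens, cache.stack([(b, a) for a, b in tr_pairs])])
            tr_cells = np.concatenate([tr_cells, tr_cells])
            tr_y = np.concatenate([tr_y, tr_y])
            tr_keys = tr_pairs + tr_pairs
        history = model.fit(tr_tokens, tr_cells, tr_y, tr_keys)
        histories.append(history)
        te_pairs = [canon[i] for i in te]
        if model_cfg.symmetrize:
            pred = model.predict_symmetric(
                cache.stack(te_pairs),
                cache.stack([(b, a) for a, b in te_pairs]),
                cells[te])
        else:
            pred = model.predict(cache.stack(te_pairs), cells[te])
        if model_cfg.task == "classification":
            fold_metrics = classification_metrics(y[te], pred).as_dict()
        else:
            fold_metrics = regression_metrics(y[te], pred).as_dict()
        fold_metrics["fold"] = fold
        per_fold.append(fold_metrics)
        oof_y.append(y[te])
        oof_pred.append(pred)
        oof_idx.append(te)

    oof_y = np.concatenate(oof_y)
    oof_pred = np.concatenate(oof_pred)
    oof_idx = np.concatenate(oof_idx)
    if model_cfg.task == "classification":
        pooled = classification_metrics(oof_y, oof_pred).as_dict()
    else:
        pooled = regression_metrics(oof_y, oof_pred).as_dict()
    summary = summarize_folds([{k: v for k, v in f.items() if k != "fold"}
                               for f in per_fold])
    return {
        "per_fold": per_fold,
        "summary": summary,
        "pooled": pooled,
        "oof_y": oof_y,
        "oof_pred": oof_pred,
        "oof_indices": oof_idx,
        "histories": histories,
    }


def run_experiment(
    fixture: Fixture,
    model_cfg: ModelConfig,
    ae_spec: AutoencoderSpec,
    variant: str = "full",
    split_strategy: str = "pair_disjoint_kfold",
    k: int = 5,
    split_seed: int | None = None,
    score_type: str = "loewe",
    task: str = "regression",
    label_threshold: float = 0.0,
    folds_to_run: list[int] | None = None,
) -> dict:
    """Cross-validated evaluation of one model variant on a fixture."""
    model_cfg, flags = ablation_config(replace(model_cfg, task=task), variant)
    featurizer = build_featurizer(
        fixture.drugs.drugs, fixture.drugs.embeddings, fixture.drugs.pathway_genes,
        fingerprints=fixture.drugs.fingerprints,
        d=model_cfg.d, n_bits=fixture.spec.n_bits, flags=flags)
    cell_vectors, ae_history = build_cell_embeddings(
        fixture.cells.expression, fixture.cells.mutation, fixture.cells.ppi,
        ae_spec, use_ppi=(variant != "no_ppi"))
    records = fixture.records
    if task == "classification":
        records = threshold_labels(records, score_type, label_threshold)
    folds = make_folds(records, split_strategy, k,
                       split_seed if split_seed is not None else model_cfg.seed)
    result = cross_validate(records, featurizer, cell_vectors, model_cfg, folds,
                            score_type=score_type, folds_to_run=folds_to_run)
    result["ae_history"] = ae_history
    result["records"] = records
    result["variant"] = variant
    return result


def fit_full_model(
    records: list[SynergyRecord],
    featurizer: DrugFeaturizer,
    cell_vectors: dict[str, np.ndarray],
    model_cfg: ModelConfig,
    score_type: str = "loewe",
):
    """Train one model on all records (no held-out fold); returns
    (model, history).  Used by the CLI ``train`` subcommand."""
    cache = _TokenCache(featurizer)
    canon = [r.pair for r in records]
    cells = np.stack([cell_vectors[r.cell_line] for r in records])
    if model_cfg.task == "classification":
        y = np.array([float(r.label) for r in records])
    else:
        y = np.array([r.scores[score_type] for r in records])
    tokens = cache.stack(canon)
    keys = list(canon)
    if model_cfg.augment_swap:
        tokens = np.concatenate([tokens, cache.stack([(b, a) for a, b in canon])])
        cells = np.concatenate([cells, cells])
        y = np.concatenate([y, y])
        keys = keys * 2
    model = SynergyModel(model_cfg)
    history = model.fit(tokens, cells, y, keys)
    return model, history


# ---------------------------------------------------------------------------
# file-based run

def _json_ready(obj):
    if isinstance(obj, dict):
        return {k: _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(_json_ready(payload), fh, sort_keys=True, indent=2)
        fh.write("\n")


def load_inputs(config: RunConfig) -> Fixture:
    """Load all inputs named in ``config.paths`` into a fixture-shaped bundle."""
    from .simulate import FixtureCells, FixtureDrugs

    p = config.paths
    records = sio.read_synergy_table(p["synergy"], score_column=config.score_type)
    if config.average_replicates:
        records = sio.average_replicate_triplets(records)
    smiles = sio.read_drug_table(p["drugs"]) if "drugs" in p else {}
    targets = sio.read_target_map(p["targets"]) if "targets" in p else {}
    if "pathways" in p:
        drug2pw, pw_genes = sio.read_pathway_map(p["pathways"])
        if "pathway_genes" in p:
            pw_genes = sio.read_pathway_genes(p["pathway_genes"])
    else:
        drug2pw, pw_genes = {}, {}
    drug_ids = sorted({d for r in records for d in (r.drug_a, r.drug_b)} | set(smiles))
    drugs = {
        did: DrugRecord(
            drug_id=did, smiles=smiles.get(did) or None,
            target_ids=frozenset(targets.get(did, ())),
            pathway_ids=frozenset(drug2pw.get(did, ())))
        for did in drug_ids
    }
    fingerprints = None
    if "fingerprints" in p:
        table = sio.read_embedding_table(p["fingerprints"])
        fingerprints = {k: np.asarray(v) for k, v in table.items()}
    embeddings = sio.read_embedding_table(p["embeddings"])
    expression = sio.read_omics_matrix(p["expression"], kind="expression")
    mutation = sio.read_omics_matrix(p["mutation"], kind="mutation")
    gene_map = sio.read_gene_map(p["gene_map"])
    ppi = sio.read_ppi_edges(p["ppi_edges"], gene_map,
                             score_threshold=config.ppi_score_threshold,
                             score_scale=config.ppi_score_scale)
    n_bits = (len(next(iter(fingerprints.values()))) if fingerprints
              else 1024)
    spec = FixtureSpec(seed=config.seed, n_drugs=len(drugs),
                       n_cells=expression.n_cells,
                       embed_dim=embeddings.dim, n_bits=n_bits)
    dr = FixtureDrugs(drugs=drugs, fingerprints=fingerprints or {},
                      embeddings=embeddings, pathway_genes=pw_genes)
    cl = FixtureCells(expression=expression, mutation=mutation, ppi=ppi,
                      ppi_edges=[], gene_map=gene_map,
                      cell_factors=np.zeros((expression.n_cells, 1)))
    import pandas as pd
    return Fixture(spec=spec, drugs=dr, cells=cl, records=records,
                   truth=pd.DataFrame(), beta=np.zeros(1))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and write all artifacts to ``config.outdir``.

    Stages: (optional) fixture simulation → drug features → cell-line
    embeddings → per-fold training → predictions → metric report.  The
    manifest records the config hash, seed and variant so any artifact can
    be traced to the run that produced it.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed,
             "variant": config.variant}

    if config.fixture is not None:
        fixture = generate_fixture(config.fixture)
        fixture.write(outdir / "fixtures")
    else:
        fixture = load_inputs(config)

    result = run_experiment(
        fixture,
        model_cfg=replace(config.model, seed=config.seed, task=config.task),
        ae_spec=replace(config.autoencoder, seed=config.seed),
        variant=config.variant,
        split_strategy=config.split_strategy,
        k=config.k,
        split_seed=config.seed,
        score_type=config.score_type,
        task=config.task,
        label_threshold=config.label_threshold,
    )

    records = result["records"]
    idx = result["oof_indices"]
    with open(outdir / "predictions.tsv", "w") as fh:
        fh.write("drug_a\tdrug_b\tcell_line\ty_true\ty_hat\n")
        for j, i in enumerate(idx):
            r = records[i]
            fh.write(f"{r.drug_a}\t{r.drug_b}\t{r.cell_line}\t"
                     f"{result['oof_y'][j]:.17g}\t{result['oof_pred'][j]:.17g}\n")
    report = {
        **stamp,
        "task": config.task,
        "score_type": config.score_type,
        "split": {"strategy": config.split_strategy, "k": config.k},
        "per_fold": result["per_fold"],
        "summary": result["summary"],
        "pooled": result["pooled"],
    }
    if config.task == "regression":
        pcl = per_cell_line_report([records[i] for i in idx], result["oof_pred"],
                                   config.score_type)
        report["per_cell_line_pcc"] = pcl.to_dict(orient="records")
    _write_json(outdir / "report.json", report)
    _write_json(outdir / "manifest.json", {
        **stamp,
        "config": config.to_dict(),
        "n_records": len(records),
        "n_folds_run": len(result["per_fold"]),
        "ae_final_loss": result["ae_history"][-1] if result["ae_history"] else None,
        "epochs_per_fold": [h.n_epochs for h in result["histories"]],
    })
    logger.info("run complete: %s", outdir)
    return outdir
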