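"""Evaluation metrics and reporting.

Regression: MSE, RMSE, Pearson r (PCC), Spearman rho (SCC) and the
concordance index (CI — fraction of comparable sample pairs whose
predicted ordering matches the true ordering; comparable means distinct
true values, tied predictions count one half).  Classification: ROC AUC,
area under the precision–recall curve, accuracy and precision at a 0.5
probability cutoff.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .records import SynergyRecord, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RegressionMetrics:
    mse: float
    rmse: float
    pcc: float | None
    scc: float | None
    ci: float | None
    n: int

    def as_dict(self) -> dict:
        return {"mse": self.mse, "rmse": self.rmse, "pcc": self.pcc,
                "scc": self.scc, "ci": self.ci, "n": self.n}


@dataclass
class ClassificationMetrics:
    auc: float | None
    aupr: float | None
    acc: float
    precision: float | None
    n: int

    def as_dict(self) -> dict:
        return {"auc": self.auc, "aupr": self.aupr, "acc": self.acc,
                "precision": self.precision, "n": self.n}


def regression_metrics(y: np.ndarray, y_hat: np.ndarray) -> RegressionMetrics:
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValidationError(f"length mismatch {y.shape} vs {y_hat.shape}")
    if y.size < 2:
        raise ValidationError("need >= 2 samples for regression metrics")
    mse = float(np.mean((y - y_hat) ** 2))
    if np.ptp(y) == 0:
        logger.warning("constant true values: PCC/SCC/CI undefined")
        pcc = scc = ci = None
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pcc = float(stats.pearsonr(y, y_hat).statistic) if np.ptp(y_hat) > 0 else None
            scc = float(stats.spearmanr(y, y_hat).statistic) if np.ptp(y_hat) > 0 else None
        ci = float(concordance_index(y, y_hat))
    return RegressionMetrics(mse=mse, rmse=float(np.sqrt(mse)), pcc=pcc,
                             scc=scc, ci=ci, n=y.size)


def classification_metrics(labels: np.ndarray, scores: np.ndarray,
                           threshold: float = 0.5) -> ClassificationMetrics:
    labels = np.asarray(labels, dtype=int).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if labels.shape != scores.shape:
        raise ValidationError(f"length mismatch {labels.shape} vs {scores.shape}")
    single_class = labels.min() == labels.max()
    if single_class:
        logger.warning("single-class labels: AUC/AUPR undefined")
        auc = aupr = None
    else:
        auc = float(roc_auc_score(labels, scores))
        aupr = float(average_precision_score(labels, scores))
    pred = (scores > threshold).astype(int)
    acc = float(np.mean(pred == labels))
    n_pos_pred = int(pred.sum())
    precision = float(labels[pred == 1].mean()) if n_pos_pred else None
    return ClassificationMetrics(auc=auc, aupr=aupr, acc=acc,
                                 precision=precision, n=labels.size)


def threshold_labels(records: list[SynergyRecord], score_type: str,
                     threshold: float) -> list[SynergyRecord]:
    """Attach binary labels: 1 iff score strictly exceeds the threshold.

    The benchmark conventions are Loewe > 30 and ZIP > 0 for calling a
    combination synergistic; a score exactly at the threshold is labelled 0.
    Records missing the score type are skipped with a logged count.
    """
    out: list[SynergyRecord] = []
    n_skipped = 0
    for r in records:
        if score_type not in r.scores:
            n_skipped += 1
            continue
        out.append(SynergyRecord(
            drug_a=r.drug_a, drug_b=r.drug_b, cell_line=r.cell_line,
            scores=dict(r.scores),
            label=int(r.scores[score_type] > threshold)))
    if n_skipped:
        logger.warning("threshold_labels: skipped %d record(s) without %r score",
                       n_skipped, score_type)
    return out


def per_cell_line_report(records: list[SynergyRecord], predictions: np.ndarray,
                         score_type: str, min_count: int = 2) -> pd.DataFrame:
    """Pearson correlation between predictions and truth, per cell line.

    Cell lines with fewer than ``min_count`` records are omitted with a
    warning.  Returns a DataFrame [cell_line, n, pcc].
    """
    predictions = np.asarray(predictions, dtype=float).ravel()
    if predictions.size != len(records):
        raise ValidationError("predictions do not align with records")
    df = pd.DataFrame({
        "cell_line": [r.cell_line for r in records],
        "y": [r.scores[score_type] for r in records],
        "y_hat": predictions,
    })
    rows = []
    for cell, grp in df.groupby("cell_line", sort=True):
        if len(grp) < min_count:
            logger.warning("cell line %s has only %d record(s); omitted", cell, len(grp))
            continue
        if np.ptp(grp["y"].to_numpy()) == 0 or np.ptp(grp["y_hat"].to_numpy()) == 0:
            pcc = np.nan
        else:
            pcc = float(stats.pearsonr(grp["y"], grp["y_hat"]).statistic)
        rows.append({"cell_line": cell, "n": len(grp), "pcc": pcc})
    return pd.DataFrame(rows, columns=["cell_line", "n", "pcc"])


def summarize_folds(per_fold: list[dict]) -> dict:
    """Per-fold metric dicts → {metric: {per_fold, mean, sd}} summary."""
    keys = [k for k in per_fold[0] if k != "n"]
    out = {}
    for k in keys:
        vals = [f[k] for f in per_fold if f.get(k) is not None]
        out[k] = {
            "per_fold": [f.get(k) for f in per_fold],
            "mean": float(np.mean(vals)) if vals else None,
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
        }
    return out
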