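"""Evaluation fold construction.

Three protocols:

* pair-disjoint k-fold — unordered drug pairs are shuffled and dealt into k
  near-equal groups, so all samples of a combination share one fold
  (prevents combination leakage);
* leave-one-drug-out — every record containing the held-out drug is test,
  records containing neither occurrence train (cold start for new drugs);
* leave-one-cell-line-out — each cell line in turn is the test object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import SynergyRecord, ValidationError, pair_key

STRATEGIES = ("pair_disjoint_kfold", "leave_one_drug_out", "leave_one_cell_line_out")


@dataclass
class FoldAssignment:
    """Mapping from evaluation units (pairs, drugs or cell lines) to folds."""

    strategy: str
    unit_to_fold: dict = field(default_factory=dict)
    units: list = field(default_factory=list)
    k: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValidationError(f"unknown split strategy {self.strategy!r}")

    @property
    def n_folds(self) -> int:
        return self.k if self.k is not None else len(self.units)

    def test_indices(self, records: list[SynergyRecord], fold: int) -> np.ndarray:
        return np.flatnonzero([self._in_fold(r, fold) for r in records])

    def train_indices(self, records: list[SynergyRecord], fold: int) -> np.ndarray:
        return np.flatnonzero([not self._in_fold(r, fold) for r in records])

    def _in_fold(self, record: SynergyRecord, fold: int) -> bool:
        if self.strategy == "pair_disjoint_kfold":
            return self.unit_to_fold[record.pair] == fold
        if self.strategy == "leave_one_drug_out":
            unit = self.units[fold]
            return unit in (record.drug_a, record.drug_b)
        unit = self.units[fold]
        return record.cell_line == unit

    def iter_folds(self, records: list[SynergyRecord]):
        """Yield (fold index, train indices, test indices)."""
        for fold in range(self.n_folds):
            yield fold, self.train_indices(records, fold), self.test_indices(records, fold)


def make_pair_disjoint_folds(records: list[SynergyRecord], k: int,
                             seed: int) -> FoldAssignment:
    """Shuffle the distinct unordered pairs with ``seed`` and deal them
    round-robin into k folds.  Every record follows its pair's fold."""
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    pairs = sorted({r.pair for r in records})
    if len(pairs) < k:
        raise ValidationError(f"only {len(pairs)} distinct pairs for k={k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    unit_to_fold = {pairs[idx]: i % k for i, idx in enumerate(order)}
    return FoldAssignment(strategy="pair_disjoint_kfold", unit_to_fold=unit_to_fold,
                          units=pairs, k=k, seed=seed)


def make_leave_one_out_folds(records: list[SynergyRecord],
                             unit: str) -> FoldAssignment:
    """One fold per drug (``unit="drug"``) or per cell line
    (``unit="cell_line"``); fold i tests every record containing unit i."""
    if unit == "drug":
        units = sorted({d for r in records for d in (r.drug_a, r.drug_b)})
        strategy = "leave_one_drug_out"
    elif unit == "cell_line":
        units = sorted({r.cell_line for r in records})
        strategy = "leave_one_cell_line_out"
    else:
        raise ValidationError(f"unit must be 'drug' or 'cell_line', got {unit!r}")
    if len(units) < 2:
        raise ValidationError(f"need >= 2 distinct {unit}s for leave-one-out")
    return FoldAssignment(strategy=strategy,
                          unit_to_fold={u: i for i, u in enumerate(units)},
                          units=units)


__all__ = ["FoldAssignment", "make_pair_disjoint_folds", "make_leave_one_out_folds",
           "pair_key"]
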