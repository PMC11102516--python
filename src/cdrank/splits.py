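"""Cancer-stratified partitioning of cell lines: novel holdout, test set, CV folds.

Cancers represented by fewer than ``novel_min`` cell lines are withheld
entirely as a novel-cancer test set (generalization to unseen cancer types).
From each remaining cancer, 15% of cell lines (rounded half away from zero,
minimum 1) go to a trained-on test set; the rest are dealt round-robin into k
cross-validation folds after a seeded per-cancer shuffle, so every fold keeps
the cancer distribution. Splits operate on cell lines — all of a cell's drug
pairs follow it, so no pair-level leakage crosses compartments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .io import CellLineProfile


@dataclass
class SplitPlan:
    novel_test: set
    trained_on_test: set
    folds: list  # list of k cell-id sets
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        compartments = [self.novel_test, self.trained_on_test, *self.folds]
        total = sum(len(c) for c in compartments)
        union = set().union(*compartments)
        if total != len(union):
            raise ValueError("split compartments overlap")
        if any(len(f) == 0 for f in self.folds):
            raise ValueError("every fold must be nonempty")

    @property
    def training_cells(self) -> set:
        return set().union(*self.folds) if self.folds else set()

    def compartment_of(self, cell_id: str) -> str:
        if cell_id in self.novel_test:
            return "novel_test"
        if cell_id in self.trained_on_test:
            return "trained_on_test"
        for i, fold in enumerate(self.folds):
            if cell_id in fold:
                return f"fold_{i}"
        raise KeyError(cell_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in sorted(self.novel_test):
            rows.append((c, "novel_test", ""))
        for c in sorted(self.trained_on_test):
            rows.append((c, "trained_on_test", ""))
        for i, fold in enumerate(self.folds):
            for c in sorted(fold):
                rows.append((c, "fold", i))
        return pd.DataFrame(rows, columns=["cell_id", "compartment", "fold"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def make_split(cells: Sequence[CellLineProfile], test_frac: float = 0.15,
               novel_min: int = 15, k: int = 5, seed: int = 0) -> SplitPlan:
    """Partition cell lines into novel holdout, trained-on test set and k folds.

    Deterministic under ``seed``; cancers are processed in sorted order and
    each cancer's cells are shuffled before assignment.
    """
    by_cancer: Dict[str, list] = {}
    for c in cells:
        if not c.cancer_type:
            raise ValueError(f"cell '{c.cell_id}' has no cancer label")
        by_cancer.setdefault(c.cancer_type, []).append(c.cell_id)

    rng = np.random.default_rng(seed)
    novel: set = set()
    test: set = set()
    folds = [set() for _ in range(k)]
    any_trainable = False
    for cancer in sorted(by_cancer):
        ids = sorted(by_cancer[cancer])
        if len(ids) < novel_min:
            novel.update(ids)
            continue
        any_trainable = True
        order = rng.permutation(len(ids))
        shuffled = [ids[i] for i in order]
        n_test = max(1, _round_half_away(test_frac * len(ids)))
        test.update(shuffled[:n_test])
        for pos, cell_id in enumerate(shuffled[n_test:]):
            folds[pos % k].add(cell_id)
    if not any_trainable:
        raise ValueError(f"no cancer has >= {novel_min} cell lines; nothing to train on")
    return SplitPlan(novel_test=novel, trained_on_test=test, folds=folds, seed=seed,
                     params={"test_frac": test_frac, "novel_min": novel_min, "k": k})
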