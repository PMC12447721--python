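"""Class-imbalance handling and cross-validation splits.

Random under-sampling (RUS): each of ``n_iter`` iterations pairs the FULL
minority class with an equal-sized majority subset drawn without replacement,
yielding balanced training sets of size 2 x minority.  Stratified k-fold uses
scikit-learn's splitter behind this module's surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold


@dataclass
class ResamplePlan:
    """Index sets for repeated balanced under-sampling."""

    iterations: list[np.ndarray]
    seed: int

    @property
    def n_iter(self) -> int:
        return len(self.iterations)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"seed": self.seed, "iterations": [s.tolist() for s in self.iterations]})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ResamplePlan":
        d = json.loads(Path(path).read_text())
        return cls([np.asarray(s, dtype=int) for s in d["iterations"]], seed=d["seed"])


@dataclass
class FoldSplit:
    """k pairwise-disjoint test-index sets covering all samples."""

    test_sets: list[np.ndarray]
    seed: int

    @property
    def k(self) -> int:
        return len(self.test_sets)

    def train_test(self, fold: int, n: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.test_sets[fold]
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        return np.nonzero(mask)[0], test

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"seed": self.seed, "test_sets": [s.tolist() for s in self.test_sets]})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldSplit":
        d = json.loads(Path(path).read_text())
        return cls([np.asarray(s, dtype=int) for s in d["test_sets"]], seed=d["seed"])


def rus_plan(labels: np.ndarray, n_iter: int = 100, seed: int = 0) -> ResamplePlan:
    """Build an ``n_iter``-iteration random under-sampling plan.

    Every iteration contains all minority indices plus a majority subset of the
    same size drawn without replacement; iterations are independent draws.
    """
    labels = np.asarray(labels).astype(int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present for under-sampling")
    minority_class = classes[np.argmin(counts)]
    minority = np.nonzero(labels == minority_class)[0]
    majority = np.nonzero(labels != minority_class)[0]
    rng = np.random.default_rng(seed)
    iters = []
    for _ in range(n_iter):
        sub = rng.choice(majority, size=len(minority), replace=False)
        s = np.sort(np.concatenate([minority, sub]))
        iters.append(s)
    return ResamplePlan(iters, seed=seed)


def stratified_kfold(
    labels: np.ndarray, k: int = 5, seed: int = 0, stratify: bool = True
) -> FoldSplit:
    """Split samples into ``k`` folds (stratified by default).

    Per-fold class proportions stay within one sample of the global proportion;
    the split is deterministic given the seed.
    """
    labels = np.asarray(labels).astype(int)
    n = len(labels)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if stratify:
        _, counts = np.unique(labels, return_counts=True)
        if k > counts.min():
            raise ValueError(
                f"k={k} exceeds the minority class count ({counts.min()}); "
                "use stratify=False or a smaller k"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        sets = [test for _, test in splitter.split(np.zeros(n), labels)]
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        sets = [test for _, test in splitter.split(np.zeros(n))]
    return FoldSplit(sets, seed=seed)
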