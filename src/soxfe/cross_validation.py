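"""Cross-validation partitions: stratified tenfold and leave-one-record-out.

Leave-one-record-out (LORO) holds out all segments of one recording session
per fold, so no record contributes to both training and testing — the
group-level protocol that guards against record-specific leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import PartitionError


@dataclass
class CVPartition:
    """Fold assignment per segment; iterable as (train_idx, test_idx) pairs."""

    scheme: str  # "tenfold" | "loro"
    fold_of: np.ndarray  # fold id per sample
    groups: list[str] | None  # record id per sample (loro)
    seed: int
    n_folds: int = field(init=False)

    def __post_init__(self) -> None:
        self.fold_of = np.asarray(self.fold_of)
        self.n_folds = int(self.fold_of.max()) + 1

    def __iter__(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        idx = np.arange(len(self.fold_of))
        for f in range(self.n_folds):
            test = idx[self.fold_of == f]
            train = idx[self.fold_of != f]
            if len(train) == 0 or len(test) == 0:
                raise PartitionError(f"fold {f} is empty")
            yield train, test


def make_partition(
    labels: Sequence[int],
    record_ids: Sequence[str] | None,
    scheme: str,
    seed: int = 0,
    n_folds: int = 10,
) -> CVPartition:
    """Build a tenfold stratified partition or a LORO (one fold per record)
    partition; deterministic given ``seed``."""
    labels = np.asarray(labels)
    n = len(labels)
    if scheme == "tenfold":
        # infeasible stratification (a class smaller than the fold count)
        # degrades gracefully to the largest feasible fold count
        smallest_class = int(np.bincount(np.unique(labels, return_inverse=True)[1]).min())
        n_folds = min(n_folds, smallest_class)
        if n_folds < 2:
            raise PartitionError("stratified CV needs >=2 samples per class")
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        fold_of = np.empty(n, dtype=int)
        for f, (_, test) in enumerate(skf.split(np.zeros((n, 1)), labels)):
            fold_of[test] = f
        return CVPartition(scheme="tenfold", fold_of=fold_of, groups=None, seed=seed)
    if scheme == "loro":
        if record_ids is None:
            raise PartitionError("loro partition requires record ids")
        record_ids = [str(r) for r in record_ids]
        unique = sorted(set(record_ids))
        if len(unique) < 2:
            raise PartitionError("loro needs at least 2 distinct records")
        fold_idx = {r: f for f, r in enumerate(unique)}
        fold_of = np.array([fold_idx[r] for r in record_ids])
        return CVPartition(scheme="loro", fold_of=fold_of, groups=record_ids, seed=seed)
    raise ValueError(f"unknown CV scheme {scheme!r}")
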