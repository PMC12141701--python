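"""Ensemble k-nearest-neighbour classifier with iterative majority voting.

The classifier enumerates a fixed grid of 120 kNN configurations —
4 distance metrics x 3 vote weightings x k = 1..10 — and collects one
cross-validated prediction vector ("parameter-based outcome") per
configuration.  Outcomes are then sorted by accuracy and, for every prefix
of the top 3..120 outcomes, an element-wise mode vote produces one of 118
additional "voted outcomes".  A greedy step finally keeps the single most
accurate of all 238 candidates.

Selection accuracy is measured on the held-out CV predictions against the
true labels (selection-on-validation), so every reported ensemble accuracy
is an optimistically selected maximum; see the package methods note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .cross_validation import CVPartition
from .errors import DimensionError

DISTANCES = ("cityblock", "euclidean", "cosine", "spearman")
# vote-weight axis order follows the grid definition
WEIGHTS = ("squared_inverse", "equal", "inverse")
K_VALUES = tuple(range(1, 11))


@dataclass(frozen=True)
class KNNConfig:
    distance: str
    weight: str
    k: int

    def __post_init__(self) -> None:
        if self.distance not in DISTANCES:
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.weight not in WEIGHTS:
            raise ValueError(f"unknown weight {self.weight!r}")
        if not 1 <= self.k <= 10:
            raise ValueError("k must be in 1..10")


def config_grid() -> list[KNNConfig]:
    """The 120 configurations, distance-major, then weight, then k."""
    return [
        KNNConfig(distance=d, weight=w, k=k)
        for d, w, k in product(DISTANCES, WEIGHTS, K_VALUES)
    ]


def _spearman_distances(test: np.ndarray, train: np.ndarray) -> np.ndarray:
    """1 - Spearman rank correlation between feature vectors.

    A zero-variance row has undefined rank correlation; its distance to
    anything is defined as 1 (correlation zero).
    """
    rt = rankdata(test, axis=1)
    rr = rankdata(train, axis=1)
    rt_c = rt - rt.mean(axis=1, keepdims=True)
    rr_c = rr - rr.mean(axis=1, keepdims=True)
    nt = np.linalg.norm(rt_c, axis=1)
    nr = np.linalg.norm(rr_c, axis=1)
    corr = rt_c @ rr_c.T
    scale = np.outer(nt, nr)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(scale > 0, corr / np.where(scale > 0, scale, 1.0), 0.0)
    return 1.0 - corr


def _cosine_distances(test: np.ndarray, train: np.ndarray) -> np.ndarray:
    """1 - cosine similarity; a zero vector gets distance 1 to everything."""
    nt = np.linalg.norm(test, axis=1)
    nr = np.linalg.norm(train, axis=1)
    sim = test @ train.T
    scale = np.outer(nt, nr)
    sim = np.where(scale > 0, sim / np.where(scale > 0, scale, 1.0), 0.0)
    return 1.0 - sim


def pairwise_distances(test: np.ndarray, train: np.ndarray, metric: str) -> np.ndarray:
    if metric == "cityblock":
        return cdist(test, train, metric="cityblock")
    if metric == "euclidean":
        return cdist(test, train, metric="euclidean")
    if metric == "cosine":
        return _cosine_distances(test, train)
    if metric == "spearman":
        return _spearman_distances(test, train)
    raise ValueError(f"unknown distance {metric!r}")


def _vote(
    neighbor_labels: np.ndarray,
    neighbor_dists: np.ndarray,
    weight: str,
    classes: np.ndarray,
) -> int:
    """Weighted class vote over one test row's k neighbours.

    Zero-distance neighbours dominate: if any neighbour coincides with the
    test point, only those neighbours vote (equally).  Vote ties go to the
    smallest class label.
    """
    zero = neighbor_dists <= 0
    if weight != "equal" and zero.any():
        neighbor_labels = neighbor_labels[zero]
        w = np.ones(len(neighbor_labels))
    elif weight == "equal":
        w = np.ones(len(neighbor_labels))
    elif weight == "inverse":
        w = 1.0 / neighbor_dists
    else:  # squared_inverse
        w = 1.0 / neighbor_dists**2
    scores = np.zeros(len(classes))
    for ci, c in enumerate(classes):
        scores[ci] = w[neighbor_labels == c].sum()
    # classes sorted ascending: argmax returns the smallest label on ties
    return int(classes[np.argmax(scores)])


def knn_predict(
    train_features: np.ndarray,
    train_labels: Sequence[int],
    test_features: np.ndarray,
    config: KNNConfig,
    distances: np.ndarray | None = None,
) -> np.ndarray:
    """Predict test labels with one kNN configuration.

    ``distances`` may carry a precomputed (n_test x n_train) matrix for
    ``config.distance`` to avoid recomputation across the grid.  Neighbour
    ties at the k-th distance are broken by training-row order.
    """
    x_train = np.asarray(train_features, dtype=float)
    x_test = np.asarray(test_features, dtype=float)
    y_train = np.asarray(train_labels)
    if config.k > len(y_train):
        raise ValueError(f"k={config.k} exceeds training size {len(y_train)}")
    if distances is None:
        distances = pairwise_distances(x_test, x_train, config.distance)
    classes = np.unique(y_train)
    order = np.argsort(distances, axis=1, kind="stable")[:, : config.k]
    out = np.empty(len(x_test), dtype=y_train.dtype)
    for i in range(len(x_test)):
        nn = order[i]
        out[i] = _vote(y_train[nn], distances[i, nn], config.weight, classes)
    return out


@dataclass
class OutcomeSet:
    """All candidate prediction vectors of one ensemble run."""

    configs: list[KNNConfig]
    parameter_outcomes: np.ndarray  # (120, n)
    voted_outcomes: np.ndarray  # (118, n)
    accuracies: np.ndarray  # (238,) percent
    sorted_order: np.ndarray  # parameter outcomes by accuracy descending
    best_index: int
    best_predictions: np.ndarray = field(repr=False)

    @property
    def best_accuracy(self) -> float:
        return float(self.accuracies[self.best_index])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "configs": [
                {"distance": c.distance, "weight": c.weight, "k": c.k}
                for c in self.configs
            ],
            "parameter_outcomes": self.parameter_outcomes.tolist(),
            "voted_outcomes": self.voted_outcomes.tolist(),
            "accuracies": self.accuracies.tolist(),
            "sorted_order": self.sorted_order.tolist(),
            "best_index": int(self.best_index),
            "best_predictions": self.best_predictions.tolist(),
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _accuracy_pct(pred: np.ndarray, truth: np.ndarray) -> float:
    return float(np.mean(pred == truth) * 100.0)


def generate_parameter_outcomes(
    features: np.ndarray,
    labels: Sequence[int],
    folds: CVPartition,
) -> tuple[list[KNNConfig], np.ndarray, np.ndarray]:
    """Held-out predictions for all 120 grid configurations.

    Distance matrices are computed once per fold and metric, then shared
    across the 30 weight/k combinations of that metric.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    configs = config_grid()
    outcomes = np.empty((len(configs), len(y)), dtype=y.dtype)
    fold_list = list(folds)
    for train, test in fold_list:
        for metric in DISTANCES:
            dmat = pairwise_distances(x[test], x[train], metric)
            for e, cfg in enumerate(configs):
                if cfg.distance != metric:
                    continue
                outcomes[e, test] = knn_predict(
                    x[train], y[train], x[test], cfg, distances=dmat
                )
    accuracies = np.array([_accuracy_pct(o, y) for o in outcomes])
    return configs, outcomes, accuracies


def elementwise_mode(outcomes: np.ndarray) -> np.ndarray:
    """Per-sample mode over outcome vectors; ties go to the smallest label."""
    classes = np.unique(outcomes)
    counts = np.stack([(outcomes == c).sum(axis=0) for c in classes])
    return classes[np.argmax(counts, axis=0)]


def iterative_majority_vote(
    outcomes: np.ndarray,
    accuracies: np.ndarray,
    labels: Sequence[int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mode votes over the top-m accuracy-sorted outcomes for m = 3..120.

    Returns ``(sorted_order, voted_outcomes, voted_accuracies)``; sorting is
    stable so accuracy ties keep grid enumeration order.
    """
    y = np.asarray(labels)
    m = len(outcomes)
    if m < 3:
        raise ValueError("need at least 3 outcomes to vote")
    order = np.argsort(-np.asarray(accuracies), kind="stable")
    ranked = outcomes[order]
    voted = np.empty((m - 2, len(y)), dtype=outcomes.dtype)
    for l in range(1, m - 1):
        voted[l - 1] = elementwise_mode(ranked[: l + 2])
    voted_acc = np.array([_accuracy_pct(v, y) for v in voted])
    return order, voted, voted_acc


def greedy_best(
    outcomes: np.ndarray, accuracies: np.ndarray
) -> tuple[np.ndarray, int]:
    """The candidate with maximal accuracy; ties go to the smallest index."""
    if len(outcomes) != len(accuracies):
        raise DimensionError("outcomes and accuracies must align")
    idx = int(np.argmax(accuracies))
    return outcomes[idx], idx


def tknn(
    features: np.ndarray,
    labels: Sequence[int],
    folds: CVPartition,
) -> OutcomeSet:
    """Run the full ensemble: grid outcomes, majority votes, greedy choice."""
    y = np.asarray(labels)
    configs, pout, pacc = generate_parameter_outcomes(features, y, folds)
    order, vout, vacc = iterative_majority_vote(pout, pacc, y)
    all_outcomes = np.vstack([pout, vout])
    all_acc = np.concatenate([pacc, vacc])
    best, idx = greedy_best(all_outcomes, all_acc)
    return OutcomeSet(
        configs=configs,
        parameter_outcomes=pout,
        voted_outcomes=vout,
        accuracies=all_acc,
        sorted_order=order,
        best_index=idx,
        best_predictions=best,
    )
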