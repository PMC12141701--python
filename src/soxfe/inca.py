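"""Iterative neighborhood-component-analysis (INCA) feature selection.

NCA with a *diagonal* weight vector learns one non-negative relevance weight
per feature by maximising the regularised leave-one-out soft-neighbour
objective

    F(w) = (1/n) sum_i sum_{j: y_j = y_i, j != i} p_ij  -  lambda * ||w||^2
    p_ij ∝ exp( - sum_f w_f^2 |x_if - x_jf| )

(features are z-scored internally; the reported relevance of feature ``f``
is ``w_f^2``).  INCA then ranks features by weight, evaluates the top-``r``
prefix for every ``r`` in a range with a 1-nearest-neighbour city-block
tenfold cross-validated misclassification loss, and keeps the
loss-minimising prefix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .cross_validation import CVPartition, make_partition
from .errors import DegenerateLabelsError, PartitionError
from .tknn import KNNConfig, knn_predict


@dataclass
class SelectionResult:
    """Ranking, loss curve over subset sizes, and the chosen prefix."""

    ranked_indices: np.ndarray  # permutation of 0..p-1, best first
    loss_curve: np.ndarray  # misclassification rate per r in [start, stop]
    start: int
    stop: int
    chosen_r: int
    seed: int

    @property
    def chosen_indices(self) -> np.ndarray:
        return self.ranked_indices[: self.chosen_r]

    @property
    def n_selected(self) -> int:
        return self.chosen_r

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "ranked_indices": self.ranked_indices.tolist(),
            "loss_curve": self.loss_curve.tolist(),
            "start": self.start,
            "stop": self.stop,
            "chosen_r": self.chosen_r,
            "chosen_indices": self.chosen_indices.tolist(),
            "seed": self.seed,
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "SelectionResult":
        p = Path(text_or_path)
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            ranked_indices=np.asarray(d["ranked_indices"]),
            loss_curve=np.asarray(d["loss_curve"]),
            start=d["start"],
            stop=d["stop"],
            chosen_r=d["chosen_r"],
            seed=d["seed"],
        )


def _zscore(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _nca_objective_grad(
    x: np.ndarray, same: np.ndarray, w: np.ndarray, lam: float
) -> tuple[float, np.ndarray]:
    """Objective F(w) and its gradient; O(n^2 p) time, O(n p) extra memory."""
    n, p = x.shape
    w2 = w * w
    # weighted L1 distances
    dist = np.zeros((n, n))
    for f in range(0, p, 64):  # feature blocks keep memory bounded
        block = x[:, f:f + 64]
        diff = np.abs(block[:, None, :] - block[None, :, :])
        dist += diff @ w2[f:f + 64]
    np.fill_diagonal(dist, np.inf)
    # row-stabilised softmax kernel
    shift = dist.min(axis=1, keepdims=True)
    shift[~np.isfinite(shift)] = 0.0
    kern = np.exp(-(dist - shift))
    np.fill_diagonal(kern, 0.0)
    denom = kern.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    pij = kern / denom
    pi = (pij * same).sum(axis=1)
    objective = pi.mean() - lam * float(w2.sum())

    grad = np.zeros(p)
    for i in range(n):
        delta = np.abs(x - x[i])  # (n, p)
        grad += pi[i] * (pij[i] @ delta) - (pij[i] * same[i]) @ delta
    grad = (2.0 * w / n) * grad - 2.0 * lam * w
    return objective, grad


def nca_weights(
    features: np.ndarray,
    labels: Sequence[int],
    regularization: float | None = None,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-7,
) -> np.ndarray:
    """Per-feature relevance weights from diagonal-weight NCA.

    ``regularization`` defaults to ``1/n``.  Deterministic: weights start at
    one and follow full-batch gradient ascent with step halving, so the seed
    only labels the run.  Returns ``w_f**2 >= 0``.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n, p = x.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("NCA needs at least two classes")
    lam = 1.0 / n if regularization is None else float(regularization)
    if lam < 0:
        raise ValueError("regularization must be non-negative")
    x = _zscore(x)
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)

    w = np.ones(p)
    step = 1.0
    obj, grad = _nca_objective_grad(x, same, w, lam)
    for _ in range(max_iter):
        gnorm = np.linalg.norm(grad)
        if gnorm < 1e-12:
            break
        improved = False
        while step > 1e-10:
            w_new = w + step * grad / max(gnorm, 1e-12)
            obj_new, grad_new = _nca_objective_grad(x, same, w_new, lam)
            if obj_new > obj:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        delta = obj_new - obj
        w, obj, grad = w_new, obj_new, grad_new
        step *= 1.2
        if delta < tol:
            break
    return w * w


def rank_features(weights: Sequence[float]) -> np.ndarray:
    """Indices sorted by weight descending; ties keep ascending index order."""
    w = np.asarray(weights, dtype=float)
    return np.argsort(-w, kind="stable")


def knn_loss(
    features: np.ndarray,
    labels: Sequence[int],
    folds: CVPartition,
) -> float:
    """Tenfold-CV misclassification rate of 1-NN with city-block distance."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    config = KNNConfig(distance="cityblock", weight="equal", k=1)
    pred = np.empty(len(y), dtype=y.dtype)
    for train, test in folds:
        if len(train) == 0:
            raise PartitionError("empty training fold")
        pred[test] = knn_predict(x[train], y[train], x[test], config)
    return float(np.mean(pred != y))


def inca_select(
    features: np.ndarray,
    labels: Sequence[int],
    start: int = 14,
    stop: int = 98,
    seed: int = 0,
    folds: CVPartition | None = None,
    weights: np.ndarray | None = None,
) -> SelectionResult:
    """Pick the loss-minimising top-``r`` feature prefix for ``r`` in
    ``[start, stop]``; ties go to the smallest ``r``.

    ``folds`` defaults to a stratified tenfold partition seeded by ``seed``;
    ``weights`` may carry precomputed NCA weights.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n, p = x.shape
    if stop > p:
        warnings.warn(f"stop={stop} clipped to feature count {p}", stacklevel=2)
        stop = p
    if not 1 <= start <= stop:
        raise ValueError(f"invalid range [{start}, {stop}]")
    if weights is None:
        weights = nca_weights(x, y, seed=seed)
    ranked = rank_features(weights)
    if folds is None:
        folds = make_partition(y, None, "tenfold", seed=seed)
    losses = np.empty(stop - start + 1)
    for i, r in enumerate(range(start, stop + 1)):
        losses[i] = knn_loss(x[:, ranked[:r]], y, folds)
    chosen_r = start + int(np.argmin(losses))  # argmin returns first minimum
    return SelectionResult(
        ranked_indices=ranked,
        loss_curve=losses,
        start=start,
        stop=stop,
        chosen_r=chosen_r,
        seed=seed,
    )
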