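"""End-to-end evaluation: fusion across feature branches, metrics, pipeline.

The three feature branches (minimum-distance, maximum-distance, merged
histograms) each pass through feature selection and the ensemble classifier,
yielding one held-out prediction vector per branch.  A mode vote fuses the
three, and a greedy step keeps whichever of the four candidates is most
accurate.  Metrics are the standard two-class set: accuracy, sensitivity,
specificity and their geometric mean, all in percent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import dlob, dmpat, inca, tknn
from .cross_validation import CVPartition, make_partition
from .errors import DegenerateLabelsError, DimensionError
from .signal_io import Dataset, Montage

BRANCH_KINDS = ("min_distance", "max_distance", "merged")


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    geometric_mean: float

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "geometric_mean": self.geometric_mean,
        }


def fuse_mode(t1: np.ndarray, t2: np.ndarray, t3: np.ndarray) -> np.ndarray:
    """Element-wise mode of the three branch predictions."""
    t1, t2, t3 = (np.asarray(t) for t in (t1, t2, t3))
    if not (t1.shape == t2.shape == t3.shape):
        raise DimensionError("prediction vectors must have equal length")
    return tknn.elementwise_mode(np.stack([t1, t2, t3]))


def greedy_final(
    t1: np.ndarray, t2: np.ndarray, t3: np.ndarray, vot: np.ndarray,
    labels: Sequence[int],
) -> tuple[np.ndarray, int]:
    """Most accurate of the four candidates; ties keep order (t1, t2, t3, vot)."""
    y = np.asarray(labels)
    candidates = [np.asarray(t) for t in (t1, t2, t3, vot)]
    accs = [float(np.mean(c == y)) for c in candidates]
    idx = int(np.argmax(accs))  # first maximum wins ties
    return candidates[idx], idx


def compute_metrics(
    predictions: Sequence[int], labels: Sequence[int], positive_class: int = 1
) -> MetricsReport:
    """Confusion counts and percent metrics for a two-class problem."""
    pred = np.asarray(predictions)
    y = np.asarray(labels)
    if positive_class not in y or not np.any(y != positive_class):
        raise DegenerateLabelsError("both classes must be present in labels")
    pos_t = y == positive_class
    pos_p = pred == positive_class
    tp = int(np.sum(pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    acc = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    sen = 100.0 * tp / (tp + fn)
    spe = 100.0 * tn / (tn + fp)
    gm = float(np.sqrt(sen * spe))
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, accuracy=acc,
                         sensitivity=sen, specificity=spe, geometric_mean=gm)


@dataclass
class PipelineConfig:
    """Everything a full run needs besides the data."""

    cv_scheme: str = "loro"  # "tenfold" | "loro"
    seed: int = 0
    inca_start: int = 14
    inca_stop: int = 98
    entropy_base: float = 2
    transition_mode: str = "consecutive"
    positive_class: int = 1
    nested_selection: bool = False  # selection inside each training fold
    montage: Montage = field(default_factory=Montage.default_14_channel)

    def as_dict(self) -> dict:
        return {
            "cv_scheme": self.cv_scheme,
            "seed": self.seed,
            "inca_start": self.inca_start,
            "inca_stop": self.inca_stop,
            "entropy_base": self.entropy_base,
            "transition_mode": self.transition_mode,
            "positive_class": self.positive_class,
            "nested_selection": self.nested_selection,
            "montage_channels": list(self.montage.channel_names),
        }


@dataclass
class PipelineResult:
    config: PipelineConfig
    selections: dict[str, inca.SelectionResult]
    outcome_sets: dict[str, tknn.OutcomeSet]
    dlob_reports: dict[str, dict]
    vot: np.ndarray
    fot: np.ndarray
    fot_choice: int
    metrics: dict[str, MetricsReport]
    labels: np.ndarray
    record_ids: list[str]

    def report(self) -> dict:
        """A JSON-serialisable summary of the whole run."""
        return {
            "config": self.config.as_dict(),
            "branches": {
                kind: {
                    "chosen_r": int(self.selections[kind].chosen_r),
                    "chosen_indices": self.selections[kind].chosen_indices.tolist(),
                    "loss_curve": self.selections[kind].loss_curve.tolist(),
                    "outcome_accuracies": self.outcome_sets[kind].accuracies.tolist(),
                    "best_outcome_index": int(self.outcome_sets[kind].best_index),
                    "predictions": self.outcome_sets[kind].best_predictions.tolist(),
                    "dlob": self.dlob_reports[kind],
                }
                for kind in BRANCH_KINDS
            },
            "vot": self.vot.tolist(),
            "fot": self.fot.tolist(),
            "fot_choice": self.fot_choice,
            "metrics": {k: m.as_dict() for k, m in self.metrics.items()},
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.report(), sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def predictions_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "segment": np.arange(len(self.labels)),
            "record_id": self.record_ids,
            "truth": self.labels,
            "t1": self.outcome_sets["min_distance"].best_predictions,
            "t2": self.outcome_sets["max_distance"].best_predictions,
            "t3": self.outcome_sets["merged"].best_predictions,
            "vot": self.vot,
            "fot": self.fot,
        })


def run_pipeline(dataset: Dataset, config: PipelineConfig | None = None) -> PipelineResult:
    """Run every stage on a segmented dataset.

    One outer CV partition is shared by the three branches so the fused vote
    compares aligned held-out predictions.  Feature selection sees the full
    dataset (the faithful, non-nested protocol) unless
    ``config.nested_selection`` is set, in which case selection is redone
    inside each outer training fold.
    """
    config = config or PipelineConfig()
    labels = dataset.labels
    record_ids = dataset.record_ids
    f1, f2, f3 = dmpat.extract_all(dataset.segments)
    branches = dict(zip(BRANCH_KINDS, (f1, f2, f3)))

    outer = make_partition(labels, record_ids, config.cv_scheme, seed=config.seed)
    selections: dict[str, inca.SelectionResult] = {}
    outcome_sets: dict[str, tknn.OutcomeSet] = {}
    dlob_reports: dict[str, dict] = {}
    for kind, feats in branches.items():
        sel = inca.inca_select(
            feats, labels, start=config.inca_start, stop=config.inca_stop,
            seed=config.seed,
        )
        selections[kind] = sel
        if config.nested_selection:
            outcome_sets[kind] = _nested_tknn(feats, labels, outer, config)
        else:
            outcome_sets[kind] = tknn.tknn(feats[:, sel.chosen_indices], labels, outer)
        dlob_reports[kind] = dlob.dlob_report(
            sel.chosen_indices, config.montage, kind,
            entropy_base=config.entropy_base,
            transition_mode=config.transition_mode,
        )

    t1, t2, t3 = (outcome_sets[k].best_predictions for k in BRANCH_KINDS)
    vot = fuse_mode(t1, t2, t3)
    fot, choice = greedy_final(t1, t2, t3, vot, labels)
    metrics = {
        "t1": compute_metrics(t1, labels, config.positive_class),
        "t2": compute_metrics(t2, labels, config.positive_class),
        "t3": compute_metrics(t3, labels, config.positive_class),
        "vot": compute_metrics(vot, labels, config.positive_class),
        "fot": compute_metrics(fot, labels, config.positive_class),
    }
    return PipelineResult(
        config=config, selections=selections, outcome_sets=outcome_sets,
        dlob_reports=dlob_reports, vot=vot, fot=fot, fot_choice=choice,
        metrics=metrics, labels=labels, record_ids=record_ids,
    )


def _nested_tknn(
    feats: np.ndarray, labels: np.ndarray, outer: CVPartition,
    config: PipelineConfig,
) -> tknn.OutcomeSet:
    """Leakage-free variant: rerun selection on each outer training fold and
    apply the fold's own ensemble to its held-out segments."""
    y = np.asarray(labels)
    pred = np.empty(len(y), dtype=y.dtype)
    for train, test in outer:
        sel = inca.inca_select(
            feats[train], y[train], start=config.inca_start,
            stop=min(config.inca_stop, feats.shape[1]), seed=config.seed,
        )
        inner = make_partition(y[train], None, "tenfold", seed=config.seed)
        inner_set = tknn.tknn(feats[train][:, sel.chosen_indices], y[train], inner)
        best_idx = inner_set.best_index
        if best_idx < len(inner_set.configs):
            cfg = inner_set.configs[best_idx]
        else:  # a voted outcome won: fall back to the best single config
            cfg = inner_set.configs[int(inner_set.sorted_order[0])]
        pred[test] = tknn.knn_predict(
            feats[train][:, sel.chosen_indices], y[train],
            feats[test][:, sel.chosen_indices], cfg,
        )
    # wrap as a degenerate outcome set: one outcome repeated
    acc = float(np.mean(pred == y) * 100.0)
    configs = tknn.config_grid()
    pout = np.tile(pred, (len(configs), 1))
    order, vout, vacc = tknn.iterative_majority_vote(
        pout, np.full(len(configs), acc), y
    )
    return tknn.OutcomeSet(
        configs=configs, parameter_outcomes=pout, voted_outcomes=vout,
        accuracies=np.concatenate([np.full(len(configs), acc), vacc]),
        sorted_order=order, best_index=0, best_predictions=pred,
    )
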