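"""Metrics, trial aggregation, and per-atom attention export.

Regression is scored by mean absolute error; classification by accuracy,
recall, precision and F1 at a probability threshold (0.5 by default) plus
the ROC curve and its trapezoidal AUC.  Metrics are averaged over trials,
with standard deviations reported alongside the means.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .model import MultiPathModel, forward
from .molgraph import MolecularGraph

__all__ = ["TrialResult", "AttentionRecord", "mae", "classification_metrics",
           "roc_points", "aggregate_trials", "evaluate_model",
           "export_attention", "write_attention_csv", "mean_roc"]


@dataclass
class TrialResult:
    trial: int
    task: str
    metrics: dict[str, float]
    n_test: int


@dataclass
class AttentionRecord:
    mol_id: str
    atom_idx: int
    alpha: dict[str, float]  # path -> attention weight, sums to 1


def mae(pred: Sequence[float], target: Sequence[float]) -> float:
    """Mean absolute error (1/n) sum |pred - target|."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.size == 0:
        raise ValueError("mae on empty input")
    if pred.shape != target.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {target.shape}")
    return float(np.mean(np.abs(pred - target)))


def classification_metrics(prob: Sequence[float], label: Sequence[int],
                           threshold: float = 0.5) -> dict[str, float]:
    """Accuracy / recall / precision / F1 from thresholded probabilities.

    Ratios with a zero denominator are reported as 0.0 and flagged in the
    returned map under ``degenerate`` (1.0 when any ratio was undefined).
    """
    prob = np.asarray(prob, dtype=float)
    label = np.asarray(label)
    if not np.isin(label, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    pred = (prob >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (label == 1)))
    tn = int(np.sum((pred == 0) & (label == 0)))
    fp = int(np.sum((pred == 1) & (label == 0)))
    fn = int(np.sum((pred == 0) & (label == 1)))
    degenerate = False

    def ratio(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            warnings.warn("undefined classification ratio (zero denominator) "
                          "reported as 0", stacklevel=2)
            return 0.0
        return num / den

    accuracy = (tp + tn) / len(label)
    recall = ratio(tp, tp + fn)
    precision = ratio(tp, tp + fp)
    if precision + recall > 0:
        f_score = 2 * precision * recall / (precision + recall)
    else:
        f_score = ratio(0, 0)
    return {"accuracy": accuracy, "recall": recall, "precision": precision,
            "f_score": f_score, "degenerate": float(degenerate),
            "tp": float(tp), "tn": float(tn), "fp": float(fp), "fn": float(fn)}


def roc_points(prob: Sequence[float], label: Sequence[int]
               ) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) from thresholding at each distinct score, and
    the trapezoidal AUC.  Requires both classes present; tied scores share
    one threshold."""
    from sklearn.metrics import roc_curve

    label = np.asarray(label)
    if len(np.unique(label)) < 2:
        raise ValueError("ROC requires at least one positive and one negative label")
    fpr, tpr, _ = roc_curve(label, np.asarray(prob, dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def write_roc_csv(prob: Sequence[float], label: Sequence[int],
                  path: str | Path) -> None:
    """Write the ROC curve as CSV rows (fpr, tpr, threshold)."""
    from sklearn.metrics import roc_curve

    label = np.asarray(label)
    if len(np.unique(label)) < 2:
        raise ValueError("ROC requires at least one positive and one negative label")
    fpr, tpr, thresholds = roc_curve(label, np.asarray(prob, dtype=float))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fpr", "tpr", "threshold"])
        writer.writerows(zip(fpr, tpr, thresholds))


def mean_roc(curves: Iterable[Sequence[tuple[float, float]]],
             grid_size: int = 101) -> list[tuple[float, float]]:
    """Vertically average ROC curves on a fixed FPR grid (for multi-trial
    ROC figures)."""
    grid = np.linspace(0.0, 1.0, grid_size)
    tprs = []
    for curve in curves:
        fpr, tpr = np.array(curve).T
        tprs.append(np.interp(grid, fpr, tpr))
    return list(zip(grid.tolist(), np.mean(tprs, axis=0).tolist()))


def aggregate_trials(results: Sequence[TrialResult]
                     ) -> dict[str, dict[str, float]]:
    """Arithmetic mean and standard deviation of each metric over trials."""
    if not results:
        raise ValueError("no trial results to aggregate")
    keys = set(results[0].metrics)
    for r in results[1:]:
        if set(r.metrics) != keys:
            raise ValueError("inconsistent metric keys across trials")
    mean = {k: float(np.mean([r.metrics[k] for r in results])) for k in keys}
    std = {k: float(np.std([r.metrics[k] for r in results])) for k in keys}
    return {"mean": mean, "std": std}


def evaluate_model(model: MultiPathModel,
                   test: Sequence[tuple[MolecularGraph, float]],
                   trial: int = 0, threshold: float = 0.5) -> TrialResult:
    """Score a trained model on a held-out split."""
    preds = [forward(model, g) for g, _ in test]
    targets = [t for _, t in test]
    if model.config.task == "regression":
        metrics = {"mae": mae(preds, targets)}
    else:
        labels = [int(t) for t in targets]
        metrics = classification_metrics(preds, labels, threshold)
        try:
            _, auc = roc_points(preds, labels)
            metrics["auc"] = auc
        except ValueError:
            metrics["auc"] = float("nan")
    return TrialResult(trial=trial, task=model.config.task,
                       metrics=metrics, n_test=len(test))


def metrics_json(results: Sequence[TrialResult], path: str | Path) -> None:
    """Write {"task", "per_trial", "mean", "std"} to a JSON file."""
    agg = aggregate_trials(results)
    payload = {"task": results[0].task,
               "per_trial": [r.metrics for r in results],
               "mean": agg["mean"], "std": agg["std"]}
    Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# attention export


def export_attention(model: MultiPathModel,
                     graphs: Iterable[MolecularGraph]) -> list[AttentionRecord]:
    """Per-atom attention weights over the enabled paths, one record per
    atom per molecule.  Requires the attention aggregator."""
    from .aggregation import AttentionParams

    if not isinstance(model.agg, AttentionParams):
        raise ValueError("attention export requires attention aggregation "
                         "with more than one path")
    records: list[AttentionRecord] = []
    for graph in graphs:
        _, alpha = forward(model, graph, return_attention=True)
        for i in range(graph.n_atoms):
            records.append(AttentionRecord(
                mol_id=graph.id, atom_idx=i,
                alpha={p: float(alpha[i, k])
                       for k, p in enumerate(model.config.paths)}))
    return records


def write_attention_csv(records: Sequence[AttentionRecord],
                        path: str | Path) -> None:
    """CSV columns mol_id, atom_idx, alpha_node, alpha_edge, alpha_3d;
    absent paths are left empty."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mol_id", "atom_idx", "alpha_node", "alpha_edge",
                         "alpha_3d"])
        for r in records:
            writer.writerow([r.mol_id, r.atom_idx,
                             *(r.alpha.get(p, "") for p in ("node", "edge", "3d"))])
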