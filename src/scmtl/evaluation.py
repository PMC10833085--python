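"""Evaluation metrics: annotation quality, protein recovery, partitions.

All metrics are pure functions of (truth, prediction) and invariant to a
simultaneous permutation of cells.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score


@dataclasses.dataclass
class MetricReport:
    accuracy: float
    per_class_recall: dict
    per_class_f1: dict
    macro_f1: float
    f1_variance: float
    n_cells: int
    class_catalog: list
    per_protein_pcc: Optional[np.ndarray] = None
    per_protein_rmse: Optional[np.ndarray] = None
    mean_pcc: Optional[float] = None
    mean_rmse: Optional[float] = None
    ari: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "per_class_recall": self.per_class_recall,
            "per_class_f1": self.per_class_f1,
            "macro_f1": self.macro_f1,
            "f1_variance": self.f1_variance,
            "n_cells": self.n_cells,
            "class_catalog": list(self.class_catalog),
        }
        if self.mean_pcc is not None:
            d["mean_pcc"] = self.mean_pcc
            d["mean_rmse"] = self.mean_rmse
            d["per_protein_pcc"] = [None if np.isnan(v) else v for v in self.per_protein_pcc]
            d["per_protein_rmse"] = list(map(float, self.per_protein_rmse))
        if self.ari is not None:
            d["ari"] = self.ari
        return d


def classification_metrics(true_labels, pred_labels) -> MetricReport:
    """Accuracy, per-class recall/F1, macro-F1 and its population variance.

    Classes present only in predictions score F1 = 0 and are included in the
    macro average (hallucinated classes are penalized); classes absent from
    both are not represented.
    """
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(pred_labels, dtype=object)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} truth vs {len(p)} predictions")
    catalog = sorted(set(t.tolist()) | set(p.tolist()))
    acc = float(np.mean(t == p))

    recall, f1 = {}, {}
    for c in catalog:
        tp = int(np.sum((t == c) & (p == c)))
        fn = int(np.sum((t == c) & (p != c)))
        fp = int(np.sum((t != c) & (p == c)))
        in_truth = (tp + fn) > 0
        if in_truth:
            recall[c] = tp / (tp + fn)
        denom = 2 * tp + fp + fn
        if in_truth or fp > 0:
            f1[c] = 2 * tp / denom if denom > 0 else 0.0
    f1s = np.array(list(f1.values()), dtype=float)
    return MetricReport(
        accuracy=acc,
        per_class_recall=recall,
        per_class_f1=f1,
        macro_f1=float(f1s.mean()) if f1s.size else 0.0,
        f1_variance=float(f1s.var()) if f1s.size else 0.0,
        n_cells=len(t),
        class_catalog=catalog,
    )


def protein_metrics(true_matrix: np.ndarray, pred_matrix: np.ndarray):
    """Per-protein Pearson r and RMSE plus cross-protein means.

    A constant truth column has undefined correlation; it is reported as NaN
    and excluded from the mean PCC (but still counts toward mean RMSE).
    """
    t = np.asarray(true_matrix, dtype=float)
    p = np.asarray(pred_matrix, dtype=float)
    if t.shape != p.shape:
        raise ValueError("shape mismatch")
    if t.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    n_prot = t.shape[1]
    pcc = np.empty(n_prot)
    rmse = np.empty(n_prot)
    for j in range(n_prot):
        tc, pc = t[:, j], p[:, j]
        rmse[j] = float(np.sqrt(np.mean((tc - pc) ** 2)))
        if tc.max() == tc.min() or pc.max() == pc.min():
            pcc[j] = np.nan
        else:
            pcc[j] = float(np.corrcoef(tc, pc)[0, 1])
    mean_pcc = float(np.nanmean(pcc)) if np.any(~np.isnan(pcc)) else float("nan")
    return pcc, rmse, mean_pcc, float(rmse.mean())


def ari(labels_a, labels_b) -> float:
    """Permutation-model adjusted Rand index between two partitions."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return float(adjusted_rand_score(a, b))


def kruskal_groups(values, group_labels):
    """Kruskal–Wallis H (tie-corrected) + chi-square p across groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(group_labels)
    keys = sorted(set(groups.tolist()))
    if len(keys) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == k] for k in keys]
    for k, s in zip(keys, samples):
        if len(s) == 0:
            raise ValueError(f"group {k!r} is empty")
    if np.all(values == values[0]):  # fully tied data: H defined as 0
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)
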