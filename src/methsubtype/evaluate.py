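"""Confusion matrices, one-vs-rest class metrics, multiclass AUC, embeddings.

Per-class metrics are computed one-vs-rest from the confusion matrix using
the elementary formulas

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 TP / (2 TP + FP + FN)

with undefined ratios (0/0) reported as NaN, never as 0.  Multiclass AUC
is the Hand-Till construction: the mean over all unordered class pairs of
the pairwise, rank-based AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "class_metrics",
    "multiclass_auc",
    "metrics_table",
    "pca_grid",
    "tsne_embed",
    "heatmap_data",
]


@dataclass
class ConfusionMatrix:
    """k x k count matrix, rows = true class, columns = predicted class."""

    counts: pd.DataFrame

    @property
    def classes(self) -> list:
        return list(self.counts.index)

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def ovr_counts(self, cls) -> dict[str, int]:
        """One-vs-rest TP/FP/TN/FN for one class."""
        m = self.counts
        tp = int(m.loc[cls, cls])
        fn = int(m.loc[cls].sum()) - tp
        fp = int(m[cls].sum()) - tp
        tn = self.n - tp - fn - fp
        return {"TP": tp, "FP": fp, "TN": tn, "FN": fn}


def confusion(true, pred, classes=None) -> ConfusionMatrix:
    """Count matrix of (true, predicted) label pairs."""
    true = np.asarray(true)
    pred = np.asarray(pred)
    if true.shape != pred.shape:
        raise ValueError("label vectors must have equal length")
    if classes is None:
        classes = sorted(set(true) | set(pred))
    else:
        known = set(classes)
        stray = (set(true) | set(pred)) - known
        if stray:
            raise ValueError(f"labels outside the class set: {sorted(stray)}")
    counts = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    for t, p in zip(true, pred):
        counts.loc[t, p] += 1
    return ConfusionMatrix(counts)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class one-vs-rest metrics plus a macro-mean row."""
    rows = {}
    for cls in cm.classes:
        c = cm.ovr_counts(cls)
        tp, fp, tn, fn = c["TP"], c["FP"], c["TN"], c["FN"]
        rows[cls] = {
            "accuracy": _ratio(tp + tn, tp + tn + fp + fn),
            "precision": _ratio(tp, tp + fp),
            "sensitivity": _ratio(tp, tp + fn),
            "specificity": _ratio(tn, tn + fp),
            "f1": _ratio(2 * tp, 2 * tp + fp + fn),
        }
    table = pd.DataFrame(rows).T
    table.loc["macro"] = table.mean(axis=0, skipna=False)
    return table


def _binary_auc(scores: np.ndarray, is_pos: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC of scores for the positive class."""
    n_pos = int(is_pos.sum())
    n_neg = len(is_pos) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return (ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def multiclass_auc(true, probs) -> float:
    """Hand-Till multiclass AUC: mean of all pairwise class AUCs.

    ``probs`` is an n x k matrix (or DataFrame with class columns) of
    class probabilities; rows must sum to 1.
    """
    true = np.asarray(true)
    if isinstance(probs, pd.DataFrame):
        classes = list(probs.columns)
        p = probs.to_numpy(dtype=float)
    else:
        p = np.asarray(probs, dtype=float)
        classes = sorted(set(map(str, true)))
        true = true.astype(str)
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    present = [c for c in classes if np.any(true.astype(str) == str(c))]
    if len(present) < 2:
        raise ValueError("need >= 2 classes present in the true labels")
    col = {c: j for j, c in enumerate(classes)}
    aucs = []
    t = true.astype(str)
    for a_i in range(len(present)):
        for b_i in range(a_i + 1, len(present)):
            a, b = str(present[a_i]), str(present[b_i])
            mask = (t == a) | (t == b)
            a_given_b = _binary_auc(p[mask, col[present[a_i]]], t[mask] == a)
            b_given_a = _binary_auc(p[mask, col[present[b_i]]], t[mask] == b)
            aucs.append((a_given_b + b_given_a) / 2.0)
    return float(np.mean(aucs))


def metrics_table(true, pred, probs=None) -> pd.DataFrame:
    """Full per-class metrics table; adds a per-class one-vs-rest AUC column
    when probabilities are supplied."""
    cm = confusion(true, pred)
    table = class_metrics(cm)
    if probs is not None:
        if not isinstance(probs, pd.DataFrame):
            raise ValueError("probs must be a DataFrame with class columns")
        t = np.asarray(true).astype(str)
        aucs = {}
        for cls in cm.classes:
            aucs[cls] = _binary_auc(
                probs[str(cls)].to_numpy(dtype=float), t == str(cls)
            )
        table["auc"] = pd.Series(aucs)
        table.loc["macro", "auc"] = np.nanmean(list(aucs.values()))
    return table


def pca_grid(model, x_train, y_train, x_test, y_test, resolution: int = 100):
    """Two-component PCA decision grid for plotting classifier boundaries.

    PCA(2) is fitted on the training set only; train and test samples are
    projected, a rectangular grid spanning the projected ranges (with a 5%
    margin) is built, and a fresh classifier of the same family/config is
    trained on the projected training data to label every grid node.

    Returns a dict with keys ``grid_x``, ``grid_y`` (resolution-length
    axes), ``grid_labels`` (resolution x resolution), ``train`` and
    ``test`` (DataFrames with pc1, pc2, label).
    """
    from .models import ModelConfig, train_model, predict as model_predict

    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    x_train = np.asarray(x_train, dtype=float)
    x_test = np.asarray(x_test, dtype=float)
    if x_train.shape[1] < 2:
        raise ValueError("need >= 2 features for a 2-component projection")
    pca = PCA(n_components=2)
    z_train = pca.fit_transform(x_train)
    z_test = pca.transform(x_test)

    config = model.config if hasattr(model, "config") else ModelConfig(family="RF")
    grid_model = train_model(z_train, np.asarray(y_train), config)

    allz = np.vstack([z_train, z_test])
    lo, hi = allz.min(axis=0), allz.max(axis=0)
    margin = 0.05 * (hi - lo)
    gx = np.linspace(lo[0] - margin[0], hi[0] + margin[0], resolution)
    gy = np.linspace(lo[1] - margin[1], hi[1] + margin[1], resolution)
    xx, yy = np.meshgrid(gx, gy)
    nodes = np.column_stack([xx.ravel(), yy.ravel()])
    labels, _, _ = model_predict(grid_model, nodes)
    return {
        "grid_x": gx,
        "grid_y": gy,
        "grid_labels": labels.reshape(resolution, resolution),
        "train": pd.DataFrame(
            {"pc1": z_train[:, 0], "pc2": z_train[:, 1], "label": np.asarray(y_train)}
        ),
        "test": pd.DataFrame(
            {"pc1": z_test[:, 0], "pc2": z_test[:, 1], "label": np.asarray(y_test)}
        ),
    }


def tsne_embed(x, dims: int = 2, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """t-SNE embedding (library-backed), deterministic for a given seed."""
    x = np.asarray(x, dtype=float)
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    if x.shape[0] <= 3 * perplexity:
        raise ValueError(
            f"n={x.shape[0]} too small for perplexity={perplexity} (need n > 3*perplexity)"
        )
    tsne = TSNE(
        n_components=dims, random_state=seed, init="pca", perplexity=perplexity
    )
    return tsne.fit_transform(x)


def heatmap_data(values: pd.DataFrame) -> dict:
    """Clustered heatmap export: value matrix plus row/column leaf orders.

    Rows and columns are ordered by hierarchical clustering with
    correlation distance and average linkage; rendering is left to any
    plotting layer.
    """
    v = values.to_numpy(dtype=float)

    def _order(mat: np.ndarray) -> np.ndarray:
        if mat.shape[0] < 3:
            return np.arange(mat.shape[0])
        sd = mat.std(axis=1)
        # correlation distance is undefined for constant rows; they sort last
        ok = sd > 0
        if ok.sum() < 3:
            return np.arange(mat.shape[0])
        lk = linkage(mat[ok], method="average", metric="correlation")
        leaves = np.flatnonzero(ok)[leaves_list(lk)]
        return np.concatenate([leaves, np.flatnonzero(~ok)])

    row_order = _order(v)
    col_order = _order(v.T)
    return {
        "values": values,
        "row_order": [values.index[i] for i in row_order],
        "col_order": [values.columns[i] for i in col_order],
    }
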