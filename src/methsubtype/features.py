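"""Probe selection, data splitting, SMOTE balancing, and gene collapsing.

The selection pipeline mirrors the two-step scheme used for methylation
classifiers: a variance screen keeping the top 5,000 probes by median
absolute deviation (MAD), then a random-forest importance ranking keeping
a fixed-size panel (default 399 probes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, KFold, train_test_split
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "SplitSpec",
    "SmoteParams",
    "mad_select",
    "rf_importance_select",
    "split_data",
    "make_folds",
    "smote",
    "balance_classes",
    "annotate_collapse",
]


@dataclass(frozen=True)
class SplitSpec:
    """Train/test (or train/val/test) split fractions and fold count."""

    train_frac: float = 0.8
    val_frac: float = 0.0
    k_folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must lie in (0, 1)")
        if not 0.0 <= self.val_frac < 1.0:
            raise ValueError("val_frac must lie in [0, 1)")
        if self.train_frac + self.val_frac >= 1.0:
            raise ValueError("train_frac + val_frac must leave room for a test set")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass(frozen=True)
class SmoteParams:
    """SMOTE settings: neighbour count and oversampling percentage."""

    k_neighbors: int = 5
    perc_over: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.perc_over <= 0 or self.perc_over % 100 != 0:
            raise ValueError("perc_over must be a positive multiple of 100")


def _mad(values: np.ndarray) -> np.ndarray:
    """Unscaled per-row MAD: median |x - median(x)|.

    The 1.4826 consistency factor is omitted — it never changes ranks.
    """
    med = np.median(values, axis=1, keepdims=True)
    return np.median(np.abs(values - med), axis=1)


def mad_select(beta: pd.DataFrame, n_top: int = 5000) -> list[str]:
    """Top ``n_top`` probes by MAD, ties broken by probe id (lexicographic)."""
    if n_top > beta.shape[0]:
        raise ValueError(f"n_top={n_top} exceeds number of probes {beta.shape[0]}")
    scores = pd.Series(_mad(beta.to_numpy(dtype=float)), index=beta.index)
    order = sorted(beta.index, key=lambda p: (-scores[p], p))
    return order[:n_top]


def rf_importance_select(
    beta_top: pd.DataFrame,
    labels,
    n_trees: int = 300,
    n_select: int = 399,
    seed: int = 0,
    method: str = "permutation",
) -> list[str]:
    """Random-forest importance panel over a variance-screened beta matrix.

    A forest of ``n_trees`` is grown on all probes; importance is
    aggregated across subgroups and the top ``n_select`` probes returned
    (ties broken by probe id).

    ``method="permutation"`` (default) is the classic out-of-bag
    mean-decrease-in-accuracy: for each tree, each feature the tree uses
    is permuted among that tree's out-of-bag samples and the drop in
    per-class OOB accuracy is recorded; drops are averaged over trees per
    class, then over classes ("importance across all subgroups").
    ``method="gini"`` uses the forest's impurity-based importance instead.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need >= 2 classes for importance ranking")
    if n_select > beta_top.shape[0]:
        raise ValueError("n_select exceeds the number of probes")
    x = beta_top.to_numpy(dtype=float).T  # samples x probes
    rf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1, oob_score=False
    )
    rf.fit(x, labels)

    if method == "gini":
        importance = rf.feature_importances_
    elif method == "permutation":
        importance = _oob_permutation_importance(rf, x, labels, seed)
    else:
        raise ValueError(f"unknown importance method {method!r}")

    scores = pd.Series(importance, index=beta_top.index)
    order = sorted(beta_top.index, key=lambda p: (-scores[p], p))
    return order[:n_select]


def _oob_permutation_importance(
    rf: RandomForestClassifier, x: np.ndarray, labels: np.ndarray, seed: int
) -> np.ndarray:
    """Per-class OOB permutation importance, averaged over classes.

    Only features a tree actually splits on are permuted for that tree
    (unused features have exactly zero effect), which keeps the cost at
    O(n_trees * features_per_tree) tree traversals.
    """
    from sklearn.ensemble._forest import (
        _generate_unsampled_indices,
        _get_n_samples_bootstrap,
    )

    rng = np.random.default_rng(seed)
    n_samples, n_feat = x.shape
    classes = rf.classes_
    k = len(classes)
    code = np.searchsorted(classes, labels)
    x32 = np.ascontiguousarray(x, dtype=np.float32)

    drop_sum = np.zeros((n_feat, k))
    try:  # sklearn >= 1.9 threads sample_weight through these helpers
        n_boot = _get_n_samples_bootstrap(n_samples, rf.max_samples, None)
    except TypeError:
        n_boot = _get_n_samples_bootstrap(n_samples, rf.max_samples)
    for tree in rf.estimators_:
        try:
            oob = _generate_unsampled_indices(tree.random_state, n_samples, n_boot, None)
        except TypeError:
            oob = _generate_unsampled_indices(tree.random_state, n_samples, n_boot)
        if len(oob) == 0:
            continue
        x_oob = x32[oob].copy()
        y_oob = code[oob]
        class_masks = [y_oob == c for c in range(k)]
        class_n = np.array([m.sum() for m in class_masks], dtype=float)
        base_pred = np.argmax(np.asarray(tree.tree_.predict(x_oob)).reshape(len(x_oob), -1), axis=1)
        base_correct = np.array(
            [np.sum(base_pred[m] == y_oob[m]) for m in class_masks], dtype=float
        )
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for j in used:
            saved = x_oob[:, j].copy()
            x_oob[:, j] = saved[rng.permutation(len(saved))]
            pred = np.argmax(np.asarray(tree.tree_.predict(x_oob)).reshape(len(x_oob), -1), axis=1)
            x_oob[:, j] = saved
            correct = np.array(
                [np.sum(pred[m] == y_oob[m]) for m in class_masks], dtype=float
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                drop = np.where(class_n > 0, (base_correct - correct) / class_n, 0.0)
            drop_sum[j] += drop
    per_class = drop_sum / rf.n_estimators
    return per_class.mean(axis=1)


def split_data(x, y, spec: SplitSpec) -> dict[str, np.ndarray]:
    """Disjoint train/test (and optionally validation) sample indices.

    Returns a dict with keys ``train``, ``test`` and, when
    ``spec.val_frac > 0``, ``val``; indices cover every sample exactly once
    and class proportions are preserved under stratification.
    """
    y = np.asarray(y)
    n = len(y)
    if n < 5:
        raise ValueError("need >= 5 samples to split")
    strat = y if spec.stratified else None
    if spec.stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < 2:
            raise ValueError("stratified split needs >= 2 samples per class")
    idx = np.arange(n)
    test_size = 1.0 - spec.train_frac - spec.val_frac
    train_val, test = train_test_split(
        idx, test_size=test_size, stratify=strat, random_state=spec.seed
    )
    if spec.val_frac == 0:
        return {"train": np.sort(train_val), "test": np.sort(test)}
    rel_val = spec.val_frac / (spec.train_frac + spec.val_frac)
    strat2 = y[train_val] if spec.stratified else None
    train, val = train_test_split(
        train_val, test_size=rel_val, stratify=strat2, random_state=spec.seed + 1
    )
    return {"train": np.sort(train), "val": np.sort(val), "test": np.sort(test)}


def make_folds(y, k: int = 10, seed: int = 0, stratified: bool = True) -> list[np.ndarray]:
    """k test-index sets partitioning all samples, sizes differing by <= 1."""
    y = np.asarray(y)
    if k > len(y):
        raise ValueError("k cannot exceed the number of samples")
    if stratified and np.unique(y, return_counts=True)[1].min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros_like(y), y)]


def smote(x_minority, params: SmoteParams) -> np.ndarray:
    """Synthetic minority samples by nearest-neighbour interpolation.

    For each original sample, ``perc_over / 100`` synthetic points are
    created as ``x + u * (neighbour - x)`` with u ~ Uniform(0, 1) and the
    neighbour drawn among the sample's ``k_neighbors`` nearest minority
    neighbours, so every synthetic coordinate lies within the segment
    between its two parents.
    """
    x = np.asarray(x_minority, dtype=float)
    if x.ndim != 2:
        raise ValueError("x_minority must be 2-D (samples x features)")
    n = x.shape[0]
    if n <= params.k_neighbors:
        raise ValueError(
            f"minority count {n} must exceed k_neighbors={params.k_neighbors}"
        )
    rng = np.random.default_rng(params.seed)
    nn = NearestNeighbors(n_neighbors=params.k_neighbors + 1).fit(x)
    _, neighbours = nn.kneighbors(x)  # first column is self
    n_per = params.perc_over // 100
    synthetic = np.empty((n * n_per, x.shape[1]))
    row = 0
    for i in range(n):
        for _ in range(n_per):
            j = neighbours[i, rng.integers(1, params.k_neighbors + 1)]
            u = rng.uniform()
            synthetic[row] = x[i] + u * (x[j] - x[i])
            row += 1
    return synthetic


def balance_classes(
    x, y, params: SmoteParams, minority: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample minority class(es) with SMOTE.

    When ``minority`` names a class, only that class is oversampled at
    ``params.perc_over`` (the 70 -> 210 scheme).  Otherwise every
    non-majority class is topped up towards the majority size using whole
    SMOTE rounds.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    parts_x, parts_y = [x], [y]
    if minority is not None:
        if minority not in classes:
            raise ValueError(f"class {minority!r} not present")
        synth = smote(x[y == minority], params)
        parts_x.append(synth)
        parts_y.append(np.full(len(synth), minority, dtype=y.dtype))
    else:
        majority = counts.max()
        for c, cnt in zip(classes, counts):
            if cnt == majority:
                continue
            rounds = int(np.floor((majority - cnt) / cnt)) * 100
            if rounds < 100:
                continue
            p = SmoteParams(
                k_neighbors=min(params.k_neighbors, cnt - 1),
                perc_over=rounds,
                seed=params.seed,
            )
            synth = smote(x[y == c], p)
            parts_x.append(synth)
            parts_y.append(np.full(len(synth), c, dtype=y.dtype))
    return np.vstack(parts_x), np.concatenate(parts_y)


def annotate_collapse(
    probes: list[str], values: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Collapse probe-level betas to gene level by per-gene median.

    Probes without a gene symbol are dropped; where several probes map to
    the same gene, the per-sample median over those probes is taken.
    Returns a genes x samples matrix with a unique gene index.
    """
    ann = annotation.set_index("probe_id")
    missing = [p for p in probes if p not in ann.index]
    if missing:
        raise KeyError(f"{len(missing)} probes missing from annotation")
    genes = ann.loc[probes, "gene"].fillna("")
    keep = [p for p, g in zip(probes, genes) if g != ""]
    if not keep:
        warnings.warn("no probe carries a gene annotation; result is empty")
        return pd.DataFrame(columns=values.columns)
    sub = values.loc[keep]
    sub = sub.assign(_gene=ann.loc[keep, "gene"].to_numpy())
    collapsed = sub.groupby("_gene").median()
    collapsed.index.name = "gene"
    return collapsed
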