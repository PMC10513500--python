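"""Seven classifier families behind one train/predict contract.

Families: random forest (RF, 300 trees, max 6 terminal nodes), support
vector machine (SVM, RBF kernel), k-nearest neighbours (KNN, k=3),
Gaussian naive Bayes (NB, 0.8 probability threshold for a low-confidence
flag), gradient-boosted trees (XGB), linear discriminant analysis (LDA),
and a feed-forward neural net (ANN, 40-30-10-k with leaky-ReLU/softmax).
Every family exposes the same ``train_model`` / ``predict`` surface and
records its resolved hyperparameters, class order, and feature ids.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score, f1_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .ann import AnnConfig, NeuralNetClassifier

__all__ = [
    "FAMILIES",
    "ModelConfig",
    "AnnConfig",
    "TrainedModel",
    "train_model",
    "train_ann",
    "predict",
    "cross_validate",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

FAMILIES = ("RF", "SVM", "KNN", "NB", "XGB", "LDA", "ANN")

_DEFAULTS: dict[str, dict[str, Any]] = {
    "RF": {"n_trees": 300, "max_terminal_nodes": 6},
    "SVM": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
    "KNN": {"k": 3},
    "NB": {"prob_threshold": 0.8},
    "XGB": {},
    "LDA": {},
    "ANN": {},
}


@dataclass(frozen=True)
class ModelConfig:
    """Classifier family plus hyperparameter overrides and seed."""

    family: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        unknown = set(self.params) - set(_DEFAULTS[self.family]) - {"ann"}
        if self.family != "ANN" and unknown:
            raise ValueError(f"unknown hyperparameters for {self.family}: {sorted(unknown)}")

    def resolved(self) -> dict[str, Any]:
        out = dict(_DEFAULTS[self.family])
        out.update(self.params)
        return out


@dataclass
class TrainedModel:
    """Opaque fitted classifier handle with its training metadata."""

    config: ModelConfig
    estimator: Any
    classes: list
    feature_ids: list[str]
    n_train: int
    resolved_params: dict[str, Any]
    trained_at: str = ""

    def __post_init__(self) -> None:
        if not self.trained_at:
            self.trained_at = datetime.now(timezone.utc).isoformat()


def _build_estimator(config: ModelConfig, n_classes: int):
    p = config.resolved()
    family = config.family
    if family == "RF":
        return RandomForestClassifier(
            n_estimators=p["n_trees"],
            max_leaf_nodes=p["max_terminal_nodes"],
            random_state=config.seed,
            n_jobs=1,
        )
    if family == "SVM":
        return SVC(
            kernel=p["kernel"], C=p["C"], gamma=p["gamma"],
            probability=True, random_state=config.seed,
        )
    if family == "KNN":
        return KNeighborsClassifier(n_neighbors=p["k"])
    if family == "NB":
        return GaussianNB()
    if family == "XGB":
        return XGBClassifier(
            random_state=config.seed, n_jobs=1, verbosity=0,
            objective="multi:softprob" if n_classes > 2 else "binary:logistic",
        )
    if family == "LDA":
        return LinearDiscriminantAnalysis()
    if family == "ANN":
        ann_cfg = config.params.get("ann")
        if ann_cfg is None:
            ann_cfg = AnnConfig(
                layer_sizes=(40, 30, 10, n_classes), seed=config.seed
            )
        return NeuralNetClassifier(ann_cfg)
    raise AssertionError(family)


def train_model(x, y, config: ModelConfig, feature_ids=None) -> TrainedModel:
    """Fit one classifier family; deterministic for a given config + seed."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape[0] != len(y):
        raise ValueError("feature matrix and labels disagree on sample count")
    if np.isnan(x).any():
        raise ValueError("missing values not allowed")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes to train")
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(x.shape[1])]
    if len(feature_ids) != x.shape[1]:
        raise ValueError("feature_ids length must match the feature dimension")

    est = _build_estimator(config, len(classes))
    if config.family == "XGB":
        codes = np.searchsorted(classes, y)
        est.fit(x, codes)
    else:
        est.fit(x, y)
    resolved = config.resolved()
    if config.family in ("SVM", "XGB", "LDA"):
        # record library defaults actually in force, for the run log
        resolved = {**resolved, "library_params": _loggable_params(est)}
        logger.info("%s resolved hyperparameters: %s", config.family, resolved)
    return TrainedModel(
        config=config,
        estimator=est,
        classes=list(classes),
        feature_ids=list(feature_ids),
        n_train=x.shape[0],
        resolved_params=resolved,
    )


def _loggable_params(est) -> dict[str, Any]:
    out = {}
    for k, v in est.get_params().items():
        if isinstance(v, (int, float, str, bool, type(None))):
            out[k] = v
    return out


def train_ann(
    x, y, config: AnnConfig | None = None, val_frac: float = 0.2, feature_ids=None
) -> TrainedModel:
    """Fit the feed-forward net with an internal validation split.

    Training halts at the configured epoch budget or when validation loss
    fails to improve for ``early_stop_patience`` consecutive epochs,
    whichever comes first; the best-validation weights are restored.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    cfg = config or AnnConfig(layer_sizes=(40, 30, 10, len(classes)))
    model_config = ModelConfig(family="ANN", params={"ann": cfg}, seed=cfg.seed)
    x = np.asarray(x, dtype=float)
    est = NeuralNetClassifier(cfg)
    est.fit(x, y, val_frac=val_frac)
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(x.shape[1])]
    return TrainedModel(
        config=model_config,
        estimator=est,
        classes=list(est.classes_),
        feature_ids=list(feature_ids),
        n_train=x.shape[0],
        resolved_params={"ann": cfg.__dict__},
    )


def predict(model: TrainedModel, x, feature_ids=None):
    """Labels, class-probability matrix, and low-confidence flags.

    Probability rows sum to 1; the predicted label is the argmax class.
    For naive Bayes a flag marks samples whose maximum posterior falls
    below the configured threshold (default 0.8); the argmax label is
    still emitted (there is no reject class).
    """
    x = np.asarray(x, dtype=float)
    if feature_ids is not None and list(feature_ids) != model.feature_ids:
        raise ValueError("feature ids do not match the training features")
    if x.shape[1] != len(model.feature_ids):
        raise ValueError(
            f"expected {len(model.feature_ids)} features, got {x.shape[1]}"
        )
    est = model.estimator
    probs = est.predict_proba(x)
    classes = np.asarray(model.classes)
    labels = classes[np.argmax(probs, axis=1)]
    flags = np.zeros(len(labels), dtype=bool)
    if model.config.family == "NB":
        threshold = model.config.resolved()["prob_threshold"]
        flags = probs.max(axis=1) < threshold
    probs_df = pd.DataFrame(probs, columns=[str(c) for c in classes])
    return labels, probs_df, flags


def cross_validate(x, y, config: ModelConfig, folds) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-fold accuracy / balanced accuracy / macro-F1 plus mean +- sd.

    ``folds`` is a list of test-index arrays partitioning the samples;
    each fold's model is trained on the complement.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    all_idx = np.concatenate(folds)
    if len(np.unique(all_idx)) != len(y):
        raise ValueError("folds must partition all samples")
    rows = []
    for i, test_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        if len(np.unique(y[train_mask])) < 2:
            raise ValueError(f"fold {i}: training partition has a single class")
        model = train_model(x[train_mask], y[train_mask], config)
        pred, _, _ = predict(model, x[test_idx])
        rows.append(
            {
                "fold": i,
                "n_test": len(test_idx),
                "accuracy": float(np.mean(pred == y[test_idx])),
                "balanced_accuracy": balanced_accuracy_score(y[test_idx], pred),
                "macro_f1": f1_score(y[test_idx], pred, average="macro"),
            }
        )
    per_fold = pd.DataFrame(rows)
    metrics = ["accuracy", "balanced_accuracy", "macro_f1"]
    summary = pd.DataFrame(
        {"mean": per_fold[metrics].mean(), "sd": per_fold[metrics].std(ddof=1)}
    )
    return per_fold, summary


def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Serialize a model as a directory with config JSON + pickled weights."""
    import pickle

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "family": model.config.family,
        "seed": model.config.seed,
        "classes": [str(c) for c in model.classes],
        "feature_ids": model.feature_ids,
        "n_train": model.n_train,
        "trained_at": model.trained_at,
        "resolved_params": {
            k: v for k, v in model.resolved_params.items() if _json_safe(v)
        },
        "format_version": 1,
    }
    (path / "config.json").write_text(json.dumps(meta, indent=2))
    with open(path / "estimator.pkl", "wb") as fh:
        pickle.dump(model, fh)
    return path


def load_model(path: str | Path) -> TrainedModel:
    import pickle

    with open(Path(path) / "estimator.pkl", "rb") as fh:
        return pickle.load(fh)


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
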