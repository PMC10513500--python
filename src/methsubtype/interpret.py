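"""Sampling-based Shapley explanations of classifier predictions.

Implements the Strumbelj-Kononenko Monte-Carlo estimator: for each of m
draws, sample a random feature permutation and a random background row,
then credit feature j with the change in predicted class probability when
j switches from the background value to the instance value, with the
features preceding j in the permutation already set to the instance.
Averaged over draws this converges to the exact Shapley value of the
coalition game "features present vs. absent", on the probability scale
per class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ShapleyExplanation", "shapley_explain", "explain_subgroups"]


@dataclass
class ShapleyExplanation:
    """Per-(feature, class) Shapley contributions for one explained instance.

    ``phi`` and ``mc_se`` are feature x class DataFrames; ``baseline`` is
    the mean background prediction per class, so local accuracy reads
    ``phi.sum(axis=0) ~= prediction - baseline``.
    """

    phi: pd.DataFrame
    mc_se: pd.DataFrame
    baseline: pd.Series
    prediction: pd.Series
    instance: pd.Series
    m_samples: int

    def to_frame(self) -> pd.DataFrame:
        """Long-form (feature, beta_value, class, phi, mc_se) table."""
        rows = []
        for feature in self.phi.index:
            for cls in self.phi.columns:
                rows.append(
                    {
                        "feature": feature,
                        "beta_value": self.instance[feature],
                        "class": cls,
                        "phi": self.phi.loc[feature, cls],
                        "mc_se": self.mc_se.loc[feature, cls],
                    }
                )
        return pd.DataFrame(rows)


def shapley_explain(
    predict_fn,
    background,
    instance,
    m_samples: int = 1000,
    seed: int = 0,
    class_names=None,
    feature_names=None,
) -> ShapleyExplanation:
    """Monte-Carlo Shapley values for one instance.

    Parameters
    ----------
    predict_fn
        Maps an (n, d) matrix to an (n, k) matrix of class probabilities
        (a single-output function returning (n,) is also accepted).
    background
        Reference feature matrix the "absent" feature values are drawn from.
    instance
        The explained feature vector, length d.
    m_samples
        Number of permutation/background draws.
    """
    if m_samples < 1:
        raise ValueError("m_samples must be >= 1")
    background = np.asarray(background, dtype=float)
    if background.ndim != 2 or background.shape[0] == 0:
        raise ValueError("background must be a non-empty 2-D matrix")
    instance = np.asarray(instance, dtype=float).ravel()
    d = background.shape[1]
    if instance.shape[0] != d:
        raise ValueError("instance and background feature dimensions differ")

    rng = np.random.default_rng(seed)

    def _predict(mat: np.ndarray) -> np.ndarray:
        out = np.asarray(predict_fn(mat), dtype=float)
        if out.ndim == 1:
            out = out[:, None]
        return out

    k = _predict(instance[None, :]).shape[1]
    contrib = np.zeros((m_samples, d, k))

    # each draw needs d+1 model evaluations (background -> fully-instance
    # chain along the permutation); evaluate them in one batched call
    for s in range(m_samples):
        perm = rng.permutation(d)
        b = background[rng.integers(background.shape[0])]
        chain = np.tile(b, (d + 1, 1))
        current = b.copy()
        for t, j in enumerate(perm):
            current[j] = instance[j]
            chain[t + 1] = current
        preds = _predict(chain)
        diffs = preds[1:] - preds[:-1]  # marginal of perm[t] at step t
        contrib[s, perm, :] = diffs

    phi = contrib.mean(axis=0)
    se = contrib.std(axis=0, ddof=1) / np.sqrt(m_samples) if m_samples > 1 else np.zeros_like(phi)

    if feature_names is None:
        feature_names = [f"f{i}" for i in range(d)]
    if class_names is None:
        class_names = [f"class{i}" for i in range(k)]
    baseline = _predict(background).mean(axis=0)
    prediction = _predict(instance[None, :])[0]
    return ShapleyExplanation(
        phi=pd.DataFrame(phi, index=feature_names, columns=class_names),
        mc_se=pd.DataFrame(se, index=feature_names, columns=class_names),
        baseline=pd.Series(baseline, index=class_names),
        prediction=pd.Series(prediction, index=class_names),
        instance=pd.Series(instance, index=feature_names),
        m_samples=m_samples,
    )


def explain_subgroups(
    model,
    x_train,
    instances: pd.DataFrame,
    instance_labels,
    m_samples: int = 1000,
    seed: int = 0,
) -> dict[str, ShapleyExplanation]:
    """One Shapley explanation per subgroup instance.

    ``instances`` holds one row per explained sample (samples x features);
    ``instance_labels`` gives each row's subgroup, and every model class
    must appear exactly once.  Contributions are reported for all classes,
    not only the instance's own.
    """
    from .models import predict as model_predict

    labels = list(instance_labels)
    missing = set(map(str, model.classes)) - set(map(str, labels))
    if missing:
        raise ValueError(f"no instance provided for class(es): {sorted(missing)}")
    x_train = np.asarray(x_train, dtype=float)

    def predict_fn(mat):
        _, probs, _ = model_predict(model, mat)
        return probs.to_numpy()

    out = {}
    for i, label in enumerate(labels):
        out[str(label)] = shapley_explain(
            predict_fn,
            x_train,
            instances.iloc[i].to_numpy(dtype=float),
            m_samples=m_samples,
            seed=seed + i,
            class_names=[str(c) for c in model.classes],
            feature_names=list(instances.columns),
        )
    return out
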