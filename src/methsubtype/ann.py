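"""Compact feed-forward neural network for subgroup classification.

A four-dense-layer net (40, 30, 10, k) with leaky-ReLU hidden activations
and a softmax output, trained by mini-batch stochastic gradient descent
with Nesterov momentum, per-step learning-rate decay, inverted dropout,
an L2 penalty on the second layer's weights, categorical cross-entropy
loss, and early stopping on validation loss.  Written directly in numpy;
the network is small enough that this trains in seconds on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AnnConfig", "NeuralNetClassifier"]


@dataclass(frozen=True)
class AnnConfig:
    """Architecture and optimizer settings for the feed-forward net."""

    layer_sizes: tuple[int, ...] = (40, 30, 10, 4)
    dropout: tuple[float, ...] = (0.5, 0.4, 0.1)
    l2_on_layer2: float = 0.009
    epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 0.03
    decay: float = 0.00006
    momentum: float = 0.05
    nesterov: bool = True
    early_stop_patience: int = 5
    leaky_alpha: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2:
            raise ValueError("need at least one hidden layer and an output layer")
        if len(self.dropout) != len(self.layer_sizes) - 1:
            raise ValueError("one dropout rate per hidden layer required")
        if any(not 0.0 <= r < 1.0 for r in self.dropout):
            raise ValueError("dropout rates must lie in [0, 1)")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid optimizer settings")


def _leaky_relu(z: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(z > 0, z, alpha * z)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class NeuralNetClassifier:
    """Multiclass MLP with the training scheme described in :class:`AnnConfig`.

    Parameters are validated against the number of classes at fit time
    (the output layer width must equal ``len(classes_)``).
    """

    def __init__(self, config: AnnConfig | None = None):
        self.config = config or AnnConfig()
        self.classes_: np.ndarray | None = None
        self.weights_: list[np.ndarray] = []
        self.biases_: list[np.ndarray] = []
        self.history_: dict[str, list[float]] = {}

    # ----------------------------------------------------------------- fit
    def fit(self, x: np.ndarray, y, val_frac: float = 0.2) -> "NeuralNetClassifier":
        cfg = self.config
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
        if x.shape[0] < 20:
            raise ValueError("need >= 20 samples to train the network")
        self.classes_ = np.unique(y)
        k = len(self.classes_)
        if cfg.layer_sizes[-1] != k:
            raise ValueError(
                f"output layer width {cfg.layer_sizes[-1]} != number of classes {k}"
            )
        onehot = (y[:, None] == self.classes_[None, :]).astype(float)

        rng = np.random.default_rng(cfg.seed)
        n = x.shape[0]
        perm = rng.permutation(n)
        n_val = max(1, int(round(val_frac * n)))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        xt, yt = x[train_idx], onehot[train_idx]
        xv, yv = x[val_idx], onehot[val_idx]

        sizes = [x.shape[1], *cfg.layer_sizes]
        self.weights_ = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.biases_ = [np.zeros(s) for s in sizes[1:]]
        vel_w = [np.zeros_like(w) for w in self.weights_]
        vel_b = [np.zeros_like(b) for b in self.biases_]

        best_loss = np.inf
        best_state = None
        patience_left = cfg.early_stop_patience
        step = 0
        self.history_ = {"train_loss": [], "val_loss": []}

        for epoch in range(cfg.epochs):
            order = rng.permutation(len(xt))
            epoch_loss = 0.0
            for start in range(0, len(xt), cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                loss = self._sgd_step(xt[batch], yt[batch], vel_w, vel_b, step, rng)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        "training loss diverged (NaN/inf); lower the learning rate"
                    )
                epoch_loss += loss * len(batch)
                step += 1
            val_loss = self._loss(xv, yv)
            self.history_["train_loss"].append(epoch_loss / len(xt))
            self.history_["val_loss"].append(val_loss)
            if val_loss < best_loss - 1e-8:
                best_loss = val_loss
                best_state = ([w.copy() for w in self.weights_],
                              [b.copy() for b in self.biases_])
                patience_left = cfg.early_stop_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
        if best_state is not None:
            self.weights_, self.biases_ = best_state
        return self

    def _forward_train(self, x: np.ndarray, rng: np.random.Generator):
        cfg = self.config
        activations = [x]
        pre = []
        masks = []
        h = x
        for li, (w, b) in enumerate(zip(self.weights_, self.biases_)):
            z = h @ w + b
            pre.append(z)
            if li < len(self.weights_) - 1:
                h = _leaky_relu(z, cfg.leaky_alpha)
                rate = cfg.dropout[li]
                if rate > 0:
                    mask = (rng.random(h.shape) >= rate) / (1.0 - rate)
                else:
                    mask = np.ones_like(h)
                h = h * mask
                masks.append(mask)
            else:
                h = _softmax(z)
            activations.append(h)
        return activations, pre, masks

    def _sgd_step(self, xb, yb, vel_w, vel_b, step, rng) -> float:
        cfg = self.config
        lr = cfg.learning_rate / (1.0 + cfg.decay * step)
        acts, pre, masks = self._forward_train(xb, rng)
        probs = acts[-1]
        m = len(xb)
        eps = 1e-12
        loss = -np.mean(np.sum(yb * np.log(probs + eps), axis=1))
        loss += 0.5 * cfg.l2_on_layer2 * np.sum(self.weights_[1] ** 2)

        delta = (probs - yb) / m
        grads_w = [None] * len(self.weights_)
        grads_b = [None] * len(self.biases_)
        for li in range(len(self.weights_) - 1, -1, -1):
            grads_w[li] = acts[li].T @ delta
            grads_b[li] = delta.sum(axis=0)
            if li == 1:
                grads_w[li] = grads_w[li] + cfg.l2_on_layer2 * self.weights_[li]
            if li > 0:
                upstream = delta @ self.weights_[li].T
                upstream = upstream * masks[li - 1]
                grad_act = np.where(pre[li - 1] > 0, 1.0, cfg.leaky_alpha)
                delta = upstream * grad_act

        for li in range(len(self.weights_)):
            vel_w[li] = cfg.momentum * vel_w[li] - lr * grads_w[li]
            vel_b[li] = cfg.momentum * vel_b[li] - lr * grads_b[li]
            if cfg.nesterov:
                self.weights_[li] += cfg.momentum * vel_w[li] - lr * grads_w[li]
                self.biases_[li] += cfg.momentum * vel_b[li] - lr * grads_b[li]
            else:
                self.weights_[li] += vel_w[li]
                self.biases_[li] += vel_b[li]
        return float(loss)

    # ------------------------------------------------------------- predict
    def _loss(self, x, onehot) -> float:
        probs = self.predict_proba(x)
        return float(-np.mean(np.sum(onehot * np.log(probs + 1e-12), axis=1)))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if self.classes_ is None:
            raise RuntimeError("model is not fitted")
        h = np.asarray(x, dtype=float)
        for li, (w, b) in enumerate(zip(self.weights_, self.biases_)):
            z = h @ w + b
            if li < len(self.weights_) - 1:
                h = _leaky_relu(z, self.config.leaky_alpha)
            else:
                h = _softmax(z)
        return h

    def predict(self, x: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(x)
        return self.classes_[np.argmax(probs, axis=1)]

    @property
    def layer_widths(self) -> tuple[int, ...]:
        """Widths of the dense layers, e.g. (40, 30, 10, 4)."""
        return tuple(w.shape[1] for w in self.weights_) if self.weights_ else self.config.layer_sizes
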