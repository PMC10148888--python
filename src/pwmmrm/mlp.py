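"""Multilayer perceptron for placebo-response propensity, trained by backprop.

A deliberately small, fully deterministic implementation: logistic activations
in every layer (hidden and output), full-batch gradient descent with a
backtracking (Armijo) line search, optional L2 penalty, and a seeded
initialization.  At the data sizes of a single clinical trial this is both
fast and exactly reproducible, which matters more here than stochastic
optimization tricks: the fitted probabilities become per-subject analysis
weights, so the whole downstream analysis must be replayable from a seed.

Inputs are standardized to zero mean / unit variance with training-set
statistics; the constants are stored inside the model so prediction on new
subjects applies the identical transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrainConfig", "MLPNet", "DivergenceError", "init_net", "train_mlp"]


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass
class TrainConfig:
    """Full-batch training settings.

    ``loss`` is binary cross-entropy by default (the standard choice for a
    probability output); a sum-of-squares alternative is selectable.  ``tol``
    stops training when the loss decrease over an accepted step falls below
    it; ``l2`` is the ridge penalty on connection weights (not biases).
    """

    loss: str = "cross_entropy"  # or "sse"
    max_epochs: int = 300
    tol: float = 1e-8
    l2: float = 1e-2
    step0: float = 1.0
    armijo_c: float = 1e-4
    max_halvings: int = 40

    def __post_init__(self) -> None:
        if self.loss not in ("cross_entropy", "sse"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be nonnegative")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class MLPNet:
    """A trained (or freshly initialized) network.

    ``weights[l]`` has shape ``(n_l, n_{l-1})`` mapping layer ``l-1`` onto
    layer ``l``; the final layer has a single logistic output, so predictions
    are strictly inside (0, 1) for finite inputs.
    """

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_mean: np.ndarray
    x_scale: np.ndarray
    loss_trace: list[float] = field(default_factory=list)

    @property
    def hidden_sizes(self) -> tuple[int, ...]:
        return self.layer_sizes[1:-1]

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Predicted probability for each row of ``X`` (raw feature scale)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.layer_sizes[0]:
            raise ValueError(
                f"input has {X.shape[1]} features, model expects {self.layer_sizes[0]}"
            )
        a = (X - self.x_mean) / self.x_scale
        for W, b in zip(self.weights, self.biases):
            a = _sigmoid(a @ W.T + b)
        return a[:, 0]

    # -- JSON (de)serialization ------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "layer_sizes": list(self.layer_sizes),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json_dict(cls, d: dict) -> "MLPNet":
        return cls(
            layer_sizes=tuple(d["layer_sizes"]),
            weights=[np.asarray(w, dtype=float) for w in d["weights"]],
            biases=[np.asarray(b, dtype=float) for b in d["biases"]],
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_scale=np.asarray(d["x_scale"], dtype=float),
        )

    @classmethod
    def load(cls, path: str) -> "MLPNet":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def init_net(
    n_features: int,
    hidden: tuple[int, ...],
    rng: np.random.Generator,
    x_mean: np.ndarray | None = None,
    x_scale: np.ndarray | None = None,
) -> MLPNet:
    """Seeded Glorot-uniform initialization; identity standardization by default."""
    sizes = (n_features, *hidden, 1)
    weights, biases = [], []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (n_in + n_out))
        weights.append(rng.uniform(-limit, limit, size=(n_out, n_in)))
        biases.append(np.zeros(n_out))
    return MLPNet(
        layer_sizes=sizes,
        weights=weights,
        biases=biases,
        x_mean=np.zeros(n_features) if x_mean is None else np.asarray(x_mean, float),
        x_scale=np.ones(n_features) if x_scale is None else np.asarray(x_scale, float),
    )


def _loss_and_grad(
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    Xs: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
):
    """Penalized loss and its gradient by backpropagation (standardized X)."""
    n = Xs.shape[0]
    activations = [Xs]
    a = Xs
    for W, b in zip(weights, biases):
        a = _sigmoid(a @ W.T + b)
        activations.append(a)
    p = np.clip(activations[-1][:, 0], 1e-12, 1 - 1e-12)

    if cfg.loss == "cross_entropy":
        data_loss = -np.mean(y * np.log(p) + (1 - y) * np.log1p(-p))
        delta = ((p - y) / n)[:, None]  # dJ/dz at the output
    else:  # sum of squares
        data_loss = 0.5 * np.mean((p - y) ** 2)
        delta = ((p - y) * p * (1 - p) / n)[:, None]

    penalty = 0.5 * cfg.l2 / n * sum(float(np.sum(W**2)) for W in weights)
    loss = data_loss + penalty

    grad_W = [np.empty_like(W) for W in weights]
    grad_b = [np.empty_like(b) for b in biases]
    for layer in range(len(weights) - 1, -1, -1):
        a_prev = activations[layer]
        grad_W[layer] = delta.T @ a_prev + (cfg.l2 / n) * weights[layer]
        grad_b[layer] = delta.sum(axis=0)
        if layer > 0:
            delta = (delta @ weights[layer]) * a_prev * (1 - a_prev)
    return loss, grad_W, grad_b


def _flatten(grads_W, grads_b) -> np.ndarray:
    return np.concatenate([g.ravel() for g in grads_W] + [g.ravel() for g in grads_b])


def train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    hidden: tuple[int, ...],
    cfg: TrainConfig | None = None,
    seed: int = 0,
) -> MLPNet:
    """Train a network on item-change features ``X`` and binary labels ``y``.

    Deterministic given ``seed``.  The accepted-step loss trace is retained on
    the returned model for diagnostics and is monotone nonincreasing by
    construction of the line search.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per label")
    if X.shape[0] < 2 or len(np.unique(y)) < 2:
        raise ValueError("training requires at least two subjects with both labels")

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    Xs = (X - x_mean) / x_scale

    rng = np.random.default_rng(seed)
    net = init_net(X.shape[1], tuple(hidden), rng, x_mean=x_mean, x_scale=x_scale)
    W, b = net.weights, net.biases

    loss, gW, gb = _loss_and_grad(W, b, Xs, y, cfg)
    if not np.isfinite(loss):
        raise DivergenceError("non-finite loss at epoch 0")
    trace = [loss]
    step = cfg.step0
    for epoch in range(cfg.max_epochs):
        gnorm2 = float(np.sum(_flatten(gW, gb) ** 2))
        if gnorm2 < 1e-20:
            break
        # backtracking line search on the steepest-descent direction
        accepted = False
        for _ in range(cfg.max_halvings):
            W_new = [w - step * g for w, g in zip(W, gW)]
            b_new = [bb - step * g for bb, g in zip(b, gb)]
            loss_new, gW_new, gb_new = _loss_and_grad(W_new, b_new, Xs, y, cfg)
            if not np.isfinite(loss_new):
                raise DivergenceError(f"non-finite loss at epoch {epoch + 1}")
            if loss_new <= loss - cfg.armijo_c * step * gnorm2:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        decrease = loss - loss_new
        W, b, loss, gW, gb = W_new, b_new, loss_new, gW_new, gb_new
        trace.append(loss)
        step = min(step * 2.0, 1e3)
        if decrease < cfg.tol:
            break

    net.weights, net.biases = W, b
    net.loss_trace = trace
    return net
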