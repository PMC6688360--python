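"""Single-hidden-layer autoencoder for feature compression.

The network maps x -> a = sigma(W1 x + b_e) -> h = sigma(W2 a + b_d) and
is trained by full-batch gradient descent on the mean squared
reconstruction error, so that the bottleneck activation a is a compressed
representation of the input.  Inputs are expected on the [0, 1] scale
(the sigmoid output range); use ``MinMaxScaler`` fit on training data.

Everything is plain numpy: the matrices involved are small (hundreds of
samples by at most a few hundred features), weights are initialised from
a seeded Glorot-uniform draw, and training is bit-reproducible for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AEModel", "AETrainConfig", "ae_train", "ae_encode", "ae_reconstruct"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class AETrainConfig:
    """Gradient-descent hyperparameters for autoencoder training.

    Full-batch gradient descent with classical momentum; the defaults
    (200 epochs, learning rate 1.0, momentum 0.9) bring the reconstruction
    error of the pipeline's three blocks close to its floor — plain descent
    with a small step underfits badly at this epoch budget, leaving the
    bottleneck uninformative.  Set ``momentum=0`` for plain descent.
    """

    epochs: int = 200
    learning_rate: float = 1.0
    momentum: float = 0.9
    seed: int = 42
    activation: str = "sigmoid"  # "sigmoid" or "linear" (for analysis)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if self.activation not in ("sigmoid", "linear"):
            raise ValueError("activation must be 'sigmoid' or 'linear'")


@dataclass
class AEModel:
    """Trained weights of a one-hidden-layer autoencoder."""

    W1: np.ndarray  # (hidden_dim, input_dim)
    W2: np.ndarray  # (input_dim, hidden_dim)
    bias_e: np.ndarray
    bias_d: np.ndarray
    activation: str = "sigmoid"
    loss_history: list[float] = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.W1.shape[1]

    @property
    def hidden_dim(self) -> int:
        return self.W1.shape[0]

    def _act(self, z: np.ndarray) -> np.ndarray:
        return _sigmoid(z) if self.activation == "sigmoid" else z


def ae_train(
    X: np.ndarray, hidden_dim: int, cfg: AETrainConfig = AETrainConfig()
) -> AEModel:
    """Train an autoencoder on the rows of X by full-batch gradient descent.

    Deterministic for a fixed ``cfg.seed``.  Raises on NaN loss; warns
    (via the returned model, without failing) when hidden_dim >= input_dim
    since no compression takes place.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a nonempty 2-D array of training rows")
    n, d = X.shape
    if hidden_dim >= d:
        import warnings

        warnings.warn(
            f"hidden_dim={hidden_dim} >= input_dim={d}: no compression",
            stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed)
    limit1 = np.sqrt(6.0 / (d + hidden_dim))
    W1 = rng.uniform(-limit1, limit1, size=(hidden_dim, d))
    W2 = rng.uniform(-limit1, limit1, size=(d, hidden_dim))
    b_e = np.zeros(hidden_dim)
    b_d = np.zeros(d)
    sigmoid = cfg.activation == "sigmoid"
    lr = cfg.learning_rate
    history: list[float] = []
    vel = [np.zeros_like(p) for p in (W1, W2, b_e, b_d)]

    for _ in range(cfg.epochs):
        Z1 = X @ W1.T + b_e
        A = _sigmoid(Z1) if sigmoid else Z1
        Z2 = A @ W2.T + b_d
        H = _sigmoid(Z2) if sigmoid else Z2
        R = H - X
        loss = float(np.mean(np.sum(R**2, axis=1)))  # per-sample squared error
        if not np.isfinite(loss):
            raise FloatingPointError("autoencoder training diverged (NaN loss)")
        history.append(loss)
        # dL/dZ2 for L = mean over samples of the summed squared residual
        G2 = (2.0 / n) * R
        if sigmoid:
            G2 = G2 * H * (1.0 - H)
        grad_W2 = G2.T @ A
        grad_bd = G2.sum(axis=0)
        G1 = G2 @ W2
        if sigmoid:
            G1 = G1 * A * (1.0 - A)
        grad_W1 = G1.T @ X
        grad_be = G1.sum(axis=0)
        for v, p, g in zip(vel, (W1, W2, b_e, b_d),
                           (grad_W1, grad_W2, grad_be, grad_bd)):
            v *= cfg.momentum
            v += lr * g
            p -= v

    return AEModel(W1, W2, b_e, b_d, cfg.activation, history)


def ae_encode(model: AEModel, x: np.ndarray) -> np.ndarray:
    """Map input(s) to the bottleneck activation a = sigma(W1 x + bias_e)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.input_dim:
        raise ValueError(
            f"input length {x.shape[-1]} != model input_dim {model.input_dim}"
        )
    return model._act(x @ model.W1.T + model.bias_e)


def ae_reconstruct(model: AEModel, x: np.ndarray) -> np.ndarray:
    """Full encode-decode pass h = sigma(W2 a + bias_d)."""
    a = ae_encode(model, x)
    return model._act(a @ model.W2.T + model.bias_d)
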