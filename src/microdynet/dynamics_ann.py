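"""A feedforward backpropagation network for one-step microbiome dynamics.

The network maps the community state at time t — the relative abundance of
every taxonomic order plus 0/1 substrate presence flags — to the community
state at t+1. Topology: input of T+S nodes, a first hidden layer of
round(0.95 * n_input) nodes with hyperbolic-tangent activation, a second
hidden layer of round(0.85 * n_input) nodes with logistic-sigmoid activation
S(x) = 1 / (1 + e^-x), and T sigmoid output nodes. Sigmoid outputs keep
predictions inside (0, 1), the range of a relative abundance.

Training is classical backpropagation with heavy-ball momentum:
v <- mu * v - eta * grad, w <- w + v, where grad is the gradient of the
half-sum-of-squares error E_p = 1/2 * sum_j (y_j - t_j)^2. The default
schedule is incremental (one weight update per training pair, pairs in
order); a batch mode (one update per epoch using the mean per-pair gradient)
is available. The logged and halt-checked quantity is the MSE averaged over
pairs and output nodes; training stops when it drops below the error
threshold or the epoch budget is exhausted. Defaults: learning rate 0.15,
momentum 0.65, error threshold 1e-5, at most 20,000 epochs.
"""

from __future__ import annotations

import base64
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .taxon_tables import DietSeries

MODEL_FORMAT = "microdynet-ann-v1"


def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class NetworkTopology:
    """Layer sizes derived from taxon and substrate counts.

    Hidden sizes follow the 95% / 85% rule relative to the input layer;
    with 56 orders and 6 substrates this gives 62 inputs and hidden layers
    of 59 and 53 nodes.
    """

    n_taxa: int
    n_substrates: int
    hidden1_fraction: float = 0.95
    hidden2_fraction: float = 0.85

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_substrates < 0:
            raise ValueError("invalid taxon/substrate counts")
        if self.n_hidden1 < 1 or self.n_hidden2 < 1:
            raise ValueError("hidden layers must have at least one node")

    @property
    def n_input(self) -> int:
        return self.n_taxa + self.n_substrates

    @property
    def n_hidden1(self) -> int:
        return _round_half_away(self.hidden1_fraction * self.n_input)

    @property
    def n_hidden2(self) -> int:
        return _round_half_away(self.hidden2_fraction * self.n_input)

    @property
    def n_output(self) -> int:
        return self.n_taxa


@dataclass
class TrainingConfig:
    learning_rate: float = 0.15
    momentum: float = 0.65
    error_threshold: float = 1e-5
    max_epochs: int = 20000
    weight_init_range: float = 0.1
    seed: int = 0
    update_mode: str = "incremental"  # or "batch"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.update_mode not in ("batch", "incremental"):
            raise ValueError("update_mode must be 'batch' or 'incremental'")


@dataclass
class TrainingPair:
    """(state at t + substrate flags) -> state at t+1."""

    input: np.ndarray
    target: np.ndarray
    diet: str = ""
    target_day: int = -1

    def __post_init__(self) -> None:
        self.input = np.asarray(self.input, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if ((self.input < 0) | (self.input > 1)).any():
            raise ValueError("input entries must be in [0, 1]")
        if ((self.target < 0) | (self.target > 1)).any():
            raise ValueError("target entries must be in [0, 1]")


_WEIGHT_NAMES = ("W1", "b1", "W2", "b2", "W3", "b3")


@dataclass
class AnnModel:
    """Weights, node-name bindings and training state of one network."""

    topology: NetworkTopology
    weights: dict[str, np.ndarray]
    taxon_order_names: tuple[str, ...]
    substrate_names: tuple[str, ...]
    config: TrainingConfig
    velocities: dict[str, np.ndarray] = field(default_factory=dict)
    training_log: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.topology
        expected = {
            "W1": (t.n_input, t.n_hidden1),
            "b1": (t.n_hidden1,),
            "W2": (t.n_hidden1, t.n_hidden2),
            "b2": (t.n_hidden2,),
            "W3": (t.n_hidden2, t.n_output),
            "b3": (t.n_output,),
        }
        for name, shape in expected.items():
            if self.weights[name].shape != shape:
                raise ValueError(
                    f"weight {name} has shape {self.weights[name].shape}, "
                    f"expected {shape}"
                )
        if len(self.taxon_order_names) != t.n_taxa:
            raise ValueError("taxon_order_names must match topology")
        if len(self.substrate_names) != t.n_substrates:
            raise ValueError("substrate_names must match topology")
        if not self.velocities:
            self.velocities = {
                k: np.zeros_like(v) for k, v in self.weights.items()
            }


def init_model(
    topology: NetworkTopology,
    taxon_order_names: Sequence[str],
    substrate_names: Sequence[str],
    config: TrainingConfig,
) -> AnnModel:
    """Seeded uniform weight initialisation on [-r, r]."""
    rng = np.random.default_rng(config.seed)
    r = config.weight_init_range
    t = topology
    shapes = {
        "W1": (t.n_input, t.n_hidden1),
        "b1": (t.n_hidden1,),
        "W2": (t.n_hidden1, t.n_hidden2),
        "b2": (t.n_hidden2,),
        "W3": (t.n_hidden2, t.n_output),
        "b3": (t.n_output,),
    }
    weights = {k: rng.uniform(-r, r, size=s) for k, s in shapes.items()}
    return AnnModel(
        topology=topology,
        weights=weights,
        taxon_order_names=tuple(taxon_order_names),
        substrate_names=tuple(substrate_names),
        config=config,
    )


# ---------------------------------------------------------------------------
# Training-pair construction
# ---------------------------------------------------------------------------


def make_training_pairs(series: Sequence[DietSeries]) -> list[TrainingPair]:
    """Consecutive-profile pairs per diet: n profiles give n-1 pairs.

    Inputs are the profile at t concatenated with the diet's substrate
    flags; targets are the profile at t+1. The final time point of each
    series is never used as an input (it has no successor).
    """
    pairs: list[TrainingPair] = []
    for s in series:
        if len(s.profiles) < 2:
            raise ValueError(f"series {s.diet!r} has fewer than 2 time points")
        for prev, nxt in zip(s.profiles, s.profiles[1:]):
            pairs.append(
                TrainingPair(
                    input=np.concatenate([prev.abundances, s.substrate_flags]),
                    target=nxt.abundances.copy(),
                    diet=s.diet,
                    target_day=nxt.day,
                )
            )
    return pairs


def pairs_to_arrays(pairs: Sequence[TrainingPair]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([p.input for p in pairs])
    T = np.stack([p.target for p in pairs])
    return X, T


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------


def forward_batch(model: AnnModel, X: np.ndarray) -> np.ndarray:
    """tanh -> sigmoid -> sigmoid forward pass for a (n, n_input) batch."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.topology.n_input:
        raise ValueError(
            f"input must be (n, {model.topology.n_input}), got {X.shape}"
        )
    w = model.weights
    h1 = np.tanh(X @ w["W1"] + w["b1"])
    h2 = sigmoid(h1 @ w["W2"] + w["b2"])
    return sigmoid(h2 @ w["W3"] + w["b3"])


def forward(model: AnnModel, x: np.ndarray) -> np.ndarray:
    """Forward pass for a single input vector of length T+S."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.topology.n_input,):
        raise ValueError(
            f"input must have length {model.topology.n_input}, got {x.shape}"
        )
    return forward_batch(model, x[None, :])[0]


def mse(model: AnnModel, pairs: Sequence[TrainingPair]) -> float:
    X, T = pairs_to_arrays(pairs)
    Y = forward_batch(model, X)
    return float(np.mean((Y - T) ** 2))


# ---------------------------------------------------------------------------
# Backpropagation with momentum
# ---------------------------------------------------------------------------


def _gradients(
    model: AnnModel, X: np.ndarray, T: np.ndarray
) -> dict[str, np.ndarray]:
    """Mean over the batch of the per-pair half-sum-of-squares gradient."""
    w = model.weights
    h1 = np.tanh(X @ w["W1"] + w["b1"])
    h2 = sigmoid(h1 @ w["W2"] + w["b2"])
    y = sigmoid(h2 @ w["W3"] + w["b3"])
    d3 = (y - T) * y * (1.0 - y) / X.shape[0]
    d2 = (d3 @ w["W3"].T) * h2 * (1.0 - h2)
    d1 = (d2 @ w["W2"].T) * (1.0 - h1 ** 2)
    return {
        "W3": h2.T @ d3,
        "b3": d3.sum(axis=0),
        "W2": h1.T @ d2,
        "b2": d2.sum(axis=0),
        "W1": X.T @ d1,
        "b1": d1.sum(axis=0),
    }


try:  # compiled inner loop for the incremental schedule
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco


@_njit(cache=True)
def _incremental_epochs(
    X, T, W1, b1, W2, b2, W3, b3, vW1, vb1, vW2, vb2, vW3, vb3,
    lr, mu, err_threshold, max_epochs, mse_log,
):  # pragma: no cover - exercised via train()
    n, n_in = X.shape
    n_h1 = W1.shape[1]
    n_h2 = W2.shape[1]
    n_out = W3.shape[1]
    for epoch in range(max_epochs):
        for p in range(n):
            x = X[p]
            h1 = np.tanh(np.dot(x, W1) + b1)
            h2 = 1.0 / (1.0 + np.exp(-(np.dot(h1, W2) + b2)))
            y = 1.0 / (1.0 + np.exp(-(np.dot(h2, W3) + b3)))
            d3 = (y - T[p]) * y * (1.0 - y)
            back2 = np.dot(W3, d3)
            d2 = back2 * h2 * (1.0 - h2)
            back1 = np.dot(W2, d2)
            d1 = back1 * (1.0 - h1 * h1)
            for a in range(n_h2):
                for b in range(n_out):
                    vW3[a, b] = mu * vW3[a, b] - lr * h2[a] * d3[b]
                    W3[a, b] += vW3[a, b]
            for b in range(n_out):
                vb3[b] = mu * vb3[b] - lr * d3[b]
                b3[b] += vb3[b]
            for a in range(n_h1):
                for b in range(n_h2):
                    vW2[a, b] = mu * vW2[a, b] - lr * h1[a] * d2[b]
                    W2[a, b] += vW2[a, b]
            for b in range(n_h2):
                vb2[b] = mu * vb2[b] - lr * d2[b]
                b2[b] += vb2[b]
            for a in range(n_in):
                for b in range(n_h1):
                    vW1[a, b] = mu * vW1[a, b] - lr * x[a] * d1[b]
                    W1[a, b] += vW1[a, b]
            for b in range(n_h1):
                vb1[b] = mu * vb1[b] - lr * d1[b]
                b1[b] += vb1[b]
        H1 = np.tanh(np.dot(X, W1) + b1)
        H2 = 1.0 / (1.0 + np.exp(-(np.dot(H1, W2) + b2)))
        Y = 1.0 / (1.0 + np.exp(-(np.dot(H2, W3) + b3)))
        epoch_mse = np.mean((Y - T) ** 2)
        mse_log[epoch] = epoch_mse
        if not np.isfinite(epoch_mse):
            return -(epoch + 1)
        if epoch_mse < err_threshold:
            return epoch + 1
    return max_epochs


def _train_incremental(
    model: AnnModel, X: np.ndarray, T: np.ndarray, cfg: TrainingConfig
) -> None:
    w, v = model.weights, model.velocities
    args = [np.ascontiguousarray(X), np.ascontiguousarray(T)]
    for name in _WEIGHT_NAMES:
        w[name] = np.ascontiguousarray(w[name])
        args.append(w[name])
    for name in _WEIGHT_NAMES:
        v[name] = np.ascontiguousarray(v[name])
        args.append(v[name])
    mse_log = np.empty(cfg.max_epochs)
    n_done = _incremental_epochs(
        *args, cfg.learning_rate, cfg.momentum,
        cfg.error_threshold, cfg.max_epochs, mse_log,
    )
    if n_done < 0:
        model.training_log.extend(mse_log[: -n_done].tolist())
        raise FloatingPointError(
            f"non-finite training loss at epoch {-n_done}"
        )
    model.training_log.extend(mse_log[:n_done].tolist())


def _apply_update(model: AnnModel, grads: dict[str, np.ndarray]) -> None:
    lr = model.config.learning_rate
    mu = model.config.momentum
    for name in _WEIGHT_NAMES:
        v = mu * model.velocities[name] - lr * grads[name]
        model.velocities[name] = v
        model.weights[name] = model.weights[name] + v


def train(
    model: AnnModel,
    pairs: Sequence[TrainingPair],
    config: TrainingConfig | None = None,
) -> AnnModel:
    """Train in place until MSE < error_threshold or max_epochs is reached.

    Each epoch performs one weight update (batch mode) or one pass of
    per-pair updates (incremental mode), then logs the post-update MSE over
    all pairs. Momentum velocities persist on the model, so a reloaded model
    resumes training exactly where it stopped. Fully deterministic given
    (weights, velocities, pairs, config): training itself draws no random
    numbers.
    """
    if not pairs:
        raise ValueError("need at least one training pair")
    if config is not None:
        model.config = config
    cfg = model.config
    X, T = pairs_to_arrays(pairs)
    if cfg.update_mode == "incremental":
        _train_incremental(model, X, T, cfg)
        return model
    for epoch in range(1, cfg.max_epochs + 1):
        grads = _gradients(model, X, T)
        _apply_update(model, grads)
        epoch_mse = float(np.mean((forward_batch(model, X) - T) ** 2))
        if not np.isfinite(epoch_mse):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}"
            )
        model.training_log.append(epoch_mse)
        if epoch_mse < cfg.error_threshold:
            break
    return model


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------


def _encode_array(a: np.ndarray) -> dict:
    a = np.ascontiguousarray(a, dtype=np.float64)
    return {
        "shape": list(a.shape),
        "data": base64.b64encode(a.tobytes()).decode("ascii"),
    }


def _decode_array(d: dict) -> np.ndarray:
    raw = base64.b64decode(d["data"])
    return np.frombuffer(raw, dtype=np.float64).reshape(d["shape"]).copy()


def save_model(model: AnnModel, path: str | Path) -> None:
    """Write the model as a single JSON file (weights base64-encoded)."""
    doc = {
        "format": MODEL_FORMAT,
        "topology": asdict(model.topology),
        "taxon_order_names": list(model.taxon_order_names),
        "substrate_names": list(model.substrate_names),
        "config": asdict(model.config),
        "weights": {k: _encode_array(v) for k, v in model.weights.items()},
        "velocities": {k: _encode_array(v) for k, v in model.velocities.items()},
        "training_log": model.training_log,
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> AnnModel:
    """Load a model saved by :func:`save_model`; round trip is bit-exact."""
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"{path}: not a valid model file ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("format") != MODEL_FORMAT:
        raise ValueError(
            f"{path}: unsupported model format "
            f"{doc.get('format') if isinstance(doc, dict) else type(doc)}; "
            f"expected {MODEL_FORMAT}"
        )
    return AnnModel(
        topology=NetworkTopology(**doc["topology"]),
        weights={k: _decode_array(v) for k, v in doc["weights"].items()},
        taxon_order_names=tuple(doc["taxon_order_names"]),
        substrate_names=tuple(doc["substrate_names"]),
        config=TrainingConfig(**doc["config"]),
        velocities={k: _decode_array(v) for k, v in doc["velocities"].items()},
        training_log=list(doc["training_log"]),
    )


def write_training_log(model: AnnModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch,mse\n")
        for i, m in enumerate(model.training_log, start=1):
            fh.write(f"{i},{m:.12g}\n")
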