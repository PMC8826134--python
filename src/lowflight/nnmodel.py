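"""Feedforward binary classifier for low-flight probability.

A two-hidden-layer dense network with an (inverted) dropout layer between
the hidden layers and a single sigmoid output unit, trained to minimize
binary cross-entropy with the Adam optimizer and early stopping on
validation AUC. Implemented directly in numpy: forward pass, analytic
backpropagation, and the standard bias-corrected Adam update, all seeded
and bit-reproducible on a given platform.

Hidden activation is rectified-linear by default (configurable); dropout is
applied only in training mode, with survivors rescaled by 1/(1 - rate) so
that inference needs no correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .terrain import FEATURE_COLUMNS, NormStats

__all__ = [
    "ModelConfig",
    "NetworkModel",
    "TrainLog",
    "AdamState",
    "init_network",
    "forward",
    "bce_loss",
    "loss_and_gradients",
    "adam_step",
    "train",
    "train_fixed_epochs",
    "predict",
    "model_to_dict",
    "model_from_dict",
]

N_FEATURES = len(FEATURE_COLUMNS)
_LOSS_EPS = 1e-7


@dataclass
class ModelConfig:
    units1: int = 256
    units2: int = 32
    dropout_rate: float = 0.4
    seed: int = 0
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    batch_size: int = 512
    max_epochs: int = 100
    patience: int = 10
    activation: str = "relu"

    def validate(self) -> None:
        if self.units1 < 1 or self.units2 < 1:
            raise ValueError("hidden layers need at least one unit")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1 or self.patience < 0:
            raise ValueError("invalid training schedule")
        if self.activation not in ("relu", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class NetworkModel:
    """Weights/biases plus configuration and the normalization statistics
    the inputs are expected to be encoded with."""

    params: dict[str, np.ndarray]
    config: ModelConfig
    norm_stats: NormStats | None = None

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            {k: v.copy() for k, v in self.params.items()}, self.config, self.norm_stats
        )

    @property
    def n_parameters(self) -> int:
        return sum(int(v.size) for v in self.params.values())


@dataclass
class TrainLog:
    train_loss: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    @property
    def best_val_auc(self) -> float:
        return self.val_auc[self.best_epoch]


def init_network(cfg: ModelConfig, n_features: int = N_FEATURES) -> NetworkModel:
    """Seeded He-style initialization: weights ~ N(0, 2/fan_in), biases 0."""
    cfg.validate()
    rng = np.random.default_rng([0, cfg.seed])
    shapes = {
        "W1": (n_features, cfg.units1), "b1": (cfg.units1,),
        "W2": (cfg.units1, cfg.units2), "b2": (cfg.units2,),
        "W3": (cfg.units2, 1), "b3": (1,),
    }
    params = {}
    for name, shape in shapes.items():
        if name.startswith("W"):
            params[name] = rng.normal(0.0, np.sqrt(2.0 / shape[0]), size=shape)
        else:
            params[name] = np.zeros(shape)
    return NetworkModel(params, cfg)


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    return np.maximum(z, 0.0) if kind == "relu" else np.tanh(z)


def _act_grad(z: np.ndarray, kind: str) -> np.ndarray:
    return (z > 0).astype(float) if kind == "relu" else 1.0 - np.tanh(z) ** 2


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _dropout_mask(rng: np.random.Generator, shape, rate: float) -> np.ndarray:
    return (rng.random(shape) >= rate).astype(float)


def forward(
    model: NetworkModel,
    rows: np.ndarray,
    training: bool = False,
    dropout_rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Predicted probabilities in (0, 1) for encoded, normalized rows.

    In training mode an inverted-dropout mask (drawn from ``dropout_rng``)
    deactivates first-hidden-layer units at the configured rate and rescales
    survivors by 1/(1 - rate); inference applies no mask and no scaling.
    """
    X = np.asarray(rows, dtype=float)
    p, _ = _forward_cache(model, X, training=training, dropout_rng=dropout_rng)
    return p


def _forward_cache(model, X, training=False, dropout_rng=None, mask=None):
    cfg = model.config
    P = model.params
    if X.ndim != 2 or X.shape[1] != P["W1"].shape[0]:
        raise ValueError(f"expected rows with {P['W1'].shape[0]} columns, got {X.shape}")
    z1 = X @ P["W1"] + P["b1"]
    h1 = _act(z1, cfg.activation)
    if training and cfg.dropout_rate > 0:
        if mask is None:
            if dropout_rng is None:
                raise ValueError("training-mode forward needs a dropout rng or mask")
            mask = _dropout_mask(dropout_rng, h1.shape, cfg.dropout_rate)
        d = h1 * mask / (1.0 - cfg.dropout_rate)
    else:
        mask = None
        d = h1
    z2 = d @ P["W2"] + P["b2"]
    h2 = _act(z2, cfg.activation)
    z3 = h2 @ P["W3"] + P["b3"]
    p = _sigmoid(z3[:, 0])
    return p, {"X": X, "z1": z1, "h1": h1, "mask": mask, "d": d, "z2": z2, "h2": h2}


def bce_loss(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Mean binary cross-entropy, with probabilities clipped away from
    {0, 1} for numerical safety."""
    y = np.asarray(labels, dtype=float)
    p = np.clip(np.asarray(probabilities, dtype=float), _LOSS_EPS, 1.0 - _LOSS_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def loss_and_gradients(model, X, y, dropout_rng=None, mask=None):
    """BCE loss and analytic gradients for one (mini-)batch.

    When ``dropout_rng`` or ``mask`` is given the pass is in training mode
    and the same dropout mask is used in forward and backward directions.
    """
    cfg = model.config
    P = model.params
    y = np.asarray(y, dtype=float)
    training = dropout_rng is not None or mask is not None
    p, cache = _forward_cache(model, np.asarray(X, dtype=float), training=training,
                              dropout_rng=dropout_rng, mask=mask)
    n = len(y)
    loss = bce_loss(y, p)

    dz3 = ((p - y) / n)[:, None]
    grads = {
        "W3": cache["h2"].T @ dz3,
        "b3": dz3.sum(axis=0),
    }
    dh2 = dz3 @ P["W3"].T
    dz2 = dh2 * _act_grad(cache["z2"], cfg.activation)
    grads["W2"] = cache["d"].T @ dz2
    grads["b2"] = dz2.sum(axis=0)
    dd = dz2 @ P["W2"].T
    if cache["mask"] is not None:
        dh1 = dd * cache["mask"] / (1.0 - cfg.dropout_rate)
    else:
        dh1 = dd
    dz1 = dh1 * _act_grad(cache["z1"], cfg.activation)
    grads["W1"] = cache["X"].T @ dz1
    grads["b1"] = dz1.sum(axis=0)
    return loss, grads


@dataclass
class AdamState:
    m: dict[str, np.ndarray]
    v: dict[str, np.ndarray]
    t: int = 0

    @classmethod
    def for_model(cls, model: NetworkModel) -> "AdamState":
        return cls(
            m={k: np.zeros_like(p) for k, p in model.params.items()},
            v={k: np.zeros_like(p) for k, p in model.params.items()},
        )


def adam_step(model: NetworkModel, grads: dict, state: AdamState, cfg: ModelConfig | None = None):
    """One standard Adam update (bias-corrected moments), in place."""
    cfg = cfg or model.config
    state.t += 1
    t = state.t
    for k, g in grads.items():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient for {k}")
        state.m[k] = cfg.beta1 * state.m[k] + (1 - cfg.beta1) * g
        state.v[k] = cfg.beta2 * state.v[k] + (1 - cfg.beta2) * g * g
        mhat = state.m[k] / (1 - cfg.beta1 ** t)
        vhat = state.v[k] / (1 - cfg.beta2 ** t)
        model.params[k] = model.params[k] - cfg.learning_rate * mhat / (np.sqrt(vhat) + cfg.epsilon)
    return model, state


def train(model, train_X, train_y, val_X, val_y, cfg: ModelConfig | None = None):
    """Mini-batch training with early stopping on validation AUC.

    One epoch is a full pass over seeded-shuffled mini-batches. After each
    epoch the validation AUC is computed; training stops when it has not
    strictly improved for more than ``patience`` consecutive epochs (or at
    ``max_epochs``), and the parameters of the best epoch are restored.
    With ``patience = 0`` the first non-improving epoch stops training.
    """
    from .evalsuite import auc  # local import: evalsuite depends on this module

    cfg = cfg or model.config
    cfg.validate()
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y, dtype=float)
    val_X = np.asarray(val_X, dtype=float)
    val_y = np.asarray(val_y, dtype=float)
    if len(train_X) == 0 or len(val_X) == 0:
        raise ValueError("empty training or validation split")
    if val_y.min() == val_y.max():
        raise ValueError("validation split has a single class; AUC undefined")

    rng = np.random.default_rng([1, cfg.seed])
    state = AdamState.for_model(model)
    log = TrainLog()
    best = model.copy()
    best_auc = -np.inf
    since_best = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_X))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, grads = loss_and_gradients(
                model, train_X[idx], train_y[idx], dropout_rng=rng
            )
            model, state = adam_step(model, grads, state, cfg)
            losses.append(loss)
        log.train_loss.append(float(np.mean(losses)))
        vauc = auc(val_y, forward(model, val_X))
        log.val_auc.append(vauc)
        if vauc > best_auc:
            best_auc = vauc
            best = model.copy()
            log.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best > cfg.patience:
                log.stopped_epoch = epoch
                break
    if log.stopped_epoch < 0:
        log.stopped_epoch = len(log.val_auc) - 1
    best.norm_stats = model.norm_stats
    return best, log


def train_fixed_epochs(model, train_X, train_y, n_epochs: int, cfg: ModelConfig | None = None):
    """Train for exactly ``n_epochs`` with no validation split and no early
    stopping (the protocol used by the cross-validation folds)."""
    cfg = cfg or model.config
    cfg.validate()
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y, dtype=float)
    rng = np.random.default_rng([1, cfg.seed])
    state = AdamState.for_model(model)
    losses = []
    for _ in range(n_epochs):
        order = rng.permutation(len(train_X))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, grads = loss_and_gradients(model, train_X[idx], train_y[idx], dropout_rng=rng)
            model, state = adam_step(model, grads, state, cfg)
            epoch_losses.append(loss)
        losses.append(float(np.mean(epoch_losses)))
    return model, losses


def predict(model: NetworkModel, rows: np.ndarray) -> np.ndarray:
    """Inference-mode probabilities (no dropout, no rescaling)."""
    return forward(model, rows, training=False)


# ---------------------------------------------------------------------------
# serialization (portable, text-only container)
# ---------------------------------------------------------------------------

def model_to_dict(model: NetworkModel) -> dict:
    out = {
        "config": asdict(model.config),
        "params": {k: v.tolist() for k, v in model.params.items()},
    }
    if model.norm_stats is not None:
        out["norm_stats"] = {
            "mean": model.norm_stats.mean.to_dict(),
            "sd": model.norm_stats.sd.to_dict(),
        }
    return out


def model_from_dict(payload: dict) -> NetworkModel:
    import pandas as pd

    cfg = ModelConfig(**payload["config"])
    params = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
    norm = None
    if "norm_stats" in payload:
        norm = NormStats(
            mean=pd.Series(payload["norm_stats"]["mean"]),
            sd=pd.Series(payload["norm_stats"]["sd"]),
        )
    return NetworkModel(params, cfg, norm)
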