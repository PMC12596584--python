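"""The coordinate-regressor MLP: architecture, losses, training loop.

The network maps a per-sample genetic feature vector to standardized
(longitude, latitude): an input batch-normalization layer, a stack of
hidden affine→ELU→dropout blocks sharing one resolved width, and a
final affine to 2 outputs. Three loss functions are supported — RMSE,
Huber, and DRMS (distance root mean square, the 2-D positional error)
— each optionally weighted by inverse sampling density. Optimization is
Adam with global-norm gradient clipping, a reduce-on-plateau learning
rate schedule, early stopping on validation loss, and a best-snapshot
return. Everything is plain NumPy and fully seed-reproducible.

Width resolution guards against over-parameterization on small panels:
while the requested hidden width exceeds the product of the training
matrix dimensions (rows × columns), it is recursively reduced by 20%
(floored); the final width is used uniformly across hidden layers.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .datatypes import CoordinateSet, FeatureMatrix
from .errors import ConfigError, DivergenceError, GeolociError, InputError

logger = logging.getLogger(__name__)

LossKind = Literal["rmse", "huber", "drms"]


def resolve_width(initial_width: int, n_rows: int, n_cols: int) -> int:
    """Recursively shrink the hidden width by 20% until ≤ rows × cols."""
    if initial_width <= 0 or n_rows <= 0 or n_cols <= 0:
        raise ConfigError("resolve_width inputs must be positive")
    bound = n_rows * n_cols
    width = int(initial_width)
    while width > bound:
        width = int(np.floor(width * 0.8))
    if width < 2:
        raise GeolociError(f"resolved width {width} < 2; data too small for this model")
    return width


@dataclass
class ModelSpec:
    """Architecture hyperparameters for the coordinate regressor."""

    input_dim: int
    n_hidden_layers: int = 2
    initial_width: int = 256
    resolved_width: int | None = None
    dropout: float = 0.2
    output_dim: int = 2

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ConfigError("input_dim must be >= 1")
        if self.n_hidden_layers < 1:
            raise ConfigError("n_hidden_layers must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError("dropout must be in [0, 1)")


@dataclass
class TrainConfig:
    """Optimization hyperparameters."""

    loss_kind: LossKind = "rmse"
    use_weights: bool = False
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 5000
    patience: int = 50
    lr_factor: float = 0.5
    lr_patience: int = 20
    grad_clip_norm: float | None = 1.0
    huber_delta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ConfigError("invalid TrainConfig (patience/batch_size/learning_rate)")
        if self.loss_kind not in ("rmse", "huber", "drms"):
            raise ConfigError(f"unknown loss kind {self.loss_kind!r}")


def _elu(a: np.ndarray) -> np.ndarray:
    return np.where(a > 0, a, np.expm1(np.minimum(a, 0.0)))


def _elu_grad(a: np.ndarray, e: np.ndarray) -> np.ndarray:
    return np.where(a > 0, 1.0, e + 1.0)


class GeoMLP:
    """Feed-forward coordinate regressor (NumPy parameters and autodiff)."""

    BN_EPS = 1e-5
    BN_MOMENTUM = 0.1

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        if spec.resolved_width is None:
            spec.resolved_width = spec.initial_width
        w = spec.resolved_width
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {
            "bn_gamma": np.ones(spec.input_dim),
            "bn_beta": np.zeros(spec.input_dim),
        }
        self.running_mean = np.zeros(spec.input_dim)
        self.running_var = np.ones(spec.input_dim)
        dims = [spec.input_dim] + [w] * spec.n_hidden_layers
        for l in range(spec.n_hidden_layers):
            fan_in = dims[l]
            self.params[f"W{l}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, w))
            self.params[f"b{l}"] = np.zeros(w)
        self.params["W_out"] = rng.normal(
            0.0, np.sqrt(1.0 / w), (w, spec.output_dim)
        )
        self.params["b_out"] = np.zeros(spec.output_dim)

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def forward(
        self,
        X: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        p = self.params
        cache: dict = {"X": X, "training": training}
        if training:
            mu = X.mean(axis=0)
            var = X.var(axis=0)
            self.running_mean = (1 - self.BN_MOMENTUM) * self.running_mean + self.BN_MOMENTUM * mu
            self.running_var = (1 - self.BN_MOMENTUM) * self.running_var + self.BN_MOMENTUM * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.BN_EPS)
        xhat = (X - mu) * inv_std
        h = p["bn_gamma"] * xhat + p["bn_beta"]
        cache.update(xhat=xhat, inv_std=inv_std)

        drop = self.spec.dropout
        for l in range(self.spec.n_hidden_layers):
            a = h @ p[f"W{l}"] + p[f"b{l}"]
            e = _elu(a)
            if training and drop > 0:
                if rng is None:
                    raise GeolociError("dropout in training mode needs an rng")
                mask = (rng.random(e.shape) >= drop) / (1.0 - drop)
                out = e * mask
            else:
                mask = None
                out = e
            cache[f"h_in{l}"], cache[f"a{l}"], cache[f"e{l}"], cache[f"mask{l}"] = h, a, e, mask
            h = out
        cache["h_last"] = h
        pred = h @ p["W_out"] + p["b_out"]
        return pred, cache

    def backward(self, cache: dict, dpred: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        grads: dict[str, np.ndarray] = {}
        grads["W_out"] = cache["h_last"].T @ dpred
        grads["b_out"] = dpred.sum(axis=0)
        dh = dpred @ p["W_out"].T
        for l in reversed(range(self.spec.n_hidden_layers)):
            mask = cache[f"mask{l}"]
            if mask is not None:
                dh = dh * mask
            da = dh * _elu_grad(cache[f"a{l}"], cache[f"e{l}"])
            grads[f"W{l}"] = cache[f"h_in{l}"].T @ da
            grads[f"b{l}"] = da.sum(axis=0)
            dh = da @ p[f"W{l}"].T
        xhat = cache["xhat"]
        grads["bn_gamma"] = (dh * xhat).sum(axis=0)
        grads["bn_beta"] = dh.sum(axis=0)
        # input gradient not needed; stop here
        return grads

    def state_dict(self) -> dict:
        state = {k: v.copy() for k, v in self.params.items()}
        state["running_mean"] = self.running_mean.copy()
        state["running_var"] = self.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        self.running_mean = state["running_mean"].copy()
        self.running_var = state["running_var"].copy()
        self.params = {k: v.copy() for k, v in state.items()
                       if k not in ("running_mean", "running_var")}


def build_model(spec: ModelSpec, seed: int = 0) -> GeoMLP:
    """Instantiate the regressor from its spec (seeded initialization)."""
    return GeoMLP(spec, seed=seed)


def _loss_and_grad(
    pred: np.ndarray,
    target: np.ndarray,
    kind: LossKind,
    weights: np.ndarray | None,
    delta: float,
) -> tuple[float, np.ndarray]:
    if pred.shape != target.shape:
        raise InputError("pred and target shapes differ")
    n, d = pred.shape
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (n,):
            raise GeolociError("weight vector length mismatch")
        w = weights / weights.sum()
    r = pred - target
    if kind == "rmse":
        msq = float(w @ (r**2).sum(axis=1)) / d
        loss = np.sqrt(msq)
        grad = (w[:, None] * r / d) / max(loss, 1e-12)
    elif kind == "drms":
        msq = float(w @ (r**2).sum(axis=1))
        loss = np.sqrt(msq)
        grad = (w[:, None] * r) / max(loss, 1e-12)
    elif kind == "huber":
        absr = np.abs(r)
        h = np.where(absr <= delta, 0.5 * r**2, delta * (absr - 0.5 * delta))
        loss = float(w @ h.sum(axis=1)) / d
        dh = np.where(absr <= delta, r, delta * np.sign(r))
        grad = w[:, None] * dh / d
    else:
        raise ConfigError(f"unknown loss kind {kind!r}")
    return float(loss), grad


def compute_loss(
    pred: np.ndarray,
    target: np.ndarray,
    kind: LossKind = "rmse",
    weights: np.ndarray | None = None,
    delta: float = 1.0,
) -> float:
    """Weighted RMSE / Huber / DRMS over a batch of standardized coordinates.

    rmse = sqrt(weighted mean over batch and both axes of r²);
    drms = sqrt(weighted mean over batch of (Δx² + Δy²));
    huber = weighted mean over batch and axes of ½r² (|r| ≤ δ) else
    δ(|r| − ½δ). Weighted means use wᵢ/Σwᵢ, so uniform weights equal the
    unweighted value exactly.
    """
    loss, _ = _loss_and_grad(
        np.asarray(pred, float), np.asarray(target, float), kind, weights, delta
    )
    return loss


@dataclass
class TrainedGeoModel:
    """A trained regressor with its scalers and training history."""

    model: GeoMLP
    feature_mean: np.ndarray
    feature_std: np.ndarray
    target_mean: np.ndarray  # (lon, lat) means of the training partition
    target_std: np.ndarray
    history: dict = field(default_factory=dict)  # epoch, train_loss, val_loss, lr
    best_epoch: int = 0
    config: TrainConfig | None = None

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for k in grads:
            grads[k] *= scale


def standardize_targets(lonlat: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    return (lonlat - mean) / std


def unstandardize_targets(z: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    return z * std + mean


def train(
    model: GeoMLP,
    train_features: np.ndarray,
    train_lonlat: np.ndarray,
    val_features: np.ndarray,
    val_lonlat: np.ndarray,
    weights: np.ndarray | None = None,
    config: TrainConfig | None = None,
    val_weights: np.ndarray | None = None,
) -> TrainedGeoModel:
    """Fit the regressor; returns the best-validation snapshot.

    Features are standardized per column and targets per axis using
    training-partition statistics only. Validation loss (same loss
    kind) drives both the reduce-on-plateau LR schedule and early
    stopping; when a weighted loss is in use, passing inverse-density
    ``val_weights`` makes model selection honour sparse regions the
    same way the training loss does. Training sample weights enter the
    loss via within-batch normalization wᵢ/Σwᵢ.
    """
    config = config or TrainConfig()
    X = np.asarray(train_features, dtype=float)
    if X.shape[0] == 0:
        raise InputError("empty training set")
    Y = np.asarray(train_lonlat, dtype=float)
    f_mean = X.mean(axis=0)
    f_std = X.std(axis=0)
    f_std[f_std == 0] = 1.0
    t_mean = Y.mean(axis=0)
    t_std = Y.std(axis=0)
    t_std[t_std == 0] = 1.0

    Xs = (X - f_mean) / f_std
    Ys = standardize_targets(Y, t_mean, t_std)
    Xv = (np.asarray(val_features, float) - f_mean) / f_std
    Yv = standardize_targets(np.asarray(val_lonlat, float), t_mean, t_std)

    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (X.shape[0],):
            raise GeolociError("weight vector length mismatch with training set")

    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.params, config.learning_rate)
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = 0
    stall = lr_stall = 0
    hist: dict[str, list] = {"epoch": [], "train_loss": [], "val_loss": [], "lr": []}
    n = X.shape[0]

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_seen = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if len(idx) == 1 and n > 1:
                continue  # a singleton batch degenerates batch-norm statistics
            bw = weights[idx] if (config.use_weights and weights is not None) else None
            pred, cache = model.forward(Xs[idx], training=True, rng=rng)
            loss, dpred = _loss_and_grad(pred, Ys[idx], config.loss_kind, bw, config.huber_delta)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            grads = model.backward(cache, dpred)
            if config.grad_clip_norm:
                _clip_global_norm(grads, config.grad_clip_norm)
            opt.step(model.params, grads)
            epoch_loss += loss * len(idx)
            n_seen += len(idx)

        val_pred, _ = model.forward(Xv, training=False)
        val_loss = compute_loss(val_pred, Yv, config.loss_kind, val_weights, config.huber_delta)
        if not np.isfinite(val_loss):
            raise DivergenceError(f"non-finite validation loss at epoch {epoch}")
        hist["epoch"].append(epoch)
        hist["train_loss"].append(epoch_loss / max(n_seen, 1))
        hist["val_loss"].append(val_loss)
        hist["lr"].append(opt.lr)

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
            stall = lr_stall = 0
        else:
            stall += 1
            lr_stall += 1
            if lr_stall >= config.lr_patience:
                opt.lr *= config.lr_factor
                lr_stall = 0
            if stall >= config.patience:
                break

    model.load_state_dict(best_state)
    logger.info("train: stopped at epoch %d, best epoch %d (val %.5f)",
                hist["epoch"][-1], best_epoch, best_val)
    return TrainedGeoModel(
        model, f_mean, f_std, t_mean, t_std, hist, best_epoch, config
    )


def predict(trained: TrainedGeoModel, F: FeatureMatrix) -> CoordinateSet:
    """Predict lon/lat (decimal degrees) for a feature matrix (eval mode)."""
    X = np.asarray(F.values, dtype=float)
    if X.shape[1] != trained.feature_mean.shape[0]:
        raise InputError(
            f"feature dimension {X.shape[1]} does not match training "
            f"dimension {trained.feature_mean.shape[0]}"
        )
    Xs = (X - trained.feature_mean) / trained.feature_std
    z, _ = trained.model.forward(Xs, training=False)
    lonlat = unstandardize_targets(z, trained.target_mean, trained.target_std)
    lonlat[:, 0] = np.clip(lonlat[:, 0], -180.0, 180.0)
    lonlat[:, 1] = np.clip(lonlat[:, 1], -90.0, 90.0)
    return CoordinateSet(F.sample_ids, lonlat[:, 0], lonlat[:, 1])
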