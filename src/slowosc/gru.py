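"""Gated-recurrent-unit forecaster for slow hemodynamic fluctuations.

The model encodes a single-vessel input sequence x(t) into a hidden state
h(t) through the standard GRU gate equations

    r(t) = sigmoid(W_ir x(t) + b_ir + W_hr h(t-1) + b_hr)
    z(t) = sigmoid(W_iz x(t) + b_iz + W_hz h(t-1) + b_hz)
    n(t) = tanh(W_in x(t) + b_in + r(t) * (W_hn h(t-1) + b_hn))
    h(t) = (1 - z(t)) * n(t) + z(t) * h(t-1)

with a linear readout y(t) = w_out . h(t) (optionally concatenating the raw
input to the readout — a residual connection). Training minimises either
mean squared error, the negative Pearson correlation (CC), or their sum,
over post-washout samples only: the first ``washout`` time points merely
drive the recurrent state into an input-specific regime and are excluded
from both the loss and the evaluation.

Everything — forward pass, backpropagation through time, Adam with L2
weight decay, optional gradient clipping and inter-layer dropout — is
implemented directly in NumPy, fully deterministic given the seeds.
The module exposes a statsmodels-style surface: build a
:class:`GRUForecaster` from training pairs, ``fit()`` it, and use the
returned :class:`GRUForecasterResults` for prediction, cross-validation
scoring and hidden-state analysis.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation
from .preprocess import TargetPair
from .timeseries import TimeSeries

__all__ = [
    "LayerParams",
    "GRUParams",
    "GRUState",
    "TrainConfig",
    "PredictionRecord",
    "GRUForecaster",
    "GRUForecasterResults",
    "TrainingDiverged",
    "gru_step",
    "readout",
    "cc_objective",
    "train",
    "predict",
    "crossvalidate",
    "hyperparameter_search",
    "hidden_state_pca",
    "HUMAN_PRESET",
    "RAT_PRESET",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite during optimisation."""


# ---------------------------------------------------------------------------
# parameters


@dataclass
class LayerParams:
    """Weights of one GRU layer: input (D->H) and recurrent (H->H) maps."""

    W_ir: np.ndarray
    W_iz: np.ndarray
    W_in: np.ndarray
    W_hr: np.ndarray
    W_hz: np.ndarray
    W_hn: np.ndarray
    b_ir: np.ndarray
    b_iz: np.ndarray
    b_in: np.ndarray
    b_hr: np.ndarray
    b_hz: np.ndarray
    b_hn: np.ndarray

    FIELDS = ("W_ir", "W_iz", "W_in", "W_hr", "W_hz", "W_hn",
              "b_ir", "b_iz", "b_in", "b_hr", "b_hz", "b_hn")

    @property
    def hidden_size(self) -> int:
        return self.W_hr.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_ir.shape[1]

    @classmethod
    def init(cls, input_size: int, hidden_size: int, rng: np.random.Generator
             ) -> "LayerParams":
        """Uniform initialisation in +-1/sqrt(hidden_size)."""
        bound = 1.0 / np.sqrt(hidden_size)
        def u(*shape):
            return rng.uniform(-bound, bound, size=shape)
        return cls(
            W_ir=u(hidden_size, input_size), W_iz=u(hidden_size, input_size),
            W_in=u(hidden_size, input_size), W_hr=u(hidden_size, hidden_size),
            W_hz=u(hidden_size, hidden_size), W_hn=u(hidden_size, hidden_size),
            b_ir=u(hidden_size), b_iz=u(hidden_size), b_in=u(hidden_size),
            b_hr=u(hidden_size), b_hz=u(hidden_size), b_hn=u(hidden_size),
        )

    @classmethod
    def zeros(cls, input_size: int, hidden_size: int) -> "LayerParams":
        z = lambda *s: np.zeros(s)
        return cls(
            W_ir=z(hidden_size, input_size), W_iz=z(hidden_size, input_size),
            W_in=z(hidden_size, input_size), W_hr=z(hidden_size, hidden_size),
            W_hz=z(hidden_size, hidden_size), W_hn=z(hidden_size, hidden_size),
            b_ir=z(hidden_size), b_iz=z(hidden_size), b_in=z(hidden_size),
            b_hr=z(hidden_size), b_hz=z(hidden_size), b_hn=z(hidden_size),
        )


@dataclass
class GRUParams:
    """Full parameter set: stacked GRU layers plus the linear readout.

    ``w_out`` has length ``hidden_size`` (+1 when the residual connection
    feeds the raw input into the readout alongside the hidden state).
    """

    layers: list[LayerParams]
    w_out: np.ndarray
    b_out: float
    residual: bool = False

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def hidden_size(self) -> int:
        return self.layers[0].hidden_size

    @classmethod
    def init(cls, hidden_size: int, n_layers: int = 1, residual: bool = False,
             seed: int = 0, input_size: int = 1) -> "GRUParams":
        rng = np.random.default_rng(seed)
        layers = []
        for layer_idx in range(n_layers):
            d = input_size if layer_idx == 0 else hidden_size
            layers.append(LayerParams.init(d, hidden_size, rng))
        n_out = hidden_size + (input_size if residual else 0)
        bound = 1.0 / np.sqrt(hidden_size)
        w_out = rng.uniform(-bound, bound, size=n_out)
        b_out = float(rng.uniform(-bound, bound))
        return cls(layers=layers, w_out=w_out, b_out=b_out, residual=residual)


@dataclass
class GRUState:
    """One step's hidden state and transient gate activations."""

    h: np.ndarray
    r: np.ndarray
    z: np.ndarray
    n: np.ndarray


def gru_step(layer: LayerParams, x_t: np.ndarray, h_prev: np.ndarray) -> GRUState:
    """A single GRU update; x_t broadcastable to (..., D), h_prev (..., H)."""
    x_t = np.atleast_1d(np.asarray(x_t, float))
    h_prev = np.asarray(h_prev, float)
    if x_t.shape[-1] != layer.input_size:
        raise ValueError(
            f"input size {x_t.shape[-1]} != layer input size {layer.input_size}"
        )
    if h_prev.shape[-1] != layer.hidden_size:
        raise ValueError(
            f"state size {h_prev.shape[-1]} != hidden size {layer.hidden_size}"
        )
    r = _sigmoid(x_t @ layer.W_ir.T + layer.b_ir + h_prev @ layer.W_hr.T + layer.b_hr)
    z = _sigmoid(x_t @ layer.W_iz.T + layer.b_iz + h_prev @ layer.W_hz.T + layer.b_hz)
    a = h_prev @ layer.W_hn.T + layer.b_hn
    n = np.tanh(x_t @ layer.W_in.T + layer.b_in + r * a)
    h = (1.0 - z) * n + z * h_prev
    return GRUState(h=h, r=r, z=z, n=n)


def readout(params: GRUParams, h_t: np.ndarray, x_t: np.ndarray | float = 0.0
            ) -> np.ndarray:
    """Linear readout y = w_out . h (+ raw input when residual)."""
    h_t = np.asarray(h_t, float)
    if params.residual:
        x_t = np.atleast_1d(np.asarray(x_t, float))
        feats = np.concatenate(
            [h_t, np.broadcast_to(x_t, h_t.shape[:-1] + (x_t.shape[-1],))], axis=-1
        )
    else:
        feats = h_t
    return feats @ params.w_out + params.b_out


# ---------------------------------------------------------------------------
# losses


def cc_objective(pred: np.ndarray, target: np.ndarray, kind: str = "cc") -> float:
    """Training objective: -CC, MSE, or MSE - CC (equal weights).

    Raises on zero-variance input (CC undefined) and on vectors shorter
    than 3 samples.
    """
    pred = np.asarray(pred, float)
    target = np.asarray(target, float)
    if pred.shape != target.shape or pred.size < 3:
        raise ValueError("pred and target must be equal-length vectors, n >= 3")
    if kind == "mse":
        return float(np.mean((pred - target) ** 2))
    p = pred - pred.mean()
    q = target - target.mean()
    sp, sq = np.linalg.norm(p), np.linalg.norm(q)
    if sp == 0 or sq == 0:
        raise ValueError("zero-variance input: CC undefined")
    cc = float(p @ q / (sp * sq))
    if kind == "cc":
        return -cc
    if kind == "mse+cc":
        return float(np.mean((pred - target) ** 2)) - cc
    raise ValueError(f"unknown loss kind {kind!r}")


def _loss_and_grad(pred: np.ndarray, target: np.ndarray, kind: str
                   ) -> tuple[float, np.ndarray]:
    """Per-trace loss and dL/dpred; pred, target 1-D post-washout vectors."""
    n = pred.size
    loss = 0.0
    grad = np.zeros_like(pred)
    if kind in ("mse", "mse+cc"):
        diff = pred - target
        loss += float(np.mean(diff**2))
        grad += 2.0 * diff / n
    if kind in ("cc", "mse+cc"):
        p = pred - pred.mean()
        q = target - target.mean()
        sp, sq = np.linalg.norm(p), np.linalg.norm(q)
        if sp == 0 or sq == 0:
            raise TrainingDiverged("zero-variance prediction or target in CC loss")
        cc = float(p @ q / (sp * sq))
        loss += -cc
        dcc = q / (sp * sq) - cc * p / sp**2
        grad += -dcc
    return loss, grad


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class TrainConfig:
    """Training configuration (architecture + optimisation).

    ``loss`` is one of ``"mse"``, ``"cc"``, ``"mse+cc"``; ``washout`` counts
    the initial samples used only to drive the state. ``grad_clip`` of
    ``None`` disables clipping, otherwise it is the maximal global gradient
    norm.
    """

    hidden_size: int = 88
    n_layers: int = 1
    loss: str = "cc"
    learning_rate: float = 0.00121
    l2: float = 0.0221
    grad_clip: float | None = None
    dropout: float = 0.0
    residual_connection: bool = False
    batch_size: int = 10
    n_epochs: int = 69
    washout: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss not in ("mse", "cc", "mse+cc"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


# Final tuned configurations for the two species' datasets.
HUMAN_PRESET = TrainConfig(
    hidden_size=88, n_layers=1, loss="cc", learning_rate=0.00121, l2=0.0221,
    grad_clip=None, dropout=0.0, residual_connection=False, batch_size=10,
    n_epochs=69, washout=250,
)
RAT_PRESET = TrainConfig(
    hidden_size=290, n_layers=2, loss="cc", learning_rate=0.001, l2=0.0003,
    grad_clip=None, dropout=0.128, residual_connection=True, batch_size=22,
    n_epochs=87, washout=250,
)


# ---------------------------------------------------------------------------
# forward / backward over sequences


def _forward_sequence(params: GRUParams, X: np.ndarray,
                      dropout_masks: list[np.ndarray] | None = None,
                      store: bool = False):
    """Run the stacked recurrence over X of shape (T, B).

    Returns (Y, H_last, cache): Y (T, B) readout outputs, H_last (T, B, H)
    hidden states of the last layer, and, when ``store``, the per-layer
    caches needed for backpropagation.
    """
    T, B = X.shape
    H = params.hidden_size
    layer_input = X[:, :, None]  # (T, B, 1)
    caches = []
    h_seq = None
    for li, layer in enumerate(params.layers):
        h = np.zeros((B, H))
        h_seq = np.empty((T, B, H))
        cache = {"x": layer_input, "r": np.empty((T, B, H)),
                 "z": np.empty((T, B, H)), "n": np.empty((T, B, H)),
                 "a": np.empty((T, B, H)), "h_prev": np.empty((T, B, H))} \
            if store else None
        Wi = np.concatenate([layer.W_ir, layer.W_iz, layer.W_in], axis=0)  # (3H, D)
        bi = np.concatenate([layer.b_ir, layer.b_iz, layer.b_in])
        Wh = np.concatenate([layer.W_hr, layer.W_hz], axis=0)  # (2H, H)
        bh = np.concatenate([layer.b_hr, layer.b_hz])
        x_proj = layer_input @ Wi.T + bi  # (T, B, 3H)
        for t in range(T):
            rz_pre = h @ Wh.T + bh
            r = _sigmoid(x_proj[t, :, :H] + rz_pre[:, :H])
            z = _sigmoid(x_proj[t, :, H:2 * H] + rz_pre[:, H:])
            a = h @ layer.W_hn.T + layer.b_hn
            n = np.tanh(x_proj[t, :, 2 * H:] + r * a)
            h_new = (1.0 - z) * n + z * h
            if store:
                cache["r"][t] = r
                cache["z"][t] = z
                cache["n"][t] = n
                cache["a"][t] = a
                cache["h_prev"][t] = h
            h = h_new
            h_seq[t] = h
        caches.append(cache)
        layer_input = h_seq
        if dropout_masks is not None and li < len(params.layers) - 1:
            layer_input = layer_input * dropout_masks[li]
            if store:
                pass  # mask applied to next layer's cached x
    w_h = params.w_out[:H]
    y = h_seq @ w_h + params.b_out
    if params.residual:
        y = y + X * params.w_out[H]
    return y, h_seq, caches


def _zero_grads(params: GRUParams) -> dict:
    grads = {"w_out": np.zeros_like(params.w_out), "b_out": 0.0, "layers": []}
    for layer in params.layers:
        grads["layers"].append(
            {f: np.zeros_like(getattr(layer, f)) for f in LayerParams.FIELDS}
        )
    return grads


def _backward_sequence(params: GRUParams, X: np.ndarray, caches: list,
                       h_last_seq: np.ndarray, dY: np.ndarray,
                       dropout_masks: list[np.ndarray] | None = None) -> dict:
    """BPTT for the stacked GRU + readout; dY has shape (T, B)."""
    T, B = X.shape
    H = params.hidden_size
    grads = _zero_grads(params)

    # readout
    grads["w_out"][:H] = np.einsum("tb,tbh->h", dY, h_last_seq)
    if params.residual:
        grads["w_out"][H] = float(np.sum(dY * X))
    grads["b_out"] = float(np.sum(dY))
    w_h = params.w_out[:H]
    d_layer_out = dY[:, :, None] * w_h  # (T, B, H) gradient w.r.t. last layer h_seq

    for li in range(len(params.layers) - 1, -1, -1):
        layer = params.layers[li]
        cache = caches[li]
        g = grads["layers"][li]
        x_seq = cache["x"]  # already includes the dropout mask when li > 0
        d_x_seq = np.zeros_like(x_seq)
        dh_carry = np.zeros((B, H))
        dW_ir, dW_iz, dW_in = g["W_ir"], g["W_iz"], g["W_in"]
        dW_hr, dW_hz, dW_hn = g["W_hr"], g["W_hz"], g["W_hn"]
        for t in range(T - 1, -1, -1):
            dh = d_layer_out[t] + dh_carry
            r, z, n = cache["r"][t], cache["z"][t], cache["n"][t]
            a, h_prev = cache["a"][t], cache["h_prev"][t]
            x_t = x_seq[t]
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_prev = dh * z
            dpre_n = dn * (1.0 - n**2)
            dr = dpre_n * a
            da = dpre_n * r
            dpre_r = dr * r * (1.0 - r)
            dpre_z = dz * z * (1.0 - z)
            dW_in += dpre_n.T @ x_t
            dW_hn += da.T @ h_prev
            dW_ir += dpre_r.T @ x_t
            dW_hr += dpre_r.T @ h_prev
            dW_iz += dpre_z.T @ x_t
            dW_hz += dpre_z.T @ h_prev
            g["b_in"] += dpre_n.sum(axis=0)
            g["b_hn"] += da.sum(axis=0)
            g["b_ir"] += dpre_r.sum(axis=0)
            g["b_hr"] += dpre_r.sum(axis=0)
            g["b_iz"] += dpre_z.sum(axis=0)
            g["b_hz"] += dpre_z.sum(axis=0)
            dh_prev += da @ layer.W_hn + dpre_r @ layer.W_hr + dpre_z @ layer.W_hz
            d_x_seq[t] = dpre_n @ layer.W_in + dpre_r @ layer.W_ir + dpre_z @ layer.W_iz
            dh_carry = dh_prev
        if li > 0:
            d_layer_out = d_x_seq
            if dropout_masks is not None:
                d_layer_out = d_layer_out * dropout_masks[li - 1]
    return grads


def _flatten_params(params: GRUParams) -> list[np.ndarray]:
    arrays = [params.w_out, np.atleast_1d(params.b_out)]
    for layer in params.layers:
        arrays.extend(getattr(layer, f) for f in LayerParams.FIELDS)
    return arrays


def _grad_arrays(grads: dict) -> list[np.ndarray]:
    arrays = [grads["w_out"], np.atleast_1d(grads["b_out"])]
    for g in grads["layers"]:
        arrays.extend(g[f] for f in LayerParams.FIELDS)
    return arrays


class _Adam:
    """Plain Adam on a list of parameter arrays (b_out handled as 1-vector)."""

    def __init__(self, shapes, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> list[np.ndarray]:
        self.t += 1
        updates = []
        for i, g in enumerate(grads):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            updates.append(-self.lr * mh / (np.sqrt(vh) + self.eps))
        return updates


def _apply_updates(params: GRUParams, updates: list[np.ndarray]) -> None:
    params.w_out += updates[0]
    params.b_out += float(updates[1][0])
    k = 2
    for layer in params.layers:
        for f in LayerParams.FIELDS:
            arr = getattr(layer, f)
            arr += updates[k]
            k += 1


# ---------------------------------------------------------------------------
# model / results


def _stack_pairs(pairs: list[TargetPair]) -> tuple[np.ndarray, np.ndarray, float]:
    lengths = {len(p.input) for p in pairs}
    if len(lengths) > 1:
        n = min(lengths)
    else:
        n = lengths.pop()
    X = np.stack([p.input.values[:n] for p in pairs], axis=1)  # (T, B)
    Y = np.stack([p.target.values[:n] for p in pairs], axis=1)
    return X, Y, pairs[0].input.dt


@dataclass
class PredictionRecord:
    """Prediction of one trace: aligned post-washout series and scores."""

    prediction: TimeSeries
    target: TimeSeries
    cc: float
    lag: float
    window_scores: TimeSeries
    label: str = ""


class GRUForecaster:
    """GRU model of 10-s-ahead slow-oscillation prediction.

    Parameters
    ----------
    pairs : list of TargetPair
        Training data (normalised inputs, band-passed shifted targets),
        typically produced by :func:`slowosc.preprocess.make_target_pair`.
    config : TrainConfig
        Architecture and optimisation settings; see :data:`HUMAN_PRESET`
        and :data:`RAT_PRESET` for the tuned configurations.
    """

    def __init__(self, pairs: list[TargetPair], config: TrainConfig = HUMAN_PRESET):
        if len(pairs) == 0:
            raise ValueError("need at least one training pair")
        shortest = min(len(p.input) for p in pairs)
        if shortest <= config.washout:
            raise ValueError(
                f"traces of length {shortest} not longer than washout {config.washout}"
            )
        self.pairs = list(pairs)
        self.config = config

    def fit(self, params_init_seed: int = 0, verbose: bool = False,
            log_path: str | Path | None = None) -> "GRUForecasterResults":
        """Train with Adam + L2 on post-washout loss; deterministic per seeds.

        ``log_path`` appends one JSON line per epoch (epoch, mean loss).
        """
        cfg = self.config
        X_all, Y_all, dt = _stack_pairs(self.pairs)
        T, n_traces = X_all.shape
        params = GRUParams.init(
            cfg.hidden_size, cfg.n_layers, cfg.residual_connection,
            seed=params_init_seed,
        )
        opt = _Adam([a.shape for a in _flatten_params(params)], cfg.learning_rate)
        order_rng = np.random.default_rng(cfg.seed)
        wash = cfg.washout
        loss_history: list[float] = []
        for epoch in range(cfg.n_epochs):
            order = order_rng.permutation(n_traces)
            epoch_losses = []
            for start in range(0, n_traces, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                X = X_all[:, idx]
                Y = Y_all[:, idx]
                masks = None
                if cfg.dropout > 0 and cfg.n_layers > 1:
                    keep = 1.0 - cfg.dropout
                    masks = [
                        (order_rng.random((1, len(idx), cfg.hidden_size)) < keep)
                        / keep
                        for _ in range(cfg.n_layers - 1)
                    ]
                y_hat, h_seq, caches = _forward_sequence(
                    params, X, dropout_masks=masks, store=True
                )
                dY = np.zeros_like(y_hat)
                batch_loss = 0.0
                for b in range(len(idx)):
                    loss_b, grad_b = _loss_and_grad(
                        y_hat[wash:, b], Y[wash:, b], cfg.loss
                    )
                    batch_loss += loss_b
                    dY[wash:, b] = grad_b
                batch_loss /= len(idx)
                dY /= len(idx)
                if not np.isfinite(batch_loss):
                    raise TrainingDiverged(
                        f"non-finite loss at epoch {epoch}, batch start {start}"
                    )
                grads = _backward_sequence(
                    params, X, caches, h_seq, dY, dropout_masks=masks
                )
                grad_arrays = _grad_arrays(grads)
                if cfg.l2 > 0:
                    for g, p in zip(grad_arrays, _flatten_params(params)):
                        g += cfg.l2 * p
                if cfg.grad_clip is not None:
                    norm = np.sqrt(sum(float(np.sum(g**2)) for g in grad_arrays))
                    if norm > cfg.grad_clip:
                        scale = cfg.grad_clip / norm
                        for g in grad_arrays:
                            g *= scale
                _apply_updates(params, opt.step(grad_arrays))
                epoch_losses.append(batch_loss)
            loss_history.append(float(np.mean(epoch_losses)))
            if verbose:
                print(f"epoch {epoch + 1}/{cfg.n_epochs}  loss {loss_history[-1]:+.4f}")
            if log_path is not None:
                with open(log_path, "a") as fh:
                    fh.write(json.dumps({"epoch": epoch,
                                         "loss": loss_history[-1]}) + "\n")
        return GRUForecasterResults(
            model=self, params=params, loss_history=np.asarray(loss_history),
            params_init_seed=params_init_seed, dt=dt,
        )


class GRUForecasterResults:
    """Fitted GRU forecaster: parameters, training diagnostics, prediction."""

    def __init__(self, model: GRUForecaster | None, params: GRUParams,
                 loss_history: np.ndarray, params_init_seed: int, dt: float):
        self.model = model
        self.params = params
        self.loss_history = np.asarray(loss_history)
        self.params_init_seed = params_init_seed
        self.dt = dt

    @property
    def config(self) -> TrainConfig:
        return self.model.config if self.model is not None else self._config

    def predict(self, pair: TargetPair, washout: int | None = None
                ) -> PredictionRecord:
        """Predict one trace; scores computed on post-washout samples only."""
        cfg_washout = self.config.washout if washout is None else washout
        if len(pair.input) <= cfg_washout:
            raise ValueError(
                f"trace length {len(pair.input)} not longer than washout {cfg_washout}"
            )
        X = pair.input.values[:, None]
        y_hat, _, _ = _forward_sequence(self.params, X, store=False)
        pred = y_hat[cfg_washout:, 0]
        tgt = pair.target.values[cfg_washout:]
        cc = evaluation.pearson_cc(pred, tgt)
        lag = evaluation.xcorr_lag(pred, tgt, dt=pair.input.dt)
        win = evaluation.sliding_window_cc(pred, tgt, dt=pair.input.dt)
        dt = pair.input.dt
        return PredictionRecord(
            prediction=TimeSeries(pred, dt=dt, label=f"{pair.input.label}_pred"),
            target=TimeSeries(tgt, dt=dt, label=f"{pair.input.label}_target"),
            cc=cc, lag=lag,
            window_scores=TimeSeries(win, dt=dt, label="window_cc"),
            label=pair.input.label,
        )

    def score_pairs(self, pairs: list[TargetPair]) -> pd.DataFrame:
        rows = [
            {"label": rec.label, "cc": rec.cc, "lag_s": rec.lag}
            for rec in (self.predict(p) for p in pairs)
        ]
        return pd.DataFrame(rows)

    def hidden_states(self, pair: TargetPair, washout: int | None = None
                      ) -> np.ndarray:
        """Post-washout hidden states of the last layer, shape (T', H)."""
        wash = self.config.washout if washout is None else washout
        X = pair.input.values[:, None]
        _, h_seq, _ = _forward_sequence(self.params, X, store=False)
        return h_seq[wash:, 0, :]

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "GRU slow-oscillation forecaster",
            "=" * 47,
            f"{'layers':<28}{cfg.n_layers:>19}",
            f"{'hidden size':<28}{cfg.hidden_size:>19}",
            f"{'loss':<28}{cfg.loss:>19}",
            f"{'learning rate':<28}{cfg.learning_rate:>19.5g}",
            f"{'L2':<28}{cfg.l2:>19.5g}",
            f"{'residual readout':<28}{str(cfg.residual_connection):>19}",
            f"{'batch size':<28}{cfg.batch_size:>19}",
            f"{'epochs':<28}{cfg.n_epochs:>19}",
            f"{'washout (samples)':<28}{cfg.washout:>19}",
            f"{'init seed':<28}{self.params_init_seed:>19}",
            f"{'final training loss':<28}{self.loss_history[-1]:>19.4f}",
            "=" * 47,
        ]
        return "\n".join(lines)

    # -- serialisation ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Save config (JSON) + weights (npz) as ``path`` and ``path.npz``."""
        path = Path(path)
        arrays = {"w_out": self.params.w_out,
                  "b_out": np.atleast_1d(self.params.b_out)}
        for i, layer in enumerate(self.params.layers):
            for f in LayerParams.FIELDS:
                arrays[f"layer{i}_{f}"] = getattr(layer, f)
        np.savez(path.with_suffix(path.suffix + ".npz"), **arrays)
        meta = {
            "config": asdict(self.config),
            "params_init_seed": self.params_init_seed,
            "dt": self.dt,
            "residual": self.params.residual,
            "n_layers": self.params.n_layers,
            "loss_history": self.loss_history.tolist(),
        }
        path.write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "GRUForecasterResults":
        path = Path(path)
        meta = json.loads(path.read_text())
        data = np.load(path.with_suffix(path.suffix + ".npz"))
        layers = []
        for i in range(meta["n_layers"]):
            layers.append(LayerParams(
                **{f: data[f"layer{i}_{f}"] for f in LayerParams.FIELDS}
            ))
        params = GRUParams(layers=layers, w_out=data["w_out"],
                           b_out=float(data["b_out"][0]),
                           residual=meta["residual"])
        results = cls(model=None, params=params,
                      loss_history=np.asarray(meta["loss_history"]),
                      params_init_seed=meta["params_init_seed"], dt=meta["dt"])
        results._config = TrainConfig(**meta["config"])
        return results


# ---------------------------------------------------------------------------
# functional surface


def train(pairs: list[TargetPair], cfg: TrainConfig, params_init_seed: int = 0
          ) -> GRUForecasterResults:
    """Fit a :class:`GRUForecaster` on the given pairs."""
    return GRUForecaster(pairs, cfg).fit(params_init_seed=params_init_seed)


def predict(results: GRUForecasterResults, pair: TargetPair,
            washout: int | None = None) -> PredictionRecord:
    return results.predict(pair, washout=washout)


def crossvalidate(subjects: list[list[TargetPair]], cfg: TrainConfig,
                  params_init_seed: int = 0) -> pd.DataFrame:
    """Leave-one-subject-out: train on k-1 folds, score the held-out fold.

    Each element of ``subjects`` is one fold (all pairs of one subject or
    trial). Returns one row per held-out trace with its fold index.
    """
    if len(subjects) < 2:
        raise ValueError("cross-validation needs at least 2 folds")
    for k, fold in enumerate(subjects):
        if len(fold) == 0:
            raise ValueError(f"fold {k} contains no traces")
    frames = []
    for k, held_out in enumerate(subjects):
        train_pairs = [p for j, fold in enumerate(subjects) if j != k for p in fold]
        # canonical order: fold scores must not depend on subject ordering
        train_pairs.sort(key=lambda p: p.input.label)
        results = GRUForecaster(train_pairs, cfg).fit(params_init_seed=params_init_seed)
        scores = results.score_pairs(held_out)
        scores.insert(0, "fold", k)
        frames.append(scores)
    return pd.concat(frames, ignore_index=True)


# Search space matching the tuned hyperparameter ranges.
DEFAULT_SEARCH_SPACE: dict = {
    "n_layers": (1, 5),
    "hidden_size": (10, 500),
    "loss": ["mse", "cc", "mse+cc"],
    "learning_rate": ("log", 1e-5, 1.0),
    "l2": (0.0, 10.0),
    "grad_clip": [None, 1.0],
    "dropout": (0.0, 0.2),
    "residual_connection": [False, True],
    "batch_size": (3, 32),
    "n_epochs": (1, 100),
}

_INT_KEYS = {"n_layers", "hidden_size", "batch_size", "n_epochs"}


def _sample_config(space: dict, rng: np.random.Generator, washout: int
                   ) -> TrainConfig:
    kwargs = {"washout": washout}
    for key, spec in space.items():
        if isinstance(spec, list):
            kwargs[key] = spec[rng.integers(len(spec))]
        elif isinstance(spec, tuple) and spec[0] == "log":
            lo, hi = np.log(spec[1]), np.log(spec[2])
            kwargs[key] = float(np.exp(rng.uniform(lo, hi)))
        elif isinstance(spec, tuple):
            lo, hi = spec
            if key in _INT_KEYS:
                kwargs[key] = int(rng.integers(lo, hi + 1))
            else:
                kwargs[key] = float(rng.uniform(lo, hi))
        else:
            kwargs[key] = spec  # collapsed to a single point
    return TrainConfig(**kwargs)


def hyperparameter_search(
    subjects: list[list[TargetPair]],
    space: dict | None = None,
    n_evals: int = 200,
    seed: int = 0,
    washout: int = 250,
) -> tuple[TrainConfig, pd.DataFrame]:
    """Seeded random search over the configuration space.

    Every candidate is scored by mean cross-validated CC over the folds;
    configurations that diverge score -inf. Returns the best
    :class:`TrainConfig` and a log of all evaluated configurations.
    """
    if n_evals < 1:
        raise ValueError("n_evals must be >= 1")
    space = DEFAULT_SEARCH_SPACE if space is None else space
    rng = np.random.default_rng(seed)
    rows = []
    best_cfg, best_score = None, -np.inf
    for k in range(n_evals):
        cfg = _sample_config(space, rng, washout)
        try:
            table = crossvalidate(subjects, cfg)
            score = float(table["cc"].mean())
        except (TrainingDiverged, FloatingPointError, ValueError):
            score = -np.inf
        rows.append({"eval": k, "score": score, **asdict(cfg)})
        if score > best_score:
            best_cfg, best_score = cfg, score
    return best_cfg, pd.DataFrame(rows)


def hidden_state_pca(results: GRUForecasterResults, pair: TargetPair,
                     n_components: int | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """PCA of post-washout hidden states.

    Returns (scores, explained_variance_ratio): scores is (T', k) component
    time courses ordered by decreasing variance.
    """
    H = results.hidden_states(pair)
    centered = H - H.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2 / (H.shape[0] - 1)
    ratio = var / var.sum()
    scores = centered @ vt.T
    if n_components is not None:
        scores = scores[:, :n_components]
        ratio = ratio[:n_components]
    return scores, ratio
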