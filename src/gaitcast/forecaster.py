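"""Multi-head LSTM forecaster with a discount-weighted multi-output loss.

The model maps a window of ``p`` past sensor samples (all ``N`` channels)
directly to ``f`` future frames.  A single LSTM layer (``5 x f`` units by
default) summarises the input window; its final hidden state feeds ``f``
parallel dense heads, head ``i`` emitting frame ``t+1+i``.  Trajectory
heads are linear; gait-phase heads are softmax over the five phases.

Training minimises a discount-weighted loss

    L = mean_over_windows  sum_{i=0}^{f-1} alpha^i * l_i  +  lambda * sum|W|

where ``l_i`` is the squared error (trajectory) or categorical
cross-entropy (phase) of frame ``i`` and ``alpha`` in [0, 1] down-weights
distant frames so the optimiser concentrates on the immediate future.
``alpha = 1`` recovers the unweighted multi-output loss.  The L1 penalty
covers weight matrices only, not biases.

The network, backpropagation through time and the Adam optimiser are
implemented directly on NumPy arrays; everything is deterministic for a
fixed config seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .errors import TrainingDivergedError, ValidationError
from .windowing import WindowedDataset

P_FLOOR = 1e-12  # probability floor inside cross-entropy, avoids log(0)


@dataclass(frozen=True)
class ForecastConfig:
    """Hyperparameters of one forecaster.

    ``units_multiplier`` sets the LSTM width to ``units_multiplier * f``;
    ``alpha`` is the discount factor (default 0.8 for trajectory, set 1.0
    for phase prediction); ``lambda_l1`` the sparsity penalty weight.
    """

    p: int = 30
    f: int = 10
    units_multiplier: int = 5
    alpha: float = 0.8
    lambda_l1: float = 1e-4
    task: str = "trajectory"
    n_layers: int = 1
    max_epochs: int = 100
    patience: int = 10
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must lie in [0, 1]")
        if self.lambda_l1 < 0:
            raise ValidationError("lambda_l1 must be >= 0")
        if self.task not in ("trajectory", "phase"):
            raise ValidationError("task must be 'trajectory' or 'phase'")
        if self.f < 1 or self.p < 1 or self.n_layers < 1:
            raise ValidationError("p, f and n_layers must be >= 1")

    @property
    def units(self) -> int:
        return self.units_multiplier * self.f


def discount_weights(alpha: float, f: int) -> np.ndarray:
    """Exponential frame weights ``w_i = alpha**i`` for i = 0..f-1.

    The first predicted frame always has weight 1 (convention 0**0 = 1).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must lie in [0, 1]")
    if f < 1:
        raise ValidationError("f must be >= 1")
    w = np.empty(f)
    w[0] = 1.0
    if f > 1:
        w[1:] = alpha ** np.arange(1, f)
    return w


def _l1_penalty(lambda_l1: float, theta) -> float:
    if lambda_l1 == 0 or theta is None:
        return 0.0
    return lambda_l1 * float(sum(np.abs(np.asarray(w)).sum() for w in theta))


def discounted_mse_loss(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    alpha: float,
    lambda_l1: float = 0.0,
    theta=None,
) -> float:
    """Discount-weighted squared-error loss.

    For a single window (f, D) the value is
    ``sum_i alpha**i * ||y_true_i - y_pred_i||^2 + lambda * sum|theta|``;
    for a batch (n, f, D) the data term is averaged over windows and the
    penalty added once.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValidationError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    if y_true.ndim == 2:
        y_true, y_pred = y_true[None], y_pred[None]
    elif y_true.ndim != 3:
        raise ValidationError("expected (f, D) or (n, f, D) arrays")
    w = discount_weights(alpha, y_true.shape[1])
    per_frame = ((y_true - y_pred) ** 2).sum(axis=2)  # (n, f)
    data = float((per_frame * w).sum(axis=1).mean())
    return data + _l1_penalty(lambda_l1, theta)


def discounted_ce_loss(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    alpha: float,
    lambda_l1: float = 0.0,
    theta=None,
) -> float:
    """Discount-weighted categorical cross-entropy.

    Mirrors :func:`discounted_mse_loss` with per-frame cross-entropy
    ``-sum_c t_c log(max(p_c, p_floor))`` replacing the squared error.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValidationError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    if y_true.ndim == 2:
        y_true, y_pred = y_true[None], y_pred[None]
    elif y_true.ndim != 3:
        raise ValidationError("expected (f, C) or (n, f, C) arrays")
    sums = y_pred.sum(axis=2)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValidationError("probability rows must sum to 1 within 1e-6")
    w = discount_weights(alpha, y_true.shape[1])
    ce = -(y_true * np.log(np.maximum(y_pred, P_FLOOR))).sum(axis=2)  # (n, f)
    data = float((ce * w).sum(axis=1).mean())
    return data + _l1_penalty(lambda_l1, theta)


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class ForecastModel:
    """A (possibly stacked) LSTM with ``f`` parallel dense output heads."""

    def __init__(self, config: ForecastConfig, n_features: int, n_targets: int):
        if n_features <= 0 or n_targets <= 0:
            raise ValidationError("n_features and n_targets must be positive")
        self.config = config
        self.n_features = n_features
        self.n_targets = n_targets
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        rng = np.random.default_rng(config.seed)
        H = config.units
        self.params: dict[str, np.ndarray] = {}
        in_dim = n_features
        for l in range(config.n_layers):
            self.params[f"Wx{l}"] = _glorot(rng, (in_dim, 4 * H))
            self.params[f"Wh{l}"] = _glorot(rng, (H, 4 * H))
            b = np.zeros(4 * H)
            b[H : 2 * H] = 1.0  # forget-gate bias init
            self.params[f"b{l}"] = b
            in_dim = H
        for i in range(config.f):
            self.params[f"Wy{i}"] = _glorot(rng, (H, n_targets))
            self.params[f"by{i}"] = np.zeros(n_targets)

    # ---- low-level forward / backward -------------------------------

    def _lstm_forward(self, X: np.ndarray, layer: int, keep_cache: bool):
        """Run one LSTM layer over a (n, T, in_dim) sequence."""
        H = self.config.units
        Wx, Wh, b = (self.params[f"{k}{layer}"] for k in ("Wx", "Wh", "b"))
        n, T, _ = X.shape
        h = np.zeros((n, H))
        c = np.zeros((n, H))
        Hseq = np.empty((n, T, H))
        cache = [] if keep_cache else None
        for t in range(T):
            z = X[:, t] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            fg = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = fg * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            if keep_cache:
                cache.append((X[:, t], h, c, i, fg, g, o, c_new, tc))
            h, c = h_new, c_new
            Hseq[:, t] = h
        return Hseq, cache

    def _lstm_backward(self, dHseq: np.ndarray, layer: int, cache):
        """Backpropagate through one layer; returns grads and dX."""
        H = self.config.units
        Wx, Wh = self.params[f"Wx{layer}"], self.params[f"Wh{layer}"]
        n, T, _ = dHseq.shape
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dX = np.empty((n, T, Wx.shape[0]))
        dh_next = np.zeros((n, H))
        dc_next = np.zeros((n, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, fg, g, o, c_new, tc = cache[t]
            dh = dHseq[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            di = dc * g
            dfg = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    dfg * fg * (1 - fg),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t] = dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * fg
        return {f"Wx{layer}": dWx, f"Wh{layer}": dWh, f"b{layer}": db}, dX

    def _forward(self, X: np.ndarray, keep_cache: bool = False):
        caches = []
        seq = X
        for l in range(self.config.n_layers):
            seq, cache = self._lstm_forward(seq, l, keep_cache)
            caches.append(cache)
        hT = seq[:, -1]
        f, D = self.config.f, self.n_targets
        raw = np.empty((X.shape[0], f, D))
        for i in range(f):
            raw[:, i] = hT @ self.params[f"Wy{i}"] + self.params[f"by{i}"]
        if self.config.task == "phase":
            raw = raw - raw.max(axis=2, keepdims=True)
            e = np.exp(raw)
            out = e / e.sum(axis=2, keepdims=True)
        else:
            out = raw
        return out, hT, caches

    def predict(self, inputs: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        """Forecast ``f`` frames for each input window.

        Returns (n, f, D) values for the trajectory task or (n, f, 5)
        per-frame probability rows (each summing to 1) for the phase task.
        """
        inputs = np.asarray(inputs, dtype=float)
        if inputs.ndim != 3 or inputs.shape[1:] != (self.config.p, self.n_features):
            raise ValidationError(
                f"inputs must be (n, {self.config.p}, {self.n_features}), "
                f"got {inputs.shape}"
            )
        outs = []
        for lo in range(0, len(inputs), batch_size):
            out, _, _ = self._forward(inputs[lo : lo + batch_size])
            outs.append(out)
        return np.concatenate(outs) if outs else np.empty((0, self.config.f, self.n_targets))

    def predict_labels(self, inputs: np.ndarray) -> np.ndarray:
        """Phase codes via argmax (lowest index wins ties)."""
        if self.config.task != "phase":
            raise ValidationError("predict_labels requires a phase model")
        return np.argmax(self.predict(inputs), axis=2)

    # ---- loss plumbing ----------------------------------------------

    def _weight_keys(self) -> list[str]:
        keys = [f"Wx{l}" for l in range(self.config.n_layers)]
        keys += [f"Wh{l}" for l in range(self.config.n_layers)]
        keys += [f"Wy{i}" for i in range(self.config.f)]
        return keys

    def weights(self) -> list[np.ndarray]:
        """All trainable weight matrices (biases excluded), for the L1 term."""
        return [self.params[k] for k in self._weight_keys()]

    def batch_loss(self, out: np.ndarray, targets: np.ndarray,
                   include_penalty: bool = True) -> float:
        theta = self.weights() if include_penalty else None
        lam = self.config.lambda_l1 if include_penalty else 0.0
        if self.config.task == "phase":
            return discounted_ce_loss(targets, out, self.config.alpha, lam, theta)
        return discounted_mse_loss(targets, out, self.config.alpha, lam, theta)

    def _loss_and_grads(self, X: np.ndarray, targets: np.ndarray):
        cfg = self.config
        n = X.shape[0]
        out, hT, caches = self._forward(X, keep_cache=True)
        w = discount_weights(cfg.alpha, cfg.f)
        if cfg.task == "phase":
            # gradient wrt the pre-softmax logits: alpha^i (p - t) / n
            draw = (out - targets) * w[None, :, None] / n
        else:
            draw = 2.0 * (out - targets) * w[None, :, None] / n
        loss = self.batch_loss(out, targets)
        grads: dict[str, np.ndarray] = {}
        dhT = np.zeros_like(hT)
        for i in range(cfg.f):
            grads[f"Wy{i}"] = hT.T @ draw[:, i]
            grads[f"by{i}"] = draw[:, i].sum(axis=0)
            dhT += draw[:, i] @ self.params[f"Wy{i}"].T
        dHseq = np.zeros((n, cfg.p, cfg.units))
        dHseq[:, -1] = dhT
        for l in range(cfg.n_layers - 1, -1, -1):
            layer_grads, dHseq = self._lstm_backward(dHseq, l, caches[l])
            grads.update(layer_grads)
        if cfg.lambda_l1 > 0:
            for k in self._weight_keys():
                grads[k] = grads[k] + cfg.lambda_l1 * np.sign(self.params[k])
        return loss, grads

    def evaluate_loss(self, data: WindowedDataset, batch_size: int = 4096) -> float:
        """Mean data-term loss over a dataset (no penalty)."""
        targets = self._targets(data)
        total, count = 0.0, 0
        for lo in range(0, len(data), batch_size):
            out, _, _ = self._forward(data.inputs[lo : lo + batch_size])
            nb = out.shape[0]
            total += self.batch_loss(out, targets[lo : lo + nb], include_penalty=False) * nb
            count += nb
        return total / max(count, 1)

    def _targets(self, data: WindowedDataset) -> np.ndarray:
        return data.targets_phase if self.config.task == "phase" else data.targets_trajectory

    # ---- checkpointing ----------------------------------------------

    def save(self, path) -> None:
        meta = dict(
            config=asdict(self.config),
            n_features=self.n_features,
            n_targets=self.n_targets,
            history=self.history,
        )
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "ForecastModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            model = cls(ForecastConfig(**meta["config"]), meta["n_features"],
                        meta["n_targets"])
            model.history = meta["history"]
            for k in model.params:
                model.params[k] = z[k]
        return model


def build_model(config: ForecastConfig, n_features: int, n_targets: int | None = None) -> ForecastModel:
    """Instantiate a forecaster; phase models always have 5-way heads."""
    if config.task == "phase":
        n_targets = 5
    if n_targets is None:
        raise ValidationError("n_targets is required for the trajectory task")
    return ForecastModel(config, n_features, n_targets)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def train(model: ForecastModel, train_data: WindowedDataset,
          val_data: WindowedDataset, verbose: bool = False) -> ForecastModel:
    """Mini-batch Adam training with early stopping.

    Runs at most ``max_epochs`` epochs and stops when the validation loss
    has not improved for ``patience`` consecutive epochs; the best-epoch
    weights are restored before returning.  Deterministic for a fixed
    config seed (shuffling uses its own stream).
    """
    if len(train_data) == 0 or len(val_data) == 0:
        raise ValidationError("train and validation datasets must be non-empty")
    cfg = model.config
    exp = (len(train_data), cfg.p, model.n_features)
    if train_data.inputs.shape != exp:
        raise ValidationError(f"training inputs {train_data.inputs.shape} != {exp}")
    rng = np.random.default_rng((cfg.seed, 0x5AD))
    opt = _Adam(model.params, cfg.learning_rate)
    targets = model._targets(train_data)
    best_loss = np.inf
    best_params = None
    bad_epochs = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_data))
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            loss, grads = model._loss_and_grads(train_data.inputs[idx], targets[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}"
                )
            opt.step(model.params, grads)
            epoch_loss += loss
            n_batches += 1
        val_loss = model.evaluate_loss(val_data)
        model.history["train_loss"].append(epoch_loss / n_batches)
        model.history["val_loss"].append(val_loss)
        if verbose:
            print(f"epoch {epoch:3d}  train {epoch_loss / n_batches:.5f}  val {val_loss:.5f}")
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    if best_params is not None:
        model.params = best_params
    return model


def predict(model: ForecastModel, inputs: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`ForecastModel.predict`."""
    return model.predict(inputs)


def split_validation(data: WindowedDataset, fraction: float,
                     seed: int) -> tuple[WindowedDataset, WindowedDataset]:
    """Random (train, val) partition of a windowed dataset."""
    if not 0 < fraction < 1:
        raise ValidationError("fraction must lie in (0, 1)")
    rng = np.random.default_rng((seed, 0x7A1))
    order = rng.permutation(len(data))
    n_val = max(1, int(round(fraction * len(data))))
    return data.subset(order[n_val:]), data.subset(order[:n_val])


def grid_search(grid: dict[str, list], data: WindowedDataset,
                base_config: ForecastConfig, n_features: int,
                n_targets: int | None = None, val_fraction: float = 0.25):
    """Exhaustive hyperparameter search on a held-out validation split.

    Returns ``(best_config, results)`` where ``results`` is one record per
    grid point with its validation metric (RMSE for trajectory, accuracy
    for phase).  Ties keep the lexicographically first grid point.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValidationError("grid must map every hyperparameter to a non-empty list")
    keys = list(grid)
    train_part, val_part = split_validation(data, val_fraction, base_config.seed)
    results = []
    best = None
    for combo in itertools.product(*(grid[k] for k in keys)):
        cfg = replace(base_config, **dict(zip(keys, combo)))
        model = build_model(cfg, n_features, n_targets)
        train(model, train_part, val_part)
        if cfg.task == "phase":
            pred = model.predict_labels(val_part.inputs)
            metric = float((pred == val_part.phase_labels).mean())
            better = best is None or metric > best[0]
        else:
            pred = model.predict(val_part.inputs)
            metric = float(np.sqrt(((pred - val_part.targets_trajectory) ** 2).mean()))
            better = best is None or metric < best[0]
        results.append({**dict(zip(keys, combo)), "metric": metric})
        if better:
            best = (metric, cfg)
    return best[1], results
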