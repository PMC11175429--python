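"""Gradient training of the neural forecasters.

The objective is the squared L2 prediction error with an L2 penalty on the
convolution and gate weights (biases excluded),

    Loss = ||Y - Y^||_2^2 + lambda ||theta||_2^2 ,

minimised with Adam on mini-batches of windows; the per-batch loss is the
per-element mean so the learning rate is insensitive to batch and panel
size.  Early stopping monitors validation loss and restores the best
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .models import NeuralForecaster
from .preprocess import WindowSet


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 64
    weight_decay: float = 1.5e-3  # lambda, the regularisation rate
    patience: int = 20
    max_grad_norm: float = 0.0  # global gradient clipping; 0 disables
    lr_decay_factor: float = 1.0  # multiply lr when validation stalls; 1 disables
    lr_patience: int = 10  # epochs without improvement before decaying
    adam_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def l2_objective(y_true, y_pred, weights=(), lam: float = 0.0):
    """Squared L2 error plus lam * squared L2 norm of the weights.

    Works on plain arrays (returns float) or on autodiff tensors (returns a
    scalar Tensor suitable for backpropagation).  Biases are excluded by
    passing only weight tensors.
    """
    if isinstance(y_pred, Tensor):
        diff = y_pred - Tensor._wrap(y_true)
        loss = (diff * diff).sum()
        for w in weights:
            loss = loss + lam * (w * w).sum()
        return loss
    y = np.asarray(y_true, dtype=float)
    yh = np.asarray(y_pred, dtype=float)
    if y.shape != yh.shape:
        raise ValueError("shape mismatch")
    loss = float(np.sum((y - yh) ** 2))
    for w in weights:
        arr = w.data if isinstance(w, Tensor) else np.asarray(w, float)
        loss += lam * float(np.sum(arr**2))
    return loss


class Adam:
    """Standard Adam over a parameter dict of Tensors."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def clip_gradients(self, max_norm: float) -> None:
        if not max_norm:
            return
        total = np.sqrt(
            sum(
                float(np.sum(p.grad**2))
                for p in self.params.values()
                if p.grad is not None
            )
        )
        if total > max_norm:
            scale = max_norm / total
            for p in self.params.values():
                if p.grad is not None:
                    p.grad = p.grad * scale


def _mse(model: NeuralForecaster, windows: WindowSet) -> float:
    pred = model.predict(windows.histories)
    return float(np.mean((pred - windows.targets) ** 2))


def train(
    model: NeuralForecaster,
    train_windows: WindowSet,
    val_windows: WindowSet | None = None,
    config: TrainConfig | None = None,
) -> dict:
    """Fit the model; returns a history dict and leaves the best state loaded.

    Deterministic given ``config.seed``: batch order and parameter
    initialisation are the only random elements.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    n = train_windows.n_samples
    dtype = getattr(model, "dtype", np.dtype(float))
    train_hist = train_windows.histories.astype(dtype, copy=False)
    train_targets = train_windows.targets.astype(dtype, copy=False)
    n_elem_per_sample = np.prod(train_windows.targets.shape[1:])
    weights = model.weight_tensors()
    optimizer = Adam(model.params, lr=config.learning_rate, eps=config.adam_eps)
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = model.get_state()
    patience_left = config.patience
    lr_patience_left = config.lr_patience
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            hist = Tensor(train_hist[idx])
            target = train_targets[idx]
            pred = model.forward(hist)
            # per-element mean error + weight penalty, per Loss above
            scale = 1.0 / (len(idx) * n_elem_per_sample)
            loss = l2_objective(target, pred, weights, config.weight_decay) * scale
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss {loss.data!r}; diverged"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.clip_gradients(config.max_grad_norm)
            optimizer.step()
            epoch_loss += float(loss.data) * len(idx)
        history["train_loss"].append(epoch_loss / n)
        monitor = _mse(model, val_windows) if val_windows is not None else history["train_loss"][-1]
        history["val_loss"].append(monitor)
        if monitor < best_val - 1e-12:
            best_val = monitor
            best_state = model.get_state()
            patience_left = config.patience
            lr_patience_left = config.lr_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
            lr_patience_left -= 1
            if lr_patience_left <= 0 and config.lr_decay_factor < 1.0:
                # restart the plateau search from the best state at a finer step
                model.set_state(best_state)
                optimizer.lr *= config.lr_decay_factor
                lr_patience_left = config.lr_patience
    model.set_state(best_state)
    history["best_val_loss"] = best_val
    return history
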