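"""Training protocol: cross-entropy loss, Adam, early stopping on
validation loss with best-weight restoration.

Defaults follow the published protocol: learning rate 1e-4, up to 800
epochs with minibatches of 32, and training stops once the validation loss
has not improved for 100 consecutive epochs; the weights of the
best-validation-loss epoch are restored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .data import MultiBandInput
from .model import LGCTModel
from .utils import derive_seed, one_hot

__all__ = ["TrainConfig", "TrainHistory", "cross_entropy", "train", "predict",
           "AdamOptimizer"]

logger = logging.getLogger(__name__)

_EPS = 1e-12  # clamp for log of a zero predicted probability


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    max_epochs: int = 800
    batch_size: int = 32
    patience_epochs: int = 100
    seed: int = 0
    shuffle: bool = True

    def validate(self) -> None:
        if min(self.learning_rate, self.max_epochs, self.batch_size,
               self.patience_epochs) <= 0:
            raise ValueError("all TrainConfig fields must be positive")
        if self.patience_epochs > self.max_epochs:
            raise ValueError("patience_epochs must be <= max_epochs")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    def to_dict(self) -> dict:
        return {"train_loss": self.train_loss, "val_loss": self.val_loss,
                "val_acc": self.val_acc, "best_epoch": self.best_epoch,
                "stopped_epoch": self.stopped_epoch}


def cross_entropy(y_pred: np.ndarray, y_true: np.ndarray) -> float:
    """Mean over the batch of -sum_m y_true[m] * log(y_pred[m])."""
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=np.float64))
    y_true = np.atleast_2d(np.asarray(y_true, dtype=np.float64))
    if y_pred.shape != y_true.shape:
        raise ValueError("prediction and target shapes differ")
    return float(-(y_true * np.log(np.maximum(y_pred, _EPS))).sum(axis=1).mean())


def _loss_tensor(probs: Tensor, y_onehot: np.ndarray) -> Tensor:
    y = y_onehot.astype(probs.data.dtype)
    n = y.shape[0]
    clipped = probs + float(_EPS)
    return -(clipped.log() * Tensor(y)).sum() * (1.0 / n)


class AdamOptimizer:
    """Adam with the cited defaults (beta1 0.9, beta2 0.999, eps 1e-8)."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / b1t
            v_hat = self.v[k] / b2t
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _as_band_arrays(data) -> list[np.ndarray]:
    if isinstance(data, MultiBandInput):
        return data.arrays()
    return [np.asarray(a) for a in data]


def _labels_of(data, labels) -> np.ndarray:
    if labels is not None:
        return np.asarray(labels, dtype=int)
    if isinstance(data, MultiBandInput):
        return data.labels
    raise ValueError("labels required when data is a plain band list")


def evaluate(model: LGCTModel, data, labels=None) -> tuple[float, float]:
    """(cross-entropy loss, accuracy in [0, 1]) in evaluation mode."""
    bands = _as_band_arrays(data)
    y = _labels_of(data, labels)
    probs, pred = predict(model, bands)
    loss = cross_entropy(probs, one_hot(y, probs.shape[1]))
    return loss, float((pred == y).mean())


def train(model: LGCTModel, train_set, val_set, cfg: TrainConfig,
          train_labels=None, val_labels=None) -> tuple[LGCTModel, TrainHistory]:
    """Adam + early stopping on validation loss; restores best weights.

    train_set / val_set are MultiBandInput (labels embedded) or plain lists
    of three band arrays with labels passed separately.
    """
    cfg.validate()
    tr_bands = _as_band_arrays(train_set)
    y_tr = _labels_of(train_set, train_labels)
    va_bands = _as_band_arrays(val_set)
    y_va = _labels_of(val_set, val_labels)
    n_val = len(y_va)
    if n_val == 0:
        raise ValueError("validation set is empty; early stopping is undefined")
    n = len(y_tr)
    if n == 0:
        raise ValueError("training set is empty")
    n_classes = model.cfg.n_classes
    y_hot = one_hot(y_tr, n_classes)
    rng = np.random.default_rng(derive_seed(cfg.seed, "shuffle"))
    opt = AdamOptimizer(model.parameters(), cfg.learning_rate)
    hist = TrainHistory()
    best_loss = np.inf
    best_state: dict[str, np.ndarray] | None = None
    since_best = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        ep_loss, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = [b[idx] for b in tr_bands]
            model.zero_grad()
            probs = model.forward(batch, training=True)
            loss = _loss_tensor(probs, y_hot[idx])
            loss.backward()
            opt.step()
            ep_loss += float(loss.data)
            n_batches += 1
        val_loss, val_acc = evaluate(model, va_bands, y_va)
        hist.train_loss.append(ep_loss / n_batches)
        hist.val_loss.append(val_loss)
        hist.val_acc.append(val_acc)
        if val_loss < best_loss:
            best_loss = val_loss
            hist.best_epoch = epoch
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
            since_best = 0
        else:
            since_best += 1
        logger.info("epoch %d train_loss %.4f val_loss %.4f val_acc %.3f "
                    "patience %d/%d", epoch, hist.train_loss[-1], val_loss,
                    val_acc, since_best, cfg.patience_epochs)
        if since_best >= cfg.patience_epochs:
            break
    hist.stopped_epoch = epoch
    if best_state is not None:
        model.load_state_arrays(best_state)
    return model, hist


def predict(model: LGCTModel, data) -> tuple[np.ndarray, np.ndarray]:
    """Evaluation-mode class probabilities and argmax labels
    (lowest index wins ties)."""
    bands = _as_band_arrays(data)
    n = bands[0].shape[0]
    chunk = 64  # bound peak memory on large evaluation sets
    parts = [model.forward([b[i : i + chunk] for b in bands],
                           training=False).data
             for i in range(0, n, chunk)]
    probs = np.concatenate(parts, axis=0)
    return probs, probs.argmax(axis=1)
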