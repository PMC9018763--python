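"""Adam training loop with validation-plateau early stopping.

Training stops when the best validation loss has not improved by more than
``patience_tolerance`` for ``patience_epochs`` consecutive epochs ("model
performance unchanged for N epochs"), or at ``max_epochs``; the returned
predictor carries the best-validation snapshot of the weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from dentseg.nets.losses import losses_and_logit_grads
from dentseg.nets.model import NetPredictor


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 1
    patience_epochs: int = 5
    patience_tolerance: float = 1e-4
    max_epochs: int = 50
    loss_weights: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.patience_epochs < 1:
            raise ValueError("patience_epochs must be >= 1")
        if any(w < 0 for w in self.loss_weights.values()):
            raise ValueError("loss weights must be non-negative")


class EarlyStopper:
    """Counts epochs without improvement beyond tolerance over the best."""

    def __init__(self, patience: int, tolerance: float):
        self.patience = patience
        self.tolerance = tolerance
        self.best = math.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record an epoch's validation loss; True means stop now."""
        if val_loss < self.best - self.tolerance:
            self.best = val_loss
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _sample_loss_and_grads(net, sample, cfg: TrainConfig, grads=None):
    keep = grads is not None
    head_raw, cls_logits, cache = net.forward(sample["input"], keep_cache=keep)
    losses, dhead, dcls = losses_and_logit_grads(
        head_raw,
        cls_logits,
        sample["targets"],
        net.cfg,
        mask=sample.get("fg_mask"),
        weights=cfg.loss_weights,
        class_target=sample.get("class_index"),
    )
    if keep:
        net.backward(dhead, dcls, cache, grads)
    return losses["total"]


def evaluate_loss(predictor: NetPredictor, dataset: Sequence[dict], cfg: TrainConfig) -> float:
    return float(
        np.mean([_sample_loss_and_grads(predictor.net, s, cfg) for s in dataset])
    )


def train_model(
    predictor: NetPredictor,
    train_set: Sequence[dict],
    val_set: Sequence[dict],
    cfg: TrainConfig,
    val_loss_fn: Callable[[int], float] | None = None,
) -> tuple[NetPredictor, list[dict]]:
    """Train in place and return (best-snapshot predictor, history).

    Samples are dicts with ``input`` (C, D, H, W), ``targets`` (head name ->
    array), optional ``fg_mask`` and ``class_index``.  ``val_loss_fn``
    substitutes the validation evaluation (used to exercise the stopping
    rule with hand-constructed loss traces).
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be nonempty")
    net = predictor.net
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.params, cfg.learning_rate)
    stopper = EarlyStopper(cfg.patience_epochs, cfg.patience_tolerance)
    history: list[dict] = []
    best_params = {k: v.copy() for k, v in net.params.items()}
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train_set))
        train_losses = []
        for i in order:
            grads = {k: np.zeros_like(v) for k, v in net.params.items()}
            train_losses.append(_sample_loss_and_grads(net, train_set[i], cfg, grads))
            opt.step(grads)
        if val_loss_fn is not None:
            val_loss = float(val_loss_fn(epoch))
        else:
            val_loss = evaluate_loss(predictor, val_set, cfg)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(train_losses)), "val_loss": val_loss}
        )
        stop = stopper.update(epoch, val_loss)
        if stopper.best_epoch == epoch:
            best_params = {k: v.copy() for k, v in net.params.items()}
        if stop:
            break
    net.params.update({k: v.copy() for k, v in best_params.items()})
    return predictor, history
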