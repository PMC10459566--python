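"""The training recipe: SGD with momentum, decaying learning rate, 10 epochs.

Defaults are the reference settings — initial learning rate 0.002 decaying at
0.0009 per iteration, momentum 0.9, batch size 50, 10 epochs, cross-entropy
loss.  Because inference is multi-label (one sigmoid per tool), the default
loss is mean per-class binary cross-entropy on the logits; a single-label
softmax variant is kept behind ``loss="softmax"`` for the 8-class reading.

"Decaying at a rate of 0.0009 per iteration" is realised as inverse-time
decay, ``lr_t = lr0 / (1 + 0.0009 t)``: it is positive and strictly
decreasing for every iteration, unlike a subtractive rule (which crosses
zero after three steps).  Subtractive and multiplicative readings remain
available via ``lr_rule``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .metrics import APResult, mean_average_precision
from .nn import SGDM, bce_with_logits, softmax_cross_entropy
from .resnet import ResNet

LR_RULES = ("inverse_time", "subtractive", "multiplicative")


@dataclass
class TrainConfig:
    lr0: float = 0.002
    lr_decay: float = 0.0009
    epochs: int = 10
    batch_size: int = 50
    momentum: float = 0.9
    loss: str = "bce"                    # "bce" | "softmax"
    lr_rule: str = "inverse_time"
    seed: int = 0

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.loss not in ("bce", "softmax"):
            raise ValueError("loss must be 'bce' or 'softmax'")
        if self.lr_rule not in LR_RULES:
            raise ValueError(f"lr_rule must be one of {LR_RULES}")

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class TrainLog:
    iterations: list = field(default_factory=list)   # (iter, lr, loss)
    epochs: list = field(default_factory=list)       # dicts per epoch

    def losses(self) -> np.ndarray:
        return np.array([rec[2] for rec in self.iterations])

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"iterations": self.iterations, "epochs": self.epochs}, indent=1))

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.iterations,
                     columns=["iter", "lr", "loss"]).to_csv(path, index=False)


def lr_schedule(iteration: int, cfg: TrainConfig) -> float:
    """Learning rate at a (0-based) iteration under the configured rule."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    if cfg.lr_rule == "inverse_time":
        return cfg.lr0 / (1.0 + cfg.lr_decay * iteration)
    if cfg.lr_rule == "multiplicative":
        return cfg.lr0 * (1.0 - cfg.lr_decay) ** iteration
    return max(cfg.lr0 - cfg.lr_decay * iteration, 0.0)


def _as_arrays(dataset):
    if isinstance(dataset, tuple):
        x, y = dataset
    else:
        x, y = dataset.training_arrays()
    x = np.ascontiguousarray(x, dtype=np.float32)
    y = np.ascontiguousarray(y, dtype=np.float32)
    if len(x) != len(y):
        raise ValueError("images and labels are misaligned")
    return x, y


def train(model, dataset, cfg: TrainConfig | None = None,
          checkpoint_dir=None, val_dataset=None, thresholds=None):
    """Run the full recipe; returns ``(model, TrainLog)``.

    ``dataset`` is either a :class:`~pcsem.synthetic.SyntheticDataset` or a
    ``(images, labels)`` pair with images (N,3,H,W) float32 and labels
    (N,K) float32.  A fixed ``cfg.seed`` fixes the batch order, so two runs
    with identical seeds and data produce identical loss logs.
    """
    cfg = cfg or TrainConfig()
    x, y = _as_arrays(dataset)
    head = model.fc.out_features if hasattr(model, "fc") else None
    if head is not None and y.shape[1] != head:
        raise ValueError(f"label width {y.shape[1]} does not match the "
                         f"{head}-unit classification head")
    loss_fn = bce_with_logits if cfg.loss == "bce" else softmax_cross_entropy
    rng = np.random.default_rng(cfg.seed)
    opt = SGDM(model.parameters(), momentum=cfg.momentum)
    log = TrainLog()
    n = len(x)
    it = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model.forward(x[idx], train=True)
            loss, dlogits = loss_fn(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss} at iteration {it}; "
                    "reduce the learning rate or check the inputs")
            opt.zero_grad()
            model.backward(dlogits)
            lr = lr_schedule(it, cfg)
            opt.step(lr)
            log.iterations.append((it, lr, loss))
            epoch_losses.append(loss)
            it += 1
        rec = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if val_dataset is not None:
            rec["val_map"] = evaluate(model, val_dataset, thresholds).map
        log.epochs.append(rec)
        if checkpoint_dir is not None:
            Path(checkpoint_dir).mkdir(parents=True, exist_ok=True)
            model.save(Path(checkpoint_dir) / f"epoch{epoch:03d}.npz")
    return model, log


def predict_scores(model, x: np.ndarray, batch_size: int = 50) -> np.ndarray:
    """Per-class sigmoid probabilities over a stack of images (eval mode)."""
    out = []
    for start in range(0, len(x), batch_size):
        logits = model.forward(x[start:start + batch_size], train=False)
        out.append(1.0 / (1.0 + np.exp(-logits.astype(np.float64))))
    return np.concatenate(out, axis=0)


def evaluate(model: ResNet, dataset, thresholds=None,
             batch_size: int = 50) -> APResult:
    """Sigmoid scores over the dataset, then threshold-swept mAP."""
    x, y = _as_arrays(dataset)
    scores = predict_scores(model, x, batch_size)
    return mean_average_precision(scores, y.astype(int), thresholds)
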