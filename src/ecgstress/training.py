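"""Loss, schedule, and the three training regimes.

* Regime I  — train from He initialization on the large (driving) set,
  base learning rate 1e-3.
* Regime II — identical recipe on the small (mental-arithmetic) set.
* Regime III — transfer: load a regime-I checkpoint, re-initialize the
  softmax head, freeze stages 1..7 (parameters *and* batch-norm running
  statistics) and fine-tune stage 8 + head at base learning rate 1e-4.

All regimes: Adam (0.9 / 0.999 / 1e-8), mini-batch 64, at most 10 epochs,
learning rate divided by 10 every 5 epochs, and the returned model is the
epoch snapshot with the highest test accuracy.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np

from . import nn
from .dataset import WindowedDataset
from .model import (ModelConfig, StressNet, build_model, he_initialize,
                    he_initialize_head, load_checkpoint, predict)

REGIMES = ("I", "II", "III")

_CLIP = 1e-12


class TrainingError(RuntimeError):
    pass


class TransferError(TrainingError):
    pass


@dataclass
class TrainConfig:
    regime: str
    seed: int = 0
    batch_size: int = 64
    max_epochs: int = 10
    base_lr: float | None = None           # derived from regime if None
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 5
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    frozen_stages: frozenset[int] = None   # derived from regime if None

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if self.base_lr is None:
            self.base_lr = 1e-4 if self.regime == "III" else 1e-3
        if self.frozen_stages is None:
            self.frozen_stages = (frozenset(range(1, 8))
                                  if self.regime == "III" else frozenset())
        else:
            self.frozen_stages = frozenset(self.frozen_stages)
        if self.max_epochs > 10:
            raise ValueError("max_epochs is capped at 10")


@dataclass
class EpochEntry:
    epoch: int
    lr: float
    loss: float
    train_acc: float
    test_acc: float


@dataclass
class TrainLog:
    entries: list[EpochEntry] = field(default_factory=list)
    selected_epoch: int | None = None

    @property
    def losses(self) -> list[float]:
        return [e.loss for e in self.entries]

    @property
    def test_accuracies(self) -> list[float]:
        return [e.test_acc for e in self.entries]


def cross_entropy(h: np.ndarray, y: np.ndarray,
                  m: int | None = None) -> float:
    """Mean binary cross-entropy of predicted stress probabilities ``h``.

    Probabilities are clipped to [1e-12, 1 - 1e-12] to guard log(0).
    """
    h = np.clip(np.asarray(h, np.float64), _CLIP, 1.0 - _CLIP)
    y = np.asarray(y, np.float64)
    if m is None:
        m = len(h)
    return float(-(y * np.log(h) + (1.0 - y) * np.log(1.0 - h)).sum() / m)


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Step decay: base_lr * factor**(epoch // every)."""
    if not 0 <= epoch < cfg.max_epochs:
        raise ValueError(f"epoch {epoch} outside 0..{cfg.max_epochs - 1}")
    return cfg.base_lr * cfg.lr_decay_factor ** (epoch // cfg.lr_decay_every)


def accuracy(net: StressNet, ds: WindowedDataset) -> float:
    _, pred = predict(net, ds.windows)
    return float((pred == ds.labels).mean())


def _eval_accuracy(net: StressNet, x: np.ndarray, y: np.ndarray,
                   start_stage: int, batch_size: int = 256) -> float:
    correct = 0
    for i in range(0, x.shape[0], batch_size):
        logits = net.forward(x[i:i + batch_size], training=False,
                             start_stage=start_stage)
        correct += int((logits.argmax(axis=1) == y[i:i + batch_size]).sum())
    return correct / len(y)


def train(net: StressNet, ds: WindowedDataset, cfg: TrainConfig,
          test_ds: WindowedDataset,
          recalibrate_bn: bool = True) -> tuple[StressNet, TrainLog]:
    """Run one training regime; returns the best-epoch snapshot and log.

    ``recalibrate_bn`` re-estimates batch-norm running statistics over
    the training windows after each epoch (see
    ``StressNet.recalibrate_bn``); momentum-based tracking alone needs
    far more optimizer steps than small cohorts provide.
    """
    if len(ds) == 0:
        raise TrainingError("empty training dataset")
    if cfg.regime == "III" and not net.frozen_stages:
        raise TrainingError(
            "regime III requires a net prepared from a pretrained "
            "checkpoint (see prepare_transfer)")
    net.set_frozen_stages(cfg.frozen_stages)
    min_stage = (max(cfg.frozen_stages) + 1) if cfg.frozen_stages else 1
    adam = nn.Adam(cfg.beta1, cfg.beta2, cfg.eps)
    rng_shuffle = np.random.default_rng(np.random.SeedSequence(
        entropy=cfg.seed, spawn_key=(1,)))
    rng_dropout = np.random.default_rng(np.random.SeedSequence(
        entropy=cfg.seed, spawn_key=(2,)))

    # A frozen contiguous prefix of stages behaves exactly as at
    # inference, so its features are precomputed once and training
    # touches only the remaining stages (large speedup for regime III).
    prefix = 0
    if cfg.frozen_stages and cfg.frozen_stages == frozenset(
            range(1, max(cfg.frozen_stages) + 1)):
        prefix = max(cfg.frozen_stages)
    start = prefix + 1
    if prefix:
        x = net.prefix_features(ds.windows, prefix)
        x_test = (net.prefix_features(test_ds.windows, prefix)
                  if len(test_ds) else None)
    else:
        x = np.asarray(ds.windows, nn.DTYPE)
        x_test = test_ds.windows if len(test_ds) else None
    y = ds.labels
    onehot = np.eye(net.cfg.n_classes, dtype=np.float64)[y]
    log = TrainLog()
    best_acc, best_state = -1.0, None
    n = len(ds)
    for epoch in range(cfg.max_epochs):
        lr = lr_at_epoch(cfg, epoch)
        order = rng_shuffle.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            logits = net.forward(x[idx], training=True, rng=rng_dropout,
                                 start_stage=start)
            probs = nn.softmax(logits.astype(np.float64))
            losses.append(cross_entropy(probs[:, 1], y[idx]))
            dlogits = ((probs - onehot[idx]) / len(idx)).astype(nn.DTYPE)
            net.backward(dlogits, min_stage=min_stage)
            adam.step(net.trainable_parameters(), lr)
        if recalibrate_bn:
            net.recalibrate_bn(x, cfg.batch_size, start_stage=start)
        train_acc = _eval_accuracy(net, x, y, start)
        test_acc = (_eval_accuracy(net, x_test, test_ds.labels, start)
                    if len(test_ds) else float("nan"))
        log.entries.append(EpochEntry(epoch, lr, float(np.mean(losses)),
                                      train_acc, test_acc))
        crit = test_acc if len(test_ds) else train_acc
        if crit > best_acc:
            best_acc = crit
            best_state = net.state_dict()
            log.selected_epoch = epoch
    net.load_state_dict(best_state)
    return net, log


def prepare_transfer(checkpoint_path, seed: int,
                     target_cfg: ModelConfig | None = None) -> StressNet:
    """Build a regime-III net from a pretrained checkpoint.

    Stage 1..8 parameters are copied; the softmax head is re-drawn from
    the He distribution; stages 1..7 are marked frozen (their batch-norm
    layers switch to inference behaviour during training).
    """
    net, meta = load_checkpoint(checkpoint_path)
    if target_cfg is not None:
        for attr in ("window_s", "fs", "n_stages", "channel_mode"):
            if getattr(net.cfg, attr) != getattr(target_cfg, attr):
                raise TransferError(
                    f"checkpoint {attr}={getattr(net.cfg, attr)} does not "
                    f"match target {attr}={getattr(target_cfg, attr)}")
    he_initialize_head(net, seed)
    net.set_frozen_stages(frozenset(range(1, net.cfg.n_stages)))
    return net
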