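"""Hybrid detection + onset-regression loss and the SGD training protocol.

The per-example loss is ``L = crossentropy(s, s_hat) + 0.1 * huber(t, t_hat)``
with natural-log cross-entropy and a Huber branch point of 1 second.  For
non-ictal examples the onset is undefined, so the Huber term is masked to
zero.  Optimization is plain mini-batch SGD with a sawtooth cyclical
learning rate (0.1 down to 0.025 every 4 epochs, held at 0.025 for the
final two epochs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .augment import AugmentConfig, augment_arrays
from .errors import ValidationError
from .network import INPUT_SCALE, ResNet1D
from ._nn import sigmoid

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LossBreakdown:
    """Cross-entropy and Huber components of one loss evaluation."""

    ce: float
    hub: float
    weight: float
    total: float


def crossentropy(s: int, s_hat: float) -> float:
    """Binary cross-entropy in nats: ``-s log(s_hat) - (1-s) log(1-s_hat)``."""
    if s not in (0, 1):
        raise ValidationError(f"label s must be 0 or 1, got {s!r}")
    p = min(max(float(s_hat), _EPS), 1.0 - _EPS)
    return -s * math.log(p) - (1 - s) * math.log(1.0 - p)


def huber(t: float, t_hat: float) -> float:
    """Huber loss with a 1-second branch point.

    ``0.5 * (t - t_hat)**2`` for ``|t - t_hat| <= 1``, else ``|t - t_hat| - 0.5``.
    """
    r = abs(float(t) - float(t_hat))
    if r <= 1.0:
        return 0.5 * r * r
    return r - 0.5


def hybrid_loss(
    s: int,
    s_hat: float,
    t: float | None,
    t_hat: float | None,
    weight: float = 0.1,
) -> LossBreakdown:
    """Joint loss for one example; the Huber term is masked when ``s == 0``."""
    ce = crossentropy(s, s_hat)
    hub = huber(t, t_hat) if s == 1 else 0.0
    return LossBreakdown(ce=ce, hub=hub, weight=weight, total=ce + weight * hub)


# ---------------------------------------------------------------------------
# Learning-rate schedule
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    n_epochs: int = 20
    batch_size: int = 128
    lr_high: float = 0.1
    lr_low: float = 0.025
    cycle_epochs: int = 4
    final_const_epochs: int = 2
    huber_weight: float = 0.1
    momentum: float = 0.0
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_low > self.lr_high:
            raise ValidationError("lr_low must be <= lr_high")
        # short runs: the constant tail cannot exceed the run itself
        self.final_const_epochs = min(self.final_const_epochs, self.n_epochs)
        if self.cycle_epochs < 2:
            raise ValidationError("cycle_epochs must be >= 2")


def cyclical_lr(epoch_index: int, config: TrainConfig) -> float:
    """Sawtooth schedule: linear decay within each cycle, constant tail."""
    if not (0 <= epoch_index < config.n_epochs):
        raise ValidationError(
            f"epoch_index {epoch_index} out of range [0, {config.n_epochs})"
        )
    if epoch_index >= config.n_epochs - config.final_const_epochs:
        return config.lr_low
    pos = epoch_index % config.cycle_epochs
    frac = pos / (config.cycle_epochs - 1)
    return config.lr_high - (config.lr_high - config.lr_low) * frac


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


@dataclass
class Example:
    """One training/evaluation example in array form."""

    samples: np.ndarray  # (4, L) microvolts
    s: int
    t: float  # NaN when s == 0
    patient_index: int


def train(
    network: ResNet1D,
    train_set: list[Example],
    config: TrainConfig,
    rng: np.random.Generator | None = None,
    augment_config: AugmentConfig | None = None,
) -> list[dict]:
    """Mini-batch SGD with on-the-fly augmentation; returns per-epoch history.

    History rows carry the epoch index, learning rate and mean total /
    cross-entropy / Huber losses.  Fully deterministic given the seed.
    """
    if not train_set:
        raise ValidationError("training set is empty")
    n_patients = network.spec.n_patients
    for ex in train_set:
        if not (0 <= ex.patient_index < n_patients):
            raise ValidationError(
                f"patient index {ex.patient_index} out of range [0, {n_patients})"
            )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if augment_config is None:
        augment_config = AugmentConfig()
    opt = network.make_optimizer(
        momentum=config.momentum, weight_decay=config.weight_decay
    )
    w = config.huber_weight
    history: list[dict] = []
    n = len(train_set)
    for epoch_idx in range(config.n_epochs):
        lr = cyclical_lr(epoch_idx, config)
        order = rng.permutation(n)
        sums = np.zeros(3)  # total, ce, hub
        seen = 0
        for lo in range(0, n, config.batch_size):
            batch = [train_set[i] for i in order[lo : lo + config.batch_size]]
            bsz = len(batch)
            xs = np.empty((bsz, batch[0].samples.shape[1], 4), dtype=np.float32)
            ss = np.empty(bsz)
            ts = np.empty(bsz)
            onehot = np.zeros((bsz, n_patients), dtype=np.float32)
            for j, ex in enumerate(batch):
                samples, t_aug = augment_arrays(
                    ex.samples, ex.s, ex.t, rng, augment_config
                )
                xs[j] = samples.T
                xs[j] *= np.float32(INPUT_SCALE)
                ss[j] = ex.s
                ts[j] = t_aug if ex.s == 1 else 0.0
                onehot[j, ex.patient_index] = 1.0
            logit, t_hat = network.forward_batch(xs, onehot, train=True, rng=rng)
            p = np.clip(sigmoid(logit), _EPS, 1.0 - _EPS)
            ce = -(ss * np.log(p) + (1.0 - ss) * np.log(1.0 - p))
            mask = ss == 1.0
            resid = np.where(mask, t_hat - ts, 0.0)
            absr = np.abs(resid)
            hub = np.where(absr <= 1.0, 0.5 * resid**2, absr - 0.5)
            total = ce + w * hub
            # gradients of the batch-mean loss
            dlogit = ((p - ss) / bsz).astype(np.float32)
            dth = (w * np.clip(resid, -1.0, 1.0) * mask / bsz).astype(np.float32)
            opt.zero_grad()
            network.backward_batch(dlogit, dth)
            opt.step(lr)
            sums += (total.sum(), ce.sum(), hub.sum())
            seen += bsz
        history.append(
            {
                "epoch": epoch_idx,
                "lr": lr,
                "loss_total": sums[0] / seen,
                "loss_ce": sums[1] / seen,
                "loss_huber": sums[2] / seen,
            }
        )
    return history
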