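"""Label-preserving training-time transformations.

Two transforms are applied to training examples only: zero-padding with a
uniformly random 90 s crop, and a single per-epoch amplitude rescale drawn
from U(0.8, 1.2).  Evaluation always runs on untransformed epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .io import EPOCH_SECONDS, SAMPLES_PER_EPOCH, SAMPLING_RATE_HZ, IEEGEpoch, OnsetAnnotation

#: zero-pad applied conceptually on each side before cropping
PAD_SECONDS = 30
PAD_SAMPLES = PAD_SECONDS * SAMPLING_RATE_HZ  # 7,500
MAX_CROP_START = 2 * PAD_SAMPLES  # 15,000

_MAX_CROP_RETRIES = 100


@dataclass
class AugmentConfig:
    pad_seconds: int = PAD_SECONDS
    crop_seconds: int = EPOCH_SECONDS
    scale_min: float = 0.8
    scale_max: float = 1.2
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.scale_min > self.scale_max:
            raise ValidationError("scale_min must be <= scale_max")
        if self.pad_seconds < 0:
            raise ValidationError("pad_seconds must be >= 0")


def _crop_samples(
    samples: np.ndarray, crop_start: int, pad_samples: int
) -> np.ndarray:
    """90 s window of the zero-padded signal, without materializing the pad."""
    n = samples.shape[1]
    out = np.zeros((samples.shape[0], SAMPLES_PER_EPOCH), dtype=samples.dtype)
    # crop covers padded indices [crop_start, crop_start + 22500);
    # original signal occupies padded indices [pad_samples, pad_samples + n)
    src_lo = max(crop_start, pad_samples)
    src_hi = min(crop_start + SAMPLES_PER_EPOCH, pad_samples + n)
    if src_hi > src_lo:
        out[:, src_lo - crop_start : src_hi - crop_start] = samples[
            :, src_lo - pad_samples : src_hi - pad_samples
        ]
    return out


def pad_and_crop(
    epoch: IEEGEpoch,
    annotation: OnsetAnnotation,
    rng: np.random.Generator,
    config: AugmentConfig | None = None,
) -> tuple[IEEGEpoch, OnsetAnnotation]:
    """Random 90 s crop of the zero-padded epoch, keeping the label intact.

    The crop start ``c`` is an integer sample offset uniform on
    ``[0, 15000]``.  For ictal epochs the onset shifts to
    ``t' = t + 30 - c/250`` and crops that would push the onset outside
    ``[0, 90)`` are re-drawn (bounded retries, then the centered crop).
    """
    config = config or AugmentConfig()
    pad_samples = config.pad_seconds * SAMPLING_RATE_HZ
    max_start = 2 * pad_samples
    if annotation.s == 0:
        c = int(rng.integers(0, max_start + 1))
        t_new: float | None = None
    else:
        c = None
        for _ in range(_MAX_CROP_RETRIES):
            cand = int(rng.integers(0, max_start + 1))
            t_shift = annotation.t + config.pad_seconds - cand / SAMPLING_RATE_HZ
            if 0.0 <= t_shift < EPOCH_SECONDS:
                c = cand
                break
        if c is None:
            c = pad_samples  # centered crop leaves the onset unchanged
        t_new = annotation.t + config.pad_seconds - c / SAMPLING_RATE_HZ
    cropped = _crop_samples(epoch.samples, c, pad_samples)
    new_epoch = replace(epoch, samples=cropped)
    new_ann = OnsetAnnotation(s=annotation.s, t=t_new)
    return new_epoch, new_ann


def amplitude_rescale(
    epoch: IEEGEpoch,
    rng: np.random.Generator,
    config: AugmentConfig | None = None,
) -> IEEGEpoch:
    """Multiply all four channels by one factor drawn from U(scale_min, scale_max)."""
    config = config or AugmentConfig()
    f = rng.uniform(config.scale_min, config.scale_max)
    return replace(epoch, samples=epoch.samples * f)


def augment(
    epoch: IEEGEpoch,
    annotation: OnsetAnnotation,
    rng: np.random.Generator,
    config: AugmentConfig | None = None,
) -> tuple[IEEGEpoch, OnsetAnnotation]:
    """Full training-time transform: rescale, then pad-and-crop.

    With ``enabled=False`` this is the identity on samples and annotation.
    """
    config = config or AugmentConfig()
    if not config.enabled:
        return epoch, annotation
    epoch = amplitude_rescale(epoch, rng, config)
    return pad_and_crop(epoch, annotation, rng, config)


def augment_arrays(
    samples: np.ndarray,
    s: int,
    t: float,
    rng: np.random.Generator,
    config: AugmentConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Array-level fast path used by the training loop.

    Applies the same rescale-then-crop composition (identical rng draw
    order) without constructing epoch objects.  ``t`` may be NaN for
    non-ictal examples; returns ``(samples, shifted_t)``.
    """
    config = config or AugmentConfig()
    if not config.enabled:
        return samples, t
    f = rng.uniform(config.scale_min, config.scale_max)
    samples = samples * f
    pad_samples = config.pad_seconds * SAMPLING_RATE_HZ
    max_start = 2 * pad_samples
    if s == 0:
        c = int(rng.integers(0, max_start + 1))
        t_new = t
    else:
        c = None
        for _ in range(_MAX_CROP_RETRIES):
            cand = int(rng.integers(0, max_start + 1))
            t_shift = t + config.pad_seconds - cand / SAMPLING_RATE_HZ
            if 0.0 <= t_shift < EPOCH_SECONDS:
                c = cand
                break
        if c is None:
            c = pad_samples
        t_new = t + config.pad_seconds - c / SAMPLING_RATE_HZ
    return _crop_samples(samples, c, pad_samples), t_new
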