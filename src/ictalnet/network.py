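"""Patient-conditioned pre-activation residual 1-D CNN.

The network maps a 4-channel voltage epoch plus a one-hot patient identifier
to two outputs: the probability that the epoch contains an ictal pattern and
the onset time of that pattern in seconds.

Structure: an initial strided convolution, then a stack of residual blocks
(two convolutions each, batch normalization and ReLU before every
convolution).  The stride is 2 at the initial layer and at the start of
every other residual block; shortcut connections use a kernel-1 projection
convolution with matching stride whenever the shape changes.  Before the
final block the feature maps are concatenated with the one-hot patient
vector tiled along time.  The head is global average pooling followed by two
affine outputs (sigmoid-squashed probability, linear onset time).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import (
    SGD,
    BatchNorm1d,
    Conv1d,
    Dense,
    Dropout,
    Param,
    ReLU,
    global_avg_pool,
    global_avg_pool_backward,
    sigmoid,
)
from .errors import ValidationError
from .io import FULL_SCALE_UV, IEEGEpoch

#: voltages are scaled by the ADC full-scale range before entering the net
INPUT_SCALE = 1.0 / FULL_SCALE_UV

#: the onset head is affine in a half-epoch parameterization:
#: t_hat = OFFSET + SCALE * (W g + b).  Training the head in O(1) units lets
#: SGD reach the required output range (0-90 s) in few steps; the loss still
#: sees raw seconds, so the 1 s Huber branch point is unchanged.
T_HEAD_OFFSET = 45.0
T_HEAD_SCALE = 45.0

_PROB_EPS = 1e-7


def filter_schedule(n_blocks: int, f_first: int, f_penultimate: int) -> list[int]:
    """Per-block filter counts: linear from ``f_first`` (block 1) to
    ``f_penultimate`` (block ``n_blocks - 1``); the last block keeps the
    penultimate width (its input is wider after patient-ID concatenation).
    """
    if n_blocks < 2:
        raise ValidationError("need at least 2 residual blocks")
    if f_first < 1 or f_penultimate < f_first:
        raise ValidationError("require 1 <= f_first <= f_penultimate")
    if n_blocks == 2:
        if f_first != f_penultimate:
            raise ValidationError("with 2 blocks the schedule must be flat")
        return [f_first, f_penultimate]
    sched = [
        int(round(f_first + (f_penultimate - f_first) * (k - 1) / (n_blocks - 2)))
        for k in range(1, n_blocks)
    ]
    return sched + [f_penultimate]


def default_stride2_blocks(n_blocks: int) -> frozenset[int]:
    """Stride-2 at the start of every other block, beginning with block 2."""
    return frozenset(range(2, n_blocks + 1, 2))


@dataclass
class NetworkSpec:
    """Full structural description of the residual CNN."""

    n_blocks: int = 11
    convs_per_block: int = 2
    kernel_size: int = 16
    first_filters: int = 16
    penultimate_filters: int = 116
    n_patients: int = 1
    dropout_rate: float = 0.2
    per_block_filters: tuple[int, ...] = field(default=None)  # type: ignore[assignment]
    stride2_blocks: frozenset[int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if self.per_block_filters is None:
            self.per_block_filters = tuple(
                filter_schedule(self.n_blocks, self.first_filters, self.penultimate_filters)
            )
        self.per_block_filters = tuple(int(f) for f in self.per_block_filters)
        if len(self.per_block_filters) != self.n_blocks:
            raise ValidationError("per_block_filters length must equal n_blocks")
        if list(self.per_block_filters) != sorted(self.per_block_filters):
            raise ValidationError("per_block_filters must be non-decreasing")
        if self.stride2_blocks is None:
            self.stride2_blocks = default_stride2_blocks(self.n_blocks)
        self.stride2_blocks = frozenset(int(b) for b in self.stride2_blocks)
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "n_blocks": self.n_blocks,
            "convs_per_block": self.convs_per_block,
            "kernel_size": self.kernel_size,
            "first_filters": self.first_filters,
            "penultimate_filters": self.penultimate_filters,
            "n_patients": self.n_patients,
            "dropout_rate": self.dropout_rate,
            "per_block_filters": list(self.per_block_filters),
            "stride2_blocks": sorted(self.stride2_blocks),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        if "per_block_filters" in d and d["per_block_filters"] is not None:
            d["per_block_filters"] = tuple(d["per_block_filters"])
        if "stride2_blocks" in d and d["stride2_blocks"] is not None:
            d["stride2_blocks"] = frozenset(d["stride2_blocks"])
        return cls(**d)


@dataclass(frozen=True)
class Prediction:
    """One forward-pass result."""

    s_hat: float
    t_hat: float


class _ResBlock:
    """Pre-activation residual block: BN-ReLU-Conv, BN-ReLU-Dropout-Conv.

    ``n_extra`` conditioning channels (the tiled patient one-hot) are
    concatenated after the first BN-ReLU, feeding the convolutions and the
    projection shortcut but not the normalization: batch statistics of a
    constant indicator channel are degenerate (an index unseen in training
    would be divided by a near-zero running variance at inference).
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int,
        dropout_rate: float,
        rng: np.random.Generator,
        name: str,
        n_extra: int = 0,
    ):
        self.c_in = c_in + n_extra  # width seen by the convolutions
        self.c_out, self.stride, self.n_extra = c_out, stride, n_extra
        self.bn1 = BatchNorm1d(c_in, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv1 = Conv1d(
            self.c_in, c_out, kernel, stride, rng=rng, name=f"{name}.conv1"
        )
        self.bn2 = BatchNorm1d(c_out, name=f"{name}.bn2")
        self.relu2 = ReLU()
        self.dropout = Dropout(dropout_rate)
        self.conv2 = Conv1d(c_out, c_out, kernel, 1, rng=rng, name=f"{name}.conv2")
        self.proj = None
        if stride != 1 or self.c_in != c_out:
            self.proj = Conv1d(
                self.c_in, c_out, 1, stride, rng=rng, name=f"{name}.proj",
                main_path=False,
            )

    def params(self) -> list[Param]:
        out = self.bn1.params() + self.conv1.params() + self.bn2.params() + self.conv2.params()
        if self.proj is not None:
            out += self.proj.params()
        return out

    def forward(self, h, train, rng, extra=None):
        a = self.relu1.forward(self.bn1.forward(h, train), train)
        if self.n_extra:
            a = np.concatenate([a, extra], axis=2)
        shortcut = h if self.proj is None else self.proj.forward(a, train)
        b = self.conv1.forward(a, train)
        c = self.relu2.forward(self.bn2.forward(b, train), train)
        c = self.dropout.forward(c, train, rng)
        d = self.conv2.forward(c, train)
        return d + shortcut

    def backward(self, dy):
        dc = self.dropout.backward(self.conv2.backward(dy))
        db = self.bn2.backward(self.relu2.backward(dc))
        da = self.conv1.backward(db)
        if self.proj is not None:
            da = da + self.proj.backward(dy)
        if self.n_extra:
            da = da[:, :, : -self.n_extra]  # one-hot channels need no grad
        dh = self.bn1.backward(self.relu1.backward(da))
        if self.proj is None:
            dh = dh + dy
        return dh


class ResNet1D:
    """The assembled network; see module docstring for the topology."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0]))
        k = spec.kernel_size
        sched = spec.per_block_filters
        self.conv0 = Conv1d(
            4, spec.first_filters, k, 2, rng=rng, name="conv0", input_grad=False
        )
        self.blocks: list[_ResBlock] = []
        prev = spec.first_filters
        for bi in range(1, spec.n_blocks + 1):
            n_extra = spec.n_patients if bi == spec.n_blocks else 0
            stride = 2 if bi in spec.stride2_blocks else 1
            self.blocks.append(
                _ResBlock(
                    prev, sched[bi - 1], k, stride, spec.dropout_rate, rng,
                    name=f"block{bi}", n_extra=n_extra,
                )
            )
            prev = sched[bi - 1]
        self.bn_final = BatchNorm1d(prev, name="bn_final")
        self.relu_final = ReLU()
        self.head_s = Dense(prev, 1, rng=rng, name="head_s")
        self.head_t = Dense(prev, 1, rng=rng, name="head_t")
        # small init so initial onset estimates sit near mid-epoch
        self.head_t.W.value *= 0.1
        self._final_len = None

    # -- parameters --------------------------------------------------------
    def params(self) -> list[Param]:
        out = self.conv0.params()
        for b in self.blocks:
            out += b.params()
        out += self.bn_final.params() + self.head_s.params() + self.head_t.params()
        return out

    def make_optimizer(self, momentum: float = 0.0, weight_decay: float = 0.0) -> SGD:
        return SGD(self.params(), momentum=momentum, weight_decay=weight_decay)

    # -- forward / backward ------------------------------------------------
    def forward_batch(
        self,
        x: np.ndarray,
        patient_onehot: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Raw heads: (classification logit, onset estimate), each shape (B,).

        ``x`` is channels-last, (B, L, 4), already scaled by
        :data:`INPUT_SCALE`; ``patient_onehot`` is (B, n_patients).
        """
        if x.ndim != 3 or x.shape[2] != 4:
            raise ValidationError(f"expected input (B, L, 4), got {x.shape}")
        if patient_onehot.shape != (x.shape[0], self.spec.n_patients):
            raise ValidationError(
                f"one-hot shape {patient_onehot.shape} does not match "
                f"(batch, n_patients)=({x.shape[0]}, {self.spec.n_patients})"
            )
        h = self.conv0.forward(x.astype(np.float32, copy=False), train)
        for bi, block in enumerate(self.blocks, start=1):
            extra = None
            if bi == self.spec.n_blocks:
                extra = np.broadcast_to(
                    patient_onehot.astype(np.float32)[:, None, :],
                    (h.shape[0], h.shape[1], self.spec.n_patients),
                )
            h = block.forward(h, train, rng, extra=extra)
        z = self.relu_final.forward(self.bn_final.forward(h, train), train)
        self._final_len = z.shape[1]
        g = global_avg_pool(z)
        logit = self.head_s.forward(g, train)[:, 0]
        t_hat = T_HEAD_OFFSET + T_HEAD_SCALE * self.head_t.forward(g, train)[:, 0]
        return logit, t_hat

    def backward_batch(self, dlogit: np.ndarray, dt_hat: np.ndarray) -> None:
        dg = self.head_s.backward(dlogit[:, None]) + self.head_t.backward(
            (dt_hat * np.float32(T_HEAD_SCALE))[:, None]
        )
        dz = global_avg_pool_backward(dg.astype(np.float32), self._final_len)
        dh = self.bn_final.backward(self.relu_final.backward(dz))
        for bi in range(len(self.blocks), 0, -1):
            dh = self.blocks[bi - 1].backward(dh)
        self.conv0.backward(dh)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """NPZ checkpoint plus a JSON sidecar with the structural spec."""
        path = Path(path)
        arrays = {}
        for i, p in enumerate(self.params()):
            arrays[f"p{i:03d}_{p.name}"] = p.value
        stats = {}
        for j, bn in enumerate(self._batchnorms()):
            stats[f"bn{j:03d}_mean"] = bn.running_mean
            stats[f"bn{j:03d}_var"] = bn.running_var
        np.savez(path, **arrays, **stats)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps({"spec": self.spec.to_dict()}, indent=2))

    def _batchnorms(self) -> list[BatchNorm1d]:
        out = []
        for b in self.blocks:
            out += [b.bn1, b.bn2]
        out.append(self.bn_final)
        return out

    @classmethod
    def load(cls, path: str | Path) -> "ResNet1D":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        net = cls(NetworkSpec.from_dict(meta["spec"]))
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
            for i, p in enumerate(net.params()):
                p.value[...] = data[f"p{i:03d}_{p.name}"]
            for j, bn in enumerate(net._batchnorms()):
                bn.running_mean[...] = data[f"bn{j:03d}_mean"]
                bn.running_var[...] = data[f"bn{j:03d}_var"]
        return net


def build_network(spec: NetworkSpec, seed: int = 0) -> ResNet1D:
    """Construct the network from a structural spec (He-initialized weights)."""
    return ResNet1D(spec, seed=seed)


def forward(
    network: ResNet1D, epoch: IEEGEpoch, patient_index: int
) -> Prediction:
    """Inference-mode prediction for a single epoch."""
    spec = network.spec
    if not (0 <= patient_index < spec.n_patients):
        raise ValidationError(
            f"patient_index {patient_index} out of range [0, {spec.n_patients})"
        )
    x = np.ascontiguousarray(epoch.samples.T * INPUT_SCALE, dtype=np.float32)[None]
    onehot = np.zeros((1, spec.n_patients), dtype=np.float32)
    onehot[0, patient_index] = 1.0
    logit, t_hat = network.forward_batch(x, onehot, train=False)
    s_hat = float(np.clip(sigmoid(logit)[0], _PROB_EPS, 1.0 - _PROB_EPS))
    return Prediction(s_hat=s_hat, t_hat=float(t_hat[0]))


def forward_many(
    network: ResNet1D,
    samples: np.ndarray,
    patient_indices: np.ndarray,
    batch_size: int = 32,
) -> tuple[np.ndarray, np.ndarray]:
    """Inference over a stack of epochs, returning (s_hat, t_hat) arrays."""
    n = samples.shape[0]
    s_hat = np.empty(n)
    t_hat = np.empty(n)
    for lo in range(0, n, batch_size):
        hi = min(lo + batch_size, n)
        x = np.empty((hi - lo, samples.shape[2], 4), dtype=np.float32)
        for j in range(hi - lo):
            x[j] = samples[lo + j].T
        x *= np.float32(INPUT_SCALE)
        onehot = np.zeros((hi - lo, network.spec.n_patients), dtype=np.float32)
        onehot[np.arange(hi - lo), patient_indices[lo:hi]] = 1.0
        logit, th = network.forward_batch(x, onehot, train=False)
        s_hat[lo:hi] = np.clip(sigmoid(logit), _PROB_EPS, 1.0 - _PROB_EPS)
        t_hat[lo:hi] = th
    return s_hat, t_hat


@dataclass(frozen=True)
class StructuralSummary:
    n_conv_layers: int
    n_residual_blocks: int
    n_shortcut_convs: int
    n_parameters: int
    downsample_factor: int


def structural_summary(network: ResNet1D) -> StructuralSummary:
    """Counts obtained by traversing the built network, not its config."""
    main_convs = [network.conv0]
    shortcut = []
    downsample = network.conv0.stride
    for b in network.blocks:
        main_convs += [b.conv1, b.conv2]
        downsample *= b.conv1.stride
        if b.proj is not None:
            shortcut.append(b.proj)
    n_params = sum(p.size for p in network.params())
    return StructuralSummary(
        n_conv_layers=len(main_convs),
        n_residual_blocks=len(network.blocks),
        n_shortcut_convs=len(shortcut),
        n_parameters=n_params,
        downsample_factor=downsample,
    )
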