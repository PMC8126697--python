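"""Epoch-level iEEG I/O.

Fixed-duration, 4-channel intracranial EEG epochs are stored as plain EDF
files with a one-row CSV sidecar carrying the annotation (ictal label and
onset time).  The acquisition conventions of the target device are enforced
on everything entering the pipeline: 90 s epochs, 250 Hz sampling, 4 bipolar
channels, 10-bit amplitude quantization.

The EDF reader/writer here is deliberately minimal (classic EDF, one
1-second data record per second of signal, int16 samples).  Digital codes
are chosen so that quantized voltages round-trip bit-exactly.
"""

from __future__ import annotations

import csv
import datetime as _dt
import importlib.resources
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError

#: Device acquisition constants.
SAMPLING_RATE_HZ = 250
EPOCH_SECONDS = 90
N_CHANNELS = 4
SAMPLES_PER_EPOCH = SAMPLING_RATE_HZ * EPOCH_SECONDS  # 22,500

#: ADC defaults.  Bit depth is a device property; the physical full-scale
#: range is not documented, so +/-512 uV (~1 uV per level at 10 bits) is used
#: as a configurable default.
ADC_BITS = 10
FULL_SCALE_UV = 512.0

IMPLANT_SITES = ("thalamus", "developmental_malformation", "neocortex", "hippocampus")
TRIGGERS = ("scheduled", "detection")

DEFAULT_CHANNEL_NAMES = ("E1-E2", "E2-E3", "E3-E4", "E4-E1")

SIDECAR_COLUMNS = ("epoch_id", "patient_id", "recorded_at", "trigger", "s", "t_seconds")

COHORT_TABLE_COLUMNS = (
    "patient",
    "age",
    "gender",
    "implantation_site",
    "n_days",
    "n_ieeg_files",
    "n_ictal_patterns",
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class IEEGEpoch:
    """One fixed-duration, 4-channel voltage recording.

    Parameters
    ----------
    samples
        Voltages in microvolts, shape ``(4, 22500)``.
    patient_id
        Opaque patient identifier.
    recorded_at
        Acquisition timestamp.
    trigger
        ``"scheduled"`` (device clock) or ``"detection"`` (onboard detector).
    channel_names
        Four bipolar-derivation labels.
    """

    samples: np.ndarray
    patient_id: str
    recorded_at: _dt.datetime
    trigger: str = "scheduled"
    channel_names: tuple[str, ...] = DEFAULT_CHANNEL_NAMES
    sampling_rate: int = SAMPLING_RATE_HZ
    duration: int = EPOCH_SECONDS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[0] != N_CHANNELS:
            raise ValidationError(
                f"epoch must have exactly {N_CHANNELS} channels, "
                f"got shape {self.samples.shape}"
            )
        expected = self.duration * self.sampling_rate
        if self.samples.shape[1] != expected:
            raise ValidationError(
                f"epoch must have {expected} samples per channel, "
                f"got {self.samples.shape[1]}"
            )
        if not np.isfinite(self.samples).all():
            ch, idx = np.argwhere(~np.isfinite(self.samples))[0]
            raise ValidationError(
                f"non-finite sample at channel {ch}, index {idx}"
            )
        if self.trigger not in TRIGGERS:
            raise ValidationError(f"unknown trigger {self.trigger!r}")
        if len(self.channel_names) != N_CHANNELS:
            raise ValidationError("need exactly 4 channel names")
        self.channel_names = tuple(str(c) for c in self.channel_names)


@dataclass(frozen=True)
class OnsetAnnotation:
    """Ground-truth ictal label and onset time for one epoch.

    ``s`` is the binary ictal label; ``t`` is the onset in seconds from the
    epoch start and is defined only when ``s == 1``.
    """

    s: int
    t: float | None = None

    def __post_init__(self) -> None:
        if self.s not in (0, 1):
            raise ValidationError(f"label s must be 0 or 1, got {self.s!r}")
        if self.s == 1:
            if self.t is None or not np.isfinite(self.t):
                raise ValidationError("ictal annotation requires a finite onset time")
            if not (0.0 <= self.t < EPOCH_SECONDS):
                raise ValidationError(
                    f"onset t={self.t} out of range [0, {EPOCH_SECONDS})"
                )
        elif self.t is not None:
            raise ValidationError("non-ictal annotation must not carry an onset time")


@dataclass(frozen=True)
class RecordingMetadata:
    """Per-patient demographics and device-recording counts."""

    patient_id: str
    implant_site: str
    n_days_with_device: int
    n_ieeg_files: int
    n_ictal_patterns: int
    age: float
    sex: str

    def __post_init__(self) -> None:
        if self.implant_site not in IMPLANT_SITES:
            raise ValidationError(f"unknown implant site {self.implant_site!r}")
        if self.sex not in ("F", "M"):
            raise ValidationError(f"sex must be 'F' or 'M', got {self.sex!r}")
        for name in ("n_days_with_device", "n_ieeg_files", "n_ictal_patterns"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.n_ictal_patterns > self.n_ieeg_files:
            raise ValidationError("n_ictal_patterns cannot exceed n_ieeg_files")


# ---------------------------------------------------------------------------
# Quantization
# ---------------------------------------------------------------------------


def quantize_adc(
    signal: np.ndarray,
    n_bits: int = ADC_BITS,
    full_scale: float = FULL_SCALE_UV,
) -> np.ndarray:
    """Map voltages onto the uniform ADC grid.

    The grid consists of ``2**n_bits`` uniformly spaced levels spanning
    ``[-full_scale, +full_scale]`` inclusive; out-of-range values are clipped
    to the extreme levels.  Idempotent and monotone.
    """
    if n_bits < 1:
        raise ValidationError("n_bits must be >= 1")
    if not (np.isfinite(full_scale) and full_scale > 0):
        raise ValidationError("full_scale must be a finite positive half-range")
    x = np.asarray(signal, dtype=np.float64)
    if not np.isfinite(x).all():
        bad = np.argwhere(~np.isfinite(x))[0]
        if x.ndim == 2:
            raise ValidationError(
                f"non-finite sample at channel {bad[0]}, index {bad[1]}"
            )
        raise ValidationError(f"non-finite sample at index {bad[0]}")
    n_levels = 2**n_bits
    step = 2.0 * full_scale / (n_levels - 1)
    codes = np.clip(np.round((x + full_scale) / step), 0, n_levels - 1)
    return -full_scale + codes * step


def _adc_codes(samples: np.ndarray, n_bits: int, full_scale: float) -> np.ndarray:
    """Integer grid codes for already-quantized samples (write-time check)."""
    n_levels = 2**n_bits
    step = 2.0 * full_scale / (n_levels - 1)
    codes = np.round((samples + full_scale) / step)
    residual = np.abs(samples - (-full_scale + codes * step))
    if residual.max() > step * 1e-6:
        raise ValidationError(
            "samples are not on the ADC quantization grid; "
            "apply quantize_adc before writing"
        )
    if codes.min() < 0 or codes.max() > n_levels - 1:
        raise ValidationError("quantized samples exceed the ADC full-scale range")
    return codes.astype(np.int32)


# ---------------------------------------------------------------------------
# Minimal classic-EDF reader/writer
# ---------------------------------------------------------------------------


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(path: Path, epoch: IEEGEpoch, digital: np.ndarray) -> None:
    """Write 4-channel int16 EDF, one 1-second record per second of signal."""
    n_sig = N_CHANNELS
    n_records = epoch.duration
    spr = epoch.sampling_rate  # samples per record per signal
    header_bytes = 256 * (1 + n_sig)
    ts = epoch.recorded_at
    half = FULL_SCALE_UV
    parts = [
        _edf_field("0", 8),
        _edf_field(epoch.patient_id, 80),
        _edf_field(f"Startdate {ts:%d-%b-%Y} trigger={epoch.trigger}", 80),
        _edf_field(ts.strftime("%d.%m.%y"), 8),
        _edf_field(ts.strftime("%H.%M.%S"), 8),
        _edf_field(str(header_bytes), 8),
        _edf_field("", 44),
        _edf_field(str(n_records), 8),
        _edf_field("1", 8),
        _edf_field(str(n_sig), 4),
    ]
    labels = [_edf_field(name, 16) for name in epoch.channel_names]
    parts += labels
    parts += [_edf_field("", 80)] * n_sig  # transducer
    parts += [_edf_field("uV", 8)] * n_sig
    parts += [_edf_field(f"{-half:g}", 8)] * n_sig  # physical min
    parts += [_edf_field(f"{half:g}", 8)] * n_sig  # physical max
    parts += [_edf_field(str(-(2 ** (ADC_BITS - 1))), 8)] * n_sig  # digital min
    parts += [_edf_field(str(2 ** (ADC_BITS - 1) - 1), 8)] * n_sig  # digital max
    parts += [_edf_field("BP:4-125Hz", 80)] * n_sig
    parts += [_edf_field(str(spr), 8)] * n_sig
    parts += [_edf_field("", 32)] * n_sig
    header = b"".join(parts)
    assert len(header) == header_bytes

    # records: for each second, each signal's 250 samples contiguously
    rec = digital.reshape(n_sig, n_records, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(np.ascontiguousarray(rec, dtype="<i2").tobytes())


def _read_ascii(fh, width: int) -> str:
    return fh.read(width).decode("ascii", errors="replace").strip()


def _read_edf(path: Path) -> tuple[np.ndarray, dict]:
    """Read a classic EDF file; returns (physical samples, header info)."""
    try:
        return _read_edf_unchecked(path)
    except (ValueError, IndexError) as exc:
        raise FormatError(f"malformed EDF header/payload in {path}: {exc}") from exc


def _read_edf_unchecked(path: Path) -> tuple[np.ndarray, dict]:
    with open(path, "rb") as fh:
        fh.read(8)  # version
        patient_id = _read_ascii(fh, 80)
        recording_id = _read_ascii(fh, 80)
        startdate = _read_ascii(fh, 8)
        starttime = _read_ascii(fh, 8)
        fh.read(8)  # header bytes
        fh.read(44)
        n_records = int(_read_ascii(fh, 8))
        record_dur = float(_read_ascii(fh, 8))
        n_sig = int(_read_ascii(fh, 4))

        def per_signal(width: int) -> list[str]:
            return [_read_ascii(fh, width) for _ in range(n_sig)]

        labels = per_signal(16)
        per_signal(80)  # transducer
        per_signal(8)  # physical dimension
        phys_min = [float(v) for v in per_signal(8)]
        phys_max = [float(v) for v in per_signal(8)]
        dig_min = [int(v) for v in per_signal(8)]
        dig_max = [int(v) for v in per_signal(8)]
        per_signal(80)  # prefiltering
        spr = [int(v) for v in per_signal(8)]
        per_signal(32)
        payload = np.frombuffer(fh.read(), dtype="<i2")

    total = n_records * sum(spr)
    if payload.size != total:
        raise FormatError(
            f"EDF payload has {payload.size} samples, header implies {total}"
        )
    if len(set(spr)) != 1:
        raise FormatError("heterogeneous samples-per-record not supported")
    rec = payload.reshape(n_records, n_sig, spr[0])
    digital = rec.transpose(1, 0, 2).reshape(n_sig, n_records * spr[0])
    physical = np.empty(digital.shape, dtype=np.float64)
    for i in range(n_sig):
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        physical[i] = phys_min[i] + (digital[i].astype(np.float64) - dig_min[i]) * gain
    info = {
        "patient_id": patient_id,
        "recording_id": recording_id,
        "startdate": startdate,
        "starttime": starttime,
        "n_signals": n_sig,
        "sampling_rate": spr[0] / record_dur,
        "n_samples": n_records * spr[0],
        "labels": labels,
    }
    return physical, info


# ---------------------------------------------------------------------------
# Epoch read/write
# ---------------------------------------------------------------------------


def _paths(path: str | os.PathLike) -> tuple[Path, Path, str]:
    p = Path(path)
    stem = p.with_suffix("") if p.suffix in (".edf", ".csv") else p
    return stem.with_suffix(".edf"), stem.with_suffix(".csv"), stem.name


def write_epoch(
    epoch: IEEGEpoch, annotation: OnsetAnnotation, path: str | os.PathLike
) -> tuple[Path, Path]:
    """Write one epoch as ``<stem>.edf`` plus a one-row ``<stem>.csv`` sidecar.

    The samples must already lie on the ADC grid (see :func:`quantize_adc`);
    digital codes are derived from the grid so the round trip is bit-exact.
    """
    edf_path, csv_path, epoch_id = _paths(path)
    codes = _adc_codes(epoch.samples, ADC_BITS, FULL_SCALE_UV)
    digital = (codes - 2 ** (ADC_BITS - 1)).astype(np.int16)
    edf_path.parent.mkdir(parents=True, exist_ok=True)
    _write_edf(edf_path, epoch, digital)
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SIDECAR_COLUMNS)
        writer.writerow(annotation_row(epoch_id, epoch, annotation))
    return edf_path, csv_path


def annotation_row(
    epoch_id: str, epoch: IEEGEpoch, annotation: OnsetAnnotation
) -> list[str]:
    """One sidecar CSV row; onset blank (not 0) for non-ictal epochs."""
    t_field = "" if annotation.s == 0 else f"{annotation.t:.3f}"
    return [
        epoch_id,
        epoch.patient_id,
        epoch.recorded_at.isoformat(),
        epoch.trigger,
        str(annotation.s),
        t_field,
    ]


def _parse_annotation(row: dict) -> OnsetAnnotation:
    s = int(row["s"])
    t_raw = (row.get("t_seconds") or "").strip()
    t = float(t_raw) if t_raw != "" else None
    if s == 0:
        return OnsetAnnotation(s=0)
    return OnsetAnnotation(s=1, t=t)


def read_epoch(path: str | os.PathLike) -> tuple[IEEGEpoch, OnsetAnnotation]:
    """Read an epoch written by :func:`write_epoch` (or conforming EDF+CSV)."""
    edf_path, csv_path, epoch_id = _paths(path)
    if not edf_path.exists():
        raise FileNotFoundError(edf_path)
    physical, info = _read_edf(edf_path)
    if info["n_signals"] != N_CHANNELS:
        raise FormatError(
            f"channel count: expected {N_CHANNELS}, got {info['n_signals']}"
        )
    if abs(info["sampling_rate"] - SAMPLING_RATE_HZ) > 1e-9:
        raise FormatError(
            f"sampling rate: expected {SAMPLING_RATE_HZ}, got {info['sampling_rate']}"
        )
    if info["n_samples"] != SAMPLES_PER_EPOCH:
        raise FormatError(
            f"samples per channel: expected {SAMPLES_PER_EPOCH}, got {info['n_samples']}"
        )
    with open(csv_path, newline="") as fh:
        rows = {r["epoch_id"]: r for r in csv.DictReader(fh)}
    if epoch_id not in rows:
        raise FormatError(f"no sidecar row for epoch id {epoch_id!r}")
    row = rows[epoch_id]
    annotation = _parse_annotation(row)
    recorded_at = _dt.datetime.fromisoformat(row["recorded_at"])
    epoch = IEEGEpoch(
        samples=physical,
        patient_id=row["patient_id"],
        recorded_at=recorded_at,
        trigger=row["trigger"],
        channel_names=tuple(info["labels"]),
    )
    return epoch, annotation


# ---------------------------------------------------------------------------
# Cohort metadata table
# ---------------------------------------------------------------------------


def cohort_table_path() -> Path:
    """Path to the packaged per-patient metadata fixture."""
    return Path(importlib.resources.files("ictalnet") / "data" / "cohort_table.csv")


def load_cohort_table(path: str | os.PathLike | None = None) -> list[RecordingMetadata]:
    """Load a per-patient metadata CSV into typed records.

    With no argument, loads the packaged 22-patient fixture.
    """
    src = Path(path) if path is not None else cohort_table_path()
    try:
        df = pd.read_csv(src)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"cohort table {src} is empty") from exc
    missing = [c for c in COHORT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing columns: {missing}")
    if len(df) == 0:
        raise SchemaError(f"cohort table {src} has no rows")
    records = []
    for _, row in df.iterrows():
        records.append(
            RecordingMetadata(
                patient_id=str(row["patient"]),
                implant_site=str(row["implantation_site"]),
                n_days_with_device=int(row["n_days"]),
                n_ieeg_files=int(row["n_ieeg_files"]),
                n_ictal_patterns=int(row["n_ictal_patterns"]),
                age=float(row["age"]),
                sex=str(row["gender"]),
            )
        )
    return records
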