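"""Synthetic multi-patient iEEG cohort with known onsets.

Generates device-style 90 s, 4-channel epochs: 1/f interictal background
with sporadic epileptiform spikes, patient-specific ictal patterns
(amplitude-growing frequency chirps), and the confound classes that are
known detector pitfalls.  Everything is a pure function of the configured
seeds so downstream stages are reproducible end to end.

Morphology here is judged by detectability and onset recoverability, not
electrophysiological realism.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from . import io as iio
from .errors import ValidationError
from .io import (
    EPOCH_SECONDS,
    IMPLANT_SITES,
    N_CHANNELS,
    SAMPLES_PER_EPOCH,
    SAMPLING_RATE_HZ,
    IEEGEpoch,
    OnsetAnnotation,
    RecordingMetadata,
    quantize_adc,
)

PASS_BAND_HZ = (4.0, 125.0)

CONFOUND_CATEGORIES = (
    "electrodecrement_onset",
    "brief_ictal",
    "single_channel_ictal",
    "dense_interictal",
    "arousal_transition",
)

#: Confound categories that produce ictal (s=1) epochs.
_ICTAL_CONFOUNDS = ("electrodecrement_onset", "brief_ictal", "single_channel_ictal")
_NONICTAL_CONFOUNDS = ("dense_interictal", "arousal_transition")


# ---------------------------------------------------------------------------
# Profiles and configuration
# ---------------------------------------------------------------------------


@dataclass
class PatientProfile:
    """Per-patient generative parameters."""

    patient_id: str
    implant_site: str
    # background
    spectral_slope: float
    background_rms_uv: float
    spike_rate_per_min: float
    spike_amp_uv: float
    # seizure morphology
    onset_freq_hz: float
    terminal_freq_hz: float
    amp_growth: float
    channel_mask: tuple[bool, bool, bool, bool]
    mean_duration_s: float
    # confounds
    confound_mix: dict = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = PASS_BAND_HZ
        for f in (self.onset_freq_hz, self.terminal_freq_hz):
            if not (lo <= f <= hi):
                raise ValidationError(f"seizure frequency {f} outside pass band")
        if not any(self.channel_mask):
            raise ValidationError("channel mask must involve at least one channel")
        if self.confound_mix:
            w = np.array(list(self.confound_mix.values()), dtype=float)
            if (w < 0).any() or w.sum() > 1.0 + 1e-12:
                raise ValidationError("confound weights must be >= 0 and sum to <= 1")
            unknown = set(self.confound_mix) - set(CONFOUND_CATEGORIES)
            if unknown:
                raise ValidationError(f"unknown confound categories: {sorted(unknown)}")


@dataclass
class CohortConfig:
    """Knobs for one synthetic cohort."""

    n_patients: int = 6
    epochs_per_patient: int = 60
    ictal_fraction: float = 0.4
    scheduled_fraction: float = 0.8
    start_date: _dt.datetime = _dt.datetime(2020, 1, 1)
    span_days: int = 180
    master_seed: int = 0
    confound_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ictal_fraction", "scheduled_fraction", "confound_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_patients < 1 or self.epochs_per_patient < 1:
            raise ValidationError("counts must be positive")


def make_patient_profile(
    patient_index: int,
    implant_site: str | None = None,
    master_seed: int = 0,
) -> PatientProfile:
    """Deterministic per-patient generative parameters.

    Distinct patient indices receive distinct seizure morphology, so
    patient-conditioned detection is learnable on the resulting cohort.
    """
    if implant_site is None:
        implant_site = IMPLANT_SITES[patient_index % len(IMPLANT_SITES)]
    seed = np.random.SeedSequence([0x5EED, master_seed, patient_index])
    rng = np.random.default_rng(seed)
    onset_f = rng.uniform(5.0, 12.0)
    terminal_f = rng.uniform(14.0, 28.0)
    # all channels involved by default: the per-channel extent of ictal
    # activity then has the same meaning for every patient, which keeps the
    # onset readout calibrated across patients (single-channel events are
    # exercised through the dedicated confound class)
    mask = (True,) * N_CHANNELS
    # amplitude scales are kept homogeneous across patients so cross-patient
    # transfer of the onset readout is calibrated; patients stay distinct
    # through frequency content, involved channels and event duration
    return PatientProfile(
        patient_id=f"SP{patient_index:02d}",
        implant_site=implant_site,
        spectral_slope=float(rng.uniform(1.3, 1.7)),
        background_rms_uv=float(rng.uniform(18.0, 24.0)),
        spike_rate_per_min=float(rng.uniform(1.0, 4.0)),
        spike_amp_uv=float(rng.uniform(100.0, 140.0)),
        onset_freq_hz=float(onset_f),
        terminal_freq_hz=float(terminal_f),
        amp_growth=float(rng.uniform(5.5, 7.0)),
        channel_mask=mask,
        mean_duration_s=float(rng.uniform(25.0, 40.0)),
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# Signal generators
# ---------------------------------------------------------------------------


def _colored_noise(rng, n: int, alpha: float) -> np.ndarray:
    """Unit-RMS 1/f^alpha noise, band-limited to the device pass band."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / SAMPLING_RATE_HZ)
    shaping = np.zeros_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    # zero-phase high-pass at the lower band edge; upper edge is Nyquist
    sos = sps.butter(4, PASS_BAND_HZ[0], btype="highpass", fs=SAMPLING_RATE_HZ, output="sos")
    x = sps.sosfiltfilt(sos, x)
    return x / np.sqrt(np.mean(x**2))


def _spike_waveform() -> np.ndarray:
    """Biphasic epileptiform transient, ~70 ms."""
    n = int(0.07 * SAMPLING_RATE_HZ)
    t = np.linspace(-1.0, 1.0, n)
    return -t * np.exp(-4.0 * t**2) * 2.9  # peak ~1

def _add_spikes(
    x: np.ndarray, rng, rate_per_min: float, amp_uv: float, n_min: int = 0
) -> int:
    """Superimpose transients at a Poisson rate; returns the count placed."""
    wave = _spike_waveform()
    n_spikes = int(rng.poisson(rate_per_min * EPOCH_SECONDS / 60.0))
    n_spikes = max(n_spikes, n_min)
    n = x.shape[1]
    for _ in range(n_spikes):
        pos = int(rng.integers(0, n - wave.size))
        ch = int(rng.integers(0, N_CHANNELS))
        a = amp_uv * rng.uniform(0.8, 1.2) * rng.choice([-1.0, 1.0])
        x[ch, pos : pos + wave.size] += a * wave
    return n_spikes


def generate_background(
    profile: PatientProfile, rng: np.random.Generator
) -> np.ndarray:
    """Interictal 4-channel background, shape ``(4, 22500)``, microvolts."""
    x = np.stack(
        [
            _colored_noise(rng, SAMPLES_PER_EPOCH, profile.spectral_slope)
            for _ in range(N_CHANNELS)
        ]
    )
    x *= profile.background_rms_uv
    _add_spikes(x, rng, profile.spike_rate_per_min, profile.spike_amp_uv)
    return x


def _chirp(
    profile: PatientProfile,
    rng: np.random.Generator,
    onset_s: float,
    duration_s: float,
    mask: tuple[bool, ...],
    attack_s: float = 0.2,
) -> np.ndarray:
    """Amplitude-growing frequency sweep added on the involved channels."""
    out = np.zeros((N_CHANNELS, SAMPLES_PER_EPOCH))
    i0 = int(round(onset_s * SAMPLING_RATE_HZ))
    i1 = min(int(round((onset_s + duration_s) * SAMPLING_RATE_HZ)), SAMPLES_PER_EPOCH)
    n = i1 - i0
    if n <= 0:
        return out
    prog = np.arange(n) / max(n - 1, 1)
    inst_freq = profile.onset_freq_hz + prog * (
        profile.terminal_freq_hz - profile.onset_freq_hz
    )
    phase = 2.0 * np.pi * np.cumsum(inst_freq) / SAMPLING_RATE_HZ
    # envelope: already above background at onset, growing through the event
    a_max = profile.amp_growth * profile.background_rms_uv * np.sqrt(2.0) * 1.8
    attack = np.minimum(1.0, np.arange(n) / max(attack_s * SAMPLING_RATE_HZ, 1.0))
    envelope = a_max * (0.75 + 0.25 * prog) * attack
    for ch in range(N_CHANNELS):
        if not mask[ch]:
            continue
        ph0 = rng.uniform(0, 2 * np.pi)
        wave = np.sin(phase + ph0) + 0.3 * np.sin(2.0 * (phase + ph0))
        out[ch, i0:i1] = envelope * wave
    return out


_PLACEHOLDER_TS = _dt.datetime(2020, 1, 1)


def _mk_epoch(
    samples: np.ndarray,
    profile: PatientProfile,
    trigger: str,
    recorded_at: _dt.datetime | None,
) -> IEEGEpoch:
    return IEEGEpoch(
        samples=samples,
        patient_id=profile.patient_id,
        recorded_at=recorded_at or _PLACEHOLDER_TS,
        trigger=trigger,
    )


def generate_ictal_epoch(
    profile: PatientProfile,
    onset: float,
    rng: np.random.Generator,
    *,
    duration_s: float | None = None,
    recorded_at: _dt.datetime | None = None,
    trigger: str = "detection",
) -> tuple[IEEGEpoch, OnsetAnnotation]:
    """Epoch whose background transitions to an ictal pattern at ``onset`` s.

    By default the discharge evolves until the end of the epoch, so the
    extent of ictal activity carries the onset information a pooling
    detector needs for onset regression (the generator's acceptance bar is
    onset recoverability).  Pass ``duration_s`` for shorter events.
    """
    if not (0.0 <= onset < EPOCH_SECONDS):
        raise ValidationError(f"onset {onset} outside [0, {EPOCH_SECONDS})")
    if duration_s is None:
        duration_s = EPOCH_SECONDS - onset
    duration_s = min(duration_s, EPOCH_SECONDS - onset)
    x = generate_background(profile, rng)
    x += _chirp(profile, rng, onset, duration_s, profile.channel_mask)
    epoch = _mk_epoch(x, profile, trigger, recorded_at)
    return epoch, OnsetAnnotation(s=1, t=float(onset))


def generate_confound_epoch(
    profile: PatientProfile,
    category: str,
    rng: np.random.Generator,
    *,
    recorded_at: _dt.datetime | None = None,
) -> tuple[IEEGEpoch, OnsetAnnotation, dict]:
    """One epoch of a known detector-pitfall class.

    Returns ``(epoch, annotation, info)``; ``info`` carries generator
    bookkeeping (onset, event duration, involved channels, spike count).
    """
    if category not in CONFOUND_CATEGORIES:
        raise ValidationError(f"unknown confound category {category!r}")
    info: dict = {"category": category}

    if category == "electrodecrement_onset":
        onset = round(float(rng.uniform(20.0, 55.0)), 3)
        suppress_s = 2.5
        duration = min(profile.mean_duration_s, EPOCH_SECONDS - onset)
        x = generate_background(profile, rng)
        i0 = int(round(onset * SAMPLING_RATE_HZ))
        i1 = min(int(round((onset + suppress_s) * SAMPLING_RATE_HZ)), SAMPLES_PER_EPOCH)
        x[:, i0:i1] *= 0.25  # amplitude falls below interictal levels
        x += _chirp(
            profile, rng, onset + suppress_s, duration - suppress_s, profile.channel_mask
        )
        info.update(onset=onset, duration=duration, suppress_s=suppress_s)
        return (
            _mk_epoch(x, profile, "detection", recorded_at),
            OnsetAnnotation(s=1, t=onset),
            info,
        )

    if category == "brief_ictal":
        onset = round(float(rng.uniform(10.0, 70.0)), 3)
        duration = float(rng.uniform(5.0, 9.0))  # <= 10 s by construction
        epoch, ann = generate_ictal_epoch(
            profile, onset, rng, duration_s=duration, recorded_at=recorded_at
        )
        info.update(onset=onset, duration=duration)
        return epoch, ann, info

    if category == "single_channel_ictal":
        onset = round(float(rng.uniform(10.0, 60.0)), 3)
        duration = min(profile.mean_duration_s, EPOCH_SECONDS - onset)
        ch = int(rng.integers(0, N_CHANNELS))
        mask = tuple(i == ch for i in range(N_CHANNELS))
        x = generate_background(profile, rng)
        x += _chirp(profile, rng, onset, duration, mask)
        info.update(onset=onset, duration=duration, channel=ch)
        return (
            _mk_epoch(x, profile, "detection", recorded_at),
            OnsetAnnotation(s=1, t=onset),
            info,
        )

    if category == "dense_interictal":
        x = np.stack(
            [
                _colored_noise(rng, SAMPLES_PER_EPOCH, profile.spectral_slope)
                for _ in range(N_CHANNELS)
            ]
        )
        x *= profile.background_rms_uv
        n_spikes = _add_spikes(
            x,
            rng,
            10.0 * profile.spike_rate_per_min,
            profile.spike_amp_uv,
            n_min=30,
        )
        info.update(n_spikes=n_spikes)
        return (
            _mk_epoch(x, profile, "detection", recorded_at),
            OnsetAnnotation(s=0),
            info,
        )

    # arousal_transition: abrupt broadband power step mid-epoch, non-ictal
    t_step = float(rng.uniform(30.0, 60.0))
    x = generate_background(profile, rng)
    i0 = int(round(t_step * SAMPLING_RATE_HZ))
    x[:, i0:] *= 2.2
    info.update(t_step=t_step)
    return (
        _mk_epoch(x, profile, "scheduled", recorded_at),
        OnsetAnnotation(s=0),
        info,
    )


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class PatientData:
    """All generated data for one synthetic patient."""

    profile: PatientProfile
    metadata: RecordingMetadata
    epochs: list  # list[tuple[IEEGEpoch, OnsetAnnotation]]


@dataclass
class Cohort:
    """In-memory synthetic cohort."""

    config: CohortConfig
    patients: list  # list[PatientData]

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def metadata(self) -> list[RecordingMetadata]:
        return [p.metadata for p in self.patients]


def _patient_timestamps(
    config: CohortConfig, rng: np.random.Generator, n: int
) -> list[_dt.datetime]:
    """Strictly increasing timestamps across the configured date span."""
    offsets = np.sort(rng.uniform(0, config.span_days * 86400.0, size=n))
    offsets = offsets + np.arange(n)  # break ties: strictly increasing
    return [config.start_date + _dt.timedelta(seconds=float(o)) for o in offsets]


def _choose_confound(rng: np.random.Generator, mix: dict, allowed: tuple) -> str | None:
    cats = [c for c in allowed if mix.get(c, 0.0) > 0]
    if not cats:
        return None
    w = np.array([mix[c] for c in cats])
    u = rng.uniform()
    if u >= w.sum():
        return None
    return cats[int(np.searchsorted(np.cumsum(w), u, side="right"))]


def generate_cohort(config: CohortConfig, out_dir: str | Path | None = None) -> Cohort:
    """Generate a full synthetic cohort; optionally write the EDF+CSV tree.

    Per patient the configured number of epochs is produced at the configured
    ictal fraction; non-ictal epochs are flagged ``scheduled`` with the
    configured probability (those feed interictal seed pairing downstream).
    The result is a pure function of the config, including ``master_seed``.
    """
    patients: list[PatientData] = []
    demo_rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 77]))
    for p in range(config.n_patients):
        profile = make_patient_profile(p, master_seed=config.master_seed)
        if config.confound_fraction > 0:
            n_cat = len(CONFOUND_CATEGORIES)
            profile = replace(
                profile,
                confound_mix={
                    c: config.confound_fraction / n_cat for c in CONFOUND_CATEGORIES
                },
            )
        rng = np.random.default_rng(
            np.random.SeedSequence([config.master_seed, 1000 + p])
        )
        n_epochs = config.epochs_per_patient
        n_ictal = int(round(n_epochs * config.ictal_fraction))
        flags = np.zeros(n_epochs, dtype=bool)
        flags[rng.choice(n_epochs, size=n_ictal, replace=False)] = True
        stamps = _patient_timestamps(config, rng, n_epochs)
        epochs = []
        for i in range(n_epochs):
            ts = stamps[i]
            if flags[i]:
                cat = _choose_confound(rng, profile.confound_mix, _ICTAL_CONFOUNDS)
                if cat is not None:
                    epoch, ann, _ = generate_confound_epoch(
                        profile, cat, rng, recorded_at=ts
                    )
                else:
                    # millisecond precision so the CSV sidecar round-trips
                    onset = round(float(rng.uniform(10.0, 70.0)), 3)
                    epoch, ann = generate_ictal_epoch(
                        profile, onset, rng, recorded_at=ts
                    )
            else:
                cat = _choose_confound(rng, profile.confound_mix, _NONICTAL_CONFOUNDS)
                if cat is not None:
                    epoch, ann, _ = generate_confound_epoch(
                        profile, cat, rng, recorded_at=ts
                    )
                else:
                    trig = (
                        "scheduled"
                        if rng.uniform() < config.scheduled_fraction
                        else "detection"
                    )
                    x = generate_background(profile, rng)
                    epoch = _mk_epoch(x, profile, trig, ts)
                    ann = OnsetAnnotation(s=0)
            epoch.samples = quantize_adc(epoch.samples)
            epochs.append((epoch, ann))
        meta = RecordingMetadata(
            patient_id=profile.patient_id,
            implant_site=profile.implant_site,
            n_days_with_device=config.span_days,
            n_ieeg_files=n_epochs,
            n_ictal_patterns=int(flags.sum()),
            age=float(demo_rng.integers(18, 65)),
            sex="F" if demo_rng.uniform() < 0.5 else "M",
        )
        patients.append(PatientData(profile=profile, metadata=meta, epochs=epochs))
    cohort = Cohort(config=config, patients=patients)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write the EDF+CSV tree, per-patient annotation sidecars, and manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for pdata in cohort.patients:
        pid = pdata.profile.patient_id
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        ann_rows = []
        for i, (epoch, ann) in enumerate(pdata.epochs):
            stem = pdir / f"epoch_{i:04d}"
            iio.write_epoch(epoch, ann, stem)
            ann_rows.append(iio.annotation_row(stem.name, epoch, ann))
        with open(pdir / "annotations.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(iio.SIDECAR_COLUMNS)
            w.writerows(ann_rows)
        manifest_rows.append(
            [
                pid,
                pdata.metadata.implant_site,
                str(pdata.metadata.n_ieeg_files),
                str(pdata.metadata.n_ictal_patterns),
            ]
        )
    with open(out / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient", "implant_site", "n_epochs", "n_ictal"])
        w.writerows(manifest_rows)
    return out


def load_cohort(cohort_dir: str | Path) -> Cohort:
    """Read a cohort tree written by :func:`write_cohort` back into memory."""
    root = Path(cohort_dir)
    manifest = root / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv in {root}")
    patients = []
    with open(manifest, newline="") as fh:
        rows = list(csv.DictReader(fh))
    for idx, row in enumerate(rows):
        pid = row["patient"]
        pdir = root / pid
        epochs = []
        for edf in sorted(pdir.glob("epoch_*.edf")):
            epochs.append(iio.read_epoch(edf))
        profile = PatientProfile(
            patient_id=pid,
            implant_site=row["implant_site"],
            spectral_slope=1.5,
            background_rms_uv=20.0,
            spike_rate_per_min=2.0,
            spike_amp_uv=120.0,
            onset_freq_hz=8.0,
            terminal_freq_hz=20.0,
            amp_growth=6.0,
            channel_mask=(True, True, True, True),
            mean_duration_s=30.0,
        )
        meta = RecordingMetadata(
            patient_id=pid,
            implant_site=row["implant_site"],
            n_days_with_device=0,
            n_ieeg_files=int(row["n_epochs"]),
            n_ictal_patterns=int(row["n_ictal"]),
            age=0.0,
            sex="F",
        )
        patients.append(PatientData(profile=profile, metadata=meta, epochs=epochs))
    return Cohort(config=CohortConfig(n_patients=max(len(patients), 1)), patients=patients)


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSummary:
    n_patients: int
    total_days: int
    total_ieeg_files: int
    total_ictal_patterns: int
    mean_age: float
    sd_age: float
    n_female: int
    n_male: int
    mean_weeks: float


def summarize_cohort(records: list[RecordingMetadata]) -> CohortSummary:
    """Column totals and demographics, rounded to 1 decimal for reporting."""
    if not records:
        raise ValidationError("summarize_cohort requires a non-empty record list")
    ages = np.array([r.age for r in records], dtype=float)
    days = np.array([r.n_days_with_device for r in records], dtype=int)
    sd = float(np.std(ages, ddof=1)) if len(records) > 1 else 0.0
    return CohortSummary(
        n_patients=len(records),
        total_days=int(days.sum()),
        total_ieeg_files=int(sum(r.n_ieeg_files for r in records)),
        total_ictal_patterns=int(sum(r.n_ictal_patterns for r in records)),
        mean_age=round(float(ages.mean()), 1),
        sd_age=round(sd, 1),
        n_female=sum(1 for r in records if r.sex == "F"),
        n_male=sum(1 for r in records if r.sex == "M"),
        mean_weeks=round(float(days.mean()) / 7.0, 1),
    )
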