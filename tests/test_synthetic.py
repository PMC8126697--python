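import numpy as np
import pytest

from ictalnet.errors import ValidationError
from ictalnet.io import SAMPLES_PER_EPOCH, SAMPLING_RATE_HZ, load_cohort_table
from ictalnet.synthetic import (
    CohortConfig,
    generate_background,
    generate_cohort,
    generate_confound_epoch,
    generate_ictal_epoch,
    make_patient_profile,
    summarize_cohort,
    write_cohort,
)


def windowed_rms(x, window_s=1.0):
    """Per-channel RMS in consecutive windows, shape (4, n_windows)."""
    w = int(window_s * SAMPLING_RATE_HZ)
    n = x.shape[1] // w
    return np.sqrt((x[:, : n * w].reshape(4, n, w) ** 2).mean(axis=2))


class TestProfiles:
    def test_deterministic(self):
        a = make_patient_profile(3, master_seed=9)
        b = make_patient_profile(3, master_seed=9)
        assert a == b

    def test_distinct_patients_distinct_seizure_params(self):
        a = make_patient_profile(0, master_seed=9)
        b = make_patient_profile(1, master_seed=9)
        assert (a.onset_freq_hz, a.terminal_freq_hz, a.mean_duration_s) != (
            b.onset_freq_hz,
            b.terminal_freq_hz,
            b.mean_duration_s,
        )

    def test_frequencies_in_pass_band_sweep(self):
        for i in range(1000):
            p = make_patient_profile(i % 40, master_seed=i)
            assert 4.0 <= p.onset_freq_hz <= 125.0
            assert 4.0 <= p.terminal_freq_hz <= 125.0
            assert any(p.channel_mask)


class TestBackground:
    def test_zero_spike_rate_no_transients(self, profile):
        import dataclasses

        quiet = dataclasses.replace(profile, spike_rate_per_min=0.0)
        x = generate_background(quiet, np.random.default_rng(5))
        rms = np.sqrt((x**2).mean(axis=1, keepdims=True))
        assert not np.any(np.abs(x) > 5.0 * rms)

    def test_power_concentrated_in_pass_band(self, profile):
        from scipy.signal import periodogram

        x = generate_background(profile, np.random.default_rng(6))
        f, pxx = periodogram(x, fs=SAMPLING_RATE_HZ, axis=1)
        out_of_band = pxx[:, f < 4.0].sum()
        assert out_of_band <= 0.05 * pxx.sum()

    def test_different_rng_states_different_paths(self, profile):
        x1 = generate_background(profile, np.random.default_rng(1))
        x2 = generate_background(profile, np.random.default_rng(2))
        assert not np.allclose(x1, x2)


class TestIctal:
    def test_post_onset_rms_elevated_by_growth_factor(self, profile):
        epoch, ann = generate_ictal_epoch(profile, 45.0, np.random.default_rng(3))
        rms = windowed_rms(epoch.samples)
        involved = np.array(profile.channel_mask)
        pre = rms[involved, :44]
        post = rms[involved, 46:]
        assert post.min() > pre.max()
        assert post.mean() / pre.mean() >= profile.amp_growth

    def test_uninvolved_channels_flat(self):
        import dataclasses

        p = dataclasses.replace(
            make_patient_profile(1, master_seed=7),
            channel_mask=(True, True, False, False),
        )
        epoch, _ = generate_ictal_epoch(p, 45.0, np.random.default_rng(3))
        rms = windowed_rms(epoch.samples)
        for ch in (2, 3):
            ratio = rms[ch, 46:].mean() / rms[ch, :44].mean()
            assert 0.7 < ratio < 1.3

    def test_onset_zero_entire_epoch_ictal(self, profile):
        epoch, ann = generate_ictal_epoch(profile, 0.0, np.random.default_rng(4))
        assert ann.t == 0.0
        rms = windowed_rms(epoch.samples)
        involved = np.array(profile.channel_mask)
        # first window already carries the discharge
        assert rms[involved, 0].mean() > 3.0 * profile.background_rms_uv

    def test_onset_exactness_and_bounds(self, profile):
        _, ann = generate_ictal_epoch(profile, 12.345, np.random.default_rng(0))
        assert ann.t == 12.345
        with pytest.raises(ValidationError):
            generate_ictal_epoch(profile, 90.0, np.random.default_rng(0))
        with pytest.raises(ValidationError):
            generate_ictal_epoch(profile, -1.0, np.random.default_rng(0))


class TestConfounds:
    def test_brief_ictal_duration(self, profile):
        for seed in range(5):
            _, ann, info = generate_confound_epoch(
                profile, "brief_ictal", np.random.default_rng(seed)
            )
            assert ann.s == 1 and info["duration"] <= 10.0

    def test_dense_interictal_nonictal_with_many_transients(self, profile):
        _, ann, info = generate_confound_epoch(
            profile, "dense_interictal", np.random.default_rng(0)
        )
        assert ann.s == 0 and info["n_spikes"] >= 30

    def test_single_channel_ictal_one_elevated_channel(self, profile):
        epoch, ann, info = generate_confound_epoch(
            profile, "single_channel_ictal", np.random.default_rng(2)
        )
        assert ann.s == 1
        onset_w = int(np.ceil(info["onset"]))
        rms = windowed_rms(epoch.samples)
        pre = rms[:, : onset_w - 1].mean(axis=1)
        post = rms[:, onset_w + 1 :].mean(axis=1)
        elevated = np.nonzero(post / pre > 3.0)[0]
        assert list(elevated) == [info["channel"]]

    def test_electrodecrement_suppressed_then_oscillating(self, profile):
        epoch, ann, info = generate_confound_epoch(
            profile, "electrodecrement_onset", np.random.default_rng(1)
        )
        assert ann.s == 1
        t = info["onset"]
        i0 = int(t * SAMPLING_RATE_HZ)
        i1 = int((t + info["suppress_s"]) * SAMPLING_RATE_HZ)
        pre_rms = epoch.samples[:, : i0 - 250].std()
        sup_rms = epoch.samples[:, i0 + 25 : i1 - 25].std()
        post_rms = epoch.samples[:, i1 + 250 :].std()
        assert sup_rms < 0.6 * pre_rms
        assert post_rms > 2.0 * pre_rms

    def test_arousal_transition_power_step(self, profile):
        epoch, ann, info = generate_confound_epoch(
            profile, "arousal_transition", np.random.default_rng(3)
        )
        assert ann.s == 0
        i0 = int(info["t_step"] * SAMPLING_RATE_HZ)
        assert epoch.samples[:, i0 + 250 :].std() > 1.5 * epoch.samples[:, : i0 - 250].std()

    def test_unknown_category(self, profile):
        with pytest.raises(ValidationError):
            generate_confound_epoch(profile, "nope", np.random.default_rng(0))


class TestCohort:
    CFG = CohortConfig(
        n_patients=3, epochs_per_patient=10, ictal_fraction=0.4, master_seed=77
    )

    def test_counts(self):
        cohort = generate_cohort(self.CFG)
        assert cohort.n_patients == 3
        total = sum(len(p.epochs) for p in cohort.patients)
        ictal = sum(
            sum(a.s for _, a in p.epochs) for p in cohort.patients
        )
        assert total == 30 and ictal == 12

    def test_reproducible_and_byte_identical_sidecars(self, tmp_path):
        c1 = generate_cohort(self.CFG)
        c2 = generate_cohort(self.CFG)
        write_cohort(c1, tmp_path / "a")
        write_cohort(c2, tmp_path / "b")
        for rel in ["manifest.csv", "SP00/annotations.csv", "SP02/annotations.csv"]:
            assert (tmp_path / "a" / rel).read_bytes() == (
                tmp_path / "b" / rel
            ).read_bytes()

    def test_timestamps_strictly_increasing(self):
        cohort = generate_cohort(self.CFG)
        for p in cohort.patients:
            stamps = [e.recorded_at for e, _ in p.epochs]
            assert all(a < b for a, b in zip(stamps, stamps[1:]))

    def test_annotations_consistent_with_signals(self):
        cohort = generate_cohort(self.CFG)
        for p in cohort.patients:
            involved = np.array(p.profile.channel_mask)
            for epoch, ann in p.epochs:
                rms = windowed_rms(epoch.samples)
                if ann.s == 1 and ann.t < 80:
                    w = int(np.ceil(ann.t))
                    post = rms[involved, w + 1 : w + 10].mean()
                    pre = rms[involved, : max(w - 1, 1)].mean() if w > 1 else None
                    if pre is not None:
                        assert post > 2.0 * pre

    def test_epoch_length_and_quantization(self):
        cohort = generate_cohort(self.CFG)
        epoch, _ = cohort.patients[0].epochs[0]
        assert epoch.samples.shape == (4, SAMPLES_PER_EPOCH)
        from ictalnet.io import quantize_adc

        np.testing.assert_array_equal(quantize_adc(epoch.samples), epoch.samples)

    def test_roundtrip_through_disk(self, tmp_path):
        from ictalnet.synthetic import load_cohort

        cohort = generate_cohort(self.CFG, out_dir=tmp_path / "c")
        back = load_cohort(tmp_path / "c")
        assert back.n_patients == 3
        for p_orig, p_back in zip(cohort.patients, back.patients):
            assert len(p_back.epochs) == len(p_orig.epochs)
            e0, a0 = p_orig.epochs[0]
            e1, a1 = p_back.epochs[0]
            np.testing.assert_array_equal(e0.samples, e1.samples)
            assert a0 == a1


class TestSummary:
    def test_table1_totals(self):
        s = summarize_cohort(load_cohort_table())
        assert s.total_ictal_patterns == 5226
        assert s.total_ieeg_files == 18368
        assert s.total_days == 7346

    def test_table1_demographics(self):
        s = summarize_cohort(load_cohort_table())
        assert s.mean_age == 33.9
        assert s.n_female == 13
        assert s.mean_weeks == 47.7

    def test_single_record(self):
        records = load_cohort_table()[:1]
        s = summarize_cohort(records)
        assert s.total_days == records[0].n_days_with_device
        assert s.n_patients == 1

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            summarize_cohort([])
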