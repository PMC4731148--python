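"""Simulator: task schedule, power-law noise, and signal injection."""

import logging

import numpy as np
import pytest
from scipy.signal import butter, sosfiltfilt, welch

from spontodecode.datatypes import EventTable
from spontodecode.synthetic import (
    ChannelSpec,
    TaskSchedule,
    default_envelope,
    make_schedule,
    preset_dataset,
    synth_noise,
    synth_recording,
)


def periodogram_slope(x, fs=1000.0, lo=5.0, hi=150.0):
    """Least-squares slope of the log-log averaged periodogram (the oracle
    for the 1/f^chi exponent)."""
    f, p = welch(x, fs=fs, nperseg=4096)
    sel = (f >= lo) & (f <= hi)
    return np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]


class TestSchedule:
    def test_defaults_give_300_balanced_stimuli(self):
        ev = make_schedule(TaskSchedule(seed=0))
        assert len(ev) == 300
        for r in range(3):
            run = ev.for_runs(r)
            assert len(run) == 100
            assert (run.labels == "face").sum() == 50
            assert (run.labels == "house").sum() == 50
            assert np.all(np.diff(run.onset_ms) == 800)

    def test_single_pair_spaced_by_display_plus_isi(self):
        ev = make_schedule(TaskSchedule(n_runs=1, stimuli_per_class_per_run=1,
                                        display_ms=400, isi_ms=400, seed=5))
        assert len(ev) == 2
        assert ev.onset_ms[1] - ev.onset_ms[0] == 800

    def test_seed_determinism(self):
        a = make_schedule(TaskSchedule(seed=42))
        b = make_schedule(TaskSchedule(seed=42))
        c = make_schedule(TaskSchedule(seed=43))
        assert np.array_equal(a.onset_ms, b.onset_ms)
        assert np.array_equal(a.labels, b.labels)
        assert not np.array_equal(a.labels, c.labels)

    @pytest.mark.parametrize("kw", [{"display_ms": 0}, {"isi_ms": -1},
                                    {"n_runs": 0}, {"stimuli_per_class_per_run": 0}])
    def test_invalid_configuration_rejected(self, kw):
        with pytest.raises(ValueError):
            TaskSchedule(**kw)


class TestNoise:
    @pytest.mark.parametrize("chi", [2.0, 0.0])
    def test_spectral_slope_matches_exponent(self, chi):
        ch = ChannelSpec(noise_exponent=chi, line_amp_60hz=0.0)
        x = synth_noise(ch, 60_000, seed=3)
        assert abs(periodogram_slope(x) - (-chi)) < 0.3

    def test_line_contamination_peak(self):
        f, p0 = welch(synth_noise(ChannelSpec(line_amp_60hz=0.0), 60_000, 2),
                      fs=1000.0, nperseg=4096)
        f, p1 = welch(synth_noise(ChannelSpec(line_amp_60hz=5.0), 60_000, 2),
                      fs=1000.0, nperseg=4096)
        at60 = np.argmin(np.abs(f - 60.0))
        local = (np.abs(f - 60.0) > 3) & (np.abs(f - 60.0) < 15)
        assert p0[at60] < 3 * np.median(p0[local])   # nothing injected
        assert p1[at60] > 3 * np.median(p1[local])   # line clearly present

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            synth_noise(ChannelSpec(), 0, seed=0)


def _schedule(n_per_class=25, seed=0, **kw):
    task = TaskSchedule(n_runs=1, stimuli_per_class_per_run=n_per_class, seed=seed, **kw)
    return make_schedule(task), task


class TestRecording:
    def test_null_channel_statistically_plain_noise(self):
        sched, task = _schedule()
        null = ChannelSpec(name="null")
        ds = synth_recording(sched, [null], seed=9, n_samples=task.total_duration_ms)
        ref = synth_noise(null, task.total_duration_ms, seed=10)
        ratio = ds.recording.potentials[:, 0].var() / ref.var()
        assert 0.9 < ratio < 1.1

    def test_noiseless_boxcar_erp_reproduced_exactly(self):
        boxcar = np.zeros(400)
        boxcar[:100] = 1.0
        ch = ChannelSpec(erp_face=boxcar, noise_std=0.0, line_amp_60hz=0.0)
        ev = EventTable([2000], ["face"], [0])
        ds = synth_recording(ev, [ch], seed=0, n_samples=4000)
        x = ds.recording.potentials[:, 0]
        assert np.array_equal(x[2000:2400], boxcar)
        assert np.all(x[:2000] == 0) and np.all(x[2400:] == 0)

    def test_broadband_gain_visible_in_band_power(self):
        # gain 4 face channel: 70-150 Hz power in 0-400 ms post-face vs ISI
        sched, task = _schedule(n_per_class=50, seed=1)
        ch = ChannelSpec(bb_gain_face=4.0, bb_envelope=default_envelope(),
                         line_amp_60hz=0.0)
        ds = synth_recording(sched, [ch], seed=4, n_samples=task.total_duration_ms)
        sos = butter(4, [70, 150], btype="bandpass", fs=1000.0, output="sos")
        y = sosfiltfilt(sos, ds.recording.potentials[:, 0])
        faces = sched.for_class("face").onset_ms
        p_face = np.mean([y[t:t + 400].var() for t in faces])
        p_isi = np.mean([y[t + 420:t + 780].var() for t in faces])
        assert 3.0 < p_face / p_isi < 5.0

    def test_erp_recovered_by_stimulus_triggered_averaging(self):
        sched, task = _schedule(n_per_class=30, seed=2)
        erp = ChannelSpec(erp_face=np.sin(np.linspace(0, 4 * np.pi, 400)) * 10,
                          noise_std=0.2, line_amp_60hz=0.0)
        ds = synth_recording(sched, [erp], seed=5, n_samples=task.total_duration_ms)
        x = ds.recording.potentials[:, 0]
        faces = sched.for_class("face").onset_ms
        avg = np.mean([x[t:t + 400] for t in faces], axis=0)
        assert np.max(np.abs(avg - erp.erp_face)) < 0.5

    def test_broadband_invisible_in_average_potential(self):
        # ERP/ERBB dissociation: multiplicative power change leaves no trace
        # in the stimulus-triggered average potential, yet band power doubles
        sched, task = _schedule(n_per_class=50, seed=3)
        ch = ChannelSpec(bb_gain_face=4.0, bb_envelope=default_envelope(),
                         line_amp_60hz=0.0)
        ds = synth_recording(sched, [ch], seed=6, n_samples=task.total_duration_ms)
        x = ds.recording.potentials[:, 0]
        faces = sched.for_class("face").onset_ms
        wins = np.array([x[t:t + 400] for t in faces])
        avg = wins.mean(axis=0)
        se = wins.std(axis=0, ddof=1) / np.sqrt(len(wins))
        assert np.mean(np.abs(avg)) < 3 * np.mean(se)

    def test_fixed_seed_bit_identical(self):
        a = preset_dataset("tiny", seed=7)
        b = preset_dataset("tiny", seed=7)
        assert np.array_equal(a.recording.potentials, b.recording.potentials)
        assert np.array_equal(a.events.onset_ms, b.events.onset_ms)

    def test_overlapping_envelopes_warn(self, caplog):
        ch = ChannelSpec(bb_gain_face=4.0, bb_envelope=default_envelope())
        ev = EventTable([1000, 1200], ["face", "face"], [0, 0])
        with caplog.at_level(logging.WARNING):
            synth_recording(ev, [ch], seed=0, n_samples=3000)
        assert any("overlap" in r.message for r in caplog.records)

    def test_schedule_must_fit_duration(self):
        ev = EventTable([5000], ["face"], [0])
        with pytest.raises(ValueError):
            synth_recording(ev, [ChannelSpec()], seed=0, n_samples=3000)
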