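"""Synthetic ECoG simulator with the face/house task structure.

The generator produces continuous multichannel recordings with the signal
physiology the decoder assumes: a 1/f^χ power-law noise background, 60 Hz
line contamination, class-selective additive event-related potentials
(polymorphic shapes, following the wide morphological variation seen across
fusiform sites), and class-selective *multiplicative* broadband power
modulation — the noise amplitude is scaled under a temporal envelope, so the
event is visible in band power but (for zero-amplitude ERPs) invisible in
the stimulus-triggered average potential.  That ERP/ERBB dissociation is the
property the decoder exploits.

Task structure: runs of balanced face/house stimuli displayed for 400 ms
with a 400 ms blank inter-stimulus interval (onset-to-onset 800 ms); the
default configuration is 3 runs × (50 faces + 50 houses) = 300 stimuli.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, rfftfreq

from .datatypes import CLASSES, ContinuousRecording, EventTable

logger = logging.getLogger(__name__)

SAMPLING_RATE_HZ = 1000.0


@dataclass
class TaskSchedule:
    """Timing configuration of the stimulus presentation task."""

    n_runs: int = 3
    stimuli_per_class_per_run: int = 50
    display_ms: int = 400
    isi_ms: int = 400
    pre_roll_ms: int = 2000   # quiet lead-in per run; peri-event windows never clip
    post_roll_ms: int = 1000  # quiet tail per run
    jitter_ms: int = 0        # per-event onset jitter (instrumentation jitter emulation)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs <= 0 or self.stimuli_per_class_per_run <= 0:
            raise ValueError("counts must be positive")
        if self.display_ms <= 0 or self.isi_ms <= 0:
            raise ValueError("durations must be positive")

    @property
    def soa_ms(self) -> int:
        """Onset-to-onset spacing (display + ISI)."""
        return self.display_ms + self.isi_ms

    @property
    def events_per_run(self) -> int:
        return 2 * self.stimuli_per_class_per_run

    @property
    def run_duration_ms(self) -> int:
        return self.pre_roll_ms + self.events_per_run * self.soa_ms + self.post_roll_ms

    @property
    def total_duration_ms(self) -> int:
        return self.n_runs * self.run_duration_ms


@dataclass
class ChannelSpec:
    """Signal physiology of one simulated channel.

    ``erp_face`` / ``erp_house`` are additive waveforms (µV) starting at
    stimulus onset; ``bb_gain_*`` are multiplicative broadband *power*
    factors applied to the noise background under ``bb_envelope`` (a
    normalized temporal envelope, zero outside 0–400 ms post-onset);
    ``noise_exponent`` is the spectral slope χ of the 1/f^χ background.
    """

    erp_face: np.ndarray = field(default_factory=lambda: np.zeros(400))
    erp_house: np.ndarray = field(default_factory=lambda: np.zeros(400))
    bb_gain_face: float = 1.0
    bb_gain_house: float = 1.0
    bb_envelope: np.ndarray = field(default_factory=lambda: np.zeros(400))
    noise_exponent: float = 2.0
    noise_std: float = 15.0
    line_amp_60hz: float = 5.0
    # single-trial response variability (0 = perfectly stereotyped trials,
    # used by the exact-recovery tests; presets use realistic values)
    amp_cv: float = 0.0            # lognormal CV of per-event response scale
    response_jitter_ms: float = 0.0  # SD of per-event response latency shift
    name: str = "ch"

    def __post_init__(self) -> None:
        self.erp_face = np.asarray(self.erp_face, dtype=float)
        self.erp_house = np.asarray(self.erp_house, dtype=float)
        self.bb_envelope = np.asarray(self.bb_envelope, dtype=float)
        if self.bb_gain_face < 0 or self.bb_gain_house < 0:
            raise ValueError("broadband gains must be >= 0")
        if not 0.0 <= self.noise_exponent <= 4.0:
            raise ValueError("noise_exponent must lie in [0, 4]")
        if len(self.bb_envelope) > 400:
            raise ValueError("bb_envelope must be zero outside 0-400 ms post-onset")

    def erp(self, label: str) -> np.ndarray:
        return self.erp_face if label == "face" else self.erp_house

    def bb_gain(self, label: str) -> float:
        return self.bb_gain_face if label == "face" else self.bb_gain_house


@dataclass
class SyntheticDataset:
    """A generated recording plus its ground truth."""

    recording: ContinuousRecording
    events: EventTable
    channel_specs: list
    latencies_ms: np.ndarray  # actual injected onsets (= onset + jitter)
    schedule: TaskSchedule | None = None


def make_schedule(cfg: TaskSchedule) -> EventTable:
    """Build the stimulus event table: per run, a seeded random permutation
    of the balanced face/house multiset at fixed onset-to-onset spacing."""
    rng = np.random.default_rng(cfg.seed)
    onsets, labels, runs = [], [], []
    base = np.array(
        ["face"] * cfg.stimuli_per_class_per_run + ["house"] * cfg.stimuli_per_class_per_run,
        dtype=object,
    )
    for r in range(cfg.n_runs):
        order = rng.permutation(cfg.events_per_run)
        run_start = r * cfg.run_duration_ms
        for i, lab in enumerate(base[order]):
            onsets.append(run_start + cfg.pre_roll_ms + i * cfg.soa_ms)
            labels.append(lab)
            runs.append(r)
    return EventTable(np.array(onsets), np.array(labels, dtype=object), np.array(runs))


def _colored_noise(exponent: float, n_samples: int, rng: np.random.Generator,
                   std: float = 1.0, fs: float = SAMPLING_RATE_HZ) -> np.ndarray:
    """1/f^χ noise by spectral shaping of white noise (exact slope control).

    The slope holds over ~0.5–200 Hz; below 0.5 Hz the amplitude plateaus
    (the amplifier high-pass makes near-DC content irrelevant) and above
    200 Hz a steep roll-off emulates the acquisition band limit.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    freqs = rfftfreq(n_samples, 1.0 / fs)
    amp = np.zeros_like(freqs)
    f_eff = np.maximum(freqs, 0.5)
    amp[1:] = f_eff[1:] ** (-exponent / 2.0)
    amp /= np.sqrt(1.0 + (freqs / 200.0) ** 16)  # band-limit roll-off
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = irfft(spec, n=n_samples)
    s = x.std()
    if s > 0:
        x *= std / s
    return x


def synth_noise(channel: ChannelSpec, n_samples: int, seed: int) -> np.ndarray:
    """Background trace for one channel: power-law noise plus 60 Hz line."""
    rng = np.random.default_rng(seed)
    x = _colored_noise(channel.noise_exponent, n_samples, rng, std=channel.noise_std)
    if channel.line_amp_60hz:
        t = np.arange(n_samples) / SAMPLING_RATE_HZ
        phase = rng.uniform(0, 2 * np.pi)
        x = x + channel.line_amp_60hz * np.sin(2 * np.pi * 60.0 * t + phase)
    return x


def synth_recording(
    schedule: EventTable,
    channels: list,
    seed: int,
    n_samples: int | None = None,
    jitter_ms: int = 0,
    task: TaskSchedule | None = None,
) -> SyntheticDataset:
    """Render a continuous recording from an event table and channel specs.

    For each event the class's ERP waveform is added at the (possibly
    jittered) onset, and the background noise amplitude is scaled by
    sqrt(bb_gain) under the channel's broadband envelope — a multiplicative
    power change, not an additive oscillation.
    """
    if n_samples is None:
        n_samples = int(schedule.onset_ms.max()) + 1400 if len(schedule) else 2000
        if task is not None:
            n_samples = task.total_duration_ms
    if len(schedule) and schedule.onset_ms.max() + 401 > n_samples:
        raise ValueError("schedule does not fit within the requested duration")

    master = np.random.SeedSequence(seed)
    jit_rng = np.random.default_rng(master.spawn(1)[0])
    if jitter_ms > 0:
        latencies = schedule.onset_ms + jit_rng.integers(
            -jitter_ms, jitter_ms + 1, size=len(schedule)
        )
    else:
        latencies = schedule.onset_ms.copy()

    ch_seeds = master.spawn(len(channels))
    # one latency draw per event, shared across channels: trial-to-trial
    # latency variation acts as a global processing delay of the whole
    # cortical response, scaled by each channel's response_jitter_ms
    shared_z = jit_rng.standard_normal(len(schedule))
    out = np.empty((n_samples, len(channels)), dtype=np.float64)
    t = np.arange(n_samples) / SAMPLING_RATE_HZ
    for ci, ch in enumerate(channels):
        rng = np.random.default_rng(ch_seeds[ci])
        noise = _colored_noise(ch.noise_exponent, n_samples, rng, std=ch.noise_std)

        # single-trial physiologic variability: per-event response scale
        # (lognormal, mean 1) and latency shift of the whole response
        n_ev = len(latencies)
        if ch.amp_cv > 0:
            s = np.sqrt(np.log1p(ch.amp_cv ** 2))
            scales = np.exp(rng.normal(-0.5 * s * s, s, size=n_ev))
        else:
            scales = np.ones(n_ev)
        if ch.response_jitter_ms > 0:
            shifts = np.round(shared_z * ch.response_jitter_ms).astype(int)
        else:
            shifts = np.zeros(n_ev, dtype=int)

        # multiplicative broadband power modulation
        env_len = len(ch.bb_envelope)
        power = np.ones(n_samples)
        overlap = np.zeros(n_samples, dtype=np.int8)
        for k, (lat, lab) in enumerate(zip(latencies, schedule.labels)):
            g = ch.bb_gain(lab)
            start = max(0, int(lat) + shifts[k])
            hi = min(start + env_len, n_samples)
            if g != 1.0 and env_len:
                power[start:hi] += (g - 1.0) * scales[k] * ch.bb_envelope[: hi - start]
                overlap[start:hi] += 1
        if np.any(overlap > 1):
            logger.warning(
                "channel %s: overlapping broadband envelopes summed", ch.name
            )
        np.maximum(power, 0.0, out=power)
        trace = noise * np.sqrt(power)

        # additive event-related potentials
        for k, (lat, lab) in enumerate(zip(latencies, schedule.labels)):
            erp = ch.erp(lab)
            start = max(0, int(lat) + shifts[k])
            hi = min(start + len(erp), n_samples)
            trace[start:hi] += scales[k] * erp[: hi - start]

        if ch.line_amp_60hz:
            phase = rng.uniform(0, 2 * np.pi)
            trace += ch.line_amp_60hz * np.sin(2 * np.pi * 60.0 * t + phase)
        out[:, ci] = trace

    rec = ContinuousRecording(
        potentials=out,
        sampling_rate_hz=SAMPLING_RATE_HZ,
        channel_labels=[c.name or f"ch{i:02d}" for i, c in enumerate(channels)],
    )
    return SyntheticDataset(rec, schedule, list(channels), latencies)


# ---------------------------------------------------------------------------
# waveform helpers and presets


def _gauss(n: int, mu: float, sigma: float) -> np.ndarray:
    t = np.arange(n, dtype=float)
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def default_envelope(n: int = 400, ramp: int = 60) -> np.ndarray:
    """Raised-cosine plateau envelope on 0..n ms (peak 1)."""
    env = np.ones(n)
    r = np.arange(ramp, dtype=float)
    env[:ramp] = 0.5 * (1 - np.cos(np.pi * r / ramp))
    env[n - ramp:] = env[:ramp][::-1]
    return env


def erp_n200(amp: float) -> np.ndarray:
    """Classic N200-like face ERP: deep trough near 200 ms, slow rebound.

    Deflection widths follow real ventral-temporal ERPs, whose peaks and
    troughs span one to several hundred milliseconds.
    """
    return -amp * _gauss(400, 200, 60) + 0.4 * amp * _gauss(400, 330, 70)


def erp_biphasic(amp: float) -> np.ndarray:
    return amp * _gauss(400, 130, 55) - amp * _gauss(400, 280, 75)


def erp_slow(amp: float) -> np.ndarray:
    return amp * _gauss(400, 250, 100)


def preset_channels(name: str = "high-snr") -> list:
    """Channel banks used by the tests and the pipeline presets.

    ``high-snr``: 8 channels — 3 face-selective, 3 house-selective, 2 null;
    within each selective triple the ERP/broadband balance varies (both
    strong / ERP-dominant / broadband-dominant), emulating the polymorphic
    mixture of selectivities across ventral temporal sites.  ``low-snr``
    shrinks ERP amplitudes 4× and broadband gains to 2 for stress tests.
    """
    var = dict(amp_cv=0.2, response_jitter_ms=30.0)  # single-trial variability
    if name in ("high-snr", "low-snr"):
        # per class: one ERP-selective site, one broadband-selective site,
        # one moderately mixed site — neither modality saturates alone, so
        # the two features carry complementary information
        scale = 1.0 if name == "high-snr" else 0.25
        g_hi = 4.0 if name == "high-snr" else 2.0
        g_mid = 2.0 if name == "high-snr" else 1.5
        env = default_envelope()
        return [
            ChannelSpec(erp_face=erp_n200(45 * scale), name="face_erp", **var),
            ChannelSpec(bb_gain_face=g_hi, bb_envelope=env, name="face_bb", **var),
            ChannelSpec(erp_face=erp_slow(25 * scale), bb_gain_face=g_mid,
                        bb_envelope=env, name="face_both", **var),
            ChannelSpec(erp_house=erp_biphasic(45 * scale), name="house_erp", **var),
            ChannelSpec(bb_gain_house=g_hi, bb_envelope=env, name="house_bb", **var),
            ChannelSpec(erp_house=-erp_slow(25 * scale), bb_gain_house=g_mid,
                        bb_envelope=env, name="house_both", **var),
            ChannelSpec(name="null_a"),
            ChannelSpec(name="null_b"),
        ]
    if name == "tiny":
        env = default_envelope()
        return [
            ChannelSpec(erp_face=erp_n200(40), bb_gain_face=4.0, bb_envelope=env,
                        name="face_both", **var),
            ChannelSpec(erp_house=erp_biphasic(40), bb_gain_house=4.0, bb_envelope=env,
                        name="house_both", **var),
            ChannelSpec(name="null_a"),
        ]
    raise ValueError(f"unknown preset {name!r}")


def preset_dataset(
    name: str = "high-snr", seed: int = 1, task: TaskSchedule | None = None
) -> SyntheticDataset:
    """Generate a full dataset for a named preset under one seed."""
    if task is None:
        if name == "tiny":
            task = TaskSchedule(n_runs=3, stimuli_per_class_per_run=5, seed=seed)
        else:
            task = TaskSchedule(seed=seed)
    schedule = make_schedule(task)
    ds = synth_recording(
        schedule, preset_channels(name), seed=seed,
        n_samples=task.total_duration_ms, jitter_ms=task.jitter_ms, task=task,
    )
    ds.schedule = task
    return ds
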