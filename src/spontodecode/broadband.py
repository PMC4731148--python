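"""Broadband spectral-change timecourse via spectral decoupling.

The continuous potential is decomposed into a time-frequency log-power
representation (Morlet wavelets, 1 Hz grid over 4–200 Hz excluding the line
frequency and its harmonics), each frequency is normalized by its mean power
across time and log-transformed, and principal component analysis across
time samples identifies the dominant motifs of power-spectral change.  The
first principal spectral component (PSC 1) — a near-flat loading across
frequencies — captures the broadband power-law shift that tracks aggregate
population firing rate; projecting each millisecond's normalized log
spectrum onto it, exponentiating, smoothing and z-scoring yields the
broadband trace B(t).

Decoupling is label-ignorant and is fitted once across the whole recording,
not per cross-validation fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, fftfreq, ifft, next_fast_len
from scipy.ndimage import gaussian_filter1d

from .config import PipelineConfig
from .datatypes import ContinuousRecording

_EDGE_PAD = 4096  # samples of zero padding on each side before the FFT


def frequency_grid(cfg: PipelineConfig | None = None) -> np.ndarray:
    """1-Hz-resolution analysis grid with the line bands excised."""
    cfg = cfg or PipelineConfig()
    freqs = np.arange(cfg.freq_lo_hz, cfg.freq_hi_hz + cfg.freq_step_hz / 2, cfg.freq_step_hz)
    keep = np.ones(len(freqs), dtype=bool)
    for lo, hi in cfg.excluded_bands_hz:
        keep &= ~((freqs >= lo) & (freqs <= hi))
    return freqs[keep]


@dataclass
class DynamicSpectrum:
    """Normalized log power, time × frequency, at 1 ms step."""

    log_power: np.ndarray  # (n_times, n_freqs) float32
    freqs_hz: np.ndarray

    @property
    def n_times(self) -> int:
        return self.log_power.shape[0]


@dataclass
class SpectralPCs:
    """Principal spectral components: orthonormal loadings, eigenvalues descending."""

    loadings: np.ndarray     # (n_freqs, n_components)
    eigenvalues: np.ndarray  # descending
    freqs_hz: np.ndarray


def dynamic_spectrum(
    rec: ContinuousRecording | np.ndarray,
    channel: int = 0,
    cfg: PipelineConfig | None = None,
    normalize: bool = True,
) -> DynamicSpectrum:
    """Morlet time-frequency log power at 1 ms step for one channel.

    Each analysis frequency uses a ~7-cycle wavelet applied in the frequency
    domain (analytic signal), giving a continuous per-millisecond power
    estimate.  Power at each frequency is divided by its mean across time
    and natural-log transformed, removing the 1/f^χ mean profile so that
    spectral *changes* are what remain.  ``normalize=False`` skips the
    per-frequency mean division (raw log power).
    """
    cfg = cfg or PipelineConfig()
    x = rec.potentials[:, channel] if isinstance(rec, ContinuousRecording) else np.asarray(rec)
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if n < 2000:
        raise ValueError("record shorter than 2 s: per-frequency normalization unstable")
    fs = 1000.0
    freqs = frequency_grid(cfg)

    nfft = next_fast_len(n + 2 * _EDGE_PAD)
    padded = np.zeros(nfft)
    padded[_EDGE_PAD:_EDGE_PAD + n] = x
    X = fft(padded)
    omega = fftfreq(nfft, 1.0 / fs)

    log_power = np.empty((n, len(freqs)), dtype=np.float32)
    for i, f in enumerate(freqs):
        sigma_f = f / cfg.wavelet_cycles
        # one-sided Gaussian kernel -> analytic signal; per-frequency gain is
        # irrelevant because of the mean-power normalization below
        H = np.exp(-0.5 * ((omega - f) / sigma_f) ** 2)
        H[omega < 0] = 0.0
        a = ifft(X * H)[_EDGE_PAD:_EDGE_PAD + n]
        p = (a.real ** 2 + a.imag ** 2)
        if normalize:
            p /= p.mean()
        np.log(p, out=p)
        log_power[:, i] = p.astype(np.float32)
    return DynamicSpectrum(log_power=log_power, freqs_hz=freqs)


def decouple(spec: DynamicSpectrum, n_components: int | None = None) -> SpectralPCs:
    """PCA across time samples of the normalized log spectra.

    Returns orthonormal frequency loadings with eigenvalues in descending
    order; the first component's sign is fixed so that its mean loading
    above 80 Hz is positive (broadband increase = positive projection).
    """
    X = spec.log_power
    n_t, n_f = X.shape
    if n_t < 1000:
        raise ValueError("decoupling requires at least 1000 time samples")
    if n_t < n_f:
        raise ValueError("rank-deficient input: fewer time samples than frequencies")
    mu = X.mean(axis=0, dtype=np.float64)
    cov = np.dot(X.T, X).astype(np.float64) / n_t - np.outer(mu, mu)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    if n_components is not None:
        evals, evecs = evals[:n_components], evecs[:, :n_components]
    hi = spec.freqs_hz > 80.0
    ref = evecs[hi, 0].mean() if hi.any() else evecs[:, 0].mean()
    if ref < 0:
        evecs[:, 0] = -evecs[:, 0]
    # deterministic sign for the remaining components
    for k in range(1, evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    return SpectralPCs(loadings=evecs, eigenvalues=evals, freqs_hz=spec.freqs_hz)


def broadband_timecourse(
    spec: DynamicSpectrum,
    pcs: SpectralPCs,
    sigma_ms: float = 25.0,
) -> np.ndarray:
    """Project onto PSC 1, exponentiate, smooth (Gaussian σ, default 25 ms),
    z-score.  Returns the unitless broadband trace B(t), one value per ms.

    The PSC-1 score is rescaled by the mean loading before exponentiation,
    i.e. what is exponentiated is the *reconstructed mean log-power change*
    across the spectrum — a multiplicative power factor of order exp(ln g²)
    during an event — rather than the raw score, whose magnitude grows with
    the size of the frequency grid.
    """
    proj = spec.log_power.astype(np.float64) @ pcs.loadings[:, 0]
    proj *= pcs.loadings[:, 0].mean()
    proj -= proj.mean()  # constant multiplicative factor; guards the exp
    bb = np.exp(proj)
    if sigma_ms > 0:
        bb = gaussian_filter1d(bb, sigma_ms, mode="nearest", truncate=4.0)
    bb -= bb.mean()
    sd = bb.std()
    if sd > 0:
        bb /= sd
    return bb


def broadband_for_recording(
    rec: ContinuousRecording, cfg: PipelineConfig | None = None
) -> np.ndarray:
    """B(t) for every good channel of a preprocessed recording.

    Returns an (n_samples, n_channels) matrix; bad channels are zero-filled.
    """
    cfg = cfg or PipelineConfig()
    out = np.zeros((rec.n_samples, rec.n_channels))
    for ch in rec.good_channels:
        spec = dynamic_spectrum(rec, ch, cfg)
        pcs = decouple(spec)
        out[:, ch] = broadband_timecourse(spec, pcs, cfg.broadband_sigma_ms)
        del spec
    return out
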