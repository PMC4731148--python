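"""Preprocessing: common-average re-referencing and 58–62 Hz notch filtering."""

from __future__ import annotations

import numpy as np
from scipy import signal

from .datatypes import ContinuousRecording


def common_average_reference(rec: ContinuousRecording) -> ContinuousRecording:
    """Subtract the instantaneous mean of the good channels from each good
    channel; bad channels are excluded from the average and passed through
    unchanged."""
    good = rec.good_channels
    if len(good) == 0:
        raise ValueError("common average reference requires at least one good channel")
    out = rec.potentials.astype(np.float64, copy=True)
    mean = out[:, good].mean(axis=1, keepdims=True)
    out[:, good] -= mean
    return rec.copy_with(out)


def notch_60hz(
    rec: ContinuousRecording,
    lo_hz: float = 58.0,
    hi_hz: float = 62.0,
    order: int = 3,
    zero_phase: bool = True,
) -> ContinuousRecording:
    """Butterworth band-stop around the line frequency.

    A 3rd-order design (per band edge) applied forward-backward by default,
    so the filter is zero-phase and template timing is not skewed by group
    delay.  ``zero_phase=False`` applies a single causal pass instead.
    """
    if rec.sampling_rate_hz != 1000.0:
        raise ValueError("notch_60hz expects a 1000 Hz recording")
    sos = signal.butter(
        order, [lo_hz, hi_hz], btype="bandstop", fs=rec.sampling_rate_hz, output="sos"
    )
    if zero_phase:
        out = signal.sosfiltfilt(sos, rec.potentials, axis=0)
    else:
        out = signal.sosfilt(sos, rec.potentials, axis=0)
    return rec.copy_with(np.ascontiguousarray(out))
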