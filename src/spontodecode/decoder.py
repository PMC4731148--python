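"""Spontaneous decoding: per-ms posteriors → discrete predicted events.

The per-millisecond class posteriors are smoothed with a σ = 80 ms Gaussian
(for well-behaved local maxima); predicted stimulus onsets are strict local
maxima of the face or house posterior exceeding 0.51, subject to a 320 ms
collision rule — no two predictions may be closer than 320 ms, and on
conflict the larger posterior wins (greedy acceptance in descending peak
order).  The peak marks the time at which the templates align with the
signal such that the implied response onset is the predicted stimulus time.
No event table is consumed: the decoder has no foreknowledge of stimulus
frequency, timing or content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .config import PipelineConfig
from .datatypes import CLASSES
from .lda import LdaModel, posterior
from .projection import FeatureSelection, project_continuous

_DEFAULT = PipelineConfig()


@dataclass
class PosteriorTrace:
    """Per-ms probabilities for face, house and the null class."""

    p_face: np.ndarray
    p_house: np.ndarray
    p_null: np.ndarray
    smoothing_sigma_ms: float = 0.0

    def trace(self, label: str) -> np.ndarray:
        return {"face": self.p_face, "house": self.p_house, "isi": self.p_null}[label]


@dataclass
class PredictedEvents:
    """Discrete predictions, sorted by time; pairwise spacing ≥ collision."""

    times_ms: np.ndarray
    classes: np.ndarray
    peak_posteriors: np.ndarray

    def __len__(self) -> int:
        return len(self.times_ms)


def smooth_posteriors(
    pt: PosteriorTrace, sigma_ms: float = 80.0
) -> PosteriorTrace:
    """Gaussian-smooth each class trace (kernel truncated at ±4σ and
    renormalized at the record edges, so unit kernel mass everywhere)."""
    if sigma_ms <= 0:
        return pt

    den = gaussian_filter1d(
        np.ones_like(pt.p_face), sigma_ms, mode="constant", truncate=4.0
    )

    def _smooth(p):
        num = gaussian_filter1d(p, sigma_ms, mode="constant", truncate=4.0)
        return num / den

    return PosteriorTrace(
        _smooth(pt.p_face), _smooth(pt.p_house), _smooth(pt.p_null), sigma_ms
    )


def _local_maxima(p: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; a flat plateau higher than both
    neighbors contributes its first sample.  Record boundaries are never
    maxima."""
    n = len(p)
    if n < 3:
        return np.empty(0, dtype=np.int64)
    cand = np.flatnonzero((p[1:-1] > p[:-2]) & (p[1:-1] >= p[2:])) + 1
    out = []
    for i in cand:
        if p[i] > p[i + 1]:
            out.append(i)
            continue
        j = i  # plateau: walk to its end and require a strict fall
        while j + 1 < n and p[j + 1] == p[i]:
            j += 1
        if j < n - 1 and p[j + 1] < p[i]:
            out.append(i)
    return np.asarray(out, dtype=np.int64)


def pick_events(
    pt: PosteriorTrace,
    threshold: float = 0.51,
    collision_ms: int = 320,
) -> PredictedEvents:
    """Apply the peak / threshold / collision rules to smoothed posteriors."""
    cands = []  # (peak value, time, class index)
    for ci, label in enumerate(CLASSES):
        p = pt.trace(label)
        for i in _local_maxima(p):
            if p[i] > threshold:
                cands.append((float(p[i]), int(i), ci))
    # descending peak value; ties resolved by time then face-before-house
    cands.sort(key=lambda c: (-c[0], c[1], c[2]))
    acc_t, acc_c, acc_p = [], [], []
    for val, t, ci in cands:
        if all(abs(t - u) >= collision_ms for u in acc_t):
            acc_t.append(t)
            acc_c.append(CLASSES[ci])
            acc_p.append(val)
    order = np.argsort(acc_t)
    return PredictedEvents(
        np.asarray(acc_t, dtype=np.int64)[order],
        np.asarray(acc_c, dtype=object)[order],
        np.asarray(acc_p)[order],
    )


def posteriors_from_projections(
    gamma: np.ndarray, model: LdaModel, cfg: PipelineConfig = _DEFAULT
) -> PosteriorTrace:
    """Per-ms 3-class posteriors from a (n_times, n_features) Γ matrix.

    Rows with undefined Γ (the first 199 ms / last 400 ms, NaN) are
    assigned to the null class.
    """
    n = gamma.shape[0]
    p = np.zeros((n, 3))
    p[:, 2] = 1.0
    valid = np.isfinite(gamma).all(axis=1)
    if valid.any():
        post = posterior(model, gamma[valid])
        for k, cls in enumerate(model.classes):
            col = {"face": 0, "house": 1, "isi": 2}[cls]
            p[np.flatnonzero(valid), col] = post[:, k]
        if "isi" not in model.classes:
            p[valid, 2] = 0.0
    return PosteriorTrace(p[:, 0], p[:, 1], p[:, 2])


def decode_stream(
    signals: dict,
    templates: list,
    selection: FeatureSelection,
    model: LdaModel,
    cfg: PipelineConfig = _DEFAULT,
) -> tuple:
    """End-to-end spontaneous decoding of one continuous record.

    ``signals`` maps feature kind to an (n_samples, n_channels) matrix for
    the record to decode.  Returns (PredictedEvents, smoothed
    PosteriorTrace).
    """
    if not templates or selection is None or model is None:
        raise ValueError("decode_stream requires templates, selection and a model")
    sel = [t for t, keep in zip(templates, selection.mask) if keep]
    if len(sel) != model.n_features:
        raise ValueError("selection does not match the model's feature count")
    n = next(iter(signals.values())).shape[0]
    gamma = np.empty((n, len(sel)))
    for j, tpl in enumerate(sel):
        gamma[:, j] = project_continuous(tpl, signals[tpl.feature_kind][:, tpl.channel], cfg)
    pt = posteriors_from_projections(gamma, model, cfg)
    pt = smooth_posteriors(pt, cfg.posterior_sigma_ms)
    events = pick_events(pt, cfg.peak_threshold, cfg.collision_ms)
    return events, pt
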