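"""Template projection: the scalar Γ features and the feature space.

A template is the stimulus-triggered average of a signal (raw potential or
broadband trace) on the peri-stimulus window t' ∈ −199..400 ms, re-centered
by its own mean over the baseline sub-window t' ∈ −199..50 ms.  Projecting
a template at a time τ is the inner product of the template with the
baseline-corrected signal window at τ:

    Γ(τ) = Σ_{t'} T(t') · (x(τ + t') − m(τ)),

where m(τ) is the instantaneous baseline — by default the *mean* of x over
τ−199..τ+50 (250 samples); ``baseline_as_sum`` uses the plain sum instead.
Γ computed at every millisecond of a continuous record is the forward
projection trace; Γ at known event times gives training/testing feature
points.  Features are down-selected by the squared point-biserial
correlation r² between each template's projections at its own class's
events and at inter-stimulus-interval (null) points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .config import PipelineConfig
from .datatypes import NULL_LABEL, EventTable

logger = logging.getLogger(__name__)

_DEFAULT = PipelineConfig()


@dataclass
class Template:
    """Per-channel, per-class, per-feature-kind averaged peri-stimulus response."""

    values: np.ndarray           # length 600, t' = -199..400 ms inclusive
    channel: int
    stimulus_class: str          # "face" | "house"
    feature_kind: str            # "potential" | "broadband"
    n_events: int = 0

    @property
    def feature_id(self) -> tuple:
        return (self.channel, self.stimulus_class, self.feature_kind)


@dataclass
class FeatureMatrix:
    """Γ values, one row per event/null point, one column per template feature."""

    points: np.ndarray           # (n_points, n_features)
    labels: np.ndarray           # "face" | "house" | "isi"
    event_times: np.ndarray
    feature_ids: list = field(default_factory=list)

    def select(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.points[:, mask],
            self.labels,
            self.event_times,
            [f for f, m in zip(self.feature_ids, mask) if m],
        )


@dataclass
class FeatureSelection:
    r2: np.ndarray
    mask: np.ndarray
    threshold: float


def build_template(
    signal: np.ndarray,
    events: EventTable,
    stimulus_class: str,
    channel: int = 0,
    feature_kind: str = "potential",
    cfg: PipelineConfig = _DEFAULT,
) -> Template:
    """Stimulus-triggered average on −199..400 ms, re-centered by its mean
    over the −199..50 ms baseline sub-window.

    Events whose window does not fit inside the record are skipped with a
    warning; zero usable events is an error.
    """
    signal = np.asarray(signal, dtype=np.float64)
    onsets = events.for_class(stimulus_class).onset_ms
    lo, hi = cfg.template_start_ms, cfg.template_end_ms
    acc = np.zeros(cfg.template_len)
    used = 0
    for tau in onsets:
        if tau + lo < 0 or tau + hi >= len(signal):
            logger.warning("event at %d ms: window out of range, skipped", tau)
            continue
        acc += signal[tau + lo: tau + hi + 1]
        used += 1
    if used == 0:
        raise ValueError(f"no usable {stimulus_class!r} events for template")
    acc /= used
    n_base = cfg.baseline_len
    acc -= acc[:n_base].mean()
    return Template(acc, channel, stimulus_class, feature_kind, n_events=used)


def _baseline(signal: np.ndarray, tau: int, cfg: PipelineConfig) -> float:
    seg = signal[tau + cfg.baseline_start_ms: tau + cfg.baseline_end_ms + 1]
    return seg.sum() if cfg.baseline_as_sum else seg.mean()


def project_at_event(
    template: Template,
    signal: np.ndarray,
    event_time: int,
    cfg: PipelineConfig = _DEFAULT,
) -> float:
    """Γ for one template at one time (the definitional form)."""
    signal = np.asarray(signal, dtype=np.float64)
    tau = int(event_time)
    lo, hi = cfg.template_start_ms, cfg.template_end_ms
    if tau + lo < 0 or tau + hi >= len(signal):
        raise ValueError(f"projection window out of range at t={tau}")
    w = signal[tau + lo: tau + hi + 1]
    return float(np.dot(template.values, w - _baseline(signal, tau, cfg)))


def valid_projection_bounds(n_samples: int, cfg: PipelineConfig = _DEFAULT) -> tuple:
    """Inclusive [first, last] time at which the full Γ window fits."""
    return (-cfg.template_start_ms, n_samples - 1 - cfg.template_end_ms)


def project_continuous(
    template: Template,
    signal: np.ndarray,
    cfg: PipelineConfig = _DEFAULT,
) -> np.ndarray:
    """Γ(t) at every millisecond, computed by FFT correlation plus a sliding
    baseline correction term; equals :func:`project_at_event` at every valid
    t.  Positions where the window does not fit are NaN."""
    signal = np.asarray(signal, dtype=np.float64)
    n = len(signal)
    lo, hi = cfg.template_start_ms, cfg.template_end_ms
    first, last = valid_projection_bounds(n, cfg)
    if last < first:
        raise ValueError("record shorter than the template window")
    T = template.values
    # cross-correlation: C(tau) = sum_i T[i] * x[tau + lo + i]
    y = fftconvolve(signal, T[::-1], mode="full")
    corr = y[hi: hi + n]  # corr[tau] = C(tau), valid for tau in [first, last]
    # sliding baseline over tau-199 .. tau+50
    cs = np.concatenate(([0.0], np.cumsum(signal)))
    out = np.full(n, np.nan)
    taus = np.arange(first, last + 1)
    base = cs[taus + cfg.baseline_end_ms + 1] - cs[taus + cfg.baseline_start_ms]
    if not cfg.baseline_as_sum:
        base /= cfg.baseline_len
    out[taus] = corr[taus] - T.sum() * base
    return out


def sample_isi_points(
    events: EventTable,
    n_per_isi: int = 4,
    display_ms: int = 400,
    isi_ms: int = 400,
    margin_ms: int = 100,
    min_gap_ms: int = 50,
    rng: np.random.Generator | None = None,
    seed: int | None = 0,
) -> np.ndarray:
    """Random null-class times, ``n_per_isi`` in the blank interval after
    each stimulus, at least ``margin_ms`` from stimulus offset and from the
    next onset, and ``min_gap_ms`` from one another."""
    if rng is None:
        rng = np.random.default_rng(seed)
    span = isi_ms - 2 * margin_ms  # usable window length within each ISI
    k = n_per_isi
    need = (k - 1) * min_gap_ms
    if span < 0 or (k > 1 and need > span):
        k = max(1, span // min_gap_ms + 1) if span >= 0 else 0
        logger.warning(
            "ISI constraints infeasible for %d points; sampling %d instead", n_per_isi, k
        )
    times = []
    for onset in events.onset_ms:
        start = int(onset) + display_ms + margin_ms
        if k <= 0:
            continue
        slack = span - (k - 1) * min_gap_ms
        u = np.sort(rng.integers(0, slack + 1, size=k))
        times.extend(start + u + np.arange(k) * min_gap_ms)
    return np.asarray(times, dtype=np.int64)


def r2_score(points_class: np.ndarray, points_isi: np.ndarray) -> float:
    """Squared cross-correlation between a class's projections and null
    projections:  r² = (mean_F − mean_o)² · N_F·N_o / N_Fo² / σ²_joint,
    with σ_joint the (population) standard deviation of the pooled sample.
    Equals the squared point-biserial correlation of (group, value)."""
    a = np.asarray(points_class, dtype=np.float64)
    b = np.asarray(points_isi, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    var = pooled.var()  # ddof=0
    if var == 0.0:
        logger.warning("zero pooled variance: r2 defined as 0")
        return 0.0
    return float((a.mean() - b.mean()) ** 2 * n_a * n_b / (n_a + n_b) ** 2 / var)


def build_feature_matrix(
    templates: list,
    signals: dict,
    times: np.ndarray,
    labels: np.ndarray,
    cfg: PipelineConfig = _DEFAULT,
) -> FeatureMatrix:
    """Project every template at every given time.

    ``signals`` maps feature kind ("potential"/"broadband") to an
    (n_samples, n_channels) matrix.
    """
    times = np.asarray(times, dtype=np.int64)
    lo, hi = cfg.template_start_ms, cfg.template_end_ms
    pts = np.empty((len(times), len(templates)))
    win_idx = times[:, None] + np.arange(lo, hi + 1)
    base_idx = times[:, None] + np.arange(cfg.baseline_start_ms, cfg.baseline_end_ms + 1)
    for j, tpl in enumerate(templates):
        sig = np.asarray(signals[tpl.feature_kind][:, tpl.channel], dtype=np.float64)
        if times.size and (times.min() + lo < 0 or times.max() + hi >= len(sig)):
            raise ValueError("projection window out of range")
        base = sig[base_idx].sum(axis=1)
        if not cfg.baseline_as_sum:
            base /= cfg.baseline_len
        pts[:, j] = sig[win_idx] @ tpl.values - tpl.values.sum() * base
    return FeatureMatrix(pts, np.asarray(labels, dtype=object), times,
                         [t.feature_id for t in templates])


def select_features(
    fm: FeatureMatrix, threshold: float = 0.05
) -> FeatureSelection:
    """Keep feature m iff its class-vs-ISI r² exceeds the threshold.

    Each template feature is scored between projections at events of the
    template's own class and projections at null (ISI) points, on training
    data only.
    """
    isi_rows = fm.labels == NULL_LABEL
    if not isi_rows.any():
        raise ValueError("feature selection requires ISI (null) training points")
    r2 = np.empty(fm.points.shape[1])
    for j, (ch, cls, kind) in enumerate(fm.feature_ids):
        cls_rows = fm.labels == cls
        r2[j] = r2_score(fm.points[cls_rows, j], fm.points[isi_rows, j])
    mask = r2 > threshold
    if not mask.any():
        raise ValueError(
            f"no feature exceeds r2 threshold {threshold}; lower the threshold"
        )
    return FeatureSelection(r2=r2, mask=mask, threshold=threshold)
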