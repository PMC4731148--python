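"""Pipeline configuration: every tunable of the decoder in one place.

Defaults are the published analysis constants: template window −199..400 ms,
baseline window −199..50 ms, r² feature threshold 0.05, posterior smoothing
σ = 80 ms, peak threshold 0.51, collision time 320 ms, correctness window
160 ms, 4 ISI points per interval with 100/50 ms margins, 58–62 Hz 3rd-order
Butterworth notch, 3 temporal folds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PipelineConfig:
    # peri-stimulus window, inclusive sample bounds (600 samples)
    template_start_ms: int = -199
    template_end_ms: int = 400
    # baseline window, inclusive sample bounds (250 samples)
    baseline_start_ms: int = -199
    baseline_end_ms: int = 50
    baseline_as_sum: bool = False  # literal printed formula (sum) vs prose (mean)

    # feature selection
    r2_threshold: float = 0.05

    # ISI null-point sampling
    isi_points_per_interval: int = 4
    isi_margin_ms: int = 100     # from stimulus offset / next onset
    isi_min_gap_ms: int = 50     # pairwise

    # spectral decoupling / broadband extraction
    wavelet_cycles: float = 7.0
    freq_lo_hz: float = 4.0
    freq_hi_hz: float = 200.0
    freq_step_hz: float = 1.0
    excluded_bands_hz: tuple = ((58.0, 62.0), (118.0, 122.0), (178.0, 182.0))
    broadband_sigma_ms: float = 25.0

    # preprocessing
    notch_lo_hz: float = 58.0
    notch_hi_hz: float = 62.0
    notch_order: int = 3
    zero_phase: bool = True

    # classifier
    lda_ridge: float = 1e-6
    empirical_priors: bool = False

    # spontaneous decoding rules
    posterior_sigma_ms: float = 80.0
    peak_threshold: float = 0.51
    collision_ms: int = 320
    correctness_window_ms: int = 160

    # evaluation
    n_folds: int = 3
    feature_set: str = "both"  # erp | erbb | both

    def __post_init__(self) -> None:
        if not (self.template_start_ms < self.baseline_end_ms < self.template_end_ms):
            raise ValueError("windows ill-ordered")
        if self.baseline_start_ms != self.template_start_ms:
            raise ValueError("baseline window must start with the template window")
        if not 0.0 <= self.peak_threshold <= 1.0:
            raise ValueError("peak_threshold must lie in [0, 1]")
        if self.r2_threshold < 0:
            raise ValueError("r2_threshold must be >= 0")
        if self.collision_ms < 0 or self.correctness_window_ms < 0:
            raise ValueError("time rules must be non-negative")
        if self.feature_set not in ("erp", "erbb", "both"):
            raise ValueError("feature_set must be erp|erbb|both")

    # window lengths implied by the inclusive bounds
    @property
    def template_len(self) -> int:
        return self.template_end_ms - self.template_start_ms + 1

    @property
    def baseline_len(self) -> int:
        return self.baseline_end_ms - self.baseline_start_ms + 1

    @property
    def feature_kinds(self) -> tuple:
        return {"erp": ("potential",), "erbb": ("broadband",),
                "both": ("potential", "broadband")}[self.feature_set]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["excluded_bands_hz"] = [list(b) for b in self.excluded_bands_hz]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "excluded_bands_hz" in d:
            d["excluded_bands_hz"] = tuple(tuple(b) for b in d["excluded_bands_hz"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
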