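"""End-to-end pipeline: preprocess → broadband → leave-one-run-out CV →
spontaneous decoding → scoring.

Cross-validation divides the data temporally into runs; per fold the
templates, feature selection and LDA are fitted on two runs and the
held-out run is decoded.  The spectral decoupling that produces B(t) is
fitted once across all data (it is ignorant of class labels and timepoint
selection), mirroring the training/testing split of the original analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .broadband import broadband_for_recording
from .config import PipelineConfig
from .datatypes import CLASSES, NULL_LABEL, ContinuousRecording, EventTable
from .decoder import PosteriorTrace, PredictedEvents, decode_stream, pick_events
from .evaluate import EvaluationReport, score_predictions
from .lda import classify_known_onsets, fit_lda
from .preprocess import common_average_reference, notch_60hz
from .projection import (
    FeatureMatrix,
    build_feature_matrix,
    build_template,
    sample_isi_points,
    select_features,
)
from .synthetic import TaskSchedule, preset_dataset

logger = logging.getLogger(__name__)


@dataclass
class PreparedData:
    """Preprocessed signals plus events, ready for cross-validation."""

    signals: dict                  # kind -> (n_samples, n_channels)
    events: EventTable
    recording: ContinuousRecording
    run_bounds: dict               # run id -> (start_sample, end_sample)
    display_ms: int = 400
    isi_ms: int = 400


@dataclass
class FoldModel:
    templates: list
    selection: object
    model3: object                 # face/house/null
    model2: object                 # face/house


@dataclass
class FoldResult:
    test_run: int
    report: EvaluationReport
    known_onset_accuracy: float
    predicted: PredictedEvents
    posteriors: PosteriorTrace
    offset_ms: int
    n_features_selected: int


@dataclass
class CvResult:
    folds: list
    pooled: EvaluationReport
    known_onset_accuracy: float

    def fold_for_run(self, run: int) -> FoldResult:
        return next(f for f in self.folds if f.test_run == run)


def prepare_dataset(
    recording: ContinuousRecording,
    events: EventTable,
    cfg: PipelineConfig | None = None,
    schedule: TaskSchedule | None = None,
    broadband: np.ndarray | None = None,
) -> PreparedData:
    """Re-reference, notch, and extract the broadband trace.

    A precomputed broadband matrix may be supplied (e.g. read from file) to
    skip the spectral decomposition.
    """
    cfg = cfg or PipelineConfig()
    rec = common_average_reference(recording)
    rec = notch_60hz(rec, cfg.notch_lo_hz, cfg.notch_hi_hz, cfg.notch_order,
                     cfg.zero_phase)
    signals = {"potential": rec.potentials}
    if broadband is not None:
        signals["broadband"] = broadband
    elif "broadband" in cfg.feature_kinds:
        signals["broadband"] = broadband_for_recording(rec, cfg)

    bounds = {}
    if schedule is not None:
        for r in events.runs:
            bounds[int(r)] = (int(r) * schedule.run_duration_ms,
                              (int(r) + 1) * schedule.run_duration_ms)
        display, isi = schedule.display_ms, schedule.isi_ms
    else:
        for r in events.runs:
            ev = events.for_runs(r)
            bounds[int(r)] = (max(0, int(ev.onset_ms.min()) - 800),
                              min(rec.n_samples, int(ev.onset_ms.max()) + 1400))
        display, isi = 400, 400
    return PreparedData(signals, events, rec, bounds, display, isi)


def train_fold(
    prep: PreparedData,
    train_runs,
    cfg: PipelineConfig,
    seed: int = 0,
) -> FoldModel:
    """Templates + r² selection + LDA, fitted on the training runs only."""
    train_events = prep.events.for_runs(train_runs)
    templates = []
    good = prep.recording.good_channels
    for kind in cfg.feature_kinds:
        sig = prep.signals[kind]
        for cls in CLASSES:
            for ch in good:
                templates.append(
                    build_template(sig[:, ch], train_events, cls, int(ch), kind, cfg)
                )

    isi_times = sample_isi_points(
        train_events,
        cfg.isi_points_per_interval,
        prep.display_ms,
        prep.isi_ms,
        cfg.isi_margin_ms,
        cfg.isi_min_gap_ms,
        seed=seed,
    )
    times = np.concatenate([train_events.onset_ms, isi_times])
    labels = np.concatenate(
        [train_events.labels, np.full(len(isi_times), NULL_LABEL, dtype=object)]
    )
    fm = build_feature_matrix(templates, prep.signals, times, labels, cfg)
    selection = select_features(fm, cfg.r2_threshold)
    fm_sel = fm.select(selection.mask)
    model3 = fit_lda(fm_sel, ["face", "house", NULL_LABEL],
                     cfg.lda_ridge, cfg.empirical_priors)
    fh = np.isin(fm_sel.labels, CLASSES)
    fm_fh = FeatureMatrix(fm_sel.points[fh], fm_sel.labels[fh],
                          fm_sel.event_times[fh], fm_sel.feature_ids)
    model2 = fit_lda(fm_fh, ["face", "house"], cfg.lda_ridge, cfg.empirical_priors)
    return FoldModel(templates, selection, model3, model2)


def decode_fold(
    prep: PreparedData, fold: FoldModel, test_run: int, cfg: PipelineConfig
) -> FoldResult:
    """Spontaneously decode the held-out run and score it."""
    lo, hi = prep.run_bounds[int(test_run)]
    signals = {k: v[lo:hi] for k, v in prep.signals.items()}
    predicted, pt = decode_stream(signals, fold.templates, fold.selection,
                                  fold.model3, cfg)
    predicted = PredictedEvents(predicted.times_ms + lo, predicted.classes,
                                predicted.peak_posteriors)
    test_events = prep.events.for_runs(test_run)
    report = score_predictions(predicted, test_events, cfg.correctness_window_ms)

    sel_templates = [t for t, m in zip(fold.templates, fold.selection.mask) if m]
    fm_test = build_feature_matrix(sel_templates, prep.signals,
                                   test_events.onset_ms, test_events.labels, cfg)
    pred_cls = classify_known_onsets(fold.model2, fm_test)
    acc = float(np.mean(pred_cls == test_events.labels))
    return FoldResult(int(test_run), report, acc, predicted, pt, lo,
                      int(fold.selection.mask.sum()))


def _pool(folds: list) -> EvaluationReport:
    n_events = sum(f.report.n_events for f in folds)
    n_pred = sum(f.report.n_predictions for f in folds)
    n_correct = sum(f.report.n_correct for f in folds)
    errs = [(f.report.mean_timing_error_ms, f.report.n_correct)
            for f in folds if f.report.mean_timing_error_ms is not None]
    err = (sum(e * w for e, w in errs) / sum(w for _, w in errs)) if errs else None
    per_class = {}
    for cls in CLASSES:
        n_ev = sum(f.report.per_class[cls]["n_events"] for f in folds)
        n_cap = sum(f.report.per_class[cls]["n_captured"] for f in folds)
        per_class[cls] = {"n_events": n_ev, "n_captured": n_cap,
                          "fraction_captured": n_cap / n_ev if n_ev else None}
    return EvaluationReport(
        fraction_captured=n_correct / n_events if n_events else 0.0,
        mean_timing_error_ms=err,
        false_positive_rate=(n_pred - n_correct) / n_pred if n_pred else None,
        n_events=n_events,
        n_predictions=n_pred,
        n_correct=n_correct,
        per_class=per_class,
    )


def crossvalidate(
    prep: PreparedData, cfg: PipelineConfig | None = None, seed: int = 0
) -> CvResult:
    """Leave-one-run-out cross-validation of the full decoder."""
    cfg = cfg or PipelineConfig()
    runs = prep.events.runs
    if len(runs) < 2:
        raise ValueError("cross-validation requires at least 2 runs")
    folds = []
    for i, test_run in enumerate(runs):
        train_runs = [r for r in runs if r != test_run]
        fold = train_fold(prep, train_runs, cfg, seed=seed * 1000 + i)
        folds.append(decode_fold(prep, fold, int(test_run), cfg))
    pooled = _pool(folds)
    acc = float(np.mean([f.known_onset_accuracy for f in folds]))
    return CvResult(folds, pooled, acc)


def collision_sweep(
    cv: CvResult,
    prep: PreparedData,
    collision_times,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Re-pick events from the stored posteriors at each collision time.

    Returns, per collision time, the pooled counts of false and correct
    predictions — the sweep used to check that the collision rule does not
    inform the decoder about stimulus timing.
    """
    cfg = cfg or PipelineConfig()
    out = {"collision_ms": list(collision_times), "n_false": [], "n_correct": []}
    for ct in collision_times:
        n_false = n_correct = 0
        for f in cv.folds:
            pred = pick_events(f.posteriors, cfg.peak_threshold, int(ct))
            pred = PredictedEvents(pred.times_ms + f.offset_ms, pred.classes,
                                   pred.peak_posteriors)
            rep = score_predictions(pred, prep.events.for_runs(f.test_run),
                                    cfg.correctness_window_ms)
            n_false += rep.n_predictions - rep.n_correct
            n_correct += rep.n_correct
        out["n_false"].append(n_false)
        out["n_correct"].append(n_correct)
    return out


def run_pipeline(
    cfg: PipelineConfig | None = None,
    preset: str | None = "high-snr",
    seed: int = 1,
    dataset=None,
) -> dict:
    """Simulate (or accept) a dataset, run the full CV decode, and report.

    Returns a JSON-serializable report with per-fold and pooled metrics.
    """
    cfg = cfg or PipelineConfig()
    if dataset is None:
        if preset is None:
            raise ValueError("either a dataset or a preset is required")
        dataset = preset_dataset(preset, seed=seed)
    prep = prepare_dataset(dataset.recording, dataset.events, cfg,
                           schedule=dataset.schedule)
    cv = crossvalidate(prep, cfg, seed=seed)
    report = {
        "config_hash": cfg.config_hash(),
        "feature_set": cfg.feature_set,
        "seed": seed,
        "preset": preset,
        "n_events": cv.pooled.n_events,
        "n_predictions": cv.pooled.n_predictions,
        "fraction_captured": cv.pooled.fraction_captured,
        "mean_timing_error_ms": cv.pooled.mean_timing_error_ms,
        "false_positive_rate": cv.pooled.false_positive_rate,
        "known_onset_accuracy": cv.known_onset_accuracy,
        "per_class": cv.pooled.per_class,
        "folds": [
            {
                "test_run": f.test_run,
                "fraction_captured": f.report.fraction_captured,
                "mean_timing_error_ms": f.report.mean_timing_error_ms,
                "false_positive_rate": f.report.false_positive_rate,
                "known_onset_accuracy": f.known_onset_accuracy,
                "n_features_selected": f.n_features_selected,
            }
            for f in cv.folds
        ],
    }
    return report
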