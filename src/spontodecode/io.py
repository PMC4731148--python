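"""File formats: HDF5 recordings, TSV event/prediction tables, model bundles.

The recording layout is a single HDF5 file with a ``potentials`` dataset
(samples × channels), attributes ``sampling_rate_hz`` and ``channel_labels``,
an optional ``bad_channel_mask`` dataset and an optional ``broadband``
dataset of the same shape as ``potentials``.  Event tables are tab-separated
with columns ``onset_ms`` (0-based sample index at 1 kHz), ``class`` and
``run``; prediction tables carry ``time_ms``, ``class``, ``peak_posterior``.
"""

from __future__ import annotations

import logging

import h5py
import numpy as np
import pandas as pd

from .datatypes import CLASSES, ContinuousRecording, EventTable
from .decoder import PredictedEvents

logger = logging.getLogger(__name__)

#: label used by the task for the rare attention-target stimulus; such rows
#: are excluded from every analysis
TARGET_LABEL = "target"


def write_recording(path, rec: ContinuousRecording, broadband: np.ndarray | None = None) -> None:
    with h5py.File(path, "w") as fh:
        d = fh.create_dataset("potentials", data=rec.potentials)
        d.attrs["units"] = "uV"
        fh.attrs["sampling_rate_hz"] = rec.sampling_rate_hz
        fh.attrs["channel_labels"] = [str(c) for c in rec.channel_labels]
        fh.create_dataset("bad_channel_mask", data=rec.bad_channel_mask)
        if broadband is not None:
            fh.create_dataset("broadband", data=broadband)


def read_recording(path, with_broadband: bool = False):
    with h5py.File(path, "r") as fh:
        if "sampling_rate_hz" not in fh.attrs:
            raise ValueError(f"{path}: missing sampling_rate_hz attribute")
        rate = float(fh.attrs["sampling_rate_hz"])
        if rate != 1000.0:
            raise ValueError(f"unsupported sampling rate {rate} Hz (expected 1000)")
        pot = fh["potentials"][()]
        if "channel_labels" in fh.attrs:
            labels = [str(c) for c in fh.attrs["channel_labels"]]
        else:
            labels = [f"ch{i:02d}" for i in range(pot.shape[1])]
            logger.warning("%s: missing channel labels, auto-labelling", path)
        mask = fh["bad_channel_mask"][()] if "bad_channel_mask" in fh else None
        rec = ContinuousRecording(pot, rate, labels, mask)
        if with_broadband:
            bb = fh["broadband"][()] if "broadband" in fh else None
            return rec, bb
    return rec


def write_events(path, events: EventTable) -> None:
    events.to_frame().to_csv(path, sep="\t", index=False)


def read_events(path) -> EventTable:
    df = pd.read_csv(path, sep="\t")
    for col in ("onset_ms", "class", "run"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    targets = df["class"] == TARGET_LABEL
    if targets.any():
        logger.info("%s: dropped %d target rows", path, int(targets.sum()))
        df = df[~targets]
    bad = set(df["class"].unique()) - set(CLASSES)
    if bad:
        raise ValueError(f"{path}: unknown stimulus classes {sorted(bad)}")
    return EventTable.from_frame(df.reset_index(drop=True))


def write_predictions(path, pred: PredictedEvents) -> None:
    pd.DataFrame(
        {"time_ms": pred.times_ms, "class": pred.classes,
         "peak_posterior": pred.peak_posteriors}
    ).to_csv(path, sep="\t", index=False)


def read_predictions(path) -> PredictedEvents:
    df = pd.read_csv(path, sep="\t")
    return PredictedEvents(
        df["time_ms"].to_numpy(np.int64),
        df["class"].to_numpy(object),
        df["peak_posterior"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# decoder bundle (templates + selection + LDA models) for the train/decode CLI


def write_model(path, fold_model) -> None:
    from .lda import LdaModel  # noqa: F401  (documented layout)

    with h5py.File(path, "w") as fh:
        tg = fh.create_group("templates")
        for i, t in enumerate(fold_model.templates):
            g = tg.create_group(f"t{i:03d}")
            g.create_dataset("values", data=t.values)
            g.attrs["channel"] = t.channel
            g.attrs["stimulus_class"] = t.stimulus_class
            g.attrs["feature_kind"] = t.feature_kind
            g.attrs["n_events"] = t.n_events
        sg = fh.create_group("selection")
        sg.create_dataset("r2", data=fold_model.selection.r2)
        sg.create_dataset("mask", data=fold_model.selection.mask)
        sg.attrs["threshold"] = fold_model.selection.threshold
        for name, model in (("lda3", fold_model.model3), ("lda2", fold_model.model2)):
            mg = fh.create_group(name)
            mg.attrs["classes"] = model.classes
            mg.create_dataset("means", data=model.means)
            mg.create_dataset("pooled_covariance", data=model.pooled_covariance)
            mg.create_dataset("priors", data=model.priors)
            mg.create_dataset("coef", data=model.coef)
            mg.create_dataset("intercept", data=model.intercept)


def read_model(path):
    from .lda import LdaModel
    from .pipeline import FoldModel
    from .projection import FeatureSelection, Template

    with h5py.File(path, "r") as fh:
        templates = []
        for key in sorted(fh["templates"]):
            g = fh["templates"][key]
            templates.append(
                Template(
                    g["values"][()],
                    int(g.attrs["channel"]),
                    str(g.attrs["stimulus_class"]),
                    str(g.attrs["feature_kind"]),
                    int(g.attrs["n_events"]),
                )
            )
        sg = fh["selection"]
        selection = FeatureSelection(
            sg["r2"][()], sg["mask"][()].astype(bool), float(sg.attrs["threshold"])
        )
        models = {}
        for name in ("lda3", "lda2"):
            mg = fh[name]
            models[name] = LdaModel(
                [str(c) for c in mg.attrs["classes"]],
                mg["means"][()],
                mg["pooled_covariance"][()],
                mg["priors"][()],
                mg["coef"][()],
                mg["intercept"][()],
            )
    return FoldModel(templates, selection, models["lda3"], models["lda2"])
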