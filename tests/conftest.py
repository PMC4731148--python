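"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from spontodecode.config import PipelineConfig
from spontodecode.pipeline import prepare_dataset
from spontodecode.synthetic import preset_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """3 runs x (5 faces + 5 houses), 3 channels (face / house / null)."""
    return preset_dataset("tiny", seed=11)


@pytest.fixture(scope="session")
def tiny_prepared(tiny_dataset):
    """Tiny dataset after re-referencing, notch and broadband extraction."""
    cfg = PipelineConfig()
    return prepare_dataset(
        tiny_dataset.recording, tiny_dataset.events, cfg, schedule=tiny_dataset.schedule
    )


@pytest.fixture(scope="session")
def highsnr_prepared():
    """Seed-1 high-SNR dataset (8 channels, 300 events) after preprocessing
    and broadband extraction; shared by the decoder and acceptance tests."""
    ds = preset_dataset("high-snr", seed=1)
    return prepare_dataset(
        ds.recording, ds.events, PipelineConfig(), schedule=ds.schedule
    )


@pytest.fixture(scope="session")
def highsnr_fold(highsnr_prepared):
    """A decoder trained on runs 1-2 of the seed-1 high-SNR dataset."""
    from spontodecode.pipeline import train_fold

    return train_fold(highsnr_prepared, [1, 2], PipelineConfig(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
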