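import numpy as np
import pytest

from eegproto.preprocess import preprocess_session
from eegproto.records import CHANNELS, SessionRecord
from eegproto.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_config() -> SynthConfig:
    """Small dataset: 5 subjects, 10 s sessions, moderate class effect."""
    return SynthConfig(n_subjects=5, duration_s=10.0, class_effect=0.5,
                       subject_sd=0.1, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    records, manifest, gt = generate_dataset(tiny_config)
    return records, manifest, gt


@pytest.fixture(scope="session")
def tiny_preprocessed(tiny_dataset):
    records, _, _ = tiny_dataset
    return [preprocess_session(r) for r in records]


@pytest.fixture(scope="session")
def default_session() -> SessionRecord:
    """One 75 s, 128 Hz session (the canonical geometry)."""
    cfg = SynthConfig(n_subjects=1, duration_s=75.0, seed=3)
    records, _, _ = generate_dataset(cfg)
    return records[0]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_record(samples: np.ndarray, fs: float = 128.0, label: int = 0,
                subject: str = "S01", session: str = "S01_lie") -> SessionRecord:
    return SessionRecord(subject_id=subject, session_id=session, label=label,
                         fs=fs, channel_names=CHANNELS, samples=samples)
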