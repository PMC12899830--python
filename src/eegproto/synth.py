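"""Synthetic five-channel EEG datasets with known ground truth.

The generator mimics the structure of the wearable recordings used by the
downstream pipelines: 128 Hz, five channels, ~75 s sessions, one LIE and one
TRUTH session per subject, 1/f background plus band-limited oscillations,
50 Hz mains contamination, and sparse high-amplitude transients. A tunable
class effect shifts delta/theta power toward LIE sessions and beta/gamma
power toward TRUTH sessions; subject-specific log-normal band gains create
the between-subject heterogeneity that separates subject-dependent from
cross-subject generalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .records import CHANNELS, LIE, TRUTH, LABEL_NAMES, ConfigurationError, SessionRecord

#: Canonical band edges (Hz) used both here and by the feature extractors.
CANONICAL_BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, 45.0),
)

#: Fraction of the class effect applied as a multiplicative band-gain shift.
CLASS_EFFECT_SCALE = 0.3

#: Bands boosted for LIE sessions (and attenuated for TRUTH), and vice versa.
_LIE_BANDS = ("delta", "theta")
_TRUTH_BANDS = ("beta", "gamma")


@dataclass
class SynthConfig:
    n_subjects: int = 27
    sessions_per_subject: int = 2
    duration_s: float = 75.0
    fs: float = 128.0
    channel_names: tuple[str, ...] = CHANNELS
    band_gains: dict = field(
        default_factory=lambda: {
            "delta": 8.0, "theta": 4.0, "alpha": 3.0, "beta": 2.0, "gamma": 1.0,
        }
    )
    class_effect: float = 0.0
    subject_sd: float = 0.25
    mains_amp: float = 2.0
    artifact_rate: float = 0.2
    artifact_amp_mult: float = 8.0
    background_amp: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ConfigurationError("duration_s and fs must be positive")
        if round(self.duration_s * self.fs) < 1:
            raise ConfigurationError("session must contain at least one sample")
        if not 0.0 <= self.class_effect <= 1.0:
            raise ConfigurationError("class_effect must lie in [0, 1]")
        if self.sessions_per_subject != 2:
            raise ConfigurationError("exactly one LIE and one TRUTH session per subject")


@dataclass
class GroundTruth:
    """Per-subject band gains and per-session artifact event times."""

    subject_band_gains: dict
    artifact_times: dict
    labels: dict


def _band_sos(lo: float, hi: float, fs: float):
    return signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz] / freqs[nz][0])
    out = np.fft.irfft(spec * scale, n=n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _class_gain(band: str, label: int, class_effect: float) -> float:
    shift = CLASS_EFFECT_SCALE * class_effect
    if band in _LIE_BANDS:
        return 1.0 + shift if label == LIE else 1.0 - shift
    if band in _TRUTH_BANDS:
        return 1.0 + shift if label == TRUTH else 1.0 - shift
    return 1.0


def subject_band_gains(config: SynthConfig, rng: np.random.Generator) -> dict:
    """Log-normal per-subject, per-band gain multipliers."""
    return {
        name: float(np.exp(rng.normal(0.0, config.subject_sd)))
        for name, _, _ in CANONICAL_BANDS
    }


def generate_session(
    config: SynthConfig,
    subject_id: str,
    label: int,
    rng: np.random.Generator,
    subject_gains: dict | None = None,
) -> tuple[SessionRecord, dict]:
    """Generate one session; returns the record and its artifact event times."""
    config.validate()
    if label not in (LIE, TRUTH):
        raise ConfigurationError(f"invalid label {label}")
    if subject_gains is None:
        subject_gains = subject_band_gains(config, rng)

    n = int(round(config.duration_s * config.fs))
    n_ch = len(config.channel_names)
    t = np.arange(n) / config.fs
    x = np.zeros((n, n_ch))

    for ch in range(n_ch):
        x[:, ch] += config.background_amp * _pink_noise(rng, n)

    for name, lo, hi in CANONICAL_BANDS:
        sos = _band_sos(lo, hi, config.fs)
        gain = (
            config.band_gains[name]
            * subject_gains[name]
            * _class_gain(name, label, config.class_effect)
        )
        for ch in range(n_ch):
            comp = signal.sosfiltfilt(sos, rng.standard_normal(n))
            sd = comp.std()
            if sd > 0:
                comp /= sd
            x[:, ch] += gain * comp

    phase = rng.uniform(0, 2 * np.pi)
    x += config.mains_amp * np.sin(2 * np.pi * 50.0 * t + phase)[:, None]

    # Sparse one-sided exponential transients (tau = 50 ms), Poisson arrivals.
    n_events = rng.poisson(config.artifact_rate * config.duration_s)
    event_times = np.sort(rng.uniform(0.0, config.duration_s, size=n_events))
    tau = 0.05
    for t0 in event_times:
        i0 = int(t0 * config.fs)
        length = min(n - i0, int(round(6 * tau * config.fs)))
        if length <= 0:
            continue
        shape = np.exp(-np.arange(length) / (tau * config.fs))
        ch = rng.integers(n_ch)
        amp = config.artifact_amp_mult * x[:, ch].std() * rng.choice([-1.0, 1.0])
        x[i0 : i0 + length, ch] += amp * shape

    record = SessionRecord(
        subject_id=subject_id,
        session_id=f"{subject_id}_{LABEL_NAMES[label].lower()}",
        label=label,
        fs=config.fs,
        channel_names=tuple(config.channel_names),
        samples=x,
    )
    return record, {"event_times": event_times}


def generate_dataset(config: SynthConfig) -> tuple[list[SessionRecord], pd.DataFrame, GroundTruth]:
    """Generate the full dataset plus a manifest table and the ground truth.

    The RNG stream is split hierarchically (dataset -> subject -> session) so
    that increasing ``n_subjects`` never perturbs earlier subjects.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    records: list[SessionRecord] = []
    gains: dict = {}
    artifacts: dict = {}
    labels: dict = {}
    rows = []
    for s, subject_seq in enumerate(root.spawn(config.n_subjects)):
        subject_id = f"S{s + 1:02d}"
        gain_seq, lie_seq, truth_seq = subject_seq.spawn(3)
        subj_gains = subject_band_gains(config, np.random.default_rng(gain_seq))
        gains[subject_id] = subj_gains
        for label, seq in ((LIE, lie_seq), (TRUTH, truth_seq)):
            rec, gt = generate_session(
                config, subject_id, label, np.random.default_rng(seq), subj_gains
            )
            records.append(rec)
            artifacts[rec.session_id] = gt["event_times"]
            labels[rec.session_id] = label
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "session_id": rec.session_id,
                    "label": rec.label,
                    "file": f"{rec.session_id}.csv",
                }
            )
    manifest = pd.DataFrame(rows, columns=["subject_id", "session_id", "label", "file"])
    return records, manifest, GroundTruth(gains, artifacts, labels)
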