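"""Core record types shared across the pipeline.

A *session* is one continuous recording carrying a single binary label
(0 = LIE, 1 = TRUTH); a *window* is a fixed-length segment cut from a
session and inherits the session's label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical channel order for the five-channel montage.
CHANNELS: tuple[str, ...] = ("AF3", "T7", "Pz", "T8", "AF4")

LIE: int = 0
TRUTH: int = 1
LABEL_NAMES: dict[int, str] = {LIE: "LIE", TRUTH: "TRUTH"}


class ConfigurationError(ValueError):
    """Invalid pipeline or model configuration."""


class DataFormatError(ValueError):
    """A data file does not match the expected layout."""


@dataclass
class SessionRecord:
    """One recording: samples in microvolts, shape (time, channels)."""

    subject_id: str
    session_id: str
    label: int
    fs: float
    channel_names: tuple[str, ...]
    samples: np.ndarray
    preprocessed: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise DataFormatError("samples must be a 2-D (time x channels) array")
        if self.samples.shape[1] != len(self.channel_names):
            raise DataFormatError(
                f"samples has {self.samples.shape[1]} columns, expected "
                f"{len(self.channel_names)} channels"
            )
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")
        if self.label not in (LIE, TRUTH):
            raise DataFormatError(f"label must be 0 (LIE) or 1 (TRUTH), got {self.label}")
        if not np.all(np.isfinite(self.samples)):
            raise DataFormatError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray, preprocessed: bool | None = None) -> "SessionRecord":
        rec = replace(self, samples=samples)
        if preprocessed is not None:
            rec.preprocessed = preprocessed
        return rec


@dataclass
class Window:
    """Fixed-length segment (samples x channels) with inherited label."""

    data: np.ndarray
    subject_id: str
    session_id: str
    label: int
    start_sample: int
    fs: float
    zscored: bool = False

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def start_time_s(self) -> float:
        return self.start_sample / self.fs
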