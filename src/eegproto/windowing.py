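"""Sliding-window segmentation and per-window channel standardization."""

from __future__ import annotations

import numpy as np

from .records import ConfigurationError, SessionRecord, Window

#: Std floor used when standardizing near-constant columns.
EPSILON = 1e-8


def count_windows(n_samples: int, win_samples: int, hop_samples: int) -> int:
    """Number of complete windows; partial trailing segments are discarded."""
    if win_samples <= 0 or hop_samples <= 0:
        raise ConfigurationError("win_samples and hop_samples must be positive")
    if n_samples < win_samples:
        return 0
    return (n_samples - win_samples) // hop_samples + 1


def _to_samples(seconds: float, fs: float, name: str) -> int:
    exact = seconds * fs
    n = round(exact)
    if abs(exact - n) > 1e-6:
        raise ConfigurationError(f"{name} of {seconds}s is not a whole number of samples at fs={fs}")
    if n <= 0:
        raise ConfigurationError(f"{name} must be positive")
    return int(n)


def segment_session(record: SessionRecord, win_s: float, hop_s: float) -> list[Window]:
    """Cut a session into overlapping windows starting at 0, hop, 2*hop, ...

    Each window inherits the subject/session/label of its parent record.
    """
    win = _to_samples(win_s, record.fs, "window length")
    hop = _to_samples(hop_s, record.fs, "hop length")
    n = count_windows(record.n_samples, win, hop)
    windows = []
    for i in range(n):
        start = i * hop
        windows.append(
            Window(
                data=record.samples[start : start + win].copy(),
                subject_id=record.subject_id,
                session_id=record.session_id,
                label=record.label,
                start_sample=start,
                fs=record.fs,
            )
        )
    return windows


def zscore_window(window: Window, epsilon: float = EPSILON) -> Window:
    """Standardize each channel to zero mean / unit variance (population std).

    Constant columns fall back to all-zeros via the epsilon guard.
    """
    x = window.data
    mean = x.mean(axis=0, keepdims=True)
    std = x.std(axis=0, keepdims=True)
    z = (x - mean) / np.maximum(std, epsilon)
    return Window(
        data=z,
        subject_id=window.subject_id,
        session_id=window.session_id,
        label=window.label,
        start_sample=window.start_sample,
        fs=window.fs,
        zscored=True,
    )


def zscore_array(x: np.ndarray, epsilon: float = EPSILON) -> np.ndarray:
    """Vectorized per-window, per-channel standardization of (N, W, C) data."""
    mean = x.mean(axis=1, keepdims=True)
    std = x.std(axis=1, keepdims=True)
    return (x - mean) / np.maximum(std, epsilon)


def stack_windows(windows: list[Window]) -> dict:
    """Pack a window list into aligned arrays for model consumption."""
    return {
        "X": np.stack([w.data for w in windows]) if windows else np.empty((0, 0, 0)),
        "y": np.array([w.label for w in windows], dtype=np.int64),
        "subject": np.array([w.subject_id for w in windows]),
        "session": np.array([w.session_id for w in windows]),
        "start": np.array([w.start_sample for w in windows], dtype=np.int64),
    }
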