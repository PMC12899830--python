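"""Periodized Daubechies discrete wavelet transforms.

Implements the orthonormal pyramid algorithm with periodic boundary
handling: a single analysis/synthesis step, the multi-level DWT used by the
wavelet feature extractor, and the full wavelet-packet decomposition used by
the artifact-reduction stage. Only the filters actually needed by the
pipeline are bundled (db4 by default, db1/db2 for testing).
"""

from __future__ import annotations

import math

import numpy as np

from .records import ConfigurationError

_SQRT2 = math.sqrt(2.0)

# Orthonormal scaling (lowpass synthesis) filters, sum = sqrt(2), energy 1.
_SCALING_FILTERS: dict[str, np.ndarray] = {
    "db1": np.array([1.0, 1.0]) / _SQRT2,
    "db2": np.array(
        [0.48296291314469025, 0.836516303737469, 0.22414386804185735, -0.12940952255092145]
    ),
    "db4": np.array(
        [
            0.23037781330885523,
            0.7148465705525415,
            0.6308807679295904,
            -0.02798376941698385,
            -0.18703481171888114,
            0.030841381835986965,
            0.032883011666982945,
            -0.010597401784997278,
        ]
    ),
}


def filters(wavelet: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (lowpass h, highpass g) orthonormal analysis filters."""
    try:
        h = _SCALING_FILTERS[wavelet]
    except KeyError as exc:
        raise ConfigurationError(f"unknown wavelet {wavelet!r}") from exc
    L = len(h)
    g = np.array([(-1) ** k * h[L - 1 - k] for k in range(L)])
    return h, g


def max_level(n: int, wavelet: str = "db4") -> int:
    """Deepest useful decomposition level for a signal of length ``n``."""
    flen = len(_SCALING_FILTERS[wavelet])
    if n < flen:
        return 0
    return int(math.floor(math.log2(n / (flen - 1))))


def _analysis_step(x: np.ndarray, h: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One periodized analysis step; returns (approx, detail)."""
    n = len(x)
    if n % 2 == 1:  # periodic wrap to even length, trimmed on synthesis
        x = np.concatenate([x, x[:1]])
        n += 1
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(len(h))[None, :]) % n
    taps = x[idx]
    return taps @ h, taps @ g


def _synthesis_step(ca: np.ndarray, cd: np.ndarray, h: np.ndarray, g: np.ndarray, out_len: int) -> np.ndarray:
    n = 2 * len(ca)
    x = np.zeros(n)
    pos = (2 * np.arange(len(ca))[:, None] + np.arange(len(h))[None, :]) % n
    np.add.at(x, pos.ravel(), (ca[:, None] * h[None, :] + cd[:, None] * g[None, :]).ravel())
    return x[:out_len]


def dwt(
    x: np.ndarray, wavelet: str = "db4", level: int | None = None, return_lengths: bool = False
):
    """Multi-level DWT; returns [A_L, D_L, D_{L-1}, ..., D_1].

    With ``return_lengths=True`` also returns the pre-step signal length at
    each level (outermost first), which :func:`idwt` needs to undo the
    odd-length wrap of the periodized transform.
    """
    x = np.asarray(x, dtype=np.float64)
    h, g = filters(wavelet)
    if level is None:
        level = max_level(len(x), wavelet)
    if level < 1:
        raise ConfigurationError(f"signal of length {len(x)} too short for {wavelet}")
    details: list[np.ndarray] = []
    lengths: list[int] = []
    ca = x
    for _ in range(level):
        lengths.append(len(ca))
        ca, cd = _analysis_step(ca, h, g)
        details.append(cd)
    coeffs = [ca] + details[::-1]
    if return_lengths:
        return coeffs, lengths
    return coeffs


def idwt(coeffs: list[np.ndarray], wavelet: str, lengths: list[int]) -> np.ndarray:
    """Invert :func:`dwt`; ``lengths`` as returned by ``return_lengths=True``."""
    h, g = filters(wavelet)
    ca = coeffs[0]
    for cd, out_len in zip(coeffs[1:], lengths[::-1]):
        ca = _synthesis_step(ca, cd, h, g, out_len)
    return ca


class _PacketNode:
    __slots__ = ("data", "low", "high", "length")

    def __init__(self, data=None, low=None, high=None, length=0):
        self.data = data
        self.low = low
        self.high = high
        self.length = length


def wavelet_packet_decompose(x: np.ndarray, wavelet: str = "db4", level: int | None = None):
    """Full wavelet-packet tree to ``level`` (default: maximum permitted)."""
    x = np.asarray(x, dtype=np.float64)
    h, g = filters(wavelet)
    if level is None:
        level = max_level(len(x), wavelet)
    level = max(level, 0)

    def build(sig: np.ndarray, depth: int) -> _PacketNode:
        node = _PacketNode(length=len(sig))
        if depth == 0 or len(sig) < 2:
            node.data = sig.copy()
            return node
        ca, cd = _analysis_step(sig, h, g)
        node.low = build(ca, depth - 1)
        node.high = build(cd, depth - 1)
        return node

    return build(x, level)


def packet_leaves(tree: _PacketNode) -> list[np.ndarray]:
    """Terminal-node coefficient arrays (natural tree order)."""
    if tree.data is not None:
        return [tree.data]
    return packet_leaves(tree.low) + packet_leaves(tree.high)


def wavelet_packet_reconstruct(tree: _PacketNode, wavelet: str = "db4") -> np.ndarray:
    h, g = filters(wavelet)

    def rebuild(node: _PacketNode) -> np.ndarray:
        if node.data is not None:
            return node.data
        ca = rebuild(node.low)
        cd = rebuild(node.high)
        return _synthesis_step(ca, cd, h, g, node.length)

    return rebuild(tree)


def soft_threshold(c: np.ndarray, thr: float) -> np.ndarray:
    """sign(c) * max(|c| - thr, 0)."""
    return np.sign(c) * np.maximum(np.abs(c) - thr, 0.0)
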