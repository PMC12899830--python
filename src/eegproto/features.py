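"""Hand-crafted window descriptors and descriptive statistics.

Three feature families are produced per window:

* DESC — interpretable 65-column table rows (60 numeric descriptors plus
  5 metadata columns): per-channel canonical band powers, Hjorth
  parameters, beta/alpha and theta/alpha ratios, and cross-channel
  mean/std aggregates per band. Computed on non-z-scored windows.
* DWT — 175 values: per channel and per level-4 db4 sub-band
  (A4, D4, D3, D2, D1), six summary statistics plus relative energy.
* FEATS — 167 values: per channel, 11 extended band powers, 11 relative
  powers, two spectral ratios, spectral entropy, three Hjorth parameters
  and five band-limited differential entropies (33 each), plus two frontal
  log-power asymmetry indices (AF4 - AF3, alpha and beta).

All vectors are finite for any finite input; zero/constant windows exercise
the epsilon guards rather than producing NaNs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import wavelets
from .records import ConfigurationError, Window
from .synth import CANONICAL_BANDS

_LOG_EPS = 1e-12


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float


#: Extended band set for the FEATS vector; edges clipped to Nyquist downstream.
EXTENDED_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("alpha_low", 8.0, 10.0),
    BandDefinition("alpha_high", 10.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("beta_low", 13.0, 20.0),
    BandDefinition("beta_high", 20.0, 30.0),
    BandDefinition("gamma", 30.0, 65.0),
    BandDefinition("gamma_low", 30.0, 45.0),
    BandDefinition("gamma_middle", 45.0, 65.0),
)

CANONICAL_BAND_DEFS: tuple[BandDefinition, ...] = tuple(
    BandDefinition(name, lo, hi) for name, lo, hi in CANONICAL_BANDS
)

DWT_SUBBANDS = ("A4", "D4", "D3", "D2", "D1")
DWT_STATS = ("min", "max", "median", "mean", "std", "var", "rel_energy")

DESC_META_COLUMNS = ("subject_id", "session_id", "label", "window_index", "start_time_s")


def welch_psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD: Hann window, constant detrend, segment length
    min(256, N), 50% overlap between segments when N > 256."""
    x = np.asarray(x, dtype=np.float64)
    nperseg = min(256, len(x))
    return sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        detrend="constant", scaling="density",
    )


def band_power(freqs: np.ndarray, psd: np.ndarray, band: BandDefinition) -> float:
    """Trapezoidal integral of the PSD over [lo, hi], clipped to Nyquist."""
    lo = max(band.lo, float(freqs[0]))
    hi = min(band.hi, float(freqs[-1]))
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        warnings.warn(f"band {band.name} [{band.lo}, {band.hi}] has no PSD bins", stacklevel=2)
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def hjorth_params(x: np.ndarray) -> tuple[float, float, float]:
    """(activity, mobility, complexity) with zero-variance guards.

    Derivatives are first differences without fs scaling.
    """
    x = np.asarray(x, dtype=np.float64)
    activity = float(np.var(x))
    if activity <= 0:
        return 0.0, 0.0, 0.0
    dx = np.diff(x)
    var_dx = float(np.var(dx))
    mobility = float(np.sqrt(var_dx / activity))
    if var_dx <= 0:
        return activity, mobility, 0.0
    ddx = np.diff(dx)
    mobility_dx = float(np.sqrt(np.var(ddx) / var_dx))
    complexity = mobility_dx / mobility if mobility > 0 else 0.0
    return activity, mobility, complexity


def spectral_entropy(psd: np.ndarray) -> float:
    """Shannon entropy of the normalized PSD, scaled to [0, 1] by log(#bins)."""
    psd = np.asarray(psd, dtype=np.float64)
    total = psd.sum()
    if total <= 0 or len(psd) < 2:
        return 0.0
    p = psd / total
    nz = p > 0
    h = -float(np.sum(p[nz] * np.log(p[nz])))
    return h / np.log(len(psd))


def differential_entropy_band(band_power_value: float) -> float:
    """0.5 * ln(2*pi*e * P) for a band-limited Gaussian of power P."""
    return float(0.5 * np.log(2 * np.pi * np.e * max(band_power_value, _LOG_EPS)))


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


# ---------------------------------------------------------------------------
# DESC: interpretable band-power / Hjorth / ratio table
# ---------------------------------------------------------------------------

def desc_feature_names(channel_names: tuple[str, ...]) -> list[str]:
    names = []
    for ch in channel_names:
        names += [f"{ch}_{b.name}_power" for b in CANONICAL_BAND_DEFS]
        names += [f"{ch}_hjorth_activity", f"{ch}_hjorth_mobility", f"{ch}_hjorth_complexity"]
        names += [f"{ch}_beta_alpha_ratio", f"{ch}_theta_alpha_ratio"]
    for b in CANONICAL_BAND_DEFS:
        names.append(f"xchan_mean_{b.name}_power")
    for b in CANONICAL_BAND_DEFS:
        names.append(f"xchan_std_{b.name}_power")
    return names


def desc_features(window: Window, window_index: int, channel_names: tuple[str, ...]) -> dict:
    """One 65-column row: 60 numeric descriptors + 5 metadata columns."""
    if window.zscored:
        raise ConfigurationError("descriptive features are computed on non-z-scored windows")
    row: dict = {
        "subject_id": window.subject_id,
        "session_id": window.session_id,
        "label": window.label,
        "window_index": window_index,
        "start_time_s": window.start_time_s,
    }
    band_matrix = np.zeros((len(channel_names), len(CANONICAL_BAND_DEFS)))
    for c, ch in enumerate(channel_names):
        x = window.data[:, c]
        freqs, psd = welch_psd(x, window.fs)
        powers = {b.name: band_power(freqs, psd, b) for b in CANONICAL_BAND_DEFS}
        band_matrix[c] = [powers[b.name] for b in CANONICAL_BAND_DEFS]
        act, mob, comp = hjorth_params(x)
        for b in CANONICAL_BAND_DEFS:
            row[f"{ch}_{b.name}_power"] = powers[b.name]
        row[f"{ch}_hjorth_activity"] = act
        row[f"{ch}_hjorth_mobility"] = mob
        row[f"{ch}_hjorth_complexity"] = comp
        row[f"{ch}_beta_alpha_ratio"] = _ratio(powers["beta"], powers["alpha"])
        row[f"{ch}_theta_alpha_ratio"] = _ratio(powers["theta"], powers["alpha"])
    for j, b in enumerate(CANONICAL_BAND_DEFS):
        row[f"xchan_mean_{b.name}_power"] = float(band_matrix[:, j].mean())
    for j, b in enumerate(CANONICAL_BAND_DEFS):
        row[f"xchan_std_{b.name}_power"] = float(band_matrix[:, j].std())
    return row


def desc_table(windows: list[Window], channel_names: tuple[str, ...]) -> pd.DataFrame:
    """DESC rows for a window stream; column order fixed and documented."""
    rows = [desc_features(w, i, channel_names) for i, w in enumerate(windows)]
    columns = list(DESC_META_COLUMNS) + desc_feature_names(channel_names)
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# DWT: level-4 db4 sub-band statistics
# ---------------------------------------------------------------------------

def dwt_feature_names(channel_names: tuple[str, ...]) -> list[str]:
    return [
        f"{ch}_{sb}_{st}" for ch in channel_names for sb in DWT_SUBBANDS for st in DWT_STATS
    ]


def dwt_features(window: Window) -> np.ndarray:
    """175 values, channel-major, sub-band order A4,D4,D3,D2,D1.

    Relative energies within a channel sum to 1 (all 0 for a zero window).
    """
    if wavelets.max_level(window.n_samples, "db4") < 4:
        raise ConfigurationError("window too short for a 4-level db4 decomposition")
    out = []
    for c in range(window.data.shape[1]):
        coeffs = wavelets.dwt(window.data[:, c], "db4", level=4)
        energies = np.array([float(np.sum(cc**2)) for cc in coeffs])
        total = energies.sum()
        for cc, e in zip(coeffs, energies):
            out += [
                float(cc.min()),
                float(cc.max()),
                float(np.median(cc)),
                float(cc.mean()),
                float(cc.std()),
                float(cc.var()),
                e / total if total > 0 else 0.0,
            ]
    return np.array(out)


# ---------------------------------------------------------------------------
# FEATS: extended spectral-statistical vector
# ---------------------------------------------------------------------------

def feats_feature_names(channel_names: tuple[str, ...]) -> list[str]:
    names = []
    for ch in channel_names:
        names += [f"{ch}_{b.name}_power" for b in EXTENDED_BANDS]
        names += [f"{ch}_{b.name}_relpower" for b in EXTENDED_BANDS]
        names += [f"{ch}_theta_beta_ratio", f"{ch}_theta_alpha_beta_ratio"]
        names += [f"{ch}_spectral_entropy"]
        names += [f"{ch}_hjorth_activity", f"{ch}_hjorth_mobility", f"{ch}_hjorth_complexity"]
        names += [
            f"{ch}_de_delta", f"{ch}_de_theta", f"{ch}_de_alpha", f"{ch}_de_beta", f"{ch}_de_gamma",
        ]
    names += ["asym_alpha_AF4_AF3", "asym_beta_AF4_AF3"]
    return names


def feats_vector(window: Window, channel_names: tuple[str, ...]) -> np.ndarray:
    """167 values: 33 descriptors per channel plus two asymmetry terms."""
    if "AF3" not in channel_names or "AF4" not in channel_names:
        raise ConfigurationError("FEATS requires AF3 and AF4 channels")
    out: list[float] = []
    alpha_by_ch: dict[str, float] = {}
    beta_by_ch: dict[str, float] = {}
    for c, ch in enumerate(channel_names):
        x = window.data[:, c]
        freqs, psd = welch_psd(x, window.fs)
        powers = np.array([band_power(freqs, psd, b) for b in EXTENDED_BANDS])
        by_name = {b.name: p for b, p in zip(EXTENDED_BANDS, powers)}
        alpha_by_ch[ch] = by_name["alpha"]
        beta_by_ch[ch] = by_name["beta"]
        total = powers.sum()
        rel = powers / total if total > 0 else np.zeros_like(powers)
        act, mob, comp = hjorth_params(x)
        out += list(powers)
        out += list(rel)
        out += [
            _ratio(by_name["theta"], by_name["beta"]),
            _ratio(by_name["theta"] + by_name["alpha"], by_name["beta"]),
            spectral_entropy(psd),
            act, mob, comp,
        ]
        out += [
            differential_entropy_band(by_name[b])
            for b in ("delta", "theta", "alpha", "beta", "gamma")
        ]
    out.append(float(np.log(max(alpha_by_ch["AF4"], _LOG_EPS)) - np.log(max(alpha_by_ch["AF3"], _LOG_EPS))))
    out.append(float(np.log(max(beta_by_ch["AF4"], _LOG_EPS)) - np.log(max(beta_by_ch["AF3"], _LOG_EPS))))
    return np.array(out)


# ---------------------------------------------------------------------------
# Descriptive statistics: effect sizes and quartile summaries
# ---------------------------------------------------------------------------

def cliffs_delta(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """(#{a > b} - #{a < b}) / (n_a * n_b), computed via rank counting."""
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ConfigurationError("both samples must be non-empty")
    bs = np.sort(b)
    greater = np.searchsorted(bs, a, side="left").sum()
    less = (b.size - np.searchsorted(bs, a, side="right")).sum()
    return float(greater - less) / (a.size * b.size)


def band_power_summary(desc: pd.DataFrame) -> pd.DataFrame:
    """Per band x class quartiles of the cross-channel mean band power.

    Returns one row per band with Q1/median/Q3/IQR for each class, the
    median difference (TRUTH - LIE), and Cliff's delta (TRUTH - LIE).
    """
    if desc.empty:
        raise ConfigurationError("descriptive table is empty")
    rows = []
    for b in CANONICAL_BAND_DEFS:
        col = f"xchan_mean_{b.name}_power"
        truth = desc.loc[desc["label"] == 1, col].to_numpy()
        lie = desc.loc[desc["label"] == 0, col].to_numpy()
        row = {"band": b.name}
        for tag, vals in (("truth", truth), ("lie", lie)):
            q1, med, q3 = np.percentile(vals, [25, 50, 75]) if vals.size else (np.nan,) * 3
            row[f"q1_{tag}"] = q1
            row[f"median_{tag}"] = med
            row[f"q3_{tag}"] = q3
            row[f"iqr_{tag}"] = q3 - q1
        row["delta_median"] = row["median_truth"] - row["median_lie"]
        row["cliffs_delta"] = (
            cliffs_delta(truth, lie) if truth.size and lie.size else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
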