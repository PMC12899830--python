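import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from eegproto import features, windowing
from eegproto.features import (
    BandDefinition,
    CANONICAL_BAND_DEFS,
    band_power,
    band_power_summary,
    cliffs_delta,
    desc_table,
    differential_entropy_band,
    dwt_features,
    feats_vector,
    hjorth_params,
    spectral_entropy,
    welch_psd,
)
from eegproto.records import CHANNELS, ConfigurationError

from conftest import make_record

FS = 128.0


def _window(data, zscore=False):
    rec = make_record(np.asarray(data, dtype=float))
    w = windowing.segment_session(rec, data.shape[0] / FS, data.shape[0] / FS)[0]
    return windowing.zscore_window(w) if zscore else w


def sine(freq, n=256, fs=FS, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs)


class TestWelch:
    def test_frequency_resolution(self):
        freqs, _ = welch_psd(np.zeros(512), FS)
        assert np.isclose(freqs[1] - freqs[0], 0.5)

    def test_zero_input(self):
        _, psd = welch_psd(np.zeros(256), FS)
        np.testing.assert_allclose(psd, 0.0)

    def test_parseval_white_noise(self):
        x = np.random.default_rng(0).standard_normal(4096)
        freqs, psd = welch_psd(x, FS)
        assert abs(np.trapezoid(psd, freqs) / x.var() - 1.0) <= 0.10


class TestBandPower:
    def test_zero_psd(self):
        freqs = np.linspace(0, 64, 129)
        assert band_power(freqs, np.zeros_like(freqs), CANONICAL_BAND_DEFS[2]) == 0.0

    def test_alpha_sine_dominates(self):
        x = sine(10.0, n=256)
        freqs, psd = welch_psd(x, FS)
        alpha = band_power(freqs, psd, BandDefinition("alpha", 8, 13))
        total = band_power(freqs, psd, BandDefinition("all", 1, 45))
        assert alpha >= 0.9 * total

    def test_band_sum_equals_total(self):
        x = np.random.default_rng(1).standard_normal(1024)
        freqs, psd = welch_psd(x, FS)
        total = band_power(freqs, psd, BandDefinition("all", 1, 45))
        parts = sum(band_power(freqs, psd, b) for b in CANONICAL_BAND_DEFS)
        assert abs(parts / total - 1.0) <= 0.01

    def test_empty_band_warns(self):
        freqs = np.linspace(0, 64, 129)
        with pytest.warns(UserWarning):
            assert band_power(freqs, np.ones_like(freqs), BandDefinition("x", 63.9, 64.0)) == 0.0


class TestHjorth:
    def test_constant(self):
        assert hjorth_params(np.ones(100)) == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("freq", [2.0, 10.0, 30.0])
    def test_sine_mobility_closed_form(self, freq):
        # discrete first difference of a sinusoid: mobility = 2 sin(pi f / fs)
        x = sine(freq, n=int(FS * 8))
        _, mob, _ = hjorth_params(x)
        assert np.isclose(mob, 2 * np.sin(np.pi * freq / FS), rtol=1e-2)

    def test_white_noise_complexity_gt_one(self):
        rng = np.random.default_rng(42)
        comp = [hjorth_params(rng.standard_normal(512))[2] for _ in range(100)]
        assert min(comp) > 1.0


class TestDesc:
    def test_column_count_65(self, tiny_preprocessed):
        wins = windowing.segment_session(tiny_preprocessed[0], 2.0, 1.0)
        table = desc_table(wins, CHANNELS)
        assert table.shape[1] == 65
        numeric = table.drop(columns=list(features.DESC_META_COLUMNS))
        assert numeric.shape[1] == 60

    def test_identical_channels_zero_std(self):
        x = np.tile(sine(10.0)[:, None], (1, 5))
        row = features.desc_features(_window(x), 0, CHANNELS)
        for b in CANONICAL_BAND_DEFS:
            assert row[f"xchan_std_{b.name}_power"] == pytest.approx(0.0, abs=1e-12)

    def test_aggregates_match_definition(self, rng):
        x = rng.standard_normal((256, 5))
        row = features.desc_features(_window(x), 0, CHANNELS)
        for b in CANONICAL_BAND_DEFS:
            per_ch = [row[f"{ch}_{b.name}_power"] for ch in CHANNELS]
            assert row[f"xchan_mean_{b.name}_power"] == pytest.approx(np.mean(per_ch))
            assert row[f"xchan_std_{b.name}_power"] == pytest.approx(np.std(per_ch))

    def test_rejects_zscored_window(self, rng):
        with pytest.raises(ConfigurationError):
            features.desc_features(_window(rng.standard_normal((256, 5)), zscore=True), 0, CHANNELS)

    def test_serialization_lossless(self, tmp_path, tiny_preprocessed):
        wins = windowing.segment_session(tiny_preprocessed[0], 2.0, 1.0)[:3]
        table = desc_table(wins, CHANNELS)
        path = tmp_path / "desc.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        numeric_cols = [c for c in table.columns if c not in ("subject_id", "session_id")]
        np.testing.assert_allclose(back[numeric_cols].to_numpy(dtype=float),
                                   table[numeric_cols].to_numpy(dtype=float), rtol=1e-12)


class TestDwtVector:
    def test_length_175(self, rng):
        vec = dwt_features(_window(rng.standard_normal((256, 5)), zscore=True))
        assert vec.shape == (175,)

    def test_zero_window_guard(self):
        vec = dwt_features(_window(np.zeros((256, 5))))
        np.testing.assert_allclose(vec, 0.0)

    def test_relative_energies_sum_to_one(self, rng):
        vec = dwt_features(_window(rng.standard_normal((256, 5)), zscore=True))
        rel = vec.reshape(5, 5, 7)[:, :, 6]
        np.testing.assert_allclose(rel.sum(axis=1), 1.0, atol=1e-9)

    def test_energy_conservation(self, rng):
        x = rng.standard_normal((256, 5))
        w = _window(x)
        vec = dwt_features(w).reshape(5, 5, 7)
        for c in range(5):
            sig_energy = (x[:, c] ** 2).sum()
            # reconstruct sub-band energies from rel energy * total:
            # orthogonality => total coefficient energy == signal energy
            from eegproto import wavelets

            coeffs = wavelets.dwt(x[:, c], "db4", level=4)
            assert np.isclose(sum((cc**2).sum() for cc in coeffs), sig_energy, rtol=1e-9)

    def test_too_short_raises(self, rng):
        with pytest.raises(ConfigurationError):
            dwt_features(_window(rng.standard_normal((64, 5))))


class TestSpectralEntropy:
    def test_single_bin(self):
        psd = np.zeros(64)
        psd[10] = 5.0
        assert spectral_entropy(psd) == pytest.approx(0.0)

    def test_flat(self):
        assert spectral_entropy(np.ones(64)) == pytest.approx(1.0)

    def test_white_noise_high(self):
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(20):
            _, psd = welch_psd(rng.standard_normal(256), FS)
            vals.append(spectral_entropy(psd))
        assert min(vals) >= 0.8


class TestDifferentialEntropy:
    def test_closed_forms(self):
        assert differential_entropy_band(1.0 / (2 * np.pi * np.e)) == pytest.approx(0.0)
        assert differential_entropy_band(1.0) == pytest.approx(0.5 * np.log(2 * np.pi * np.e))
        assert differential_entropy_band(1.0) == pytest.approx(1.4189, abs=1e-4)

    def test_monotone(self):
        ps = np.linspace(0.01, 10, 50)
        de = [differential_entropy_band(p) for p in ps]
        assert all(a < b for a, b in zip(de, de[1:]))


class TestFeats:
    def test_length_167(self, rng):
        vec = feats_vector(_window(rng.standard_normal((256, 5)), zscore=True), CHANNELS)
        assert vec.shape == (167,)
        assert np.all(np.isfinite(vec))

    def test_relative_powers_sum_to_one(self, rng):
        vec = feats_vector(_window(rng.standard_normal((256, 5)), zscore=True), CHANNELS)
        per_ch = vec[:165].reshape(5, 33)
        rel = per_ch[:, 11:22]
        np.testing.assert_allclose(rel.sum(axis=1), 1.0, atol=1e-9)

    def test_asymmetry_antisymmetric_under_swap(self, rng):
        x = rng.standard_normal((256, 5))
        sw = x.copy()
        af3, af4 = CHANNELS.index("AF3"), CHANNELS.index("AF4")
        sw[:, [af3, af4]] = sw[:, [af4, af3]]
        v1 = feats_vector(_window(x), CHANNELS)
        v2 = feats_vector(_window(sw), CHANNELS)
        np.testing.assert_allclose(v2[-2:], -v1[-2:], atol=1e-9)

    def test_requires_frontal_channels(self, rng):
        with pytest.raises(ConfigurationError):
            feats_vector(_window(rng.standard_normal((256, 5))), ("a", "b", "c", "d", "e"))

    def test_zero_window_finite(self):
        vec = feats_vector(_window(np.zeros((256, 5))), CHANNELS)
        assert np.all(np.isfinite(vec))


class TestCliffsDelta:
    def test_identical(self):
        assert cliffs_delta([1, 1, 1], [1, 1, 1]) == 0.0

    def test_total_separation(self):
        assert cliffs_delta([5, 6, 7], [1, 2, 3]) == 1.0
        assert cliffs_delta([1, 2, 3], [5, 6, 7]) == -1.0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31))
    def test_matches_pair_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 10, size=50).astype(float)
        b = rng.integers(0, 10, size=50).astype(float)
        oracle = sum(np.sign(x - y) for x in a for y in b) / (len(a) * len(b))
        assert cliffs_delta(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ConfigurationError):
            cliffs_delta([], [1.0])


class TestBandPowerSummary:
    @staticmethod
    def _table(rng, n_rows=40):
        cols = {"label": rng.integers(0, 2, n_rows)}
        for b in CANONICAL_BAND_DEFS:
            cols[f"xchan_mean_{b.name}_power"] = rng.gamma(2.0, 5.0, n_rows)
        return pd.DataFrame(cols)

    def test_single_row_per_class(self, rng):
        df = pd.DataFrame({
            "label": [0, 1],
            **{f"xchan_mean_{b.name}_power": [1.0, 2.0] for b in CANONICAL_BAND_DEFS},
        })
        out = band_power_summary(df)
        assert (out["q1_truth"] == out["median_truth"]).all()
        assert (out["iqr_truth"] == 0).all()

    def test_iqr_identity(self, rng):
        out = band_power_summary(self._table(rng))
        np.testing.assert_allclose(out["iqr_truth"], out["q3_truth"] - out["q1_truth"])
        np.testing.assert_allclose(out["iqr_lie"], out["q3_lie"] - out["q1_lie"])

    def test_quartiles_match_sort_oracle(self):
        rng = np.random.default_rng(5)
        df = self._table(rng, n_rows=1000)
        out = band_power_summary(df).set_index("band")
        for b in CANONICAL_BAND_DEFS:
            vals = np.sort(df.loc[df["label"] == 1, f"xchan_mean_{b.name}_power"].to_numpy())
            assert out.loc[b.name, "median_truth"] == pytest.approx(np.percentile(vals, 50))
            assert out.loc[b.name, "q1_truth"] == pytest.approx(np.percentile(vals, 25))

    def test_configured_effect_direction(self, tiny_preprocessed):
        from eegproto.protocol import run_describe

        summary, _ = run_describe(tiny_preprocessed)
        signs = summary.set_index("band")["delta_median"]
        # class effect boosts delta/theta for LIE and beta/gamma for TRUTH
        assert signs["delta"] < 0 and signs["theta"] < 0
        assert signs["beta"] > 0 and signs["gamma"] > 0
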