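"""Windowing, the 16 per-window features, and min-max normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from physioaffect.features import (
    FEATURE_NAMES,
    WindowSpec,
    eda_decompose,
    eda_features,
    extract_condition_features,
    hrv_freq_features,
    hrv_time_features,
    normalize_minmax,
    skt_features,
    slide_windows,
)
from physioaffect.preprocess import RRSeries
from physioaffect.simulate import SimParams, simulate_recording


def make_rr_series(intervals_ms, midpoints_s):
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    return RRSeries(
        intervals_ms=intervals_ms,
        midpoint_times_s=np.asarray(midpoints_s, dtype=float),
        valid=np.ones(intervals_ms.size, dtype=bool),
    )


class TestSlideWindows:
    def test_hour_long_recording_yields_111_windows(self):
        spec = WindowSpec()
        assert len(slide_windows(3600.0, spec, select=False)) == 111

    def test_last_100_windows_retained(self):
        windows = slide_windows(3600.0, WindowSpec())
        assert len(windows) == 100
        assert windows[0] == (330.0, 630.0)
        assert windows[-1] == (3300.0, 3600.0)

    def test_exactly_one_window_at_minimum_duration(self):
        spec = WindowSpec(selection_count=1)
        assert slide_windows(300.0, spec) == [(0.0, 300.0)]

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError):
            slide_windows(200.0, WindowSpec())

    def test_selection_beyond_available_rejected(self):
        with pytest.raises(ValueError):
            slide_windows(400.0, WindowSpec(selection_count=100))


class TestHRVTime:
    def test_hand_computed_values(self):
        f = hrv_time_features([800, 810, 790, 805, 795])
        assert f["MeanHRV"] == pytest.approx(800.0, abs=1e-9)
        assert f["SDNN"] == pytest.approx(np.sqrt(250.0 / 4.0), abs=1e-9)
        assert f["RMSSD"] == pytest.approx(np.sqrt(825.0 / 4.0), abs=1e-9)
        assert f["NN50"] == 0
        assert f["pNN50"] == 0.0

    def test_nn50_counts_absolute_differences(self):
        f = hrv_time_features([700, 760, 700])
        assert f["NN50"] == 2
        assert f["pNN50"] == pytest.approx(200.0 / 3.0, abs=1e-9)

    def test_constant_train_has_zero_variability(self):
        f = hrv_time_features([800.0] * 50)
        assert f["SDNN"] == 0.0 and f["RMSSD"] == 0.0 and f["NN50"] == 0

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError):
            hrv_time_features([800.0])

    @given(
        rr=st.lists(st.floats(min_value=400, max_value=1500), min_size=3, max_size=40),
        shift=st.floats(min_value=-100, max_value=100),
    )
    @settings(max_examples=50, deadline=None)
    def test_shift_invariance(self, rr, shift):
        """Adding a constant to all intervals moves MeanHRV only."""
        base = hrv_time_features(rr)
        moved = hrv_time_features([x + shift for x in rr])
        assert moved["MeanHRV"] == pytest.approx(base["MeanHRV"] + shift, abs=1e-6)
        assert moved["SDNN"] == pytest.approx(base["SDNN"], abs=1e-6)
        assert moved["RMSSD"] == pytest.approx(base["RMSSD"], abs=1e-6)
        assert moved["NN50"] == base["NN50"]


class TestHRVFrequency:
    def _tachogram(self, freq_hz, duration=300.0, mean=800.0, amp=50.0):
        t = np.arange(0.0, duration, 0.8)
        rr = mean + amp * np.sin(2 * np.pi * freq_hz * t)
        return make_rr_series(rr, t)

    def test_band_fractions_sum_to_one(self):
        f = hrv_freq_features(self._tachogram(0.1))
        assert f["nLF"] + f["nHF"] == pytest.approx(1.0, abs=1e-9)

    def test_lf_band_localization(self):
        f = hrv_freq_features(self._tachogram(0.1))
        assert f["nLF"] >= 0.95
        assert f["LF_HF"] > 10

    def test_hf_band_localization(self):
        f = hrv_freq_features(self._tachogram(0.25))
        assert f["nHF"] >= 0.95
        assert f["LF_HF"] < 0.1

    def test_total_power_nonnegative(self):
        f = hrv_freq_features(self._tachogram(0.1))
        assert f["TP"] >= 0


class TestSKT:
    def test_constant_window(self):
        f = skt_features(np.full(100, 33.0))
        assert f == {"MeanSKT": 33.0, "SDSKT": 0.0}

    def test_two_sample_sd_uses_n_minus_one(self):
        f = skt_features([32.0, 34.0])
        assert f["MeanSKT"] == 33.0
        assert f["SDSKT"] == pytest.approx(np.sqrt(2.0), abs=1e-9)

    def test_linear_ramp_mean(self):
        ramp = np.linspace(32.0, 33.0, 15000)
        assert skt_features(ramp)["MeanSKT"] == pytest.approx(32.5, abs=0.01)


class TestEDADecompose:
    def test_constant_is_pure_tonic(self):
        tonic, phasic = eda_decompose(np.full(4096, 5.0), fs=32.0)
        np.testing.assert_allclose(tonic, 5.0, atol=1e-8)
        assert np.max(np.abs(phasic)) < 1e-6

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5.0, 1.0, 4096)
        tonic, phasic = eda_decompose(x, fs=32.0)
        np.testing.assert_allclose(tonic + phasic, x, atol=1e-10)

    def test_band_split_of_slow_and_fast_components(self):
        fs = 32.0
        t = np.arange(0, 300, 1 / fs)
        slow = 2.0 + 0.5 * np.sin(2 * np.pi * 0.001 * t)
        fast = 0.3 * np.sin(2 * np.pi * 0.2 * t)
        tonic, phasic = eda_decompose(slow + fast, fs=fs)
        slow_ac = slow - slow.mean()
        tonic_ac = tonic - tonic.mean()
        slow_captured = 1 - np.sum((tonic_ac - slow_ac) ** 2) / np.sum(slow_ac**2)
        fast_captured = 1 - np.sum((phasic - fast) ** 2) / np.sum(fast**2)
        assert slow_captured >= 0.95
        assert fast_captured >= 0.90

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            eda_decompose(np.ones(512), fs=32.0)


class TestEDAFeatures:
    def test_zero_phasic(self):
        f = eda_features(tonic=np.full(100, 5.0), phasic=np.zeros(100))
        assert f["ZC_EDAP"] == 0 and f["SD_EDAP"] == 0.0

    def test_one_sine_cycle_crosses_twice(self):
        t = np.arange(0, 10.0, 1 / 32.0)
        phasic = np.sin(2 * np.pi * 0.1 * t + np.pi / 4)
        f = eda_features(tonic=np.full(t.size, 5.0), phasic=phasic)
        assert f["ZC_EDAP"] == 2

    def test_constant_tonic(self):
        f = eda_features(tonic=np.full(100, 5.0), phasic=np.zeros(100))
        assert f["Mean_EDAT"] == 5.0
        assert f["SD_EDAT"] == 0.0
        assert f["Amp_EDAT"] == 0.0


class TestFeatureMatrix:
    def test_structure_and_invariants(self, short_recordings):
        from physioaffect.features import build_feature_matrix

        spec = WindowSpec(selection_count=10)
        m = build_feature_matrix(short_recordings, spec)
        assert list(m.columns[:16]) == FEATURE_NAMES
        assert len(m) == 20
        assert (m.groupby("condition").size() == 10).all()
        np.testing.assert_allclose(m["nHF"] + m["nLF"], 1.0, atol=1e-9)
        assert ((m["pNN50"] >= 0) & (m["pNN50"] <= 100)).all()
        assert (m["NN50"] >= 0).all() and (m["NN50"] == m["NN50"].astype(int)).all()
        assert (m["TP"] >= 0).all() and (m["Amp_EDAT"] >= 0).all()
        assert set(m["label"]) == {0, 1}

    def test_missing_condition_rejected(self, short_recordings):
        from physioaffect.features import build_feature_matrix

        with pytest.raises(ValueError, match="missing condition"):
            build_feature_matrix({"basic": short_recordings["basic"]})

    def test_parameter_recovery_on_noiseless_input(self):
        """A noise-free simulation must hand back its programmed quantities."""
        p = SimParams(duration_s=360, seed=3)
        p.rr_sd_ms = {"basic": 0.0, "negative": 0.0}
        p.rr_mean_ms["basic"] = 800.0
        p.noise_sd = {"ECG": 0.0, "SKT": 0.0, "EDA": 0.0}
        p.scr_rate_per_min["basic"] = 0.0
        p.tonic_drift_uS_per_min["basic"] = 0.0
        p.skt_drift_C_per_min["basic"] = 0.0
        rec = simulate_recording(p, condition="basic")
        m = extract_condition_features(rec, WindowSpec(selection_count=1))
        row = m.iloc[0]
        assert row["MeanHRV"] == pytest.approx(800.0, abs=1.0)
        assert row["Mean_EDAT"] == pytest.approx(p.tonic_level_uS["basic"], rel=0.01)
        assert row["MeanSKT"] == pytest.approx(p.skt_base_C["basic"], abs=0.01)


class TestNormalization:
    def _frame(self, column):
        data = {name: np.linspace(0, 1, len(column)) for name in FEATURE_NAMES}
        data["MeanHRV"] = np.asarray(column, dtype=float)
        df = pd.DataFrame(data)
        df["subject_id"] = "S"
        df["condition"] = "basic"
        df["window_index"] = range(len(df))
        return df

    def test_linear_mapping(self):
        out, bounds = normalize_minmax(self._frame([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(out["MeanHRV"], [0.0, 0.5, 1.0])
        assert bounds.loc["min", "MeanHRV"] == 2.0
        assert bounds.loc["max", "MeanHRV"] == 6.0

    def test_unit_interval_column_unchanged(self):
        out, _ = normalize_minmax(self._frame([0.0, 0.25, 1.0]))
        np.testing.assert_allclose(out["MeanHRV"], [0.0, 0.25, 1.0])

    def test_constant_column_pinned_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out, _ = normalize_minmax(self._frame([5.0, 5.0, 5.0]))
        assert (out["MeanHRV"] == 0.5).all()

    def test_output_in_unit_interval(self, normalized_matrix):
        vals = normalized_matrix[FEATURE_NAMES].to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_round_trip_with_bounds(self):
        df = self._frame([2.0, 4.0, 6.0])
        out, bounds = normalize_minmax(df)
        from physioaffect.features import denormalize

        back = denormalize(out, bounds)
        np.testing.assert_allclose(back["MeanHRV"], df["MeanHRV"])
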