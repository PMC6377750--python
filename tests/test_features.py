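import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import taxograsp as tg
from taxograsp.features import (FeatureSpec, build_feature_table, mavs_series,
                                window_features)
from taxograsp.preprocessing import Window


def _win(x, **kw):
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    defaults = dict(t_start=0.0, grasp_id=1, repetition=1, subject_id="s",
                    modality="emg")
    defaults.update(kw)
    return Window(samples=x, **defaults)


class TestWindowFeatures:
    @pytest.mark.parametrize("x, family, expected", [
        ([0, 0, 0], "RMS", 0.0),
        ([0, 0, 0], "MAV", 0.0),
        ([0, 0, 0], "IAV", 0.0),
        ([0, 0, 0], "WL", 0.0),
        ([3, -4, 3], "RMS", np.sqrt(34 / 3)),
        ([3, -4, 3], "MAV", 10 / 3),
        ([3, -4, 3], "IAV", 10.0),
        ([3, -4, 3], "WL", 14.0),
        ([5, 5, 5, 5], "RMS", 5.0),
        ([5, 5, 5, 5], "MAV", 5.0),
        ([5, 5, 5, 5], "IAV", 20.0),
        ([5, 5, 5, 5], "WL", 0.0),
    ])
    def test_amplitude_families_hand_values(self, x, family, expected):
        got = window_features(_win(x), FeatureSpec(family))
        assert got[0] == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("x, zc, ssc", [
        ([3, -4, 3], 2, 1),
        ([5, 5, 5, 5], 0, 0),
        ([0, 0, 0], 0, 0),
        ([1, -1, 1, -1], 3, 2),
    ])
    def test_zc_ssc_counts(self, x, zc, ssc):
        td = window_features(_win(x), FeatureSpec("TD", zc_threshold=0.1,
                                                  ssc_threshold=0.1))
        # TD single-window components are [MAV, ZC, SSC, WL]
        assert td[0, 1] == zc
        assert td[0, 2] == ssc

    def test_zc_threshold_suppresses_small_crossings(self):
        x = [0.01, -0.01, 0.01]
        td0 = window_features(_win(x), FeatureSpec("TD", zc_threshold=0.0))
        td1 = window_features(_win(x), FeatureSpec("TD", zc_threshold=0.5))
        assert td0[0, 1] == 2 and td1[0, 1] == 0

    def test_zero_sample_breaks_strict_sign_change(self):
        # strict inequalities: a touch of zero is not a crossing
        x = [1.0, 0.0, -1.0]
        td = window_features(_win(x), FeatureSpec("TD"))
        assert td[0, 1] == 0

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            window_features(_win([1, 2]), FeatureSpec("RMS"))

    def test_depends_only_on_samples_not_metadata(self):
        a = window_features(_win([1, -2, 3], grasp_id=1), FeatureSpec("RMS"))
        b = window_features(_win([1, -2, 3], grasp_id=9, repetition=4,
                                 modality="glove"), FeatureSpec("RMS"))
        np.testing.assert_array_equal(a, b)

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_rms_dominates_mav(self, xs):
        w = _win(xs)
        rms = window_features(w, FeatureSpec("RMS"))[0]
        mav = window_features(w, FeatureSpec("MAV"))[0]
        assert rms >= mav - 1e-12


class TestMavsSeries:
    @pytest.mark.parametrize("series, expected", [
        ([2, 5, 4], [3, -1]),
        ([7, 7, 7], [0, 0]),
        ([0, 7], [7]),
    ])
    def test_hand_values(self, series, expected):
        np.testing.assert_allclose(mavs_series(np.array(series, float)),
                                   expected)

    def test_single_window_yields_empty(self):
        assert mavs_series(np.array([3.0])).size == 0


class TestBuildFeatureTable:
    def test_iav_equals_t_times_mav(self, quick_windows):
        emg = [w for w in quick_windows if w.modality == "emg"]
        t_iav = build_feature_table(emg, FeatureSpec("IAV"))
        t_mav = build_feature_table(emg, FeatureSpec("MAV"))
        T = emg[0].length
        np.testing.assert_allclose(t_iav.feature_matrix,
                                   T * t_mav.feature_matrix, rtol=1e-12)

    def test_simple_family_column_count(self, quick_windows):
        emg = [w for w in quick_windows if w.modality == "emg"]
        table = build_feature_table(emg, FeatureSpec("RMS"))
        assert table.data.shape[1] == 12

    def test_td_drops_last_window_per_repetition(self, quick_windows):
        emg = [w for w in quick_windows if w.modality == "emg"]
        td = build_feature_table(emg, FeatureSpec("TD"))
        rms = build_feature_table(emg, FeatureSpec("RMS"))
        n_segments = len({(w.grasp_id, w.repetition, w.segment) for w in emg})
        assert len(td) == len(rms) - n_segments
        assert td.data.shape[1] == 12 * 5
        assert np.isfinite(td.feature_matrix).all()

    def test_td_mavs_column_is_adjacent_mav_difference(self, quick_windows):
        emg = sorted((w for w in quick_windows if w.modality == "emg"),
                     key=lambda w: w.t_start)
        one_seg = [w for w in emg
                   if (w.grasp_id, w.repetition) == (emg[0].grasp_id,
                                                     emg[0].repetition)]
        td = build_feature_table(one_seg, FeatureSpec("TD"))
        mav = build_feature_table(one_seg, FeatureSpec("MAV"))
        expected = np.diff(mav.feature_matrix[:, 0])
        np.testing.assert_allclose(td.data["MAVS_ch00"].to_numpy(), expected,
                                   rtol=1e-12)

    def test_empty_window_list_rejected(self):
        with pytest.raises(ValueError):
            build_feature_table([], FeatureSpec("RMS"))

    def test_mixed_modalities_rejected(self, quick_windows):
        with pytest.raises(ValueError, match="one subject and one modality"):
            build_feature_table(quick_windows, FeatureSpec("RMS"))
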