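import numpy as np
import pytest
from scipy.signal import periodogram

import taxograsp as tg
from taxograsp.preprocessing import (hampel_powerline_filter, segment_windows,
                                     synchronize)


class TestHampelPowerline:
    fs = 2000.0

    def test_removes_50hz_line_by_20db(self, rng):
        t = np.arange(int(10 * self.fs)) / self.fs
        x = np.sin(2 * np.pi * 50 * t) + 0.01 * rng.standard_normal(t.size)
        y = hampel_powerline_filter(x, self.fs)
        f, p_before = periodogram(x, fs=self.fs)
        _, p_after = periodogram(y, fs=self.fs)
        band = np.abs(f - 50) <= 1
        reduction_db = 10 * np.log10(p_before[band].sum() / p_after[band].sum())
        assert reduction_db >= 20

    def test_zero_in_zero_out(self):
        x = np.zeros(4000)
        assert np.allclose(hampel_powerline_filter(x, self.fs), 0.0)

    def test_clean_broadband_left_untouched(self, rng):
        x = rng.standard_normal(int(10 * self.fs))
        y = hampel_powerline_filter(x, self.fs)
        p_x = np.mean(x ** 2)
        p_y = np.mean(y ** 2)
        assert abs(p_y - p_x) / p_x < 0.01

    def test_rejects_low_sampling_rate(self):
        with pytest.raises(ValueError):
            hampel_powerline_filter(np.zeros(100), fs=80.0, target_hz=50.0)

    def test_multichannel_shape_preserved(self, rng):
        x = rng.standard_normal((4000, 3))
        y = hampel_powerline_filter(x, self.fs)
        assert y.shape == x.shape


class TestSynchronize:
    def _recording(self, emg_n=2000, glove_n=25):
        return tg.SignalRecording(
            subject_id="s", emg=np.zeros((emg_n, 2)),
            glove=np.linspace(0, 1, glove_n)[:, None] * np.ones((1, 3)),
            stimulus=np.r_[np.zeros(emg_n // 2), np.ones(emg_n - emg_n // 2)],
            repetition=np.r_[np.zeros(emg_n // 2), np.ones(emg_n - emg_n // 2)],
            fs_emg=2000.0, fs_glove=25.0,
        )

    def test_linear_ramp_upsampled_exactly(self):
        rec = self._recording()
        out = synchronize(rec)
        # glove channel is linear in time; linear interpolation is exact
        t = out.timestamps_glove
        t_g = rec.timestamps_glove
        expected = (t - t_g[0]) / (t_g[-1] - t_g[0])
        inside = (t >= t_g[0]) & (t <= t_g[-1])
        np.testing.assert_allclose(out.glove[inside, 0], expected[inside],
                                   atol=1e-12)

    def test_on_grid_modality_passed_through_bit_identical(self):
        rec = self._recording()
        out = synchronize(rec, target_fs=2000.0)
        assert out.emg is rec.emg
        np.testing.assert_array_equal(out.stimulus, rec.stimulus)

    def test_constant_channel_stays_constant(self):
        rec = self._recording()
        rec.glove[:, 1] = 7.0
        out = synchronize(rec)
        np.testing.assert_allclose(out.glove[:, 1], 7.0)

    def test_sine_interpolation_error_small(self):
        # 1 Hz sine sampled at 25 Hz, upsampled to 2 kHz
        n_g = 251
        ts_g = np.arange(n_g) / 25.0
        n_e = int(ts_g[-1] * 2000) + 1
        rec = tg.SignalRecording(
            subject_id="s", emg=np.zeros((n_e, 1)),
            glove=np.sin(2 * np.pi * 1.0 * ts_g)[:, None],
            stimulus=np.zeros(n_e), repetition=np.zeros(n_e),
            fs_emg=2000.0, fs_glove=25.0,
        )
        out = synchronize(rec)
        expected = np.sin(2 * np.pi * 1.0 * out.timestamps_glove)
        assert np.max(np.abs(out.glove[:, 0] - expected)) < 0.01

    def test_non_monotonic_timestamps_rejected(self):
        rec = self._recording()
        rec.timestamps_glove[3] = rec.timestamps_glove[2]
        with pytest.raises(ValueError, match="increasing"):
            synchronize(rec)

    def test_labels_nearest_neighbor_not_interpolated(self):
        rec = self._recording()
        rec.fs_emg = 1000.0  # force resampling of the label stream
        rec.timestamps_emg = np.arange(rec.emg.shape[0]) / 1000.0
        out = synchronize(rec, target_fs=2000.0)
        assert set(np.unique(out.stimulus)) <= {0, 1}


class TestSegmentWindows:
    def _synced(self, seg_samples, fs=2000.0, n_rep=1):
        blocks = []
        stim = []
        rep = []
        for r in range(1, n_rep + 1):
            blocks.append(np.zeros((200, 2)))
            stim += [0] * 200
            rep += [0] * 200
            blocks.append(np.ones((seg_samples, 2)))
            stim += [1] * seg_samples
            rep += [r] * seg_samples
        sig = np.vstack(blocks)
        return tg.SignalRecording(
            subject_id="s", emg=sig, glove=np.hstack([sig, sig]),
            stimulus=stim, repetition=rep, fs_emg=fs, fs_glove=fs,
        )

    def test_window_count_5s_segment(self, small_grasp_set):
        rec = self._synced(10_000)
        wins = [w for w in segment_windows(rec, 200, 100, small_grasp_set)
                if w.modality == "emg"]
        assert len(wins) == 49  # floor((10000 - 400) / 200) + 1
        assert all(w.length == 400 for w in wins)

    def test_short_segment_yields_no_windows(self, small_grasp_set):
        rec = self._synced(300)
        assert segment_windows(rec, 200, 100, small_grasp_set) == []

    def test_windows_never_mix_repetitions(self, small_grasp_set):
        rec = self._synced(2000, n_rep=2)
        wins = segment_windows(rec, 200, 100, small_grasp_set)
        for w in wins:
            lo = int(w.t_start * rec.fs_emg)
            seg = rec.repetition[lo:lo + w.length]
            assert len(set(seg)) == 1
            assert seg[0] == w.repetition

    def test_rest_excluded_and_equal_lengths(self, quick_windows):
        assert all(w.grasp_id != 0 for w in quick_windows)
        assert len({w.length for w in quick_windows}) == 1

    def test_overlap_must_be_smaller_than_window(self, small_grasp_set):
        rec = self._synced(1000)
        with pytest.raises(ValueError):
            segment_windows(rec, 200, 200, small_grasp_set)

    def test_unsynchronized_recording_rejected(self, quick_recording,
                                               small_grasp_set):
        with pytest.raises(ValueError, match="synchron"):
            segment_windows(quick_recording, 200, 100, small_grasp_set)
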