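"""Power-line removal, timestamp-based synchronization and windowing.

The preprocessing chain mirrors standard practice for unshielded surface
EMG electrodes: 50 Hz interference is removed with a Hampel identifier on
the short-time spectrum, then all modalities are brought onto the time
grid of the fastest device (2 kHz) by linear interpolation against their
per-sample timestamps, and finally each movement repetition is cut into
overlapping fixed-length windows (200 ms window, 100 ms overlap by
default).  Rest samples (stimulus 0) never enter windows, and no window
straddles a repetition boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

from .io_formats import GraspSet, SignalRecording

__all__ = ["Window", "hampel_powerline_filter", "synchronize", "segment_windows"]


@dataclass
class Window:
    """One fixed-length window of one modality, tagged with its labels."""

    samples: np.ndarray  # (T, channels)
    t_start: float
    grasp_id: int
    repetition: int
    subject_id: str
    modality: str
    segment: int = 0  # index of the contiguous (grasp, repetition) run

    @property
    def length(self) -> int:
        return self.samples.shape[0]


def hampel_powerline_filter(signal: np.ndarray, fs: float, target_hz: float = 50.0,
                            *, n_sigma: float = 3.0, band_hz: float = 1.0,
                            window_s: float = 1.0, harmonics: bool = False,
                            ref_hz: float = 10.0) -> np.ndarray:
    """Remove narrow-band power-line interference with a spectral Hampel filter.

    The short-time Fourier magnitude is inspected frame by frame: bins
    within ``band_hz`` of ``target_hz`` whose magnitude exceeds the median
    of the surrounding ``ref_hz`` neighbourhood by more than
    ``n_sigma`` robust standard deviations (1.4826 x MAD) are replaced by
    that median magnitude, keeping the phase.  Bins that are not outliers
    — i.e. when no line is present — are left untouched, so broadband
    content passes through up to reconstruction tolerance.

    Parameters
    ----------
    signal : (n,) or (n, channels) array
    fs : sampling rate in Hz; must exceed ``2 * target_hz``
    harmonics : if True, also clean integer harmonics of ``target_hz``
    """
    if fs <= 2 * target_hz:
        raise ValueError(f"fs={fs} must exceed twice the target frequency {target_hz}")
    x = np.asarray(signal, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    nperseg = min(int(round(window_s * fs)), n)
    hop = max(nperseg // 2, 1)
    sft = ShortTimeFFT(hann(nperseg, sym=False), hop=hop, fs=fs)
    freqs = sft.f

    targets = [target_hz]
    if harmonics:
        h = 2
        while h * target_hz < fs / 2:
            targets.append(h * target_hz)
            h += 1

    out = np.empty_like(x)
    for ch in range(x.shape[1]):
        spec = sft.stft(x[:, ch])
        mag = np.abs(spec)
        for f0 in targets:
            band = np.abs(freqs - f0) <= band_hz
            ref = (np.abs(freqs - f0) <= ref_hz) & ~band
            if not band.any() or not ref.any():
                continue
            med = np.median(mag[ref], axis=0)
            mad = np.median(np.abs(mag[ref] - med[None, :]), axis=0)
            thresh = med + n_sigma * 1.4826 * mad
            bad = mag[band] > thresh[None, :]
            scale = np.ones_like(mag[band])
            nz = mag[band] > 0
            scale[bad & nz] = (np.broadcast_to(med, mag[band].shape)[bad & nz]
                               / mag[band][bad & nz])
            rows = np.where(band)[0]
            spec[rows] = spec[rows] * scale
            mag[rows] = mag[rows] * scale
        out[:, ch] = sft.istft(spec, k1=n)
    return out[:, 0] if squeeze else out


def synchronize(recording: SignalRecording, target_fs: float = 2000.0) -> SignalRecording:
    """Bring all modalities onto one common time grid at ``target_fs``.

    Signal channels are linearly interpolated against their timestamps;
    the label streams (stimulus, repetition) are resampled by
    nearest-neighbour so labels are never interpolated.  A modality whose
    samples already sit on the target grid is passed through bit-identical.
    """
    rec = recording
    for name, ts in (("timestamps_emg", rec.timestamps_emg),
                     ("timestamps_glove", rec.timestamps_glove)):
        if ts.size > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError(f"{name} not strictly increasing")

    t0 = min(rec.timestamps_emg[0], rec.timestamps_glove[0])
    t1 = max(rec.timestamps_emg[-1], rec.timestamps_glove[-1])
    n_grid = int(np.floor((t1 - t0) * target_fs)) + 1
    grid = t0 + np.arange(n_grid) / target_fs

    def on_grid(ts):
        return ts.shape[0] == n_grid and np.array_equal(ts, grid)

    if on_grid(rec.timestamps_emg):
        emg, stim, rep = rec.emg, rec.stimulus, rec.repetition
    else:
        emg = np.column_stack([
            np.interp(grid, rec.timestamps_emg, rec.emg[:, c])
            for c in range(rec.emg.shape[1])
        ])
        nn = np.searchsorted(rec.timestamps_emg, grid)
        nn = np.clip(nn, 1, rec.timestamps_emg.size - 1)
        left = rec.timestamps_emg[nn - 1]
        right = rec.timestamps_emg[nn]
        nn = np.where(grid - left <= right - grid, nn - 1, nn)
        stim = rec.stimulus[nn]
        rep = rec.repetition[nn]

    if on_grid(rec.timestamps_glove):
        glove = rec.glove
    else:
        glove = np.column_stack([
            np.interp(grid, rec.timestamps_glove, rec.glove[:, c])
            for c in range(rec.glove.shape[1])
        ])

    return SignalRecording(
        subject_id=rec.subject_id,
        emg=emg,
        glove=glove,
        stimulus=stim,
        repetition=rep,
        timestamps_emg=grid,
        timestamps_glove=grid,
        fs_emg=target_fs,
        fs_glove=target_fs,
    )


def segment_windows(recording: SignalRecording, window_ms: float = 200.0,
                    overlap_ms: float = 100.0, grasp_set: GraspSet = None,
                    modalities=("emg", "glove")) -> list:
    """Cut each (grasp, repetition) run into equal-length overlapping windows.

    The recording must be synchronized (both modalities on one grid).
    Windows are taken strictly inside contiguous runs of constant
    (stimulus, repetition) with stimulus in the grasp set, so rest samples
    and repetition boundaries never enter a window.  The stride is
    ``window_ms - overlap_ms`` and trailing partial windows are dropped,
    so every window has the same sample count T.  A run shorter than one
    window yields no windows.
    """
    if window_ms <= overlap_ms:
        raise ValueError("window_ms must exceed overlap_ms")
    rec = recording
    if rec.glove.shape[0] != rec.emg.shape[0]:
        raise ValueError("recording is not synchronized (modal lengths differ); "
                         "run synchronize() first")
    fs = rec.fs_emg
    T = int(round(window_ms * fs / 1000.0))
    stride = int(round((window_ms - overlap_ms) * fs / 1000.0))
    if T < 1 or stride < 1:
        raise ValueError("window/stride shorter than one sample at this rate")
    wanted = set(grasp_set.grasp_ids) if grasp_set is not None else None

    # contiguous runs of constant (stimulus, repetition)
    change = np.flatnonzero(
        (np.diff(rec.stimulus) != 0) | (np.diff(rec.repetition) != 0)
    ) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [rec.stimulus.size]])

    signals = {"emg": rec.emg, "glove": rec.glove}
    windows: list = []
    segment = 0
    for s, e in zip(starts, ends):
        gid = int(rec.stimulus[s])
        rep = int(rec.repetition[s])
        if gid == 0 or (wanted is not None and gid not in wanted):
            continue
        n = e - s
        n_win = (n - T) // stride + 1 if n >= T else 0
        for modality in modalities:
            sig = signals[modality]
            for w in range(n_win):
                a = s + w * stride
                windows.append(Window(
                    samples=sig[a:a + T],
                    t_start=float(rec.timestamps_emg[a]),
                    grasp_id=gid,
                    repetition=rep,
                    subject_id=rec.subject_id,
                    modality=modality,
                    segment=segment,
                ))
        segment += 1
    return windows
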