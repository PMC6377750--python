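"""Time-domain feature families computed per window and per channel.

Five families are supported, the standard amplitude/complexity statistics
of windowed surface-EMG analysis, applied identically to glove channels:

* ``RMS``  — root mean square, sqrt(sum(x_t^2)/T)
* ``MAV``  — mean absolute value, sum(|x_t|)/T
* ``IAV``  — integrated absolute value, sum(|x_t|)  (= T * MAV for the
  equal-length windows this pipeline produces)
* ``WL``   — waveform length, sum_{t>=2} |x_t - x_{t-1}|
* ``TD``   — the time-domain statistics set {MAV, MAVS, ZC, SSC, WL},
  where MAVS is the MAV difference between adjacent windows of one
  repetition, ZC counts strict sign changes between consecutive samples
  with |x_t - x_{t+1}| at or above a threshold, and SSC counts strict
  local extrema with at least one adjacent difference at or above a
  threshold.

Because MAVS needs the *next* window, TD feature rows are assembled by
:func:`build_feature_table`, which drops the last window of every
repetition so each retained row is complete.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import Window

__all__ = [
    "FAMILIES", "TD_COMPONENTS", "FeatureSpec", "FeatureTable",
    "rms", "mav", "iav", "waveform_length", "zero_crossings",
    "slope_sign_changes", "window_features", "mavs_series",
    "build_feature_table",
]

FAMILIES = ("RMS", "MAV", "IAV", "TD", "WL")
TD_COMPONENTS = ("MAV", "MAVS", "ZC", "SSC", "WL")
META_COLUMNS = ("subject", "modality", "family", "grasp", "repetition", "segment")


@dataclass(frozen=True)
class FeatureSpec:
    family: str = "RMS"
    zc_threshold: float = 0.0
    ssc_threshold: float = 0.0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if self.zc_threshold < 0 or self.ssc_threshold < 0:
            raise ValueError("thresholds must be >= 0")


# -- primitives -------------------------------------------------------------
# Each accepts samples shaped (..., T, C) and reduces over the T axis.

def rms(x: np.ndarray) -> np.ndarray:
    return np.sqrt(np.mean(np.square(x), axis=-2))


def mav(x: np.ndarray) -> np.ndarray:
    return np.mean(np.abs(x), axis=-2)


def iav(x: np.ndarray) -> np.ndarray:
    return np.sum(np.abs(x), axis=-2)


def waveform_length(x: np.ndarray) -> np.ndarray:
    return np.sum(np.abs(np.diff(x, axis=-2)), axis=-2)


def zero_crossings(x: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    a = x[..., :-1, :]
    b = x[..., 1:, :]
    crossing = ((a > 0) & (b < 0)) | ((a < 0) & (b > 0))
    big = np.abs(a - b) >= threshold
    return np.sum(crossing & big, axis=-2)


def slope_sign_changes(x: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    prev = x[..., :-2, :]
    mid = x[..., 1:-1, :]
    nxt = x[..., 2:, :]
    extremum = ((mid > prev) & (mid > nxt)) | ((mid < prev) & (mid < nxt))
    big = (np.abs(mid - nxt) >= threshold) | (np.abs(mid - prev) >= threshold)
    return np.sum(extremum & big, axis=-2)


def window_features(window: Window, spec: FeatureSpec) -> np.ndarray:
    """Feature vector for one window.

    For RMS/MAV/IAV/WL the result has one value per channel.  For TD the
    result is a (channels, 4) array of the single-window components
    [MAV, ZC, SSC, WL]; the two-window MAVS component is assembled at
    table level by :func:`build_feature_table`.
    """
    x = np.asarray(window.samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 3:
        raise ValueError(f"window has T={x.shape[0]} < 3 samples")
    if spec.family == "RMS":
        return rms(x)
    if spec.family == "MAV":
        return mav(x)
    if spec.family == "IAV":
        return iav(x)
    if spec.family == "WL":
        return waveform_length(x)
    return np.stack([
        mav(x),
        zero_crossings(x, spec.zc_threshold),
        slope_sign_changes(x, spec.ssc_threshold),
        waveform_length(x),
    ], axis=-1)


def mavs_series(mav_per_window: np.ndarray) -> np.ndarray:
    """MAV slope across consecutive windows of one repetition segment.

    Input is the MAV series over the segment's windows (length n, possibly
    per channel); output has length n - 1.  A single-window segment yields
    an empty series.
    """
    m = np.asarray(mav_per_window, dtype=float)
    if m.shape[0] < 2:
        return np.empty((0,) + m.shape[1:])
    return np.diff(m, axis=0)


class FeatureTable:
    """Windowed feature vectors with their grouping metadata.

    ``data`` holds one row per window and one column per channel (x TD
    component), ``meta`` the aligned subject/modality/family/grasp/
    repetition/segment labels.
    """

    def __init__(self, data: pd.DataFrame, meta: pd.DataFrame):
        if len(data) != len(meta):
            raise ValueError("data and meta must have equal row counts")
        if not np.isfinite(data.to_numpy()).all():
            raise ValueError("feature table contains non-finite values")
        self.data = data.reset_index(drop=True)
        self.meta = meta.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def family(self) -> str:
        return self.meta["family"].iloc[0]

    @property
    def feature_matrix(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def grasp_ids(self) -> np.ndarray:
        return self.meta["grasp"].to_numpy(dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.meta, self.data], axis=1)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_feature_table(windows, spec: FeatureSpec) -> FeatureTable:
    """Compute a :class:`FeatureTable` for one subject/modality and one family.

    Windows are grouped by (grasp, repetition, segment); within a group
    they are assumed consecutive in time (as produced by
    ``segment_windows``).  For the TD family, each row stacks the
    components [MAV, MAVS, ZC, SSC, WL] per channel and the last window of
    every group is dropped so the MAVS column is defined for every row.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("empty window list")
    subjects = {w.subject_id for w in windows}
    modalities = {w.modality for w in windows}
    if len(subjects) > 1 or len(modalities) > 1:
        raise ValueError("windows must come from one subject and one modality")
    lengths = {w.length for w in windows}
    if len(lengths) > 1:
        raise ValueError(f"windows have unequal lengths {sorted(lengths)}")

    X = np.stack([np.asarray(w.samples, dtype=float) for w in windows])  # (n, T, C)
    if X.ndim == 2:
        X = X[:, :, None]
    n, T, C = X.shape
    if T < 3:
        raise ValueError(f"windows have T={T} < 3 samples")
    meta = pd.DataFrame({
        "subject": [w.subject_id for w in windows],
        "modality": [w.modality for w in windows],
        "family": spec.family,
        "grasp": [w.grasp_id for w in windows],
        "repetition": [w.repetition for w in windows],
        "segment": [w.segment for w in windows],
    })

    ch = [f"ch{c:02d}" for c in range(C)]
    if spec.family in ("RMS", "MAV", "IAV", "WL"):
        fn = {"RMS": rms, "MAV": mav, "IAV": iav, "WL": waveform_length}[spec.family]
        data = pd.DataFrame(fn(X), columns=[f"{spec.family}_{c}" for c in ch])
        return FeatureTable(data, meta)

    # TD: per-channel [MAV, MAVS, ZC, SSC, WL]; MAVS via within-group diff
    mav_all = mav(X)
    zc_all = zero_crossings(X, spec.zc_threshold)
    ssc_all = slope_sign_changes(X, spec.ssc_threshold)
    wl_all = waveform_length(X)

    keep_rows = []
    mavs_rows = np.zeros_like(mav_all)
    group_key = meta[["grasp", "repetition", "segment"]].apply(tuple, axis=1)
    for _, idx in meta.groupby(group_key, sort=False).groups.items():
        idx = np.asarray(idx)
        if idx.size < 2:
            continue  # single-window segment: no MAVS, row dropped
        mavs_rows[idx[:-1]] = mavs_series(mav_all[idx])
        keep_rows.extend(idx[:-1])
    if not keep_rows:
        raise ValueError("no TD rows remain after MAVS boundary handling")
    keep_rows = np.asarray(keep_rows)

    blocks = {"MAV": mav_all, "MAVS": mavs_rows, "ZC": zc_all, "SSC": ssc_all,
              "WL": wl_all}
    cols = {}
    for c, cname in enumerate(ch):
        for comp in TD_COMPONENTS:
            cols[f"{comp}_{cname}"] = blocks[comp][keep_rows, c]
    data = pd.DataFrame(cols)
    return FeatureTable(data, meta.iloc[keep_rows])
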