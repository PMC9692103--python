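"""NN-interval construction and HRV-based SQIs.

Beat-to-beat (NN) intervals are derived from detected peak indices;
ectopic/false intervals can be removed before the HRV statistics. On a
poor-quality segment false peaks inflate the interval variability, which
is what makes SDNN/RMSSD-family statistics useful as quality indices.

Conventions: sample (n−1) standard deviations for SDNN/SDSD; pNN50/pNN20
denominators are the number of successive differences; frequency-domain
powers integrate a Welch PSD of the cubic-interpolated 4-Hz tachogram
over the Task-Force bands VLF [0.003, 0.04), LF [0.04, 0.15),
HF [0.15, 0.4) Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import interp1d

from ..errors import InputError
from ..peaks import PeakAnnotation

__all__ = [
    "NNIntervalSeries",
    "nn_intervals",
    "hrv_time_sqi",
    "hrv_freq_sqi",
    "ectopic_sqi",
    "HRV_TIME_KEYS",
    "HRV_FREQ_KEYS",
]

HRV_TIME_KEYS = ("mean_nni", "sdnn", "sdsd", "rmssd", "cvsd", "cvnni",
                 "pnn_50", "pnn_20", "hr_mean", "hr_std", "hr_min", "hr_max")
HRV_FREQ_KEYS = ("vlf", "lf", "hf", "lf_hf_ratio", "total_power")

FREQ_BANDS = {"vlf": (0.003, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.4)}


@dataclass
class NNIntervalSeries:
    """Beat-to-beat intervals in milliseconds after ectopic filtering."""

    intervals_ms: np.ndarray
    source_peaks: np.ndarray = field(default_factory=lambda: np.array([], int))
    n_removed_ectopic: int = 0

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        if np.any(self.intervals_ms <= 0):
            raise InputError("all NN intervals must be > 0")

    @property
    def n_intervals(self) -> int:
        return int(self.intervals_ms.size)

    @property
    def span_s(self) -> float:
        return float(np.sum(self.intervals_ms)) / 1000.0


def _malik_flags(intervals: np.ndarray) -> np.ndarray:
    """Malik rule: flag intervals differing from the last *retained*
    interval by more than 20%."""
    flags = np.zeros(intervals.size, dtype=bool)
    if intervals.size == 0:
        return flags
    ref = intervals[0]
    for i in range(1, intervals.size):
        if abs(intervals[i] - ref) > 0.2 * ref:
            flags[i] = True
        else:
            ref = intervals[i]
    return flags


def _median_flags(intervals: np.ndarray, window: int = 5,
                  tol: float = 0.3) -> np.ndarray:
    flags = np.zeros(intervals.size, dtype=bool)
    half = window // 2
    for i in range(intervals.size):
        lo, hi = max(0, i - half), min(intervals.size, i + half + 1)
        med = float(np.median(intervals[lo:hi]))
        if med > 0 and abs(intervals[i] - med) > tol * med:
            flags[i] = True
    return flags


def nn_intervals(peaks: PeakAnnotation | np.ndarray, rate: float,
                 ectopic_rule: str = "malik") -> NNIntervalSeries:
    """Successive peak-index differences in ms, with ectopic removal.

    ``malik`` removes intervals deviating > 20% from the last retained
    interval; ``median`` removes intervals deviating > 30% from the
    running median of 5; ``none`` keeps everything.
    """
    idx = peaks.peak_indices if isinstance(peaks, PeakAnnotation) else np.asarray(peaks)
    idx = np.asarray(idx, dtype=float)
    if idx.size < 3:
        raise InputError(f"need >= 3 peaks for NN intervals, got {idx.size}")
    intervals = np.diff(idx) / rate * 1000.0
    if np.any(intervals <= 0):
        raise InputError("peak indices must be strictly increasing")
    if ectopic_rule == "none":
        flags = np.zeros(intervals.size, dtype=bool)
    elif ectopic_rule == "malik":
        flags = _malik_flags(intervals)
    elif ectopic_rule == "median":
        flags = _median_flags(intervals)
    else:
        raise InputError(f"unknown ectopic rule {ectopic_rule!r}")
    return NNIntervalSeries(intervals[~flags], idx.astype(int),
                            int(flags.sum()))


def ectopic_sqi(nn_raw: NNIntervalSeries | np.ndarray) -> float:
    """Fraction of raw intervals flagged ectopic by the Malik rule."""
    intervals = (nn_raw.intervals_ms if isinstance(nn_raw, NNIntervalSeries)
                 else np.asarray(nn_raw, dtype=float))
    if intervals.size < 3:
        raise InputError("need >= 3 raw intervals")
    flags = _malik_flags(intervals)
    return float(np.mean(flags))


def hrv_time_sqi(nn: NNIntervalSeries | np.ndarray) -> dict[str, float]:
    """Time-domain HRV map: mean NN, SDNN, SDSD, RMSSD, CV forms,
    pNN50/pNN20 and heart-rate summaries."""
    intervals = (nn.intervals_ms if isinstance(nn, NNIntervalSeries)
                 else np.asarray(nn, dtype=float))
    out = {k: float("nan") for k in HRV_TIME_KEYS}
    n = intervals.size
    if n < 2:
        return out
    mean_nni = float(np.mean(intervals))
    out["mean_nni"] = mean_nni
    out["sdnn"] = float(np.std(intervals, ddof=1))
    hr = 60000.0 / intervals
    out["hr_mean"] = float(np.mean(hr))
    out["hr_std"] = float(np.std(hr, ddof=1))
    out["hr_min"] = float(np.min(hr))
    out["hr_max"] = float(np.max(hr))
    out["cvnni"] = out["sdnn"] / mean_nni if mean_nni else float("nan")
    if n >= 3:
        d = np.diff(intervals)
        out["rmssd"] = float(np.sqrt(np.mean(d ** 2)))
        out["sdsd"] = float(np.std(d, ddof=1)) if d.size >= 2 else float("nan")
        out["cvsd"] = out["rmssd"] / mean_nni if mean_nni else float("nan")
        out["pnn_50"] = float(np.mean(np.abs(d) > 50.0))
        out["pnn_20"] = float(np.mean(np.abs(d) > 20.0))
    return out


def hrv_freq_sqi(nn: NNIntervalSeries | np.ndarray,
                 interp_rate: float = 4.0) -> dict[str, float]:
    """Frequency-domain HRV from the evenly resampled tachogram.

    Requires the NN series to span at least 60 s; shorter input yields
    an all-nan map (LF resolution is meaningless below that).
    """
    intervals = (nn.intervals_ms if isinstance(nn, NNIntervalSeries)
                 else np.asarray(nn, dtype=float))
    out = {k: float("nan") for k in HRV_FREQ_KEYS}
    if intervals.size < 4:
        return out
    t = np.cumsum(intervals) / 1000.0  # beat times, s
    span = t[-1] - t[0]
    if span < 60.0:
        return out
    grid = np.arange(t[0], t[-1], 1.0 / interp_rate)
    tach = interp1d(t, intervals, kind="cubic")(grid)
    nperseg = min(tach.size, int(256 * interp_rate / 4.0))
    freqs, psd = sps.welch(tach - np.mean(tach), fs=interp_rate,
                           nperseg=nperseg, noverlap=nperseg // 2,
                           detrend="constant")
    df = freqs[1] - freqs[0] if freqs.size > 1 else 0.0
    for name, (lo, hi) in FREQ_BANDS.items():
        out[name] = float(psd[(freqs >= lo) & (freqs < hi)].sum() * df)
    out["total_power"] = float(psd[freqs >= FREQ_BANDS["vlf"][0]].sum() * df)
    out["lf_hf_ratio"] = out["lf"] / out["hf"] if out["hf"] > 0 else float("nan")
    return out
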