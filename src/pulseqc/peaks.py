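"""Peak/trough detection and beat extraction for ECG and PPG.

Seven deterministic detectors are provided, selected by integer id:

1. ``adaptive_threshold`` — local maxima above a fraction of a decaying
   running maximum (threshold tracks signal amplitude, so the detector
   is invariant to positive rescaling).
2. ``count_origin`` — candidate local maxima validated by the length of
   the monotone ascent/descent runs flanking them.
3. ``clustering`` — a deterministic 2-means split of local-extremum
   amplitudes (initialised at min/max); the upper cluster are peaks.
4. ``slope_sum`` — windowed sum of positive slopes with an adaptive
   threshold and local search-back to the waveform maximum.
5. ``moving_average`` — two moving averages of the clipped-squared
   signal (beat-scale vs segment-scale) define blocks of interest whose
   maxima are peaks. Default detector for PPG.
6. ``scipy_find_peaks`` — prominence + minimum-distance constraints.
7. ``billauer`` — alternating max/min tracking with a lookahead delta.

For ECG the signal is first passed through a squared-derivative
transform (band-pass 5–15 Hz, differentiate, square, moving-window
integrate) so that QRS energy dominates before block detection; detected
block peaks are then refined to the R-wave maximum of the filtered ECG.

All detectors enforce a refractory period (default 0.3 s, a 200 bpm
ceiling): of two candidates closer than that, the larger survives.
Ties in amplitude are broken toward the earliest index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d, uniform_filter1d

from .containers import Segment, SignalType
from .errors import ConfigurationError, InputError

__all__ = [
    "PeakAnnotation",
    "detect_peaks",
    "detect_troughs",
    "extract_beats",
    "DETECTOR_NAMES",
    "DEFAULT_DETECTOR",
]

logger = logging.getLogger(__name__)

DETECTOR_NAMES = {
    1: "adaptive_threshold",
    2: "count_origin",
    3: "clustering",
    4: "slope_sum",
    5: "moving_average",
    6: "scipy_find_peaks",
    7: "billauer",
}

DEFAULT_DETECTOR = 5
DEFAULT_REFRACTORY_S = 0.3


@dataclass
class PeakAnnotation:
    """Detector output: peak and trough sample indices (segment-local)."""

    peak_indices: np.ndarray
    trough_indices: np.ndarray
    detector_id: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        self.trough_indices = np.asarray(self.trough_indices, dtype=int)
        for idx in (self.peak_indices, self.trough_indices):
            if idx.size > 1 and not np.all(np.diff(idx) > 0):
                raise InputError("annotation indices must be strictly increasing")

    @property
    def n_peaks(self) -> int:
        return int(self.peak_indices.size)


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices i with x[i-1] < x[i] >= x[i+1] (earliest of a plateau)."""
    if x.size < 3:
        return np.array([], dtype=int)
    return np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])) + 1


def _local_minima(x: np.ndarray) -> np.ndarray:
    return _local_maxima(-x)


def _enforce_refractory(x: np.ndarray, cand: np.ndarray, min_dist: int) -> np.ndarray:
    """Greedy minimum-distance pruning, keeping larger amplitudes first."""
    if cand.size <= 1:
        return cand
    # sort by (-amplitude, index): larger first, earlier wins ties
    order = np.lexsort((cand, -x[cand]))
    kept: list[int] = []
    for i in order:
        c = cand[i]
        if all(abs(c - k) >= min_dist for k in kept):
            kept.append(c)
    return np.array(sorted(kept), dtype=int)


# --- detector implementations (each returns candidate peak indices) -----

def _det_adaptive_threshold(x: np.ndarray, rate: float, frac: float = 0.5,
                            decay_s: float = 2.0) -> np.ndarray:
    maxima = _local_maxima(x)
    if maxima.size == 0:
        return maxima
    floor = float(np.median(x))  # robust baseline
    env = np.max(x) - floor
    if env <= 0:
        return np.array([], dtype=int)
    out = []
    running = 0.0
    last_t = None
    for m in maxima:
        amp = x[m] - floor
        if amp <= 0:
            continue
        if last_t is not None:
            running *= np.exp(-(m - last_t) / (decay_s * rate))
        if amp >= frac * max(running, 0.3 * env):
            out.append(m)
            running = max(running, amp)
            last_t = m
    return np.array(out, dtype=int)


def _det_count_origin(x: np.ndarray, rate: float, min_run_s: float = 0.04,
                      pre_smooth_s: float = 0.05) -> np.ndarray:
    w = max(1, int(round(pre_smooth_s * rate)))
    xs = uniform_filter1d(x, w, mode="nearest") if w > 1 else x
    maxima = _local_maxima(xs)
    min_run = max(2, int(round(min_run_s * rate)))
    d = np.diff(xs)
    out = []
    for m in maxima:
        up = 0
        i = m - 1
        while i >= 0 and d[i] > 0:
            up += 1
            i -= 1
        down = 0
        i = m
        while i < d.size and d[i] < 0:
            down += 1
            i += 1
        if up >= min_run and down >= min_run:
            out.append(m)
    return np.array(out, dtype=int)


def _det_clustering(x: np.ndarray, rate: float, max_iter: int = 50) -> np.ndarray:
    maxima = _local_maxima(x)
    if maxima.size == 0:
        return maxima
    amps = x[maxima]
    lo, hi = float(np.min(amps)), float(np.max(amps))
    if hi == lo:
        return maxima
    # deterministic 2-means on amplitude, centroids seeded at min/max
    c0, c1 = lo, hi
    for _ in range(max_iter):
        upper = np.abs(amps - c1) < np.abs(amps - c0)
        if upper.all() or not upper.any():
            break
        n0, n1 = np.mean(amps[~upper]), np.mean(amps[upper])
        if n0 == c0 and n1 == c1:
            break
        c0, c1 = n0, n1
    upper = np.abs(amps - c1) < np.abs(amps - c0)
    return maxima[upper]


def _slope_sum_function(x: np.ndarray, rate: float, win_s: float = 0.128
                        ) -> np.ndarray:
    dx = np.diff(x, prepend=x[0])
    pos = np.where(dx > 0, dx, 0.0)
    w = max(1, int(round(win_s * rate)))
    return np.convolve(pos, np.ones(w), mode="full")[: x.size]


def _det_slope_sum(x: np.ndarray, rate: float, win_s: float = 0.128,
                   thresh_frac: float = 0.5, search_back_s: float = 0.15
                   ) -> np.ndarray:
    ssf = _slope_sum_function(x, rate, win_s)
    if np.max(ssf) <= 0:
        return np.array([], dtype=int)
    # adaptive threshold: fraction of the local (±2 s window) SSF maximum
    local_max = maximum_filter1d(ssf, size=max(3, int(4 * rate)), mode="nearest")
    cand = _local_maxima(ssf)
    cand = cand[ssf[cand] >= thresh_frac * local_max[cand]]
    # search back/forward to the waveform maximum near the SSF onset
    k = max(1, int(round(search_back_s * rate)))
    out = []
    for c in cand:
        lo, hi = max(0, c - k), min(x.size, c + k + 1)
        out.append(lo + int(np.argmax(x[lo:hi])))
    return np.unique(np.array(out, dtype=int))


def _det_moving_average(x: np.ndarray, rate: float, w_peak_s: float = 0.111,
                        w_beat_s: float = 0.667, beta: float = 0.1
                        ) -> np.ndarray:
    # two-moving-average block detection on the clipped, squared signal
    clipped = np.where(x > 0, x, 0.0)
    y = clipped ** 2
    w1 = max(1, int(round(w_peak_s * rate)))
    w2 = max(w1 + 1, int(round(w_beat_s * rate)))
    ma_peak = uniform_filter1d(y, w1, mode="nearest")
    ma_beat = uniform_filter1d(y, w2, mode="nearest")
    thr = ma_beat + beta * float(np.mean(y))
    blocks = ma_peak > thr
    out = []
    for start, end in _bool_runs(blocks):
        if end - start >= w1:
            out.append(start + int(np.argmax(x[start:end])))
    return np.array(out, dtype=int)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    return list(zip(np.flatnonzero(d == 1).tolist(),
                    np.flatnonzero(d == -1).tolist()))


def _det_scipy(x: np.ndarray, rate: float, prominence_frac: float = 0.3,
               min_dist_s: float = DEFAULT_REFRACTORY_S) -> np.ndarray:
    rng = float(np.max(x) - np.min(x))
    if rng == 0:
        return np.array([], dtype=int)
    peaks, _ = sps.find_peaks(x, prominence=prominence_frac * rng,
                              distance=max(1, int(round(min_dist_s * rate))))
    return peaks.astype(int)


def _det_billauer(x: np.ndarray, rate: float, delta_frac: float = 0.3
                  ) -> np.ndarray:
    rng = float(np.max(x) - np.min(x))
    if rng == 0:
        return np.array([], dtype=int)
    delta = delta_frac * rng
    peaks = []
    mn, mx = np.inf, -np.inf
    mn_pos = mx_pos = 0
    look_for_max = True
    for i, v in enumerate(x):
        if v > mx:
            mx, mx_pos = v, i
        if v < mn:
            mn, mn_pos = v, i
        if look_for_max:
            if v < mx - delta:
                peaks.append(mx_pos)
                mn, mn_pos = v, i
                look_for_max = False
        else:
            if v > mn + delta:
                mx, mx_pos = v, i
                look_for_max = True
    return np.array(peaks, dtype=int)


_DETECTORS = {
    1: _det_adaptive_threshold,
    2: _det_count_origin,
    3: _det_clustering,
    4: _det_slope_sum,
    5: _det_moving_average,
    6: _det_scipy,
    7: _det_billauer,
}


def _ecg_precondition(x: np.ndarray, rate: float) -> np.ndarray:
    """Squared-derivative QRS-energy transform (Pan–Tompkins style)."""
    nyq = rate / 2.0
    hi = min(15.0, 0.9 * nyq)
    sos = sps.butter(2, [5.0, hi], btype="bandpass", fs=rate, output="sos")
    y = sps.sosfiltfilt(sos, x)
    d = np.diff(y, prepend=y[0])
    sq = d ** 2
    return uniform_filter1d(sq, max(1, int(round(0.15 * rate))), mode="nearest")


def detect_peaks(segment: Segment | np.ndarray, detector_id: int = DEFAULT_DETECTOR,
                 params: dict | None = None, *, sampling_rate: float | None = None,
                 signal_type: SignalType | str | None = None) -> PeakAnnotation:
    """Detect systolic peaks (PPG) or R peaks (ECG) in a segment.

    Accepts either a :class:`Segment` (rate and signal type taken from
    the parent record) or a bare array plus ``sampling_rate``. ECG input
    is preconditioned with a squared-derivative transform and detected
    peaks are refined to the filtered-signal maximum within ±100 ms.
    """
    params = dict(params or {})
    if detector_id not in _DETECTORS:
        raise ConfigurationError(f"unknown detector id {detector_id}")
    if isinstance(segment, Segment):
        x = segment.filtered_samples
        rate = segment.sampling_rate
        stype = SignalType(signal_type) if signal_type else segment.parent.signal_type
        seg_mask = segment.parent.valid_mask[segment.start : segment.end]
        if not seg_mask.any():
            raise InputError("segment is entirely invalid")
    else:
        x = np.asarray(segment, dtype=float)
        if sampling_rate is None:
            raise ConfigurationError("sampling_rate required for array input")
        rate = float(sampling_rate)
        stype = SignalType(signal_type) if signal_type else SignalType.PPG
        if not np.isfinite(x).any():
            raise InputError("segment is entirely invalid")
    x = np.where(np.isfinite(x), x, np.nanmean(x[np.isfinite(x)]) if np.isfinite(x).any() else 0.0)
    refractory_s = float(params.pop("refractory_s", DEFAULT_REFRACTORY_S))
    min_dist = max(1, int(round(refractory_s * rate)))

    if np.max(x) == np.min(x):
        return PeakAnnotation(np.array([], int), np.array([], int),
                              detector_id, params)

    if stype is SignalType.ECG:
        work = _ecg_precondition(x, rate)
        cand = _DETECTORS[detector_id](work, rate, **params)
        refine = max(1, int(round(0.1 * rate)))
        refined = []
        for c in cand:
            lo, hi = max(0, c - refine), min(x.size, c + refine + 1)
            refined.append(lo + int(np.argmax(x[lo:hi])))
        cand = np.unique(np.array(refined, dtype=int))
    else:
        cand = _DETECTORS[detector_id](x, rate, **params)

    peaks = _enforce_refractory(x, cand, min_dist)
    logger.debug("detector %d (%s): %d peaks", detector_id,
                 DETECTOR_NAMES[detector_id], peaks.size)
    return PeakAnnotation(peaks, np.array([], dtype=int), detector_id,
                          dict(params, refractory_s=refractory_s))


def detect_troughs(segment: Segment | np.ndarray, peaks: PeakAnnotation
                   ) -> PeakAnnotation:
    """One trough per inter-peak gap: the minimum strictly between peaks.

    Ties break to the earliest index. Fewer than 2 peaks yields an empty
    trough list.
    """
    x = segment.filtered_samples if isinstance(segment, Segment) else np.asarray(segment, float)
    p = peaks.peak_indices
    troughs = []
    for a, b in zip(p[:-1], p[1:]):
        if b - a < 2:
            continue
        inner = x[a + 1 : b]
        troughs.append(a + 1 + int(np.argmin(inner)))
    return PeakAnnotation(p, np.array(troughs, dtype=int),
                          peaks.detector_id, peaks.params)


def extract_beats(segment: Segment | np.ndarray, troughs: np.ndarray,
                  target_len: int = 100, sampling_rate: float | None = None,
                  min_beat_s: float = 0.25, max_beat_s: float = 2.0
                  ) -> list[np.ndarray]:
    """Slice trough-to-trough beats, resample each to ``target_len``.

    Each beat is baseline-shifted so its first sample is 0. Beats shorter
    than ``min_beat_s`` or longer than ``max_beat_s`` are skipped (with a
    log entry) — they are segmentation failures, not beats.
    """
    if isinstance(segment, Segment):
        x, rate = segment.filtered_samples, segment.sampling_rate
    else:
        x = np.asarray(segment, dtype=float)
        if sampling_rate is None:
            raise ConfigurationError("sampling_rate required for array input")
        rate = float(sampling_rate)
    troughs = np.asarray(troughs, dtype=int)
    if troughs.size < 2:
        raise InputError("need at least 2 troughs to extract beats")
    beats = []
    grid = np.linspace(0.0, 1.0, int(target_len))
    for a, b in zip(troughs[:-1], troughs[1:]):
        dur = (b - a) / rate
        if dur < min_beat_s or dur > max_beat_s:
            logger.info("skipping beat [%d, %d): duration %.3f s outside "
                        "[%g, %g] s", a, b, dur, min_beat_s, max_beat_s)
            continue
        raw = x[a : b + 1]
        src = np.linspace(0.0, 1.0, raw.size)
        beat = np.interp(grid, src, raw)
        beats.append(beat - beat[0])
    return beats
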