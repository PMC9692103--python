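"""Filtering, invalid-signal marking, resampling, tapering and segmentation.

The preprocessing contract mirrors the standard QC workflow for wearable
ECG/PPG: zero-phase band-pass filtering (so peak locations are not
shifted), marking of flatline and zero runs as invalid, tiling the record
into fixed-duration segments, and per-beat enhancement (taper + moving
average) before beat-wise SQIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .containers import Segment, SignalType, WaveformRecord
from .errors import ConfigurationError, InputError

__all__ = [
    "FilterSpec",
    "bandpass_filter",
    "mark_invalid",
    "segment_by_duration",
    "resample",
    "taper_and_smooth",
    "default_filter",
]

logger = logging.getLogger(__name__)


@dataclass
class FilterSpec:
    """Band-pass design: method, corner frequencies (Hz) and order.

    ``low_cut = 0`` degenerates to a low-pass. Chebyshev-I uses 1 dB
    passband ripple, elliptic 1 dB ripple / 40 dB stopband attenuation.
    """

    method: str = "butterworth"
    low_cut: float = 0.5
    high_cut: float = 8.0
    order: int = 4

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        if self.method not in ("butterworth", "chebyshev1", "ellip"):
            raise ConfigurationError(f"unknown filter method {self.method!r}")
        if not (0 <= self.low_cut < self.high_cut < nyq):
            raise ConfigurationError(
                f"need 0 <= low_cut < high_cut < Nyquist ({nyq} Hz); "
                f"got [{self.low_cut}, {self.high_cut}]"
            )
        if self.order < 1:
            raise ConfigurationError("filter order must be >= 1")

    def design(self, sampling_rate: float) -> np.ndarray:
        self.validate(sampling_rate)
        if self.low_cut > 0:
            wn, btype = [self.low_cut, self.high_cut], "bandpass"
        else:
            wn, btype = self.high_cut, "lowpass"
        if self.method == "butterworth":
            return sps.butter(self.order, wn, btype=btype, fs=sampling_rate,
                              output="sos")
        if self.method == "chebyshev1":
            return sps.cheby1(self.order, 1.0, wn, btype=btype,
                              fs=sampling_rate, output="sos")
        return sps.ellip(self.order, 1.0, 40.0, wn, btype=btype,
                         fs=sampling_rate, output="sos")


def default_filter(signal_type: SignalType) -> FilterSpec:
    """Default Butterworth order-4 band: PPG 0.5–8 Hz, ECG 0.5–40 Hz."""
    if SignalType(signal_type) is SignalType.ECG:
        return FilterSpec("butterworth", 0.5, 40.0, 4)
    return FilterSpec("butterworth", 0.5, 8.0, 4)


def bandpass_filter(record: WaveformRecord, spec: FilterSpec | None = None
                    ) -> WaveformRecord:
    """Zero-phase (forward–backward) band-pass; length and mask preserved.

    Invalid samples are replaced by the record mean before filtering so a
    NaN burst does not poison the whole output; they remain flagged.
    """
    spec = spec or default_filter(record.signal_type)
    sos = spec.design(record.sampling_rate)
    x = record.samples.copy()
    if not record.valid_mask.all():
        fill = float(np.mean(x[record.valid_mask])) if record.valid_mask.any() else 0.0
        x[~record.valid_mask] = fill
    y = sps.sosfiltfilt(sos, x)
    return WaveformRecord(y, record.sampling_rate, record.signal_type,
                          record.channel_label, record.start_time,
                          record.valid_mask.copy())


def _runs(boundary_mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, end) spans of True runs in a boolean array."""
    if boundary_mask.size == 0:
        return []
    padded = np.concatenate([[False], boundary_mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def mark_invalid(record: WaveformRecord, flatline_min_s: float = 2.0,
                 zero_run_min_s: float = 2.0) -> WaveformRecord:
    """Flag flatline runs, zero runs and non-finite samples as invalid.

    Maximal runs of exactly repeated values lasting at least
    ``flatline_min_s`` and runs of zeros lasting at least
    ``zero_run_min_s`` are marked invalid; already-invalid samples stay
    invalid. Idempotent.
    """
    if flatline_min_s <= 0 or zero_run_min_s <= 0:
        raise ConfigurationError("run-length thresholds must be > 0")
    x = record.samples
    rate = record.sampling_rate
    mask = record.valid_mask & np.isfinite(x)

    flat_n = int(np.ceil(flatline_min_s * rate))
    zero_n = int(np.ceil(zero_run_min_s * rate))
    if x.size >= 2:
        same = np.zeros(x.size, dtype=bool)
        eq = x[1:] == x[:-1]
        # a sample belongs to a repeat-run if it equals a neighbour
        same[1:] |= eq
        same[:-1] |= eq
        for start, end in _runs(same):
            if end - start >= flat_n:
                mask[start:end] = False
    for start, end in _runs(x == 0.0):
        if end - start >= zero_n:
            mask[start:end] = False

    out = record.copy()
    out.valid_mask = mask
    n_new = int(record.valid_mask.sum() - mask.sum())
    if n_new:
        logger.info("mark_invalid: %d samples newly invalid", n_new)
    return out


def segment_by_duration(record: WaveformRecord, length_s: float = 30.0,
                        invalid_tolerance: float = 0.0,
                        filtered: np.ndarray | None = None) -> list[Segment]:
    """Tile the record into consecutive ``length_s`` segments.

    The trailing partial segment is dropped. A segment whose
    invalid-sample fraction exceeds ``invalid_tolerance`` gets
    ``valid = False`` (it is kept so table rows align with segment
    positions). ``filtered`` supplies per-segment filtered samples; when
    omitted the raw samples are used.
    """
    if length_s <= 0:
        raise ConfigurationError("segment length must be > 0")
    seg_len = int(round(length_s * record.sampling_rate))
    if seg_len < 1:
        raise ConfigurationError("segment length shorter than one sample")
    y = record.samples if filtered is None else np.asarray(filtered, dtype=float)
    if y.size != record.n_samples:
        raise InputError("filtered array must match record length")
    n_seg = record.n_samples // seg_len
    segments = []
    for i in range(n_seg):
        start, end = i * seg_len, (i + 1) * seg_len
        invalid_frac = 1.0 - float(np.mean(record.valid_mask[start:end]))
        segments.append(Segment(record, i, start, end, y[start:end],
                                valid=invalid_frac <= invalid_tolerance))
    return segments


def resample(record: WaveformRecord, target_rate: float) -> WaveformRecord:
    """Band-limited (polyphase) resampling preserving duration.

    The validity mask is carried over by nearest-neighbour mapping.
    """
    if target_rate <= 0:
        raise ConfigurationError("target rate must be > 0")
    if abs(target_rate - record.sampling_rate) < 1e-12:
        return record.copy()
    frac = Fraction(target_rate / record.sampling_rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    x = record.samples.copy()
    if not record.valid_mask.all():
        fill = float(np.mean(x[record.valid_mask])) if record.valid_mask.any() else 0.0
        x[~record.valid_mask] = fill
    y = sps.resample_poly(x, up, down)
    src_idx = np.clip(
        np.round(np.arange(y.size) * record.sampling_rate / target_rate).astype(int),
        0, record.n_samples - 1,
    )
    return WaveformRecord(y, float(target_rate), record.signal_type,
                          record.channel_label, record.start_time,
                          record.valid_mask[src_idx])


def taper_and_smooth(beat_samples: np.ndarray, window: str = "tukey",
                     smooth_len: int = 1) -> np.ndarray:
    """Taper a beat toward zero at its endpoints, then moving-average it.

    ``window = "flat"`` with ``smooth_len = 1`` is the identity. Output
    length equals input length.
    """
    x = np.asarray(beat_samples, dtype=float)
    if smooth_len < 1:
        raise InputError("smooth_len must be >= 1")
    if smooth_len >= x.size:
        raise InputError(f"smooth_len {smooth_len} >= beat length {x.size}")
    if window == "tukey":
        w = sps.windows.tukey(x.size, alpha=0.5)
    elif window == "hann":
        w = sps.windows.hann(x.size)
    elif window == "flat":
        w = np.ones(x.size)
    else:
        raise ConfigurationError(f"unknown taper window {window!r}")
    y = x * w
    if smooth_len > 1:
        kernel = np.ones(smooth_len) / smooth_len
        y = np.convolve(y, kernel, mode="same")
    return y
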