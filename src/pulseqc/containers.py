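"""Core data containers shared by every pipeline stage.

A :class:`WaveformRecord` is a single-channel sampled physiological signal
(ECG or PPG) with a per-sample validity mask; samples are never dropped on
read, only flagged, so sample indices stay aligned with the source file.
A :class:`Segment` is a half-open sample span of a record carrying the
band-pass-filtered samples used for SQI computation. A
:class:`SignalSQISession` accumulates the results of the three workflow
steps (preprocessing, SQI computation, rule-based decision) around one
record.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "SignalType",
    "WaveformRecord",
    "Segment",
    "SignalSQISession",
]


class SignalType(str, enum.Enum):
    ECG = "ecg"
    PPG = "ppg"


@dataclass
class WaveformRecord:
    """A sampled waveform with sampling rate, type and validity mask.

    Parameters
    ----------
    samples : ndarray of float
        Amplitudes in arbitrary units. Non-finite samples are retained
        (indices preserved) but forced invalid in ``valid_mask``.
    sampling_rate : float
        Sampling rate in Hz, strictly positive.
    signal_type : SignalType
        ECG or PPG; selects defaults downstream (filter band, detector
        preconditioning, templates).
    channel_label : str
        Label of the source channel.
    start_time : datetime or None
        Recording start, if the source format carries one.
    valid_mask : ndarray of bool or None
        Per-sample validity; defaults to "finite sample" when omitted.
    """

    samples: np.ndarray
    sampling_rate: float
    signal_type: SignalType = SignalType.PPG
    channel_label: str = ""
    start_time: datetime | None = None
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InputError("samples must be one-dimensional")
        if not np.isfinite(self.sampling_rate) or self.sampling_rate <= 0:
            raise InputError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        self.sampling_rate = float(self.sampling_rate)
        if isinstance(self.signal_type, str):
            self.signal_type = SignalType(self.signal_type.lower())
        finite = np.isfinite(self.samples)
        if self.valid_mask is None:
            self.valid_mask = finite
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.samples.shape:
                raise InputError("valid_mask must have one entry per sample")
            # a sample flagged valid must be a finite number
            self.valid_mask = self.valid_mask & finite

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy(self) -> "WaveformRecord":
        return WaveformRecord(
            samples=self.samples.copy(),
            sampling_rate=self.sampling_rate,
            signal_type=self.signal_type,
            channel_label=self.channel_label,
            start_time=self.start_time,
            valid_mask=self.valid_mask.copy(),
        )


@dataclass
class Segment:
    """A half-open sample span ``[start, end)`` of a parent record.

    ``filtered_samples`` holds the band-passed samples for the span (the
    ``y`` that the perfusion index relates to the raw mean); ``valid`` is
    False when the span's invalid-sample fraction exceeded the tolerance
    at segmentation time.
    """

    parent: WaveformRecord
    index: int
    start: int
    end: int
    filtered_samples: np.ndarray
    valid: bool = True

    def __post_init__(self) -> None:
        self.filtered_samples = np.asarray(self.filtered_samples, dtype=float)
        if not (0 <= self.start < self.end <= self.parent.n_samples):
            raise InputError(
                f"segment span [{self.start}, {self.end}) outside parent bounds"
            )
        if self.filtered_samples.size != self.end - self.start:
            raise InputError("filtered_samples length must equal span length")

    @property
    def raw_samples(self) -> np.ndarray:
        return self.parent.samples[self.start : self.end]

    @property
    def valid_fraction(self) -> float:
        mask = self.parent.valid_mask[self.start : self.end]
        return float(np.mean(mask))

    @property
    def sampling_rate(self) -> float:
        return self.parent.sampling_rate

    @property
    def start_s(self) -> float:
        return self.start / self.sampling_rate

    @property
    def end_s(self) -> float:
        return self.end / self.sampling_rate

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SignalSQISession:
    """Accumulates one record's pipeline state across the workflow steps."""

    record: WaveformRecord
    segments: list[Segment] = field(default_factory=list)
    sqi_table: pd.DataFrame | None = None
    ruleset: object | None = None
    decisions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self._check()

    def _check(self) -> None:
        prev_end = 0
        for seg in self.segments:
            if seg.start < prev_end:
                raise InputError("segments must be non-overlapping and ordered")
            prev_end = seg.end
        if self.sqi_table is not None and self.segments:
            if len(self.sqi_table) != len(self.segments):
                raise InputError("sqi_table row count must equal segment count")
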