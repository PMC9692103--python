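"""Seeded synthetic ECG/PPG generator with ground truth and artifacts.

The generator renders quasi-periodic waveforms from the same analytic
beat templates the DTW SQI matches against: beat-to-beat intervals are
drawn from a Gaussian around 60000/HR ms (sd ``hrv_sd_ms``, truncated at
±40%), each cycle is rendered trough-to-trough from the PPG double
Gaussian or the ECG P-QRS-T Gaussian sum, then baseline wander (a slow
sinusoid, emulating respiration/autonomic drift) and white noise are
added. Ground truth carries beat onsets, systolic/R peak indices and
injected artifact spans.

Artifacts emulate the dominant failure modes of wearable recordings —
loose sensor contact and transmission dropouts: ``flatline`` (held
value), ``dropout_zero`` (zeros), ``spike_burst`` (random impulses) and
``gaussian_noise``.

Identical spec (including seed) → bit-identical output.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .containers import SignalType, WaveformRecord
from .errors import ConfigurationError, InputError
from .sqi.morphology import make_template

__all__ = ["SynthesisSpec", "GroundTruth", "synth_record", "inject_artifact"]

ARTIFACT_KINDS = ("flatline", "dropout_zero", "spike_burst", "gaussian_noise")

# fraction of the cycle at which the rendered template peaks
_PPG_PEAK_PHASE = 0.30
_ECG_PEAK_PHASE = 0.40


@dataclass
class SynthesisSpec:
    """Study conditions for one synthetic recording.

    Defaults describe a clean 30-s wearable PPG at 100 Hz, 75 bpm with
    30 ms beat-to-beat jitter, mild white noise (5% of the unit pulse
    amplitude) and respiration-band baseline wander.
    """

    signal_type: SignalType = SignalType.PPG
    duration_s: float = 30.0
    rate: float = 100.0
    heart_rate_bpm: float = 75.0
    hrv_sd_ms: float = 30.0
    noise_sd: float = 0.05
    baseline_wander: tuple[float, float] = (0.2, 0.25)  # amplitude, Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.signal_type, str):
            self.signal_type = SignalType(self.signal_type.lower())
        if not 30 <= self.heart_rate_bpm <= 220:
            raise ConfigurationError(
                f"heart_rate_bpm must be in [30, 220], got {self.heart_rate_bpm}")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be > 0")
        if self.rate < 50:
            raise ConfigurationError("rate must be >= 50 Hz")
        if self.hrv_sd_ms < 0 or self.noise_sd < 0:
            raise ConfigurationError("hrv_sd_ms and noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Generator-known beat onsets, peak indices and artifact spans."""

    beat_onsets: np.ndarray
    peak_indices: np.ndarray
    artifact_spans: list[tuple[str, tuple[int, int]]] = field(default_factory=list)


def _draw_interval(rng: np.random.Generator, mean_ms: float, sd_ms: float) -> float:
    """Gaussian interval truncated at ±40% of the mean (rejection)."""
    if sd_ms == 0:
        return mean_ms
    lo, hi = 0.6 * mean_ms, 1.4 * mean_ms
    for _ in range(1000):
        v = rng.normal(mean_ms, sd_ms)
        if lo <= v <= hi:
            return v
    return mean_ms


def synth_record(spec: SynthesisSpec) -> tuple[WaveformRecord, GroundTruth]:
    """Render a synthetic recording and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    rate = float(spec.rate)
    n = int(round(spec.duration_s * rate))
    mean_ms = 60000.0 / spec.heart_rate_bpm
    kind = ("ppg_double_gaussian" if spec.signal_type is SignalType.PPG
            else "ecg_pqrst_gaussian_sum")
    peak_phase = (_PPG_PEAK_PHASE if spec.signal_type is SignalType.PPG
                  else _ECG_PEAK_PHASE)

    x = np.zeros(n)
    onsets, peaks_true = [], []
    pos = 0.0  # beat onset in samples (fractional)
    while True:
        interval_ms = _draw_interval(rng, mean_ms, spec.hrv_sd_ms)
        beat_len = int(round(interval_ms / 1000.0 * rate))
        start = int(round(pos))
        if start >= n or beat_len < 16:
            break
        onsets.append(start)
        end = min(n, start + beat_len)
        template = make_template(kind, beat_len)
        x[start:end] += template.samples[: end - start]
        peak = start + int(round(peak_phase * beat_len))
        if peak < n:
            peaks_true.append(peak)
        pos += interval_ms / 1000.0 * rate

    t = np.arange(n) / rate
    amp, freq = spec.baseline_wander
    if amp > 0 and freq > 0:
        x += amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    if spec.noise_sd > 0:
        x += rng.normal(0.0, spec.noise_sd, size=n)

    record = WaveformRecord(x, rate, spec.signal_type,
                            channel_label=f"synthetic_{spec.signal_type.value}")
    truth = GroundTruth(np.array(onsets, dtype=int),
                        np.array(peaks_true, dtype=int))
    return record, truth


def inject_artifact(record: WaveformRecord, truth: GroundTruth, kind: str,
                    span: tuple[float, float], magnitude: float = 1.0,
                    seed: int = 0) -> tuple[WaveformRecord, GroundTruth]:
    """Inject one artifact over ``span`` = (start_s, end_s).

    ``flatline`` holds the value at span start; ``dropout_zero`` zeroes
    the span; ``spike_burst`` adds seeded random impulses of the given
    magnitude; ``gaussian_noise`` adds white noise of sd ``magnitude``.
    Overlapping spans of the same kind are rejected.
    """
    if kind not in ARTIFACT_KINDS:
        raise ConfigurationError(f"unknown artifact kind {kind!r}")
    rate = record.sampling_rate
    a = int(round(span[0] * rate))
    b = int(round(span[1] * rate))
    if not 0 <= a < b <= record.n_samples:
        raise InputError(f"artifact span {span} outside record")
    for k, (s0, s1) in truth.artifact_spans:
        if k == kind and a < s1 and s0 < b:
            raise InputError(f"overlapping {kind} spans")
    out = record.copy()
    if kind == "flatline":
        out.samples[a:b] = out.samples[a]
    elif kind == "dropout_zero":
        out.samples[a:b] = 0.0
    elif kind == "spike_burst":
        rng = np.random.default_rng(seed)
        n_spikes = max(1, (b - a) // max(1, int(0.1 * rate)))
        pos = rng.integers(a, b, size=n_spikes)
        out.samples[pos] += rng.choice([-1.0, 1.0], size=n_spikes) * magnitude
    else:  # gaussian_noise
        if magnitude > 0:
            rng = np.random.default_rng(seed)
            out.samples[a:b] += rng.normal(0.0, magnitude, size=b - a)
    new_truth = GroundTruth(truth.beat_onsets.copy(), truth.peak_indices.copy(),
                            copy.deepcopy(truth.artifact_spans))
    new_truth.artifact_spans.append((kind, (a, b)))
    return out, new_truth
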