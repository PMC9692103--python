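"""Waveform- and agreement-based SQIs.

These indices judge a segment by its shape rather than its sample
distribution: agreement between two peak detectors (MSQ), periodicity of
the autocorrelation (correlogram), dynamic-time-warping distance of each
beat to an idealized template, QRS-band energy fraction, and beat
amplitude ratios.

Beat templates are analytic: the PPG pulse is a double Gaussian
(systolic bump plus a smaller diastolic bump); the ECG beat is a sum of
five signed Gaussians (P, Q, R, S, T). Both are peak-normalized to 1 and
parameterized on the unit interval, so the same shape renders at any
length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ..errors import ConfigurationError, InputError
from ..peaks import DEFAULT_DETECTOR, PeakAnnotation, detect_peaks
from .statistical import relative_power_sqi

__all__ = [
    "BeatTemplate",
    "make_template",
    "msq_sqi",
    "msq_shift_sqi",
    "correlogram_sqi",
    "dtw_sqi",
    "qrs_energy_sqi",
    "amplitude_ratio_sqi",
    "PPG_TEMPLATE_PARAMS",
    "ECG_TEMPLATE_PARAMS",
]

logger = logging.getLogger(__name__)

# (center, width, amplitude) on the unit-interval beat
PPG_TEMPLATE_PARAMS = {
    "mu1": 0.30, "sigma1": 0.10,           # systolic bump
    "mu2": 0.65, "sigma2": 0.16, "a": 0.5,  # diastolic bump
}
ECG_TEMPLATE_PARAMS = {  # P, Q, R, S, T Gaussians
    "waves": [
        (0.15, 0.030, 0.12),
        (0.36, 0.012, -0.15),
        (0.40, 0.016, 1.00),
        (0.44, 0.012, -0.20),
        (0.62, 0.050, 0.30),
    ]
}


@dataclass
class BeatTemplate:
    """Unit-normalized ideal beat (max |samples| == 1)."""

    samples: np.ndarray
    kind: str
    length: int


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def make_template(kind: str, length: int = 100,
                  params: dict | None = None) -> BeatTemplate:
    """Render an analytic beat template of ``length`` samples.

    ``ppg_double_gaussian``: systolic Gaussian plus a scaled diastolic
    Gaussian. ``ecg_pqrst_gaussian_sum``: five signed Gaussians.
    """
    if length < 16:
        raise ConfigurationError("template length must be >= 16")
    t = np.linspace(0.0, 1.0, length, endpoint=False)
    if kind == "ppg_double_gaussian":
        p = dict(PPG_TEMPLATE_PARAMS, **(params or {}))
        for key in ("sigma1", "sigma2"):
            if p[key] <= 0:
                raise ConfigurationError(f"{key} must be > 0")
        for key in ("mu1", "mu2"):
            if not 0 <= p[key] < 1:
                raise ConfigurationError(f"{key} must lie in [0, 1)")
        y = _gauss(t, p["mu1"], p["sigma1"]) + p["a"] * _gauss(t, p["mu2"], p["sigma2"])
    elif kind == "ecg_pqrst_gaussian_sum":
        p = dict(ECG_TEMPLATE_PARAMS, **(params or {}))
        y = np.zeros_like(t)
        for mu, sigma, amp in p["waves"]:
            if sigma <= 0:
                raise ConfigurationError("wave sigma must be > 0")
            if not 0 <= mu < 1:
                raise ConfigurationError("wave center must lie in [0, 1)")
            y = y + amp * _gauss(t, mu, sigma)
    else:
        raise ConfigurationError(f"unknown template kind {kind!r}")
    y = y / np.max(np.abs(y))
    return BeatTemplate(y, kind, length)


def _match_counts(a: np.ndarray, b: np.ndarray, tol: int) -> int:
    """Greedy one-to-one matching of sorted index sets within ``tol``."""
    used = np.zeros(b.size, dtype=bool)
    matched = 0
    j = 0
    for p in a:
        # advance to nearest unmatched candidate
        best, best_d = -1, tol + 1
        for k in range(b.size):
            if used[k]:
                continue
            d = abs(int(b[k]) - int(p))
            if d < best_d:
                best, best_d = k, d
        if best >= 0 and best_d <= tol:
            used[best] = True
            matched += 1
    return matched


def msq_sqi(segment, rate: float | None = None, detector_a: int = 6,
            detector_b: int = 7, tolerance_s: float = 0.15,
            peaks_a: np.ndarray | None = None,
            peaks_b: np.ndarray | None = None) -> float:
    """Agreement between two distinct peak detectors on one segment.

    Greedy one-to-one matching within ``tolerance_s``; the score is
    |matched| / max(|A|, |B|) ∈ [0, 1]. Pre-computed peak sets can be
    passed directly (``peaks_a``/``peaks_b``).
    """
    from ..containers import Segment
    if isinstance(segment, Segment):
        rate = segment.sampling_rate
    if rate is None:
        raise ConfigurationError("sampling rate required")
    if peaks_a is None or peaks_b is None:
        if detector_a == detector_b:
            raise ConfigurationError("msq_sqi needs two distinct detectors")
        peaks_a = detect_peaks(segment, detector_a, sampling_rate=rate).peak_indices
        peaks_b = detect_peaks(segment, detector_b, sampling_rate=rate).peak_indices
    a = np.asarray(peaks_a, dtype=int)
    b = np.asarray(peaks_b, dtype=int)
    if a.size == 0 and b.size == 0:
        return float("nan")
    tol = int(round(tolerance_s * rate))
    return _match_counts(a, b, tol) / max(a.size, b.size)


def msq_shift_sqi(segment, rate: float | None = None,
                  detector_id: int = DEFAULT_DETECTOR, shift_s: float = 1.0,
                  tolerance_s: float = 0.15) -> float:
    """Self-consistency MSQ: detect on the signal and on the same signal
    shifted ``shift_s`` forward; a good-quality signal yields the same
    peaks (offset by the shift)."""
    from ..containers import Segment
    x = segment.filtered_samples if isinstance(segment, Segment) else np.asarray(segment, float)
    if isinstance(segment, Segment):
        rate = segment.sampling_rate
    if rate is None:
        raise ConfigurationError("sampling rate required")
    k = int(round(shift_s * rate))
    if not 0 < k < x.size:
        raise ConfigurationError("shift must be shorter than the segment")
    a = detect_peaks(x, detector_id, sampling_rate=rate).peak_indices
    b = detect_peaks(x[k:], detector_id, sampling_rate=rate).peak_indices + k
    a = a[a >= k]
    if a.size == 0 and b.size == 0:
        return float("nan")
    tol = int(round(tolerance_s * rate))
    return _match_counts(a, b, tol) / max(a.size, b.size, 1)


def correlogram_sqi(segment, rate: float | None = None, max_lag_s: float = 3.0,
                    n_peaks: int = 3, min_prominence: float = 0.1
                    ) -> dict[str, list[float]]:
    """First ``n_peaks`` autocorrelation peaks (lag in s, prominence).

    The autocorrelation is normalized to 1 at lag 0; lists are padded
    with ``nan`` when fewer peaks exist. Peaks below ``min_prominence``
    are ignored (sampling noise produces many micro-maxima; structural
    periodicity peaks have prominence near 1), so on a quasi-periodic
    signal the first reported peak sits at the beat period.
    """
    from ..containers import Segment
    x = segment.filtered_samples if isinstance(segment, Segment) else np.asarray(segment, float)
    if isinstance(segment, Segment):
        rate = segment.sampling_rate
    if rate is None:
        raise ConfigurationError("sampling rate required")
    max_lag = int(round(max_lag_s * rate))
    if x.size <= max_lag:
        raise InputError("segment shorter than the requested maximum lag")
    xc = x - np.mean(x)
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        return {"lags_s": [float("nan")] * n_peaks,
                "prominences": [float("nan")] * n_peaks}
    acf = np.correlate(xc, xc, mode="full")[xc.size - 1 : xc.size + max_lag]
    acf = acf / denom
    pk, props = sps.find_peaks(acf, prominence=min_prominence)
    lags = [float("nan")] * n_peaks
    proms = [float("nan")] * n_peaks
    for i, (p, pr) in enumerate(zip(pk[:n_peaks], props["prominences"][:n_peaks])):
        lags[i] = p / rate
        proms[i] = float(pr)
    return {"lags_s": lags, "prominences": proms}


def _normalize_beat(x: np.ndarray) -> np.ndarray | None:
    x = np.asarray(x, dtype=float)
    x = x - np.mean(x)
    m = float(np.max(np.abs(x)))
    if m == 0.0:
        return None
    return x / m


def dtw_sqi(beat: np.ndarray, template: BeatTemplate | np.ndarray) -> float:
    """Mean per-step dynamic-time-warping cost between a beat and a
    template, after zero-mean / unit-max-abs normalization of both.

    Classic DTW with |a − b| local cost, full alignment, no window; the
    accumulated optimal-path cost is divided by that path's length.
    Returns 0 iff the normalized sequences are identical; ``nan`` for a
    constant (degenerate) beat.
    """
    t = template.samples if isinstance(template, BeatTemplate) else np.asarray(template, float)
    a = _normalize_beat(beat)
    b = _normalize_beat(t)
    if a is None or b is None:
        return float("nan")
    if a.size < 4:
        raise InputError("beat must have at least 4 samples")
    n, m = a.size, b.size
    inf = np.inf
    cost = np.full((n + 1, m + 1), inf)
    steps = np.zeros((n + 1, m + 1), dtype=np.int64)
    cost[0, 0] = 0.0
    local = np.abs(a[:, None] - b[None, :])
    for i in range(1, n + 1):
        row_local = local[i - 1]
        for j in range(1, m + 1):
            # diagonal preferred on ties, then insertion, then deletion
            c_diag, c_up, c_left = cost[i-1, j-1], cost[i-1, j], cost[i, j-1]
            best = c_diag
            step = steps[i-1, j-1]
            if c_up < best:
                best, step = c_up, steps[i-1, j]
            if c_left < best:
                best, step = c_left, steps[i, j-1]
            cost[i, j] = best + row_local[j - 1]
            steps[i, j] = step + 1
    return float(cost[n, m] / steps[n, m])


def qrs_energy_sqi(x: np.ndarray, rate: float) -> float:
    """QRS-band energy fraction: power in [5, 15) Hz over [5, 40) Hz."""
    if rate < 80.0:
        raise InputError("qrs_energy_sqi requires rate >= 80 Hz")
    return relative_power_sqi(x, rate, num_band=(5.0, 15.0),
                              den_band=(5.0, 40.0))


def amplitude_ratio_sqi(beats: list[np.ndarray], signal_type) -> dict[str, float]:
    """Per-beat amplitude feature aggregated over a segment's beats.

    ECG: peak-to-nadir range (max − min) of each beat. PPG: systolic /
    diastolic amplitude ratio, the diastolic shoulder being the highest
    local maximum after the global maximum (``nan`` when absent).
    """
    from ..containers import SignalType
    stype = SignalType(signal_type)
    if not beats:
        return {"mean": float("nan"), "std": float("nan")}
    values = []
    for beat in beats:
        b = np.asarray(beat, dtype=float)
        if stype is SignalType.ECG:
            values.append(float(np.max(b) - np.min(b)))
            continue
        g = int(np.argmax(b))
        tail = b[g + 1 :]
        locmax = np.flatnonzero((tail[1:-1] > tail[:-2]) & (tail[1:-1] >= tail[2:])) + 1
        if locmax.size == 0:
            logger.info("amplitude_ratio_sqi: no diastolic shoulder in beat")
            values.append(float("nan"))
            continue
        dias = float(np.max(tail[locmax]))
        base = float(b.min())
        if dias - base <= 0:
            values.append(float("nan"))
            continue
        values.append((float(b[g]) - base) / (dias - base))
    values = np.asarray(values, dtype=float)
    if np.all(np.isnan(values)):
        return {"mean": float("nan"), "std": float("nan")}
    return {"mean": float(np.nanmean(values)),
            "std": float(np.nanstd(values))}
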