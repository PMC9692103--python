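"""Statistical SQIs: distributional summaries of a signal segment.

All functions return ``nan`` for the declared undefined cases (zero
variance, zero mean where a mean normalizes, all-zero energy) rather
than raising — an undefined SQI is a legitimate table entry that the
rule engine handles via its NA policy.

Conventions pinned here:

* Kurtosis is the raw standardized fourth moment (Gaussian → 3); no
  excess subtraction, no bias correction (1/N normalization).
* The energy entropy first scales the signal to unit energy so the
  squared samples form a probability distribution; the result lies in
  [0, ln N] nats.
* Power spectra use Welch's method (4-s windows, 50% overlap, constant
  detrend) and band masks are half-open ``[low, high)``.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps
from scipy import stats
from scipy.ndimage import uniform_filter1d

from ..errors import InputError

__all__ = [
    "perfusion_sqi",
    "moment_sqi",
    "entropy_sqi",
    "snr_sqi",
    "relative_power_sqi",
    "crossing_sqi",
    "welch_psd",
]

logger = logging.getLogger(__name__)


def perfusion_sqi(raw: np.ndarray, filtered: np.ndarray) -> float:
    """Perfusion index: pulsatile range of the filtered signal relative
    to the mean raw level, in percent: ``(max y − min y)/|mean x| × 100``.
    """
    x = np.asarray(raw, dtype=float)
    y = np.asarray(filtered, dtype=float)
    denom = abs(float(np.nanmean(x)))
    if denom == 0 or not np.isfinite(denom):
        logger.info("perfusion_sqi undefined: mean of raw signal is 0")
        return float("nan")
    return (float(np.nanmax(y)) - float(np.nanmin(y))) / denom * 100.0


def moment_sqi(x: np.ndarray, order: str) -> float:
    """Standardized central moment: ``skewness`` (3rd) or ``kurtosis``
    (4th, raw — Gaussian gives 3), with 1/N normalization."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return float("nan")
    if float(np.std(x)) == 0.0:
        return float("nan")
    if order == "skewness":
        return float(stats.skew(x, bias=True))
    if order == "kurtosis":
        return float(stats.kurtosis(x, fisher=False, bias=True))
    raise InputError(f"unknown moment order {order!r}")


def entropy_sqi(x: np.ndarray) -> float:
    """Shannon entropy of the normalized signal energy, in nats.

    The signal is scaled to unit energy so ``p_n = x_n²/Σx²`` is a
    distribution; zero-energy samples contribute 0; an all-zero signal
    is undefined (nan).
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return float("nan")
    energy = float(np.sum(x * x))
    if energy == 0.0:
        return float("nan")
    p = (x * x) / energy
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def snr_sqi(x: np.ndarray, rate: float, smooth_s: float = 0.1) -> float:
    """Variance ratio of a moving-average "signal part" to its residual.

    The decomposition is exact (signal_part + noise_part == x); the
    ratio var(signal)/var(noise) is ``nan`` when the residual variance
    is zero (infinite SNR).
    """
    x = np.asarray(x, dtype=float)
    width = int(round(smooth_s * rate))
    if width < 3:
        raise InputError(f"smooth_s × rate must be >= 3 samples, got {width}")
    signal_part = uniform_filter1d(x, width, mode="nearest")
    noise_part = x - signal_part
    vn = float(np.var(noise_part))
    if vn == 0.0:
        logger.info("snr_sqi undefined: zero residual variance")
        return float("nan")
    return float(np.var(signal_part)) / vn


def welch_psd(x: np.ndarray, rate: float, window_s: float = 4.0):
    """Welch PSD with 4-s windows, 50% overlap, constant detrend."""
    x = np.asarray(x, dtype=float)
    nperseg = min(x.size, max(8, int(round(window_s * rate))))
    freqs, psd = sps.welch(x, fs=rate, nperseg=nperseg,
                           noverlap=nperseg // 2, detrend="constant")
    return freqs, psd


def relative_power_sqi(x: np.ndarray, rate: float,
                       num_band: tuple[float, float] = (1.0, 2.25),
                       den_band: tuple[float, float] = (0.0, 8.0)) -> float:
    """Fraction of spectral power in ``num_band`` relative to ``den_band``.

    Defaults target the PPG pulse band (1–2.25 Hz over 0–8 Hz). Band
    membership is half-open ``[low, high)`` on the Welch frequency grid,
    so a flat spectrum yields exactly the bandwidth ratio.
    """
    if den_band[1] >= rate / 2.0:
        raise InputError(
            f"denominator band edge {den_band[1]} Hz requires rate > "
            f"{2 * den_band[1]} Hz"
        )
    freqs, psd = welch_psd(x, rate)
    num = psd[(freqs >= num_band[0]) & (freqs < num_band[1])].sum()
    den = psd[(freqs >= den_band[0]) & (freqs < den_band[1])].sum()
    if den == 0.0:
        return float("nan")
    return float(num / den)


def crossing_sqi(x: np.ndarray, mode: str = "zero") -> float:
    """Count strict sign alternations about zero or about the mean.

    Samples exactly at the reference level carry the sign of the
    previous non-reference sample (leading reference samples are
    ignored), making the count deterministic on quantized signals.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return float("nan")
    if mode == "zero":
        ref = 0.0
    elif mode == "mean":
        ref = float(np.mean(x))
    else:
        raise InputError(f"unknown crossing mode {mode!r}")
    s = np.sign(x - ref)
    nz = s[s != 0]
    if nz.size < 2:
        return 0.0
    return float(np.count_nonzero(nz[1:] != nz[:-1]))
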