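"""Reading waveforms into :class:`WaveformRecord` and writing result tables.

Three input formats are supported: EDF, WFDB (MIT format) and delimited
text. Reads never drop samples — unparseable or missing values stay in
place with ``valid_mask`` set to False, so indices remain aligned with
the source. The CSV dialect is pinned (comma separator, ``.`` decimal,
header row, ``NA`` token) so table round-trips are bit-stable.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from . import formats
from .containers import SignalType, WaveformRecord
from .errors import ConfigurationError, InputError

__all__ = ["read_waveform", "write_waveform", "write_sqi_table", "read_sqi_table"]

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"

_TIME_COLUMNS = {"time", "timestamp", "t", "time_s", "seconds"}


def read_waveform(
    path: str | os.PathLike,
    format: str,
    signal_type: SignalType | str = SignalType.PPG,
    channel: int | str = 0,
    sampling_rate: float | None = None,
) -> WaveformRecord:
    """Read one channel of a waveform file into a :class:`WaveformRecord`.

    Parameters
    ----------
    format : {"edf", "wfdb", "csv"}
        File format. For ``csv`` the sampling rate must either be given by
        the caller or be inferable from a timestamp column (first column
        named ``time``/``timestamp``/... in seconds).
    channel : int or str
        Channel index or label (CSV: column name or index among the
        non-time columns).
    """
    fmt = str(format).lower()
    if fmt == "edf":
        samples, rate, label, start = formats.read_edf(path, channel)
        rec = WaveformRecord(samples, rate, signal_type, label, start)
    elif fmt == "wfdb":
        samples, rate, label = formats.read_wfdb(path, channel)
        rec = WaveformRecord(samples, rate, signal_type, label)
    elif fmt == "csv":
        rec = _read_csv(path, signal_type, channel, sampling_rate)
    else:
        raise ConfigurationError(f"unknown waveform format {format!r}")
    if rec.sampling_rate <= 0:
        raise InputError(f"{path}: non-positive sampling rate")
    logger.info(
        "read %s: %d samples @ %g Hz, %d invalid",
        path, rec.n_samples, rec.sampling_rate, int((~rec.valid_mask).sum()),
    )
    return rec


def _read_csv(path, signal_type, channel, sampling_rate) -> WaveformRecord:
    try:
        df = pd.read_csv(path, sep=",", na_values=[NA_TOKEN, "NaN", "nan", ""])
    except (OSError, pd.errors.ParserError) as exc:
        raise InputError(f"{path}: cannot parse CSV: {exc}") from None
    if df.empty:
        raise InputError(f"{path}: empty CSV")
    time_col = None
    for col in df.columns:
        if str(col).strip().lower() in _TIME_COLUMNS:
            time_col = col
            break
    value_cols = [c for c in df.columns if c != time_col]
    if not value_cols:
        raise InputError(f"{path}: no value column")
    if isinstance(channel, str):
        if channel not in value_cols:
            raise InputError(f"{path}: no column named {channel!r}")
        col = channel
    else:
        try:
            col = value_cols[int(channel)]
        except IndexError:
            raise InputError(f"{path}: channel index {channel} out of range") from None
    values = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
    mask = np.isfinite(values)

    if sampling_rate is None:
        if time_col is None:
            raise ConfigurationError(
                f"{path}: sampling rate not given and no timestamp column found"
            )
        t = pd.to_numeric(df[time_col], errors="coerce").to_numpy(dtype=float)
        dt = np.diff(t)
        good = np.isfinite(dt) & (dt > 0)
        if not good.any():
            raise InputError(f"{path}: cannot infer rate from timestamp column")
        step = float(np.median(dt[good]))
        sampling_rate = 1.0 / step
        # samples adjacent to a timestamp gap are not trusted: mark invalid
        gap = np.flatnonzero(np.isfinite(dt) & (dt > 1.5 * step))
        for g in gap:
            mask[g] = mask[g + 1] = False
    if sampling_rate <= 0:
        raise InputError(f"{path}: non-positive sampling rate")
    return WaveformRecord(values, float(sampling_rate), signal_type,
                          channel_label=str(col), valid_mask=mask)


def write_waveform(record: WaveformRecord, path: str | os.PathLike,
                   format: str = "csv") -> None:
    """Write a record to EDF, WFDB or the pinned CSV dialect."""
    fmt = str(format).lower()
    if fmt == "edf":
        formats.write_edf(path, record.samples, record.sampling_rate,
                          label=record.channel_label or "signal",
                          start_time=record.start_time)
    elif fmt == "wfdb":
        formats.write_wfdb(path, record.samples, record.sampling_rate,
                           label=record.channel_label or "signal")
    elif fmt == "csv":
        x = record.samples.copy()
        x[~record.valid_mask] = np.nan
        df = pd.DataFrame({
            "time": np.arange(record.n_samples) / record.sampling_rate,
            record.channel_label or "value": x,
        })
        df.to_csv(path, index=False, na_rep=NA_TOKEN)
    else:
        raise ConfigurationError(f"unknown waveform format {format!r}")


def write_sqi_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write an SQI table as CSV (one row per segment, ``NA`` for undefined).

    Values survive a write/read round trip to better than 10 significant
    digits (full ``repr`` precision is written).
    """
    if table is None or len(table) == 0:
        raise InputError("refusing to write an empty SQI table")
    table.to_csv(path, index=False, na_rep=NA_TOKEN)


def read_sqi_table(path: str | os.PathLike) -> pd.DataFrame:
    try:
        return pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=True)
    except (OSError, pd.errors.ParserError) as exc:
        raise InputError(f"{path}: cannot parse SQI table: {exc}") from None
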