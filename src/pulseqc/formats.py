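"""Minimal EDF and WFDB (MIT-format) codecs for single/multi-channel reads.

Both formats are simple enough to encode directly:

* EDF — a fixed 256-byte ASCII header, one 256-byte ASCII sub-header per
  signal, then data records of little-endian 16-bit integers mapped
  linearly between the digital and physical ranges declared per signal.
* WFDB — an ASCII ``.hea`` header naming a binary ``.dat`` file; only
  format 16 (little-endian int16) is supported here, with the standard
  ``gain(baseline)/units`` scaling: physical = (digital − baseline)/gain.

Writing uses the full int16 range for the observed amplitude span, so
round-tripping quantizes amplitudes to ~1/65535 of the range.
"""

from __future__ import annotations

import datetime as _dt
import os
import re

import numpy as np

from .errors import InputError

__all__ = ["read_edf", "write_edf", "read_wfdb", "write_wfdb"]

_INT16_MIN, _INT16_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise InputError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _num(width: int, value: float) -> bytes:
    for fmt in (f"{{:.{p}g}}" for p in range(width - 1, 0, -1)):
        s = fmt.format(float(value))
        if len(s) <= width:
            return s.ljust(width).encode("ascii")
    raise InputError(f"cannot encode {value} in {width} chars")


def write_edf(
    path: str | os.PathLike,
    samples: np.ndarray,
    sampling_rate: float,
    label: str = "signal",
    start_time: _dt.datetime | None = None,
    physical_dimension: str = "uV",
) -> None:
    """Write a single-channel EDF file.

    When the sample count divides into whole 1-second records the file
    uses 1-s data records; otherwise a single record holds everything
    (readers accept arbitrary record durations).
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise InputError("EDF writer needs a non-empty 1-D array")
    x = np.where(np.isfinite(x), x, 0.0)
    pmin, pmax = float(x.min()), float(x.max())
    if pmax <= pmin:  # constant signal: widen range so gain is finite
        pmax = pmin + 1.0
    # re-parse the truncated header fields so scaling matches what a
    # reader will reconstruct
    pmin = float(_num(8, pmin).decode())
    pmax = float(_num(8, pmax).decode())
    n = x.size
    rate_int = int(round(sampling_rate))
    if abs(sampling_rate - rate_int) < 1e-9 and n % rate_int == 0:
        spr, n_records, duration = rate_int, n // rate_int, 1.0
    else:
        spr, n_records, duration = n, 1, n / sampling_rate
    start = start_time or _dt.datetime(2000, 1, 1)

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii("Startdate X X X X", 80),
            _ascii(start.strftime("%d.%m.%y"), 8),
            _ascii(start.strftime("%H.%M.%S"), 8),
            _ascii(256 + 256 * 1, 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _num(8, duration),
            _ascii(1, 4),
        ]
    )
    sig_header = b"".join(
        [
            _ascii(label[:16], 16),
            _ascii("", 80),
            _ascii(physical_dimension[:8], 8),
            _num(8, pmin),
            _num(8, pmax),
            _ascii(_INT16_MIN, 8),
            _ascii(_INT16_MAX, 8),
            _ascii("", 80),
            _ascii(spr, 8),
            _ascii("", 32),
        ]
    )
    gain = (_INT16_MAX - _INT16_MIN) / (pmax - pmin)
    digital = np.clip(
        np.round((x - pmin) * gain) + _INT16_MIN, _INT16_MIN, _INT16_MAX
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(digital.tobytes())


def read_edf(path: str | os.PathLike, channel: int | str = 0):
    """Read one channel of an EDF file.

    Returns ``(samples, sampling_rate, label, start_time)`` with samples
    rescaled to physical units.
    """
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise InputError(f"{path}: truncated EDF header")

        def fld(off: int, width: int) -> str:
            return head[off : off + width].decode("ascii", "replace").strip()

        try:
            n_records = int(fld(236, 8))
            duration = float(fld(244, 8))
            ns = int(fld(252, 4))
        except ValueError as exc:
            raise InputError(f"{path}: malformed EDF header: {exc}") from None
        try:
            start_time = _dt.datetime.strptime(
                fld(168, 8) + " " + fld(176, 8), "%d.%m.%y %H.%M.%S"
            )
        except ValueError:
            start_time = None
        sig = fh.read(256 * ns)
        labels = [sig[16 * i : 16 * (i + 1)].decode("ascii", "replace").strip()
                  for i in range(ns)]
        if isinstance(channel, str):
            if channel not in labels:
                raise InputError(f"{path}: no channel labeled {channel!r}")
            ch = labels.index(channel)
        else:
            ch = int(channel)
            if not 0 <= ch < ns:
                raise InputError(f"{path}: channel {ch} out of range (ns={ns})")

        # per-signal field blocks in order: label16, transducer80, dim8,
        # pmin8, pmax8, dmin8, dmax8, prefilter80, spr8, reserved32
        offsets = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
        starts = np.concatenate([[0], np.cumsum(np.array(offsets) * ns)[:-1]])

        def per_signal(field_idx: int, i: int) -> str:
            w = offsets[field_idx]
            base = int(starts[field_idx]) + i * w
            return sig[base : base + w].decode("ascii", "replace").strip()

        pmin = float(per_signal(3, ch))
        pmax = float(per_signal(4, ch))
        dmin = float(per_signal(5, ch))
        dmax = float(per_signal(6, ch))
        spr = [int(per_signal(8, i)) for i in range(ns)]
        if duration <= 0:
            raise InputError(f"{path}: non-positive record duration")
        rate = spr[ch] / duration
        rec_len = sum(spr)
        raw = np.frombuffer(fh.read(2 * rec_len * n_records), dtype="<i2")
        if raw.size < rec_len * n_records:
            n_records = raw.size // rec_len
            raw = raw[: rec_len * n_records]
        recs = raw.reshape(n_records, rec_len)
        off = sum(spr[:ch])
        digital = recs[:, off : off + spr[ch]].reshape(-1).astype(float)
    if dmax == dmin:
        raise InputError(f"{path}: degenerate digital range")
    samples = (digital - dmin) / (dmax - dmin) * (pmax - pmin) + pmin
    return samples, rate, labels[ch], start_time


def write_wfdb(
    path: str | os.PathLike,
    samples: np.ndarray,
    sampling_rate: float,
    label: str = "signal",
    units: str = "mV",
) -> None:
    """Write a WFDB record (``.hea`` + format-16 ``.dat``).

    ``path`` is the record base name (with or without ``.hea``).
    """
    base = re.sub(r"\.hea$", "", os.fspath(path))
    record = os.path.basename(base)
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise InputError("WFDB writer needs a non-empty 1-D array")
    x = np.where(np.isfinite(x), x, 0.0)
    amax = float(np.max(np.abs(x)))
    gain = 30000.0 / amax if amax > 0 else 200.0
    digital = np.clip(np.round(x * gain), _INT16_MIN, _INT16_MAX).astype("<i2")
    fs = f"{sampling_rate:.10g}"
    with open(base + ".hea", "w") as fh:
        fh.write(f"{record} 1 {fs} {x.size}\n")
        fh.write(
            f"{record}.dat 16 {gain:.10g}(0)/{units} 16 0 "
            f"{int(digital[0])} 0 0 {label}\n"
        )
    with open(base + ".dat", "wb") as fh:
        fh.write(digital.tobytes())


def read_wfdb(path: str | os.PathLike, channel: int | str = 0):
    """Read one channel of a WFDB record (format 16 only).

    Returns ``(samples, sampling_rate, label)``.
    """
    base = re.sub(r"\.hea$", "", os.fspath(path))
    hea = base + ".hea"
    if not os.path.exists(hea):
        raise InputError(f"{hea}: header file not found")
    with open(hea) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    if len(head) < 4:
        raise InputError(f"{hea}: malformed record line")
    nsig = int(head[1])
    fs = float(head[2].split("/")[0])
    nsamp = int(head[3])
    sig_lines = lines[1 : 1 + nsig]
    specs = []
    for ln in sig_lines:
        parts = ln.split()
        fname, fmt = parts[0], parts[1].split("x")[0]
        if fmt != "16":
            raise InputError(f"{hea}: unsupported WFDB format {fmt} (only 16)")
        gain_field = parts[2] if len(parts) > 2 else "200"
        m = re.match(r"([-\d.eE+]+)(?:\(([-\d.eE+]+)\))?(?:/(\S+))?", gain_field)
        gain = float(m.group(1)) if m else 200.0
        if gain == 0:
            gain = 200.0
        baseline = float(m.group(2)) if m and m.group(2) else 0.0
        desc = " ".join(parts[9:]) if len(parts) > 9 else ""
        specs.append((fname, gain, baseline, desc))
    labels = [s[3] for s in specs]
    if isinstance(channel, str):
        if channel not in labels:
            raise InputError(f"{hea}: no channel labeled {channel!r}")
        ch = labels.index(channel)
    else:
        ch = int(channel)
        if not 0 <= ch < nsig:
            raise InputError(f"{hea}: channel {ch} out of range (nsig={nsig})")
    dat = os.path.join(os.path.dirname(base), specs[ch][0])
    raw = np.fromfile(dat, dtype="<i2")
    if nsig > 1:
        raw = raw[: (raw.size // nsig) * nsig].reshape(-1, nsig)[:, ch]
    raw = raw[:nsamp].astype(float)
    _, gain, baseline, _ = specs[ch]
    return (raw - baseline) / gain, fs, labels[ch]
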