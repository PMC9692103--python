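"""End-to-end pipelines: waveform → SQI table, SQI table → decisions.

``extract_pipeline`` runs filter → invalid-marking → segmentation, then
per segment: peak/trough detection, beat extraction and enhancement, and
every selected SQI. Segment-level SQIs run on the whole (filtered)
segment; beat-level SQIs are computed per beat and aggregated as mean,
median and std (columns ``<name>_mean`` etc.). Invalid segments keep
their row, all-NA, so row order always matches segment position.

``classify_pipeline`` applies a :class:`~pulseqc.rules.RuleSet` row by
row, producing one accept/reject decision per segment with the
triggering rule recorded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import Segment, SignalType, WaveformRecord
from .errors import ConfigurationError, InputError, PulseQCError
from .peaks import DEFAULT_DETECTOR, detect_peaks, detect_troughs, extract_beats
from .preprocess import (FilterSpec, bandpass_filter, default_filter,
                         mark_invalid, segment_by_duration, taper_and_smooth)
from .rules import RuleSet, apply_ruleset
from .sqi import hrv as sqi_hrv
from .sqi import morphology as sqi_morph
from .sqi import statistical as sqi_stat

__all__ = ["PipelineConfig", "extract_pipeline", "classify_pipeline",
           "SEGMENT_SQIS", "BEAT_SQIS", "DEFAULT_SQI_SELECTION"]

logger = logging.getLogger(__name__)

META_COLUMNS = ("segment_id", "start_s", "end_s")


@dataclass
class PipelineConfig:
    """All tunables of the extraction pipeline, JSON round-trippable."""

    filter: FilterSpec | None = None
    segment_length_s: float = 30.0
    invalid_tolerance: float = 0.0
    flatline_min_s: float = 2.0
    zero_run_min_s: float = 2.0
    detector_id: int = DEFAULT_DETECTOR
    detector_params: dict = field(default_factory=dict)
    sqi_selection: list[str] = field(default_factory=lambda: list(DEFAULT_SQI_SELECTION))
    beat_target_len: int = 100
    taper_window: str = "tukey"
    smooth_len: int = 3

    def __post_init__(self) -> None:
        if self.segment_length_s <= 0:
            raise ConfigurationError("segment_length_s must be > 0")
        if not self.sqi_selection:
            raise ConfigurationError("sqi_selection must name at least one SQI")
        known = set(SEGMENT_SQIS) | set(BEAT_SQIS)
        for name in self.sqi_selection:
            if name not in known:
                raise ConfigurationError(f"unknown SQI {name!r}; known: "
                                         f"{sorted(known)}")

    @classmethod
    def from_json(cls, json_text: str) -> "PipelineConfig":
        try:
            doc = json.loads(json_text)
        except json.JSONDecodeError as exc:
            raise ConfigurationError(f"config is not valid JSON: {exc}") from None
        if not isinstance(doc, dict):
            raise ConfigurationError("config must be a JSON object")
        filt = doc.pop("filter", None)
        kwargs = {k: v for k, v in doc.items()}
        cfg = cls(**kwargs) if kwargs else cls()
        if filt is not None:
            cfg.filter = FilterSpec(**filt)
        return cfg

    def to_json(self) -> str:
        doc = asdict(self)
        return json.dumps(doc, indent=2)


# --- SQI registry -------------------------------------------------------
# Each segment-level entry maps a canonical name to a function of the
# per-segment context returning {column: value}.

def _ctx_perfusion(ctx):
    return {"perfusion_sqi": sqi_stat.perfusion_sqi(ctx["raw"], ctx["filtered"])}


def _ctx_stat(name, func):
    def inner(ctx):
        return {name: func(ctx["filtered"])}
    return inner


def _ctx_snr(ctx):
    return {"snr_sqi": sqi_stat.snr_sqi(ctx["filtered"], ctx["rate"])}


def _ctx_relative_power(ctx):
    return {"relative_power_sqi": sqi_stat.relative_power_sqi(
        ctx["filtered"], ctx["rate"])}


def _ctx_qrs_energy(ctx):
    return {"qrs_energy_sqi": sqi_morph.qrs_energy_sqi(ctx["filtered"], ctx["rate"])}


def _ctx_msq(ctx):
    return {"msq_sqi": sqi_morph.msq_sqi(ctx["filtered"], ctx["rate"])}


def _ctx_msq_shift(ctx):
    return {"msq_shift_sqi": sqi_morph.msq_shift_sqi(
        ctx["filtered"], ctx["rate"], detector_id=ctx["detector_id"])}


def _ctx_correlogram(ctx):
    res = sqi_morph.correlogram_sqi(ctx["filtered"], ctx["rate"])
    out = {}
    for i, (lag, prom) in enumerate(zip(res["lags_s"], res["prominences"]), 1):
        out[f"acf_lag_{i}"] = lag
        out[f"acf_prom_{i}"] = prom
    return out


def _ctx_hrv_time(ctx):
    if ctx["peaks"].size < 3:
        return {k: float("nan") for k in sqi_hrv.HRV_TIME_KEYS}
    nn = sqi_hrv.nn_intervals(ctx["peaks"], ctx["rate"], "malik")
    return sqi_hrv.hrv_time_sqi(nn)


def _ctx_hrv_freq(ctx):
    if ctx["peaks"].size < 4:
        return {k: float("nan") for k in sqi_hrv.HRV_FREQ_KEYS}
    nn = sqi_hrv.nn_intervals(ctx["peaks"], ctx["rate"], "malik")
    return sqi_hrv.hrv_freq_sqi(nn)


def _ctx_ectopic(ctx):
    if ctx["peaks"].size < 4:
        return {"ectopic_sqi": float("nan")}
    raw = sqi_hrv.nn_intervals(ctx["peaks"], ctx["rate"], "none")
    return {"ectopic_sqi": sqi_hrv.ectopic_sqi(raw)}


def _ctx_amplitude_ratio(ctx):
    res = sqi_morph.amplitude_ratio_sqi(ctx["beats"], ctx["signal_type"])
    return {"qrs_a_sqi_mean": res["mean"], "qrs_a_sqi_std": res["std"]}


SEGMENT_SQIS = {
    "perfusion_sqi": _ctx_perfusion,
    "kurtosis_sqi": _ctx_stat("kurtosis_sqi",
                              lambda x: sqi_stat.moment_sqi(x, "kurtosis")),
    "skewness_sqi": _ctx_stat("skewness_sqi",
                              lambda x: sqi_stat.moment_sqi(x, "skewness")),
    "entropy_sqi": _ctx_stat("entropy_sqi", sqi_stat.entropy_sqi),
    "snr_sqi": _ctx_snr,
    "relative_power_sqi": _ctx_relative_power,
    "zero_crossing_sqi": _ctx_stat("zero_crossing_sqi",
                                   lambda x: sqi_stat.crossing_sqi(x, "zero")),
    "mean_crossing_sqi": _ctx_stat("mean_crossing_sqi",
                                   lambda x: sqi_stat.crossing_sqi(x, "mean")),
    "qrs_energy_sqi": _ctx_qrs_energy,
    "msq_sqi": _ctx_msq,
    "msq_shift_sqi": _ctx_msq_shift,
    "correlogram_sqi": _ctx_correlogram,
    "hrv_time_sqi": _ctx_hrv_time,
    "hrv_freq_sqi": _ctx_hrv_freq,
    "ectopic_sqi": _ctx_ectopic,
    "qrs_a_sqi": _ctx_amplitude_ratio,
}

# beat-level SQIs: computed per enhanced beat, aggregated mean/median/std
BEAT_SQIS = {
    "kurtosis": lambda beat, ctx: sqi_stat.moment_sqi(beat, "kurtosis"),
    "skewness": lambda beat, ctx: sqi_stat.moment_sqi(beat, "skewness"),
    "entropy": lambda beat, ctx: sqi_stat.entropy_sqi(beat),
    "dtw_sqi": lambda beat, ctx: sqi_morph.dtw_sqi(beat, ctx["template"]),
}

DEFAULT_SQI_SELECTION = (
    "perfusion_sqi", "kurtosis_sqi", "skewness_sqi", "entropy_sqi",
    "snr_sqi", "relative_power_sqi", "zero_crossing_sqi", "mean_crossing_sqi",
    "msq_sqi", "correlogram_sqi", "hrv_time_sqi", "ectopic_sqi",
    "kurtosis", "skewness", "entropy", "dtw_sqi", "qrs_a_sqi",
)

_AGGS = {"mean": np.nanmean, "median": np.nanmedian, "std": np.nanstd}


def _columns_for(selection, signal_type) -> list[str]:
    cols: list[str] = []
    probe_ctx_keys = {
        "hrv_time_sqi": list(sqi_hrv.HRV_TIME_KEYS),
        "hrv_freq_sqi": list(sqi_hrv.HRV_FREQ_KEYS),
        "correlogram_sqi": [f"acf_{w}_{i}" for i in (1, 2, 3)
                            for w in ("lag", "prom")],
        "qrs_a_sqi": ["qrs_a_sqi_mean", "qrs_a_sqi_std"],
    }
    # correlogram column order: lag_1, prom_1, lag_2, ...
    probe_ctx_keys["correlogram_sqi"] = [c for i in (1, 2, 3)
                                         for c in (f"acf_lag_{i}", f"acf_prom_{i}")]
    for name in selection:
        if name in BEAT_SQIS:
            cols.extend(f"{name}_{agg}" for agg in _AGGS)
        elif name in probe_ctx_keys:
            cols.extend(probe_ctx_keys[name])
        else:
            cols.append(name)
    return cols


def extract_pipeline(record: WaveformRecord,
                     config: PipelineConfig | None = None) -> pd.DataFrame:
    """Run the full waveform → SQI-table pipeline on one record."""
    config = config or PipelineConfig()
    spec = config.filter or default_filter(record.signal_type)
    marked = mark_invalid(record, config.flatline_min_s, config.zero_run_min_s)
    filtered = bandpass_filter(marked, spec)
    segments = segment_by_duration(marked, config.segment_length_s,
                                   config.invalid_tolerance,
                                   filtered=filtered.samples)
    logger.info("extract: %d segments (%d valid)", len(segments),
                sum(s.valid for s in segments))
    if not segments:
        logger.warning("extract: record shorter than one segment — empty table")

    columns = _columns_for(config.sqi_selection, record.signal_type)
    template = sqi_morph.make_template(
        "ppg_double_gaussian" if record.signal_type is SignalType.PPG
        else "ecg_pqrst_gaussian_sum", config.beat_target_len)

    rows = []
    for seg in segments:
        row = {"segment_id": seg.index, "start_s": seg.start_s,
               "end_s": seg.end_s}
        if not seg.valid:
            row.update({c: np.nan for c in columns})
            rows.append(row)
            continue
        ann = detect_peaks(seg, config.detector_id, config.detector_params)
        ann = detect_troughs(seg, ann)
        beats: list[np.ndarray] = []
        if ann.trough_indices.size >= 2:
            raw_beats = extract_beats(seg, ann.trough_indices,
                                      config.beat_target_len)
            for b in raw_beats:
                try:
                    beats.append(taper_and_smooth(b, config.taper_window,
                                                  config.smooth_len))
                except PulseQCError:
                    continue
        ctx = {
            "raw": seg.raw_samples, "filtered": seg.filtered_samples,
            "rate": seg.sampling_rate, "peaks": ann.peak_indices,
            "troughs": ann.trough_indices, "beats": beats,
            "signal_type": record.signal_type, "template": template,
            "detector_id": config.detector_id,
        }
        for name in config.sqi_selection:
            if name in BEAT_SQIS:
                vals = []
                for beat in beats:
                    try:
                        vals.append(BEAT_SQIS[name](beat, ctx))
                    except PulseQCError:
                        vals.append(float("nan"))
                arr = np.asarray(vals, dtype=float)
                for agg, fn in _AGGS.items():
                    col = f"{name}_{agg}"
                    row[col] = (float(fn(arr)) if arr.size and
                                not np.all(np.isnan(arr)) else float("nan"))
            else:
                try:
                    row.update(SEGMENT_SQIS[name](ctx))
                except PulseQCError as exc:
                    logger.info("segment %d: %s failed: %s", seg.index, name, exc)
                    row.update({c: np.nan for c in columns if
                                c.startswith(name.replace("_sqi", ""))
                                or c == name})
        # any column still missing (e.g. failed expansion) becomes NA
        for c in columns:
            row.setdefault(c, np.nan)
        rows.append(row)
    table = pd.DataFrame(rows, columns=list(META_COLUMNS) + columns)
    return table


def classify_pipeline(table: pd.DataFrame, ruleset: RuleSet) -> pd.DataFrame:
    """Apply a ruleset to every row of an SQI table.

    Returns a DataFrame with ``segment_id``, ``label`` and
    ``triggered_rule`` (empty string when no rule fired).
    """
    for name in ruleset.order:
        if name not in table.columns:
            raise ConfigurationError(f"ruleset references missing column {name!r}")
    seg_ids = (table["segment_id"].tolist() if "segment_id" in table.columns
               else list(range(len(table))))
    out = []
    for sid, (_, row) in zip(seg_ids, table.iterrows()):
        d = apply_ruleset(ruleset, row.to_dict(), segment_id=sid)
        out.append({"segment_id": d.segment_id, "label": d.label,
                    "triggered_rule": d.triggered_rule or ""})
    df = pd.DataFrame(out, columns=["segment_id", "label", "triggered_rule"])
    n_acc = int((df["label"] == "accept").sum())
    logger.info("classify: %d accept / %d reject", n_acc, len(df) - n_acc)
    return df
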