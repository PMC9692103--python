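"""Morphology/agreement SQIs: MSQ, correlogram, templates, DTW, ratios."""

import math

import numpy as np
import pytest

import pulseqc as p
from pulseqc.errors import ConfigurationError
from pulseqc.sqi.morphology import (amplitude_ratio_sqi, correlogram_sqi,
                                    dtw_sqi, make_template, msq_shift_sqi,
                                    msq_sqi, qrs_energy_sqi)

RATE = 100.0


class TestMSQ:
    def test_identical_peak_sets(self):
        peaks = np.arange(50, 950, 80)
        assert msq_sqi(None, RATE, peaks_a=peaks, peaks_b=peaks) == 1.0

    def test_half_missing(self):
        """|A| = 10, B = first 5 of A → 5 matched / max(10, 5) = 0.5."""
        a = np.arange(50, 850, 80)
        assert a.size == 10
        assert msq_sqi(None, RATE, peaks_a=a, peaks_b=a[:5]) == 0.5

    def test_disjoint_sets(self):
        a = np.array([100, 300, 500])
        b = a + 60  # 0.6 s away, beyond the 0.15 s tolerance
        assert msq_sqi(None, RATE, peaks_a=a, peaks_b=b) == 0.0

    def test_empty_sets_na(self):
        assert math.isnan(msq_sqi(None, RATE, peaks_a=np.array([]),
                                  peaks_b=np.array([])))

    def test_symmetric_in_detector_order(self, clean_ppg_filtered):
        record, _ = clean_ppg_filtered
        x = record.samples[:3000]
        ab = msq_sqi(x, RATE, detector_a=6, detector_b=7)
        ba = msq_sqi(x, RATE, detector_a=7, detector_b=6)
        assert ab == pytest.approx(ba)

    def test_same_detector_rejected(self, clean_ppg_filtered):
        record, _ = clean_ppg_filtered
        with pytest.raises(ConfigurationError):
            msq_sqi(record.samples[:3000], RATE, detector_a=5, detector_b=5)

    def test_shift_variant_high_on_clean(self, clean_ppg_filtered):
        """Shifting a good-quality signal does not change its peaks."""
        record, _ = clean_ppg_filtered
        assert msq_shift_sqi(record.samples[:3000], RATE) >= 0.9


class TestCorrelogram:
    def test_first_peak_at_beat_period(self, clean_ppg_filtered):
        record, _ = clean_ppg_filtered  # 75 bpm → 0.8 s period
        out = correlogram_sqi(record.samples[:3000], RATE)
        assert out["lags_s"][0] == pytest.approx(0.8, abs=0.05)

    @pytest.mark.parametrize("hr", [50, 75, 100, 120])
    def test_lag_tracks_heart_rate(self, hr):
        """First autocorrelation peak sits at 60/HR s within ±5%."""
        spec = p.SynthesisSpec(duration_s=30.0, heart_rate_bpm=hr,
                               hrv_sd_ms=10.0, noise_sd=0.05, seed=300 + hr)
        record, _ = p.synth_record(spec)
        x = p.bandpass_filter(record).samples
        out = correlogram_sqi(x, RATE, max_lag_s=2.0)
        assert out["lags_s"][0] == pytest.approx(60.0 / hr, rel=0.05)

    def test_white_noise_no_prominent_peaks(self):
        x = np.random.default_rng(9).standard_normal(3000)
        out = correlogram_sqi(x, RATE)
        proms = [v for v in out["prominences"] if not math.isnan(v)]
        assert all(v <= 0.2 for v in proms)

    def test_sine_peaks_at_period_multiples(self):
        t = np.arange(0, 30, 1 / RATE)
        x = np.sin(2 * np.pi * t / 1.0)  # period 1 s
        out = correlogram_sqi(x, RATE, max_lag_s=3.5)
        # grid resolution is one sample = 0.01 s
        for i, expected in enumerate([1.0, 2.0, 3.0]):
            assert out["lags_s"][i] == pytest.approx(expected, abs=0.02)

    def test_zero_variance_na(self):
        out = correlogram_sqi(np.full(1000, 1.5), RATE)
        assert all(math.isnan(v) for v in out["lags_s"])


class TestTemplates:
    def test_ppg_shape(self):
        tpl = make_template("ppg_double_gaussian", 100)
        assert np.max(np.abs(tpl.samples)) == pytest.approx(1.0)
        assert np.argmax(tpl.samples) == pytest.approx(30, abs=2)

    def test_ecg_shape(self):
        tpl = make_template("ecg_pqrst_gaussian_sum", 200)
        x = tpl.samples
        assert np.argmax(x) == pytest.approx(80, abs=3)  # R at 0.40
        # Q and S are negative deflections flanking R
        r = int(np.argmax(x))
        assert np.min(x[:r]) < -0.05 and np.min(x[r:]) < -0.05

    def test_length_scale_invariance(self):
        a = make_template("ppg_double_gaussian", 100).samples
        b = make_template("ppg_double_gaussian", 200).samples
        b_down = np.interp(np.linspace(0, 1, 100, endpoint=False),
                           np.linspace(0, 1, 200, endpoint=False), b)
        assert np.corrcoef(a, b_down)[0, 1] > 0.999

    def test_invalid_params(self):
        with pytest.raises(ConfigurationError):
            make_template("ppg_double_gaussian", 100, {"sigma1": -1.0})
        with pytest.raises(ConfigurationError):
            make_template("ppg_double_gaussian", 100, {"mu1": 1.5})
        with pytest.raises(ConfigurationError):
            make_template("nope", 100)
        with pytest.raises(ConfigurationError):
            make_template("ppg_double_gaussian", 8)


class TestDTW:
    def test_identity_is_zero(self):
        tpl = make_template("ppg_double_gaussian", 100)
        assert dtw_sqi(tpl.samples, tpl) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(21)
        a, b = rng.standard_normal(40), rng.standard_normal(50)
        assert dtw_sqi(a, b) == pytest.approx(dtw_sqi(b, a))

    def test_single_sample_perturbation_bound(self):
        """Perturbing one sample by δ costs at most δ/path_length via
        the identity alignment."""
        tpl = make_template("ppg_double_gaussian", 100)
        pert = tpl.samples.copy()
        delta = 0.05
        pert[50] += delta
        cost = dtw_sqi(pert, tpl)
        # normalization shifts every sample by O(delta/n), so the
        # identity-path bound carries a small constant factor
        assert 0 < cost <= 4 * delta / 100

    def test_cost_increases_with_noise(self):
        """Mean DTW cost is non-decreasing in noise amplitude over
        seeded trials."""
        tpl = make_template("ppg_double_gaussian", 100)
        rng = np.random.default_rng(31)
        means = []
        for sd in (0.0, 0.05, 0.15, 0.4):
            costs = [dtw_sqi(tpl.samples + sd * rng.standard_normal(100), tpl)
                     for _ in range(50)]
            means.append(np.mean(costs))
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_degenerate_beat_na(self):
        tpl = make_template("ppg_double_gaussian", 100)
        assert math.isnan(dtw_sqi(np.full(50, 2.0), tpl))


class TestBandEnergyAndRatios:
    def test_qrs_energy_band_localization(self):
        t = np.arange(0, 30, 1 / RATE)
        assert qrs_energy_sqi(np.sin(2 * np.pi * 10 * t), RATE) >= 0.95
        assert qrs_energy_sqi(np.sin(2 * np.pi * 30 * t), RATE) <= 0.05

    def test_qrs_energy_white_noise(self):
        x = np.random.default_rng(41).standard_normal(60_000)
        assert qrs_energy_sqi(x, RATE) == pytest.approx(10 / 35, abs=0.05)

    def test_ecg_peak_to_nadir(self):
        beat = np.concatenate([np.linspace(0, 1.0, 30),
                               np.linspace(1.0, -0.3, 30)])
        out = amplitude_ratio_sqi([beat], "ecg")
        assert out["mean"] == pytest.approx(1.3)
        assert out["std"] == 0.0

    def test_ppg_systolic_diastolic_ratio(self):
        tpl = make_template("ppg_double_gaussian", 200)
        out = amplitude_ratio_sqi([tpl.samples], "ppg")
        assert out["mean"] == pytest.approx(2.0, abs=0.15)

    def test_single_bump_na(self):
        bump = make_template("ppg_double_gaussian", 100, {"a": 0.0}).samples
        out = amplitude_ratio_sqi([bump], "ppg")
        assert math.isnan(out["mean"])

    def test_empty_beats_na(self):
        out = amplitude_ratio_sqi([], "ppg")
        assert math.isnan(out["mean"])
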