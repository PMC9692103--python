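# Methods

This note documents the models, conventions and design choices behind
`pulseqc`: what each stage computes, the defaults and why, what the
synthetic generator does and does not emulate, and the known limits of
what the test suite demonstrates.

## Signal model and preprocessing

A recording is a single-channel sampled waveform (ECG or PPG) with a
per-sample validity mask. Reading never drops samples: unparseable or
missing values stay in place, flagged invalid, so indices remain aligned
with the source file. Invalid-signal marking flags maximal runs of
exactly repeated values (flatlines, e.g. a frozen sensor) and runs of
zeros (transmission dropout) lasting at least a threshold duration.
Both thresholds default to 2 s — long enough to exceed any plausible
diastolic plateau at the slowest physiological heart rates, short
enough to catch brief disconnections. Marking is idempotent, and
already-invalid samples never return to valid.

Filtering is a zero-phase (forward–backward) band-pass, Butterworth
order 4 by default, so that peak positions are not shifted by filter
phase delay. Default bands: 0.5–8 Hz for PPG (pulse fundamental and
first harmonics for any heart rate in 30–220 bpm), 0.5–40 Hz for ECG
(QRS spectral content). Chebyshev-I (1 dB ripple) and elliptic
(1 dB/40 dB) designs are available. Invalid samples are replaced by the
record mean before filtering so a NaN burst does not poison the output;
their flags are preserved.

Segmentation tiles the record into consecutive, non-overlapping
segments of fixed duration (default 30 s — long enough for meaningful
HRV statistics, short enough that a single artifact does not dominate).
The trailing partial segment is dropped so all rows have equal length.
A segment whose invalid-sample fraction exceeds `invalid_tolerance`
(default 0.0, i.e. any invalid sample) is kept in the table as an
all-NA row: only fully valid spans contribute SQI values, and row
positions always match segment positions.

## Peak detection

Seven deterministic detectors are exposed by integer id; all share a
refractory-period constraint (default 0.3 s, a 200 bpm ceiling): of two
candidates closer than that, the larger-amplitude one survives, with
amplitude ties broken toward the earlier index.

1. *Adaptive threshold* — local maxima above a fraction (0.5) of an
   exponentially decaying running maximum (2 s time constant).
   Amplitudes are measured from the median baseline, which is robust to
   the asymmetric pulse shape.
2. *Count origin* — local maxima of a lightly smoothed copy, validated
   by requiring monotone ascent and descent runs of at least 40 ms on
   each side.
3. *Clustering* — deterministic 2-means on local-maximum amplitudes,
   centroids seeded at the min and max amplitude; the upper cluster are
   peaks. No randomness, hence bit-reproducible.
4. *Slope sum* — windowed sum of positive slopes (128 ms window); SSF
   maxima above half the local (±2 s) SSF maximum, refined to the
   waveform maximum within ±150 ms.
5. *Two moving averages* (default for PPG) — the clipped signal is
   squared; a beat-scale average (111 ms) crossing above a segment-scale
   average (667 ms) plus an offset of 0.1 × the mean squared signal
   defines blocks of interest; each sufficiently wide block contributes
   its waveform maximum. The offset suppresses diastolic-bump blocks at
   slow heart rates, where the cycle is much longer than the beat-scale
   window.
6. *Prominence/distance* — `scipy.signal.find_peaks` with prominence
   0.3 × the signal range and the refractory distance.
7. *Billauer delta* — alternating max/min tracking with a lookahead
   delta of 0.3 × the signal range.

Thresholds are relative (fractions of range, running maxima, or mean
energy), so detectors 1, 3, 5, 6 and 7 are invariant to positive
amplitude scaling, and all are equivariant to time translation.

For ECG, detection runs on a squared-derivative transform (band-pass
5–15 Hz, differentiate, square, 150 ms moving-window integration — the
classic QRS-energy preconditioning); detected peaks are then refined to
the filtered-signal maximum within ±100 ms so indices land on the R
wave.

Troughs are the minima strictly between consecutive peaks (earliest
index on plateaus). Beats are cut trough-to-trough, resampled to a
common length (default 100 samples) by linear interpolation,
baseline-shifted to start at zero, and — before beat-wise SQIs —
enhanced by a Tukey taper (α = 0.5) and a short moving average
(3 samples), which unifies beat baselines and suppresses single-sample
spikes. Beats shorter than 0.25 s or longer than 2 s are segmentation
failures and are skipped with a log entry.

## Signal quality indices

**Statistical.** Perfusion = (max − min of the filtered segment) /
|mean raw| × 100. Skewness and kurtosis are 1/N-normalized standardized
moments; kurtosis is reported raw (Gaussian → 3), with no excess
subtraction. The energy entropy first scales the signal to unit energy
so that p_n = x_n²/Σx² is a probability distribution; the result lies
in [0, ln N] nats. Without that normalization the quantity would be
scale-dependent and unbounded, which would make any fixed threshold
meaningless across devices. SNR is the variance ratio of a
moving-average "signal part" (default 100 ms) to its exact residual.
Relative power is the Welch-PSD mass in 1–2.25 Hz over 0–8 Hz (the PPG
pulse band); the QRS-energy variant uses 5–15 Hz over 5–40 Hz. Welch
uses 4-s windows, 50% overlap, constant detrend; band masks are
half-open [low, high) so a flat spectrum yields exactly the bandwidth
ratio. Crossing counts use strict sign alternation with carry-forward
at samples exactly on the reference level, which is deterministic on
quantized signals.

**HRV / RR-interval.** NN intervals are successive peak-index
differences in ms. The Malik ectopic rule removes intervals deviating
more than 20% from the last *retained* interval (comparing to the raw
predecessor would cascade: the interval after an ectopic would also be
flagged); the alternative median rule removes deviations > 30% from the
running median of 5. SDNN/SDSD use the sample (n−1) standard deviation,
the HRV-literature convention. pNN50/pNN20 divide by the number of
successive differences (not the number of intervals): each |d_i| is a
per-difference event. The frequency-domain indices interpolate the NN
series to a 4 Hz tachogram (cubic), take a Welch PSD, and integrate the
Task-Force bands VLF [0.003, 0.04), LF [0.04, 0.15), HF [0.15, 0.4) Hz;
they are undefined for series spanning under 60 s. The ectopic SQI is
the Malik-flagged fraction of raw intervals.

**Waveform/agreement.** MSQ is the greedy one-to-one matching fraction
(within 0.15 s, below half the shortest physiological beat) between two
distinct detectors' peak sets, normalized by the larger set. A
self-consistency variant compares detection on the original and on a
1-s-shifted copy of the signal. The correlogram SQI reports the lags
and prominences of the first autocorrelation peaks (normalized to 1 at
lag 0); peaks with prominence below 0.1 are ignored, since sampling
noise produces micro-maxima with prominence < 0.02 at arbitrary lags
while true periodicity peaks sit near 1 — with the floor, the first
reported lag equals the beat period on quasi-periodic signal. DTW is
the classic dynamic programming alignment with |a − b| local cost, no
windowing (beats are ≤ a few hundred samples, so the full O(nm) table
is cheap), after zero-mean/unit-max-abs normalization of both
sequences; the reported value is the optimal path's accumulated cost
divided by that path's length, so it is 0 exactly for identical shapes
and insensitive to beat length. Templates are analytic: the PPG beat is
a double Gaussian (systolic bump at 30% of the cycle, diastolic bump at
65% with half amplitude), the ECG beat a sum of five signed Gaussians
(P, Q, R, S, T with R at 40%). Amplitude ratios: ECG peak-to-nadir
range per beat; PPG systolic/diastolic ratio, the diastolic shoulder
being the highest local maximum after the global one (NA when the
waveform shows no diastolic bump).

## Rule engine and threshold derivation

A rule attaches ordered threshold boundaries to one SQI column; the
first matching boundary decides, no match accepts, and an undefined
value falls to the rule's NA policy (default reject — in quality
control an uncomputable index is evidence against the segment, and it
is what routes fully invalid segments to rejection). A ruleset executes
rules in a fixed order with AND semantics: the first rejecting rule
short-circuits and is recorded as the trigger. Under conjunction the
accept/reject label is order-independent; only the recorded trigger
depends on order. The JSON schema is pinned in the module docstring and
validated with error paths to the offending node.

Threshold derivation offers (a) the 95th percentile of the accept-class
histogram (linear interpolation) and (b) a brute-force search over
pooled-value quantiles on a 0.05 grid, trying both rejection directions
and maximizing balanced accuracy (ties: smallest threshold, then
reject-below). Balanced accuracy is used because labeled QC datasets
are typically imbalanced toward accepts. Pair search builds the
AND-ruleset for every unordered pair of candidate SQIs from their
single-SQI searches and reports per-class accuracies, overall accuracy,
the Brier score of the 0/1 decision, the ROC AUC of the pair's combined
margin score (the minimum of the members' threshold margins, scaled by
each SQI's spread), and F-beta; pairs are ranked by AUC.

## Synthetic generator

The generator is the package's stand-in for device recordings: beat
intervals are drawn i.i.d. Gaussian around 60000/HR ms (default jitter
30 ms), truncated at ±40% of the mean; each cycle is rendered
trough-to-trough from the same analytic templates the DTW SQI uses;
baseline wander is a slow sinusoid (default amplitude 0.2, 0.25 Hz —
respiration band) and measurement noise is white (default sd 0.05 of
the unit pulse amplitude). Defaults describe a clean wearable PPG at
100 Hz and 75 bpm. Artifacts are injected over explicit spans:
flatline (hold), dropout (zeros), seeded spike bursts, added Gaussian
noise. Identical specs (including the mandatory seed) produce
bit-identical records.

What it does **not** emulate: autocorrelated (autoregressive) HRV —
LF/HF structure must be added explicitly as sinusoidal modulation in
tests; pathological rhythms (AF, bigeminy, ectopy with compensatory
pauses); morphology drift, pulsus alternans, or motion artifacts with
in-band spectral content; sensor nonlinearities. Consequently, passing
tests demonstrate correctness of the *computations* and sensible
behavior of the *pipeline* on idealized quasi-periodic input, not
clinical-grade classification performance on patient data; thresholds
that separate clean from corrupted synthetic segments will generally
need re-derivation on labeled recordings from the actual device, for
which the `derive-thresholds` procedure is provided.

## Template ruleset

`resources/ppg_ruleset.json` ships thresholds derived by running the
package's own quantile-grid search on a labeled synthetic set (80
segments, half clean across 50–120 bpm, half corrupted by heavy noise
or spike bursts; seed 2024), then rounding with margin: kurtosis > 2.6
rejects (a clean pulse segment has sub-Gaussian kurtosis ≈ 2.4; spikes
and noise push it up), mean beat-template DTW distance > 0.04 rejects,
first correlogram prominence < 0.9 rejects (loss of periodicity),
detector-agreement MSQ < 0.7 rejects, and Malik ectopic fraction > 0.1
rejects. All NA policies reject, which routes flatline/dropout
segments (all-NA rows) to rejection. The ECG template carries only the
generic agreement/periodicity rules (MSQ, correlogram prominence,
ectopic fraction); it was not derived from a labeled set. These
thresholds are tuned to the synthetic study conditions; see the caveat
above for real data.

## Numerical choices and degenerate inputs

Undefined SQI values are NaN, never 0: zero-variance input for moments
and SNR, zero-mean raw signal for perfusion, zero-energy signal for
entropy, constant beats for DTW, zero-variance segments for the
correlogram. Ties break deterministically everywhere (earliest index
for equal amplitudes and plateau minima; smallest threshold, then
reject-below in the search). EDF and WFDB writing quantizes to the
16-bit integer range of the observed amplitude span (relative error
~1/65535 of the range). Written CSV uses full `repr` precision, comma
separator, `.` decimal and the `NA` token, so tables round-trip to
better than 10 significant digits and repeated runs are byte-identical.

## Problem sizes

The test suite and the acceptance script use 30–120 s records for
detector and SQI checks, a 10-minute record for the end-to-end
classification scenario, 100 random signals for formula-agreement
checks, and 10⁵ draws for the Gaussian-kurtosis spot check — sizes at
which every Monte-Carlo assertion has comfortable margin while the full
suite runs in well under a minute of compute per module.
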