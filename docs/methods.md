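# Methods

`neuroload` implements an EEG analysis chain for detecting elevated
mental workload during turning maneuvers in simulated flight: band-pass
filtering and ICA artifact rejection, wavelet-packet rhythm-band
energies, amplitude-histogram Shannon entropy and sample entropy,
Pearson correlation screening, NASA-TLX questionnaire scoring, and a
binary SVM that labels 2-second epochs as high (turn) or low (cruise)
workload. Because no pilot recordings ship with the package, a
synthetic-data generator provides study conditions with known planted
effects; every claim the test suite makes should be read as a statement
about those conditions, not about real pilots.

## Signal model of the generator

Each of the 14 channels (Emotiv EPOC+ montage, default fs = 128 Hz) is a
sum of independent Gaussian processes, in microvolts RMS:

* 1/f (pink) background, 10 µV;
* band-limited noise in delta [0,4) Hz at 8 µV, theta [4,8) at 6 µV,
  alpha [8,12) at 10 µV, beta [12,30) at 4 µV, each synthesized by FIR
  band-passing white noise (so within-band spectra are flat rather than
  tonal);
* two planted effects during turns: the beta component's amplitude at T7
  is multiplied by `beta_boost` (default 2.0) during left turns, and at
  T8 during right turns — the lateralized temporal beta surge the
  analysis is designed to localize; and `complexity_boost` (default
  2 µV) of white noise is added to **all** channels during any turn,
  raising broadband irregularity;
* artifacts: eye blinks as squared-half-sine pulses (150 µV peak, 0.4 s,
  4/min) added coherently to AF3/AF4, and >20 Hz EMG bursts (20 µV RMS,
  0.3 s, 2/min per channel) on T7/T8/F7/F8.

The default schedule is 60 s cruise, 20 s left turn, 60 s cruise, 20 s
right turn, 60 s cruise, honouring a ≥10 s separation between turns;
`balanced_schedule(n)` builds longer alternating schedules that yield
exactly `n` cruise and `n` turn epochs under the default windowing. All
draws come from one `numpy` generator seeded by a single integer, so
output is bit-reproducible.

What the generator does **not** emulate: non-Gaussian amplitude
statistics, non-stationary rhythms, volume-conduction correlation
between channels, inter-subject variability, or any biophysical forward
model. Consequences are noted below where they matter.

## Preprocessing

The band-pass is a linear-phase windowed-sinc FIR (Hamming), 0.1–40 Hz.
The tap count follows the Hamming transition-width rule 3.3·fs/Δf with
Δf = min(transition, 2·low_hz), capped at 4097 taps; at the defaults
this gives 2111 taps, a measured passband deviation of <0.001 dB at
10 Hz, ~89 dB attenuation at 50 Hz, and DC suppressed below 1% of input.
The filter is applied forward with group-delay compensation
(reflect-padding by half the filter length), keeping the operation
strictly FIR while leaving the output on the input timebase. Signals
shorter than the filter are rejected rather than silently degraded.

ICA uses FastICA (deflation, tanh contrast, fixed seed), components
ordered by explained channel variance. Recordings longer than 40 000
samples are fitted on an evenly strided subsample and the learned
unmixing applied to the full series; since the unmixing is full rank,
the reconstruction identity (mixing · sources + mean = input) is exact
regardless. Ocular components are flagged either by |correlation| > 0.7
with a supplied blink-reference series, or — with no reference — by
frontal (AF3/AF4) mixing-weight dominance > 2 together with a < 4 Hz
spectral fraction > 0.5. The 0.5 figure is deliberate: a blink train is
a *sparse pulse* process whose spectrum is concentrated but not confined
below 4 Hz, and demanding 0.6 was observed to miss unambiguous blink
components (frontal dominance ≈ 30) on some seeds. Muscle components
are flagged when the > 20 Hz spectral fraction exceeds 0.6. Flagged
sources are zeroed before reconstruction; flagging everything is
refused.

## Band energies

Epochs (default 2 s, 50% overlap) are decomposed with a db4 wavelet
packet to level J = log2(fs/(2·bw)), giving uniform ~2 Hz terminal
nodes at the defaults. Terminal nodes are re-ordered into ascending
frequency with the binary-reflected Gray code — the node at frequency
rank f sits at natural (Paley) position f xor (f >> 1) — which the test
suite verifies both against a 1–31 Hz tone sweep and node-by-node
against an independent reference implementation.

Extension mode is **periodized**, not symmetric. With a periodized
orthonormal transform the sum of node energies equals the epoch's sum
of squares to machine precision, which is the invariant the whole
band-energy accounting rests on; measured with the reference oracle,
symmetric extension inflates energy through redundant boundary
coefficients and degrades a boundary tone's in-band fraction from 0.81
to 0.43. The cost is wrap-around leakage for epochs whose ends differ
strongly, negligible at 256-sample epochs of noise-like EEG.

Band energies sum the nodes lying inside delta/theta/alpha/beta; ratios
divide by the in-range (0–30 Hz) total, so the four ratios form a
probability vector; beta/(theta+alpha) is NaN-flagged when its
denominator vanishes. A known sharpness limit: iterated db4 filters
have strong sidelobes, so a pure tone at a node edge (e.g. 10 Hz)
places only ~81% of in-range energy in its nominal band (99% would
require a longer wavelet such as db16, selectable via the `wavelet`
argument). Noise-like signals, for which the pipeline is intended, are
unaffected in the mean. The beta band is 12–30 Hz (the computational
convention; a 14–30 Hz descriptive convention exists and can be
configured). Nodes above 30 Hz are computed but excluded from ratios.

The electrode map reports the per-channel phase-mean band energy, its
argmax channel (ties broken by channel order), and optionally an
inverse-distance-weighted grid over projected 10–20 coordinates for
plotting; publication-grade scalp rendering is out of scope.

## Entropies

Shannon entropy uses an equal-width amplitude histogram over
[min, max] with B = 100 bins and log base 10 (units: dits), so
0 ≤ H ≤ log10 B and a constant epoch scores 0. Sample entropy follows
Richman–Moorman: m = 2, r = 0.2·SD, Chebyshev distance, self-matches
excluded, both template counts taken over the same N−m starts, SampEn =
−ln(A/B), NaN-flagged when a count is zero (no small-count correction).
The implementation builds the m-template distance matrix as a running
maximum of diagonal shifts of the scalar distance matrix (O(mN²), no
embedding copies) and is tested for exact count agreement with a naive
double-loop oracle.

A deliberate asymmetry, kept because the definitions are conventionally
printed that way: Shannon in log10, SampEn in natural log.

**Generator limitation worth knowing:** because every generator
component is Gaussian, adding the complexity noise changes neither the
amplitude-histogram *shape* nor, therefore, the histogram Shannon
entropy in expectation — measured turn-minus-cruise Shannon differences
on 3000-epoch pools are −0.002 to 0.000 dits depending on seed, while
sample entropy rises by ~+0.05 robustly (it sees the extra template
mismatches directly). Real EEG plausibly couples workload to
non-Gaussian amplitude structure that this generator does not model; a
passing suite therefore validates the Shannon *estimator*, not a
Shannon workload effect.

## Statistics

Channel correlation: per epoch a 14×14 Pearson matrix of (optionally
beta-band-filtered) series, averaged across epochs via the Fisher
z-transform (plain averaging of r is biased toward 0), summarized per
channel as mean |r| to all others, with the hub (argmax) channel
reported. Feature correlations reproduce the entropy-by-ratio table
layout per phase. Normality screening is Shapiro–Wilk per feature and
phase, pass = p > 0.05, subsampled deterministically above n = 5000;
the screen is informational and never gates the pipeline.

## NASA-TLX

Six dimensions rated 0–10; 15 pairwise comparisons (ties disallowed)
give weights P_i summing to 15; the overall score is Σ M_i P_i / 15,
bounded by the rating extremes and invariant to joint permutation of
(M, P). Group reliability is Cronbach's alpha from the classic variance
decomposition; "validity" is reported as the Kaiser–Meyer–Olkin
sampling-adequacy measure (the conventional companion statistic in this
questionnaire literature — an interpretation, as the symbol K is not
otherwise pinned down), NaN-flagged for singular correlation matrices.

## Classifier

Features are min-max normalized with extrema fitted on training rows
only (Eq-style (x − min)/(max − min)); test rows may leave [0, 1] and
are not clipped; features constant on the training rows are dropped
with a warning. The split is random stratified (default 2700/300 on a
balanced 3000 pool → 150 per class in the test set), deterministic per
seed. The SVM is a standard maximum-margin dual solve via scikit-learn's
SVC — the package's contribution is the feature pipeline and reporting,
not a bespoke QP. The default kernel is RBF with C = 1 and
gamma = "scale" (1/(d·Var)); a linear kernel is selectable, matching the
two kernel conventions in circulation for this detector.

Default feature columns: beta ratio at T7 and at T8 as *separate*
columns, plus channel-mean Shannon entropy and channel-mean sample
entropy. The spatial aggregation mirrors each effect's footprint: the
beta surge lives on single temporal electrodes (averaging hemispheres
would halve its contrast), while the complexity rise is global
(channel-averaging suppresses estimator noise by ~√14). Measured on the
default study conditions, the two-feature (beta ratio, Shannon) variant
plateaus near 88% test accuracy because of the Shannon non-effect
described above; adding sample entropy lifts the default configuration
to ~91–93%. Any feature subset and channel set remains selectable.

## Pipeline, determinism and problem sizes

`run_pipeline` validates the full config up front (unknown keys are
errors), echoes the resolved config, logs one line per stage, and
round-trips every stage artifact through its declared on-disk format
(EDF, TSV, CSV, JSON). Three named seeds (simulate, ica, split) make
runs byte-reproducible; `features.csv` is compared byte-for-byte in the
determinism test.

EDF output is 16-bit quantized with per-channel physical ranges,
written as a single data record so non-integer sampling rates stay
exact; the files are read back by this package and by an independent
EDF reader in the tests.

Problem sizes used by the test suite and the acceptance script, chosen
to exercise the method at the scale its contracts describe while
keeping runs desk-sized: the localization property uses 20 independent
short runs; phase contrasts and the classifier use one balanced
3000-epoch pool (2700/300 split); chance-level calibration uses 20 (in
tests) or 5 (in the script) pools of 300 epochs; blink-cleaning checks
use 5 short runs. The questionnaire metrics in the acceptance script
are computed on a seeded synthetic response set (10 pilots × 2 phases
with a +1.2 mean rating shift during turns) and exercise the scoring
and reliability code, not any empirical claim.

## Known limitations

* The generator's Gaussianity makes histogram Shannon entropy blind to
  the planted complexity effect (see above).
* db4's sidelobes bound single-tone band purity at ~81% for node-edge
  frequencies; band *means* over noise-like epochs are unbiased.
* Blink artifacts at the default amplitudes leave a filtered-AF3 ×
  blink-train correlation of ~0.6–0.7 before cleaning (cleaning reduces
  it below 0.01); a stronger pre-cleaning correlation would require
  louder blinks than the default conditions specify.
* Overlapping epochs share samples, so train/test splits of a pooled
  epoch set are not fully independent — accuracies should be read as
  within-pool figures, as in the single-split design this mirrors.
* ICA assumes stationary mixing; per-burst EMG is not a single source
  and is typically not removable as one component.
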