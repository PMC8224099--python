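# Methods

`pcgfusion` implements a multi-domain, multi-channel analysis of heart-sound
(phonocardiogram, PCG) recordings for coronary-artery-disease (CAD)
screening: five synchronously recorded chest-wall channels are filtered,
cropped into 10-s segments, delimited into the four cardiac states (S1,
systole, S2, diastole), summarized into a 270-column feature table spanning
time, frequency, entropy and cross-entropy domains, and classified with a
subject-wise cross-validated support-vector machine after feature ranking.
Because multi-site PCG recordings with angiography-confirmed labels are not
publicly available, the package ships a synthetic-cohort generator that
reproduces the statistical structure the analysis assumes; every empirical
statement below is the output of the package's own tests or scripts.

## Signal model (synthetic generator)

A subject is a sequence of cardiac cycles of nominal length 60/HR s with
i.i.d. Gaussian length jitter (SD `hr_jitter` as a fraction of the cycle,
truncated at ±3 SD; no long-range heart-rate variability). Within a cycle
the four states tile it contiguously:

* S1: 90 ms, a Gaussian-enveloped cosine burst (envelope sigma = duration/6,
  carrier ≈ 55 Hz, detuned ±6 % per channel);
* systole: 0.35 × cycle (so the systolic-interval/cycle ratio is 0.35 by
  construction);
* S2: 70 ms burst, carrier ≈ 95 Hz, amplitude ≈ 0.75 of S1 with a
  per-channel ratio perturbation;
* diastole: the remainder.

The five channels are time-aligned copies of the cardiac source with
channel-specific morphology (carrier detune, S2/S1 ratio) and gain, plus
independent sensor noise (unit-RMS noise shaped as 1/(1+(f/100 Hz)^4) in
power at RMS 0.03, a small white floor at 0.006), a 0.2 Hz respiration
drift (amplitude 0.05) and 50 Hz mains (amplitude 0.02). The contaminants
exist so the preprocessing chain has something to remove. Every recording
is a pure function of the profile's integer seed.

### CAD signature

Two mechanisms, both scaled by per-subject severity parameters:

* **Murmur** — 200–800 Hz band-limited noise gated to the systolic and
  diastolic windows (20 ms Hann ramps), at `murmur_snr_db` decibels
  relative to the channel's RMS. Channels share the murmur source only
  partially (50 % common variance) and receive it through lognormal
  coupling gains (log-SD 1.2): sound radiated from a localized stenosis
  reaches the five auscultation sites very unevenly, so *no single site
  reliably captures every subject's murmur*. This heterogeneity is the
  structural reason multi-channel fusion outperforms any single channel,
  and it mirrors the anatomical argument that sites over the left coronary
  artery hear more than others.
* **Dyssynchrony** — each channel is warped by a smooth random timing
  jitter (bounded by 15 ms × `desync_level`) and mixed with independent
  low-frequency noise (RMS fraction 0.25 × `desync_level`), modelling
  non-synchronized myocardial motion. This raises every pairwise cross
  entropy monotonically in `desync_level`.

Cohort defaults draw heart rate from U(60, 100) bpm, jitter from
U(0.02, 0.05), channel gains lognormal (log-SD 0.2) and, for CAD subjects,
`murmur_snr_db` from U(−30, −12) dB and `desync_level` from U(0.1, 0.7).
The murmur range deliberately sits near the audibility floor: clinical CAD
murmurs are faint, and a cohort whose murmurs are obvious on every channel
would make single-channel classification trivial and the fusion question
moot. With these defaults part of the CAD group overlaps the non-CAD group
on any single channel, which is the moderate-effect regime the evaluation
is designed to probe.

What the generator does **not** emulate: real murmur spectro-temporal
structure (it is gated noise, not turbulence physics), valvular-disease
murmurs, ECG timing, long-range heart-rate variability, body-habitus
effects on channel coupling, or recording artifacts beyond stationary
noise/mains/drift. Passing tests therefore demonstrate the pipeline's
internal correctness and its sensitivity to the *modelled* CAD signature,
not clinical performance.

## Preprocessing

Fifth-order Butterworth high-pass at 30 Hz, then a second-order IIR notch
at 50 Hz with Q = 30. Both are applied forward–backward (zero phase) so
state boundaries are not delayed against the generator's ground truth;
attenuations are therefore the squared single-pass magnitudes. Filtering is
applied to the full recording before cropping into floor(duration/10 s)
consecutive segments (trailing remainder discarded).

The quality gate computes three per-channel metrics: clipping fraction
(samples within 0.1 % of the rail), spectral flatness (geometric/arithmetic
mean of the Welch PSD; near 1 for broadband noise), and the peak of the
mean-removed envelope autocorrelation in the 0.4–1.5 s lag band (cardiac
periodicity). Defaults: fail if clip > 1 %, flatness > 0.5, or
autocorrelation peak < 0.15, on any channel. Thresholds live in
`QualityConfig`, not code.

## State segmentation

For synthetic data the generator's exact boundaries are passed through
(cropped and re-indexed per segment). For recordings without ground truth a
simplified envelope detector is provided: the Shannon-energy envelope
(20 ms moving average, downsampled to 50 Hz) is peak-picked and peaks are
assigned alternately to S1/S2 by the rule that diastole (S2→next S1) is
longer than systole, with a variance-minimizing tie-break; fixed-width
windows (±45 ms for S1, ±35 ms for S2) delimit the states. Incomplete
first/last cycles are discarded (sub-envelope-sample overhang at the
segment edge is clamped rather than discarded). This deliberately replaces
trained hidden-semi-Markov segmenters, which need labelled training data;
on synthetic cohorts the detector finds the expected cycle count and ≥ 90 %
of S1 onsets within 50 ms of ground truth, which is sufficient because the
downstream features average over cycles.

Numerical note: the per-sample Shannon energy −u²·log u² is non-monotone
in u² above 1/e, which splits a narrow saturating burst into two side
lobes; the normalized signal is scaled so u² ≤ 1/e, keeping the map
monotone and the envelope peak at the burst center.

## Features (270 per segment)

Per channel (48 × 5 = 240), each as mean and population SD across the
segment's cycles (at least 3 cycles required):

* **Time (20)** — cycle, S1, S2, systole and diastole durations (s); the
  systole/cycle, diastole/cycle and systole/diastole duration ratios; the
  systole/S1 and diastole/S2 average-amplitude ratios (amplitude = mean
  |x| over the state window).
* **Frequency (16)** — for each state, the high-frequency (> 200 Hz) and
  low-frequency (< 50 Hz) *power* proportions of the state's DFT spectrum
  (no taper; proportions of total power from 0 to Nyquist, so they are
  Parseval-consistent, scale-invariant and disjoint). 200 Hz separates
  murmur energy from normal heart-sound energy; 50 Hz captures the
  low-frequency band reported to differ in CAD.
* **Entropy (12)** — SampEn, FuzzyEn and DistEn of the systolic and of the
  diastolic window of every cycle. Tolerances r are 0.2 × the SD of each
  window; m = 2; DistEn uses B = 256 bins.

Across channels (30): XSampEn, XFuzzyEn and JDistEn for each of the 10
unordered channel pairs, computed on the whole preprocessed segment after
anti-aliased decimation (default factor 4, to 500 Hz) and re-normalization
to zero mean/unit SD. By default cross entropies are not restricted to a
cardiac state (one value per pair per measure); an option restricts them to
one state's concatenated windows. A Hann taper for the state spectra is
likewise available but off by default (the slices are short).

### Estimator conventions

All estimators compare delay templates under the Chebyshev (max-norm)
distance, matching strictly (d < r). Template counts at lengths m and m+1
are equalized (indices 0 … N − m·τ − 1), the sample-entropy convention that
makes the conditional-probability ratio well defined. Specifics:

* `sampen`: self-matches excluded; returns NaN (with a warning) when no
  pair matches at length m; when matches exist at m but none at m+1 the
  +∞ limit is capped at log(#pairs), the largest resolvable value.
* `fuzzyen`: membership exp(−d^n / r) with exponent n = 2 by default, on
  baseline-removed templates (each template minus its own mean). Note this
  membership is quadratic in distance but linear in r, so the value is
  invariant under amplitude scaling only when r scales with the *squared*
  amplitude; the per-window tolerance r = 0.2 × SD therefore makes the
  feature deliberately sensitive to within-window amplitude structure.
* `disten`/`jdisten`: all pairwise template distances (i < j), histogrammed
  into B equal-width bins spanning [0, max distance] (degenerate all-zero
  distances give entropy 0), Shannon entropy normalized by log2 B — bounded
  in [0, 1]. The *joint* distance of a pair of channels is the geometric
  mean √(d_x(i,j) · d_y(i,j)) of the two within-channel template distances,
  chosen because it reduces exactly to single-channel DistEn when the
  channels coincide. Under this construction JDistEn responds to timing
  dyssynchrony between structured signals (verified on matched PCG
  segments) but is *not* a general-purpose coupling measure for arbitrary
  unmatched signal families.
* `xsampen`: every template of x against every template of y (the
  self-index pair included, so xsampen(x, x) is SampEn with self-matches);
  `xfuzzyen`: same grid excluding the self-index pair, membership
  exp(−ln 2 · (d/r)²), which equals ½ exactly at d = r. Both are exactly
  symmetric in their arguments.

The O(N²) pair scans are compiled (numba) loops that never materialize an
N×N distance matrix; the test suite pins them to naive double-loop
references exactly (match counts) or to 1e-10 (fuzzy sums) on exhaustive
short-input suites.

## Feature sets and evaluation

Five column-selection rules: Sin1 (one channel, time+frequency, 36), Sin2
(adds entropy, 48), Mul1 (five channels, time+frequency, 180), Mul2 (adds
entropy, 240), Mul3 (adds cross entropy, 270). Rows with any missing
feature are excluded from modelling (counted and logged).

Evaluation (`SubjectwiseSVM`) is subject-wise throughout: folds partition
subjects (stratified by label), never segments, so no individual
contributes to both training and test. Within each training fold, features
are standardized with training statistics only and ranked by information
gain (equal-frequency 10-bin discretization, base-2 entropies) or by
SVM-RFE (linear-kernel SVM, squared-weight scoring, default elimination
step 10; the final classifier is RBF, but elimination follows the standard
linear-weight recipe). Ranking inside the fold avoids selection leakage; a
`global_ranking` flag reproduces the optimistic variant. The RBF SVM's C
and gamma are selected on an inner subject-wise 5-fold accuracy grid over
powers of two 2⁻⁵ … 2⁵, with class-balanced weighting. Metrics are
accuracy, sensitivity and specificity in percent (CAD positive), averaged
over the k = 5 outer folds; `sweep` evaluates top-n features at n = step,
2·step, …, truncated to the full set.

## Problem sizes and numerical choices in the shipped tests

The acceptance-style tests run the full pipeline on a scaled-down cohort:
21 CAD / 15 non-CAD subjects, 25-s recordings (2 × 10-s segments each,
~70 usable segments), cross-entropy decimation 8 (250 Hz, 2 500-sample
series). At this scale the central qualitative ordering — mean accuracy of
Mul3 > Mul1 > best single channel over 5 cross-validation repetitions — is
reproduced in minutes on one CPU; a representative run gives ≈ 96.5 %
(Mul3) > 94.0 % (Mul1) > 89.2 % (best Sin2). The label-permutation null
calibrates to the majority-class rate within 3 SE, and matched CAD /
non-CAD pairs (n = 20) shift the diastolic high-frequency proportion and
all three pairwise cross entropies upward (paired t-tests, p < 0.01).
These sizes are the package's own choice of desk-scale defaults; the
generator's 5-min/30-segment defaults match the full study conditions.

## Known limitations

* The envelope segmenter is a deliberately simple stand-in for trained
  duration-modelling segmenters and will degrade on noisy real recordings.
* JDistEn's joint-distance construction is one of several possible
  interpretations (chosen for its exact reduction to DistEn).
* The equal-count template convention and the strict-inequality match are
  conventions; absolute entropy values are comparable only within them.
* Synthetic accuracies should not be read as clinical estimates; only the
  qualitative structure (fusion ordering, sign of feature shifts) is
  designed to transfer.
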