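# Methods

## Scope and model

The package implements the analysis chain used when 48-h Holter recordings
from a small paired cohort (the motivating setting is six beagles measured
before and after a cumulative doxorubicin course) are screened for an early
autonomic signature of cardiotoxicity: restriction to a nocturnal sleep
window, reduction of annotated beats to normal-to-normal (NN) intervals,
per-subject linear and nonlinear HRV indices, and an exact paired
signed-rank comparison. Everything operates on beat *times* with per-beat
labels; QRS detection from raw ECG is out of scope, as Holter systems emit
annotations.

## Synthetic data: the IPFM generator

Real recordings of this kind are rarely deposited, so the test substrate is
an integral pulse frequency modulation (IPFM) model: a beat is emitted each
time the running integral of an instantaneous rate

r(t) = (1000/meanRR) · (1 + a_lf sin(2π f_lf t + φ_lf)
                          + a_hf sin(2π f_hf t + φ_hf) + η(t))   [beats/s]

crosses an integer. This is the standard way to produce RR series whose
spectral content is known by construction: the HF sinusoid emulates
respiratory sinus arrhythmia, the LF sinusoid the Mayer-wave band, and η a
broadband modulation floor.

Numerical choices:

- Integration on a fixed 4 ms grid (`IPFM_GRID_DT`) with trapezoidal
  accumulation and linear interpolation of the crossing times; with zero
  modulation the emitted beats land on exact multiples of the mean RR to
  well below 0.01 ms. A crossing within ~1e-9 beats of the final grid node
  still counts, so a record of duration exactly k·meanRR emits all k beats
  despite float rounding.
- η(t) is Gaussian white noise smoothed by a 2-s moving average and rescaled
  to the requested standard deviation; the smoothing keeps the tachogram
  noise floor broadband but finite-variance so band powers do not inherit
  aliasing artifacts from the grid.
- Configurations must satisfy a_hf + a_lf + 3·noise_sd < 1; a rate that
  still touches zero on the grid (possible in the noise tails) rejects the
  configuration rather than emitting unphysical beats.

The default preset emulates a young adult dog asleep — mean RR 560 ms
(~107 bpm), f_hf = 0.30 Hz, a_hf = 0.12, f_lf = 0.09 Hz, a_lf = 0.05,
noise_sd = 0.02, 8-h duration. The heart-rate level is anchored to the kind
of nocturnal canine medians such studies report; the modulation depths are
chosen so the vagal-dominant preset yields SD1/SD2 near 0.5, positive DC
and negative AC of roughly 10 ms magnitude, which is the regime the method
is meant to discriminate. A `sympatho_shift` parameter ρ ∈ [0, 1] rescales
(meanRR, a_hf, a_lf) by (1−0.08ρ, 1−0.6ρ, 1+0.4ρ) before simulation —
faster rate, damped respiratory arrhythmia, enhanced LF — producing the
direction and rough magnitude of a doxorubicin-like sympathetic shift.
These coefficients are package constants, configuration rather than
physiological claims. Cohort generation adds 5% relative inter-individual
jitter to mean RR and both amplitudes, shared between a subject's Pre and
Post runs, with independent noise paths.

The contamination model injects premature ("ectopic") beats — shifted
earlier by 40% of the local RR by default — and missed beats, each as
independent per-beat Bernoulli events, keeping ground-truth labels so
filtering can be scored against the injection record.

What the generator does **not** emulate: closed-loop baroreflex coupling
between the LF and HF sources, circadian nonstationarity within the sleep
window, respiratory frequency drift, and realistic Holter annotation noise
(mislabeled rather than displaced beats). Passing tests therefore
demonstrate that the pipeline recovers known autonomic structure and known
contrasts from event series with this statistical shape — not that any
fixed effect size would be recovered from real dogs.

## Window selection and NN filtering

Windows are wall-clock based and half-open, `[start, end)`, with day
indices counting midnights after record start — a recording started at
20:00 has 00:00 of day 1 at 4 h elapsed. The default span, midnight of the
first night to 08:00 of the second day, is a contiguous 32-h block; a
`nightly` option instead unites each day's 00:00–08:00 window, since the
phrase "night one to morning two" is genuinely ambiguous between the two
readings. The literal contiguous span is the default.

NN filtering rejects an interval when either endpoint beat is non-normal
(switchable), when it lies outside [200, 2000] ms, or when its relative
step from the previously *retained* interval exceeds 0.25. The bounds are
generous physiologic limits for dogs with pronounced respiratory sinus
arrhythmia; the 25% step rule is what actually catches displaced beats
whose labels are missing. Rejections leave gaps — onset times are retained
and no interpolation happens at this stage — so each downstream module can
apply its own gap policy: successive-difference statistics, Poincaré pairs
and PRSA windows never bridge a gap, while spectral resampling bridges
long holes linearly. Filtering is idempotent: re-filtering the
reconstructed surviving beats changes nothing, because gap-spanning
intervals re-evaluate to the same rejected values.

## Index conventions

- SDNN uses the N−1 (sample) denominator; RMSSD divides by the number of
  successive differences. These are the common conventions in HRV
  reference implementations and are documented so cross-package
  comparisons are explainable.
- Poincaré SD1/SD2 use the population denominator (number of pairs) on
  both axes, so the projection definitions agree with the closed forms
  sd1² = ½Var(y−x) and sd2² = ½Var(x+y) exactly rather than to O(1/n);
  at Holter scale the bias difference is negligible, and exact
  testability of the identity network is worth more. SD2 is implemented
  as dispersion along the identity-line direction about the centroid —
  the standard ellipse convention. A sometimes-seen alternative phrasing,
  distance from the line y = x + meanRR, describes a line *parallel* to
  the identity and would duplicate SD1's direction up to a constant
  offset; it is geometrically degenerate as a second axis, so the ellipse
  convention is used. SD1/SD2, SD2/SD1, nHF, nLF and LF/HF are reported
  dimensionless, as their defining equations are ratios.
- Spectral analysis resamples the (onset, interval) tachogram at 4 Hz by
  cubic spline with linear detrending — standard tachogram practice.
  Bands use the half-open convention [lo, hi) over bin centres so shared
  edges are assigned deterministically, and TP is computed as the sum of
  the four bands, making additivity structural. The default estimator is
  the full-record rectangular periodogram, for which the discrete
  Parseval identity (band sum + supra-0.4 Hz remainder = tachogram
  variance) holds to float precision. Welch mode (600-s Hann segments,
  50% overlap) reduces variance but cannot resolve ULF at 8-h records
  (fundamental ≈ 3.5e-5 Hz), so it reports ULF from a full-record
  periodogram of the same tachogram; the hybrid is recorded in the
  result's `method` field.
- PRSA uses L = 5, anchor threshold 1.05, and the quarter-sum capacity
  [X(0)+X(1)−X(−1)−X(−2)]/4 — the standard single-scale form of the
  method; all three are configurable. Ties are anchors in neither mode.
- The exact Wilcoxon signed-rank test drops zero differences, assigns
  midranks to ties, and doubles the smaller tail (capped at 1). The null
  distribution is computed by exact integer convolution over doubled
  midranks, which is mathematically identical to enumerating all 2^m sign
  assignments; the test suite checks it against a literal enumeration.
  Above m = 20 pairs the continuity-corrected normal approximation is
  used and flagged in the result. Summary cells use linear-interpolation
  percentiles; both `median (q25–q75)` and `median (min–max)` renderings
  are supported, defaulting to quartiles.

## Pipeline behaviour

A failing subject (unreadable file, empty window, insufficient NN data) is
dropped with a logged reason rather than aborting the run, mirroring how a
cohort study excludes a subject with missing data; a paired comparison
requires at least two complete subjects. Runs are deterministic under a
fixed seed — cohort simulation derives per-subject sub-seeds from a seed
sequence — and the manifest echoes the full configuration, seed, library
versions and per-record rejection counts, with no timestamps, so repeated
runs produce byte-identical bundles.

## Verification problem sizes

The test and acceptance computations use 1-h simulated records standing in
for the 8-h sleep window: every spectral band above VLF, the beat-domain
statistics and the Poincaré/PRSA indices are unaffected by the shorter
span, and cohort Monte-Carlo (100 null and 100 shifted cohorts of six
subjects) stays inexpensive. ULF behaviour at full length is exercised by
the resolution argument above rather than by 8-h simulation. Monte-Carlo
checks at these sizes show: recovery of the shifted cohorts' sympathetic
signature (every subject's SD1/SD2 down, SD2/SD1 up, exact p = 2/2⁶) in
all 100 shifted cohorts; per-index false-positive fractions at or below
4% under the null (the exact test's most extreme attainable level at
n = 6 is 3.125%); and, at 1% injected ectopics, filtered RMSSD within a
median 0.06% of the clean value while the unfiltered tachogram inflates
by a median ~50%.

## Known limitations

- The simulator's autonomic parameters are calibrated to heart-rate level
  and qualitative index regimes, not to any specific cohort's HRV medians;
  absolute index values from synthetic data should not be read as canine
  reference values.
- The spectral estimator is a design choice; commercial Holter software
  uses unspecified proprietary estimators, so absolute band powers are not
  comparable across packages, only the normalised indices are reasonably
  stable.
- No lagged Poincaré maps, no multi-scale PRSA sweep, no multitaper or
  autoregressive spectra, and no multiplicity correction across indices —
  with eleven indices tested at the exact level ≈ 3%, about one null
  cohort in six flags *some* index, so single-index significance in small
  cohorts should be interpreted per pre-registered hypothesis, not after
  scanning the table.
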