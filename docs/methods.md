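# Methods

## Signal diversity measures

Both measures quantify the diversity of EEG activity through the number of
distinct "words" produced by the LZ76 exhaustive-history parsing of a binary
sequence.  Per 10-s epoch and channel:

1. **Standardize** — subtract the segment mean, divide by the segment
   standard deviation, then remove the least-squares linear trend, in that
   order.  A constant channel is an error (the caller is told which channel).
2. **Envelope binarization** — the Hilbert analytic signal is computed on
   the full 2,500-sample segment without padding or tapering; its magnitude
   is the instantaneous amplitude envelope.  Bits are 1 where the envelope
   strictly exceeds its mean, 0 otherwise.  Values exactly equal to the
   threshold map to 0; this is a measure-zero event for real signals but
   makes edge cases deterministic.  Edge distortion of the FFT-based
   analytic signal affects well under 1% of samples and is accepted.
3. **LZ76 word count** — the sequence is parsed left to right; each word is
   the shortest extension that cannot be copied from anywhere in the
   history extended up to (but not including) the word's last symbol
   (self-overlap allowed), and the trailing word is counted even when still
   copyable.  The production-counting loop follows the classical
   Kaspar–Schuster scheme (numba-compiled, with a pure-Python fallback) and
   is pinned to an independent brute-force parser by an exhaustive test
   over every binary string of length ≤ 12 plus 1,000 random length-500
   strings.
4. **Surrogate normalization** — the raw count is divided by the count of
   the same sequence shuffled uniformly in time (mean over `n_surrogates`
   seeded permutations, default 1).  Scores are capped at 1, since a lucky
   shuffle can be marginally less complex than the original; cap events are
   logged.  A constant sequence is its own shuffle and is flagged
   degenerate.

**LZs** applies this pipeline per channel and also reports the arithmetic
mean of the *normalized* per-channel scores (averaging after normalization).
**LZc** binarizes each channel identically, concatenates channel-major
within each time step (all channels at time 1, then all at time 2, ...) and
scores the single concatenated string; its default surrogate permutes the
whole concatenated string, destroying spatial and temporal structure
symmetrically.  A within-channel shuffle, which preserves each channel's
marginal bit pattern, is available behind a flag.

## Preprocessing

The default chain reproduces a conventional high-density EEG cleaning
pipeline at 500 Hz: a 1 Hz high-pass FIR (order 1,650), a 45–55 Hz notch FIR
(order 826) and a 100 Hz low-pass FIR (order 66), all Hamming-window
linear-phase designs (the design window is configurable; only the orders and
corners are fixed).  Filters are applied in a single pass with the kernel
centered, i.e. the group delay of order/2 samples is compensated exactly and
output length equals input length; edges are implicitly zero-padded.
Downsampling to 250 Hz is plain decimation by 2, with anti-aliasing provided
by the preceding low-pass.  Epochs of 10 s are tiled from each presentation
onset (0-based, half-open sample intervals); remainder samples at a
presentation's end are dropped, and epoching restarts at every presentation
boundary, so no epoch spans two presentations.

Visual artifact screening is replaced by two explicit rules: reject an epoch
if any sample exceeds ±100 µV, or if any channel's peak-to-peak range falls
below 0.1 µV (flatline).  ICA-based artifact removal is out of scope; the
pipeline expects either cleaned data or the generator's clean output.  Bad
channels are interpolated as the inverse-distance-weighted mean of the 4
nearest good electrodes, then the data are re-referenced (channel average,
or the mean of A1/A2 for the linked-ears scheme).  More than 25% bad
channels is treated as unrepairable.

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes
rather than the biophysics of EEG.  A session is 7 conditions × 4
presentations × 90 s (fully configurable), in a seeded random order covering
each (condition, repetition) pair exactly once.  Channels are unit-norm
linear mixtures of unit-variance sources (default: one global source with
10% shared variance plus one private source per channel, so pairwise channel
correlation equals 0.1).  Each source mixes

* broadband background with a 1/f^α spectrum (α = 1 by default, recovered
  by periodogram regression to within ±0.2 over 1–40 Hz), and
* narrowband noise (boxcar 9–11 Hz), whose amplitude envelope fluctuates on
  the ~0.5 s timescale of the 2 Hz bandwidth.

The **narrowband fraction** of source variance is the diversity dial:
rhythmic, narrowband-dominated signals have slowly varying envelopes, hence
fewer LZ76 words after binarization, hence lower normalized diversity.  Mean
LZs is monotone decreasing in the fraction over the whole [0, 1] range
(tested on a 5-point grid).  Condition effects add per-condition offsets to
the fraction; a vigilance drift adds `slope × presentation_index`.  Offsets
or drifts that push the fraction outside [0, 1] raise an error rather than
clip.  A small white noise floor (2% variance) and an overall 20 µV RMS
scale complete the signal.  Generation is a pure, fully seeded function of
(design, config): effect injection re-renders the session from its recorded
provenance, so zero offsets reproduce the input bit for bit.

What the generator does **not** model: realistic artifact morphologies (a
Gaussian transient injector exists only to exercise epoch rejection),
non-stationary spectra within a presentation, volume-conduction geometry, or
subject-level trait differences beyond sampling noise.  Passing tests
therefore show that the measures and models behave correctly under the
assumed statistical structure, not that they are robust to everything real
EEG can do.

## Statistical battery

Scores are summarized per subject × condition as means over surviving
epochs.  The omnibus is the Friedman rank test (within-subject midranks,
χ² with k − 1 df, standard tie correction), preceded by a
Kolmogorov–Smirnov normality screen of each condition's scores (standardized
with their own mean/SD — the usual conservatism caveat applies and is
reported, not corrected).  Post hoc contrasts use the two-sided Wilcoxon
signed-rank test: zero differences dropped, exact enumeration of all sign
assignments for n ≤ 15 (ties handled by midranks), and a
continuity-and-tie-corrected normal approximation above; the reported Z
always comes from the approximation so tables share an effect scale.
Families of post hoc p-values are Holm-adjusted within each model.

Bayes factors: paired contrasts use the default JZS BF10 — a Cauchy(0,
0.707) prior on the standardized effect, evaluated by adaptive quadrature of
the noncentral-t likelihood against the prior (relative tolerance 1e-8,
split at the likelihood peak so narrow peaks at large |t| are never stepped
over), accurate to ~1e-10 against a dense fixed-grid quadrature in the
g-parameterization.  The omnibus uses a one-way repeated-measures BF under
default mixed g-priors (scale 1.0 for subjects, 0.5 for condition effects);
for the balanced additive design the conditional marginal likelihood reduces
to a closed form in the three classical sums of squares, and the remaining
two-dimensional g-integral is evaluated by seeded Monte Carlo (≥10,000
draws) with a delta-method standard error reported alongside.  Exact
agreement with GUI implementations that use different samplers is a
non-goal; agreement within Monte Carlo error on simulated data is the
contract.  Evidential bands are the conventional 0.1 / 1⁄3 / 3 / 10 cuts,
with boundaries assigned to the lower band.

The time-on-task model orders each subject's epochs by session time,
irrespective of condition, and splits them into four quartiles (sizes differ
by at most one, remainders to the earliest quartiles); quartile means then
enter the same Friedman + post hoc machinery.

Topographic contrasts use a one-sample cluster-based sign-flip permutation
test on subject × channel differences: per-channel t, two-sided threshold at
`cluster_alpha = 0.05`, connected same-sign clusters under a distance
adjacency (electrodes projected to the unit sphere; neighbors within 0.4 ×
the maximum inter-electrode distance — about 12 neighbors per channel on the
64-channel layout with this projection), cluster mass = Σ|t|, and the null
distribution of the maximal mass over `n_perm` seeded whole-subject sign
flips.  Cluster p-values use the (count + 1)/(n_perm + 1) convention, so
they are never zero.  `n_perm` defaults to 5,000 with a hard floor of 500.

## Problem sizes used in the validation studies

The validation suites scale the study design down so the full battery runs
on a single CPU in minutes; sizes were chosen once as the smallest that
leave clear statistical headroom:

* **Effect recovery** — 100 cohorts of 19 subjects; 3 conditions × 2
  presentations × 80 s, 1 channel, 250 Hz.  The planted rest-vs-task
  contrast is a −0.04 narrowband-fraction offset, calibrated once so the
  LZs shift is ≈0.5 within-subject (epoch-level) SD under generator
  defaults; with 16 epochs per condition (the full design has 36) the
  subject-level effect is ≈0.5·√(16/2) ≈ 1.4 SD, giving the Wilcoxon/Holm
  battery comfortable power.
* **Drift recovery** — 100 cohorts of 12 subjects; 4 presentations × 40 s
  with drift slope 0.05 per presentation.
* **Calibration** — 2,000 null 19 × 5 matrices for the Friedman type-I
  rate; 200 null 19-subject datasets (500 sign-flip permutations each) for
  the cluster familywise error rate.
* **Normalization bound** — 200 seeded 10-s white-noise epochs.

## Numerical choices and degenerate inputs

* Normalized scores are validated to [0, 1] at construction; violations are
  bugs, not warnings.
* Constant binary strings flag `degenerate_flag` and score 1.0 with a
  warning (shuffling is the identity; the ratio convention keeps the score
  defined).
* The Friedman test returns (0, k − 1, p = 1) when every subject ties all
  conditions, where the tie-corrected statistic is otherwise 0/0.
* scipy's noncentral-t density returns NaN where it has underflowed; the
  BF integrand maps those points to 0.
* Filter orders must be even so the linear-phase kernel centers on an
  integer delay.
* EDF output quantizes to 16 bits with per-channel symmetric physical
  ranges; round trips are exact to one quantum.

## Known limitations

* The generator's diversity dial is a stand-in: real condition effects on
  EEG diversity need not act through envelope rhythmicity.
* The KS normality screen with estimated parameters is conservative
  (Lilliefors correction not applied; the screen only gates reporting, the
  omnibus is always the rank test).
* The repeated-measures Bayes factor covers the one-way balanced design
  only; no model averaging across random-effect structures.
* Decimation relies on the 100 Hz low-pass for anti-aliasing, which leaves
  the 125–150 Hz transition band only partially suppressed, as in the
  original chain.
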