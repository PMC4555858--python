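# Methods

This note documents the models, conventions and parameter choices behind
`rivalcall`, in the order the pipeline runs them.

## 1. Contest season generator

A colony of `n_males` males carries a latent resource-holding potential
`s_i` (arbitrary scale).  Contests draw a dyad uniformly at random; male
*a* beats male *b* with probability `logistic(steepness · (s_a − s_b))`.
The logistic form was chosen because it matches the Elo observer's own
expected-score model (a logistic in rating difference), which makes
latent-strength recovery by the rating engine a well-posed experiment: with
20 males, distinct strengths and 2000 contests, the Spearman correlation
between final Elo score and true strength exceeds 0.9.

Annotation probabilities are the field rates: winners vocalise in 95 % of
contests and losers in 29 %; ~5.1 % of contests involve physical contact,
~1.8 % sustained combat, and ~20 % of sustained fights end without a
decision (recorded as draws, which never update ratings).  Records are
stamped with an integer day in a 90-day season and returned chronologically.

Default `steepness` in the end-to-end pipeline is 8 with strengths drawn
from N(0, 1.5²) — a strongly despotic hierarchy.  Even so, simulated dyad
asymmetry settles near 85 %, below the >97 % a real colony can show: with
uniform dyad sampling, closely matched pairs meet far more often than they
do on a beach structured by space and familiarity.  Spatial structure is a
non-goal, so this divergence is documented rather than patched.

## 2. Elo engine

* Initial score 1000 for every male, auto-enrolled at first appearance.
* `E_a = 1/(1+10^((R2−R1)/400))`; winner gains `K(1−E_a)`, loser loses the
  same amount — zero-sum by construction, asserted exactly in the tests.
* `K` defaults to 100 (common practice for short observation windows); the
  expected-score formula is K-agnostic, so K only scales volatility.
* Records fold in date order with stable tie-breaking by ledger row order.
  Order sensitivity is real: permuting records changes trajectories but
  never the rating sum.
* Undecided contests (draws) are skipped with a logged notice and counted
  in the tallies.
* Tallied percentages always report against the explicit denominator
  (total interactions), since published tallies of this kind often leave
  denominators ambiguous.

## 3. Call synthesis

Each male's signature fixes a pulse rate (Hz), pulse count, spectral
centroid target and Q25 target.  One call is synthesized as:

1. **Pulses.**  Each pulse is a 120 ms burst with a flat-topped
   raised-cosine (Tukey, 30 % taper) envelope.  The carrier is
   frequency-modulated noise: the instantaneous frequency steps
   phase-continuously through ~6 ms holds whose values are a stratified
   (exact-quantile) sample of a gamma density solved so that its mean
   equals the centroid target and its 25 % quantile the Q25 target.  Time
   spent near each frequency then reproduces the density, while the
   analytic magnitude stays essentially equal to the deterministic
   envelope — which is what lets threshold-based pulse detection count
   exactly one onset per burst.  No transition smoothing is applied to the
   frequency track: smoothing drags time-at-frequency toward the mean and
   biases the quartiles (this was measured, not guessed).
2. **Spacing.**  The measurement convention downstream is pulse rate =
   n_pulses/duration with duration running from the first envelope
   threshold up-crossing to the last down-crossing.  Spacing is therefore
   solved against the *threshold-level* pulse width (the width the detector
   will see, computed from the envelope window itself), not the nominal
   120 ms.  This keeps the re-measured rate within ~0.2 % of target across
   the whole realistic grid.
3. **Closed-loop spectral tuning.**  The realized spectrum of a finite
   pulse train never lands exactly on its design targets, so two knobs are
   tuned against the same Welch measurement the feature extractor uses: an
   energy-preserving reshaping of the band above 1.5×Q25 steers the
   centroid (it cannot move any energy quantile below the hinge), then a
   full-band spectral tilt pins Q25.  The two couple weakly through the
   windowed estimate, so the loop alternates up to four rounds, always
   ending on the Q25 tilt.  Final accuracy: Q25 within half an FFT bin,
   centroid within ~3 %.

Within-individual variation is multiplicative lognormal jitter (default
CV 5 %) applied per call to pulse rate, centroid, Q25 and (rounded, ≥3)
pulse count.  5 % was chosen so that the synthetic within/between-individual
variance ratio produces clearly separated but overlapping signature
clusters, comparable to a measured call-to-call centroid scatter of
~150 Hz against a between-male range of ~330 Hz.  No field estimate of
within-individual acoustic CV exists to copy, so this is a modelling
choice.

Signature bounds for synthetic colonies are the observed per-male mean
ranges: pulse rate 0.94–2.84 Hz, centroid 1574–1902 Hz, Q25 263–781 Hz.

## 4. Feature extraction

* **Envelope**: low-pass at 6 kHz (4th-order Butterworth, forward-backward),
  Hilbert magnitude, centred moving average of 41 samples at 48 kHz
  (expressed internally as 0.854 ms so other sample rates behave the same),
  peak-normalised.  The sample rate that the original 41-point smoothing
  referred to is not recorded anywhere authoritative; 48 kHz matches the
  recorder settings and is declared, not inferred.
* **Pulse detection**: above-threshold runs of the envelope (threshold 0.15
  of max), with runs separated by silent gaps shorter than `min_gap`
  (50 ms) merged as within-pulse ripple.  Onsets are run starts, so
  accepted onsets are always ≥ 50 ms apart.  Both parameters are exposed;
  the values used by proprietary pulse-train tools are undocumented.
* **Temporal**: duration = first onset to last down-crossing; pulse rate =
  n_pulses/duration.  Stated prominently because the alternative
  (n−1)/span convention changes every published rate.
* **Spectral**: Welch mean power spectrum (Hann, 4096-point segments) over
  the rhythmic portion only.  F_max is the arg-max bin; centroid the
  power-weighted mean frequency; Q25/Q50/Q75 the first bins where
  cumulative power reaches 25/50/75 %; the −12 dB bandwidth is the
  contiguous band around F_max within 12 dB of the peak (the phrase admits
  a non-contiguous reading; contiguous is the standard bioacoustic
  convention).  All values are reported at FFT-bin resolution (11.7 Hz at
  48 kHz), no interpolation.
* **Level**: dB_peak re 20 µPa at 1 m, `20·log10(max|p|/20 µPa)`, requiring
  a pascals-per-full-scale calibration (peak, not RMS, because the calls
  are impulsive).  Calibration travels in a sidecar CSV because WAV has no
  calibration field.
* Calls are expected pre-trimmed of introductory/terminal snorts; the
  envelope threshold crossings then delimit the rhythmic portion.

## 5. Individual signatures (pDFA)

Nine measures (six spectral, three temporal; amplitude excluded) enter a
pooled-covariance linear discriminant analysis.  Per iteration, a
stratified random split takes ⌈2n/3⌉ training calls per male — rounding
*up* guarantees every male keeps at least one validation call; the held-out
third is classified.  The effect size is the mean held-out accuracy over
100 iterations; the confusion matrix aggregates all held-out
classifications and is row-normalised.  Features are z-scored first, making
the analysis invariant to per-feature scaling.  If the pooled covariance is
singular the fit falls back to an eigen solver with a small (1e−6)
shrinkage ridge.

**Permutation p-value.**  Labels are shuffled across calls — deliberately
ignoring within-individual dependence, as the original design did — and the
train/validate procedure re-run per permutation.  p = (b+1)/(m+1) with ties
counted as exceedances (the standard valid estimator; it differs from a raw
proportion by at most 1/(m+1), and its minimum is 1/(m+1)).

One subtlety is worth stating loudly: the observed statistic entering the
comparison is recomputed with the *same* number of random splits as each
permutation uses (`iters_per_perm`, default 1).  Comparing a 100-split
average against single-split permuted statistics looks harmless but is
invalid — the averaged statistic has far smaller Monte-Carlo variance, and
the test's null rejection rate collapses to zero (measured on 200 null
datasets).  With matched procedures the empirical rejection rate at
α = 0.05 is ~0.04, inside the expected band for a discrete statistic.  The
100-iteration average is still reported as the effect size; whether the
original analysis nested its iterations inside each permutation is not
documented anywhere, so `iters_per_perm` is exposed.

**Stability.**  Calls are placed in the (pulse rate, centroid) plane — the
two most individually distinctive measures — and z-scored using the
mean/s.d. of the reference-level pool (year 1, or the directed context),
applied to all calls; the standardisation pool is configurable because no
authoritative convention exists.  Three distance categories are computed
per individual: within the reference level, between levels, and against all
other individuals' reference calls.  Within/between per-individual means
are compared with a matched-pairs Wilcoxon test; individuals with fewer
than two calls in a level are excluded with a logged notice.

## 6. Morphometric correlations

Per-male *mean* features (the aggregation rule is not documented in the
source analyses; the mean is the obvious choice and is stated) are
regressed on each of four morphometric measures and on the final Elo score,
plus Elo on each morph measure — ordinary least squares, adjusted
R² = 1−(1−R²)(n−1)/(n−2), two-sided slope p.  Adjusted R² can go negative
for uninformative predictors at n = 16; the tests verify this happens
routinely under the null.  No multiple-testing correction is applied to the
headline columns; a Benjamini–Hochberg column is emitted alongside, marked
as an addition.

The synthetic morph generator inverts the observed field link
(pulse rate = 3.11·height − 0.68) plus noise, so the correlation analysis
has a known truth to recover, and generates morphology independently of
rank so the Elo rows calibrate the type-I error (~5 %).

## 7. Playback stimuli

* `modify_pulse_rate`: detected pulses are cut out verbatim (10 ms margins)
  and re-laid at the uniform interval that makes the re-measured rate hit
  the target; count unchanged; overlapping targets raise an error.
* `modify_pulse_count`: pulses are deleted from the call's end or appended
  as copies of the final pulse.  The rebuilt train is re-spaced uniformly
  at the interval that preserves the originally measured rate.  (Appending
  at the unchanged inter-pulse interval — the literal reading of the
  protocol — drifts the measured rate by up to 2 % under the
  n_pulses/duration convention; re-spacing preserves it exactly, which is
  what the fixed-rate design intends.)
* `shift_q25`: a smooth spectral tilt applied in the Fourier domain,
  bisected until the re-measured Q25 of the rhythmic portion is within half
  an FFT bin of target.  This replaces pitch-synchronous (PSOLA-style)
  resynthesis deliberately: the calls are pulsatile broadband noise with no
  pitch periods to synchronise on, so a spectral-domain reshaping with
  closed-loop verification is better defined and leaves temporal features
  intact (within 1 %, asserted by round-trip).
* The printed Q25 targets (536 and 804 Hz) are used as given even though
  "mean ± 20 %" of 643 Hz would be 514/772 Hz; the discrepancy is inherited
  from the protocol description and recorded, not resolved.
* `build_series`: three distinct calls with 3 s gaps (natural series) or
  two repetitions of one call (modified series), peak-scaled so the
  rendered level is 116 dB_peak re 20 µPa at 1 m.  The contract is that the
  supplied calibration maps digital full scale to pascals at 1 m; when no
  calibration is attached the series is peak-normalised and the output
  calibration carries the level.

## 8. Response scoring

Six measures per trial; latencies are censored at the 90 s observation
window (imputed at 90 s with the censoring flag retained — the original
protocol is silent on censoring).  `distance_moved` is signed with
*negative = toward the loudspeaker*, so that after the sign convention
below, negative PC scores consistently mean strong aggressive responses.

PCA runs on the correlation matrix; components with eigenvalue > 1 are
retained; varimax is applied to the retained loadings only (rotating all
components is the less common reading and is not what rotation is for);
rotated components are re-ordered by explained variance.  Each component's
sign is fixed so the aggression-linked measures (number of calls, distance
moved) load negatively.  Rotation is orthogonal: the retained-subspace
variance and the reproduced correlation matrix L·Lᵀ are preserved exactly
(asserted to 1e−9).  Constant measures are dropped with a notice.

Paired comparisons use the matched-pairs Wilcoxon signed-rank test: exact
null distribution when the non-zero, untied pair count is ≤ 25 (verified
against full 2ⁿ enumeration for all n ≤ 12), normal approximation with tie
correction above; zero differences are dropped; an all-zero difference set
returns p = 1 with a notice.

The alpha-male distance design (4 speaker distances × call categories per
male) is scored with a within-male permutation test of the mean OLS slope
of score on distance — explicitly a methodological substitute for the
original mixed-model likelihood-ratio analysis, which is out of scope.  It
answers the narrower question "does response strength trend with
distance?", with exact within-male exchangeability and p = (b+1)/(m+1).

## 9. What the synthetic data does and does not show

The generators reproduce the statistical *structure* the analyses assume:
a latent hierarchy behind contest outcomes, stable per-male acoustic
signatures with within-male jitter, size-linked acoustic features,
condition-shifted paired responses.  Passing tests therefore demonstrate
that the pipeline recovers known truths from data of that structure at
realistic sizes — they do not certify field performance.  In particular:

* synthetic calls are cleaner than field recordings (no wind, surf,
  overlapping callers, or amplitude fades), so classification accuracies
  on synthetic colonies run higher than the ~61 % reported from real
  recordings;
* dyad asymmetry saturates near 85 %, not >97 %, for the reason given in
  §1;
* headline field statistics (61.3 % correct classification, Z = 2.19 /
  p = 0.028, PCA variances 55 %/18 %) derive from unreleased recordings and
  are treated as qualitative anchors, not regression targets.

## 10. Problem sizes and numerical conventions

Simulation sizes used by the test suite and drivers (chosen as realistic
desk-scale conditions): 16–20 male colonies; 1200–2000 contests per season;
5 calls per male per year at 16–24 kHz (stimulus work at the 48 kHz
recorder rate); 100 cross-validation iterations; 200–1000 permutations
(calibration experiments use 200 each over 200 null datasets).  All
randomness flows from explicit integer seeds through `numpy` generators;
same seed, same bytes.  Degenerate inputs (silence, constant measures,
single-pulse calls, all-zero difference sets) raise typed errors or return
documented sentinel results rather than propagating NaNs.
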