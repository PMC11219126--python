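# Methods

## Scope and data model

The package evaluates low-pass filters for 1000 Hz gaze recordings.  The
universal container is `GazeTrace`: uniformly sampled gaze position in
degrees of visual angle (dva), horizontal channel mandatory, vertical
optional.  All analyses below operate on the horizontal channel; the
clean-segment screen can optionally use the two-channel speed.

## Filter designs

| family | parameters | application | final −3 dB point |
|---|---|---|---|
| Savitzky-Golay | window 23, order 5 | single centred convolution | ≈ 74.3–74.9 Hz |
| Butterworth IIR | order 7, cutoff 81 Hz | forward-backward (`filtfilt`) | ≈ 75.4–76.0 Hz |
| windowed-sinc FIR | 80 taps, cutoff 84 Hz, Hamming | forward-backward | ≈ 74.7–75.0 Hz |

Design notes:

* The SG kernel comes from `scipy.signal.savgol_coeffs`; it is symmetric
  (zero-phase by construction) and is applied single-pass as a centred
  convolution with odd-reflection edge padding.  Its transfer function
  is real but alternates sign through the stop-band lobes.
* The Butterworth design is the standard analog prototype + bilinear
  transform (`scipy.signal.butter`).  Stability is checked with the
  unit-circle test on the feedback-polynomial roots.
* The FIR design is `scipy.signal.firwin` with a Hamming window — the
  common default for the window method — renormalised to exact unit DC
  gain.  With 80 taps and an 84 Hz cutoff the two-pass −3 dB point lands
  at 75.0 Hz; had it missed 75 ± 1 Hz the window choice would be the
  first thing to revisit.
* Forward-backward filtering uses odd-reflection padding of
  3 × max(len(b), len(a)) samples.  It removes phase and delay and
  doubles the attenuation in dB at every frequency; both properties are
  verified in the tests by steady-state sinusoid fits.
* The FIR length estimate `estimate_fir_taps` implements the Bellanger
  approximation N ≈ (2/3)·log₁₀(1/(10·δ₁δ₂))·(fs/Δf), with a floor of
  2 taps for degenerate inputs.  The reference pipeline treats 80 taps
  as a given design constant rather than deriving it, since the
  ripple/transition inputs behind that choice are not part of the
  design record.
* Coefficient files store six-decimal scientific notation (`%.6e`).
  Fixed-point six decimals would corrupt the Butterworth numerator
  coefficients, which are O(1e-4); at 1e-6 relative precision every
  crossing frequency is stable to well below 0.01 Hz and a
  save/load/save round trip is bit-stable.

## Frequency-response estimation

Three routes, kept deliberately distinct:

1. **Direct** (`response_direct`): |H| evaluated from the coefficients
   on a dense uniform grid (default 8192 points to fs/2; interpolation
   error of crossings ≪ 0.1 Hz), in dB, multiplied by the number of
   passes.
2. **Empirical ratio** (`response_by_ratio`): the bin-wise ratio of the
   averaged magnitude spectrum of filtered blocks to that of the same
   blocks unfiltered.  This is the only route available for filters
   without coefficients (e.g. proprietary on-tracker smoothers), so the
   reference analysis uses it for *all* filters to keep curves
   comparable.  A literal per-block complex-ratio mode (average of
   Re(B/A)) is provided separately; it is unbiased for zero-phase
   filters but noisier than magnitude averaging.
3. **Analytic ratio limit** (`expected_ratio_response`): for stationary
   Gaussian input, the expected block-spectrum power at analysis bin k
   is the true power spectrum smoothed by the squared window transform,
   so the infinite-data ratio curve is computable exactly from the
   coefficients.  This reproduces the measured ratio curve without
   Monte-Carlo noise and is what the acceptance script reports.

**Where ratio and direct disagree — and why that is physics, not a
bug.**  A windowed 256-sample block has 3.90625 Hz bins and a
spectral-leakage floor: Hann-window sidelobes of the passband put the
measurable floor around −50…−70 dB, and steep response changes are
smeared across a few bins.  Consequences, all deterministic and
reproduced by the analytic limit:

* inside the narrow Savitzky-Golay stop-band nulls the measured curve
  stays 5–25 dB above the direct curve (the first two nulls fill in
  completely, so the measured SG response first crosses −30 dB near
  205 Hz even though the dense direct curve first dips through −30 dB
  at 105.6 Hz and its lobes never stay below it);
* in the deep stop band of the two-pass FIR (≈ −106 dB) and Butterworth
  (falling to ≈ −208 dB at 450 Hz) the measured curve sits at the
  leakage floor, tens of dB above the direct curve.  No empirical
  spectral-ratio estimator at this block length can track those levels.

The two methods agree to well under 1 dB wherever the response is above
about −10 dB, which covers the passband and the −3 dB crossings; the
−30/−40 dB milestones are properties of the *measured* ratio curve and
are reported as such.  `crossing_frequency` returns the first
interpolated crossing; for ringing responses the companion
`last_exceedance_frequency` marks where the curve finally stays below
the level (NaN when it never settles, as for single-pass SG at −30 dB).
A level L dB is annotated as 100·10^(L/10) percent of signal power
remaining (−18 dB ↔ 1.58 %, −25 dB ↔ 0.32 %).

## Segment selection and spectra

Velocity for screening is the six-point central difference
v[t] = (x[t+3] − x[t−3])·fs/6 (the difference spans six sample
intervals, so the denominator is the span — a linear ramp reproduces its
slope exactly).  The first/last three samples are undefined and never
block acceptance.  Clean segments are 2048-sample windows with every
defined |v| ≤ 25 deg/s, packed greedily left to right; for
fixed-length windows the earliest-feasible greedy packing is maximal,
and the tests confirm it against an exhaustive dynamic program on small
traces.  Segments are split into eight 256-sample blocks (27 segments →
216 blocks).

Each block is detrended with a least-squares quadratic (residual mean
zero by construction), tapered with a periodic Hann window and
transformed; the 128 bins below Nyquist are kept with scaling
2/Σwindow, so a unit-amplitude on-bin sinusoid reports magnitude ≈ 1
dva.  Block spectra are averaged as magnitudes, never as complex values
— phase-incoherent components would otherwise cancel across blocks.
The DC bin is retained but excluded from shape statistics (detrending
drives it to ~0).  Whether to detrend before or after filtering is
immaterial for the ratio curves; the pipeline filters the full trace
first and detrends each extracted block, in that order.

## Autocorrelation study

Per-block autocorrelations use the biased (divide-by-n) normalisation,
which guarantees |r| ≤ 1; lag 0 is identically 1 and not stored.  All
testing is done on Fisher-Z transforms z = atanh(r).  Lag-1 significance
uses the normal statistic z·√(n−3) (consistent with the Fisher-Z
framework; its type-I error calibrates to 0.05 ± 0.01 in the tests).
Condition differences are tested with the Friedman repeated-measures
rank test (scipy implementation, average-rank ties; a table with no
within-block variation is reported as chi² = 0, p = 1, where the raw
formula is 0/0).  Pairwise follow-ups use the Nemenyi construction:
|R̄ᵢ − R̄ⱼ| / √(k(k+1)/(12n)) referred to the studentized range with k
groups and infinite degrees of freedom — the behaviour of MATLAB's
`multcompare` after `friedman`, which is the de-facto standard even
though Tukey HSD formally assumes ANOVA.  Both the mean-rank difference
and the mean Fisher-Z difference are reported per pair, since either can
serve as the effect-size column in the comparison table.

On matched synthetic blocks the study reproduces the expected pattern:
every filter raises lag-1 autocorrelation in ≥ 99 % of blocks, the
ordering unfiltered < SG < FIR ≈ IIR holds for median Fisher-Z, the
FIR–IIR pair is non-significant (per-block noise decides their rank
order roughly 50/50) and every unfiltered-vs-filter pair is significant
at p < 0.001.

## Velocity exemplar

Instantaneous velocity v[t] = (x[t] − x[t−1])·fs is deliberately the
noisiest velocity estimate.  Three noise metrics are computed: the SD of
the series, the RMS of the series, and the RMS of sample-to-sample
differences (RMS-S2S, the standard eye-tracking precision metric).  Both
RMS variants are reported because "RMS of the velocity channel" is
ambiguous: for a smooth (autocorrelated) series RMS-S2S falls *below*
the SD, while the plain RMS cannot (at zero mean), and only RMS-S2S
reproduces the characteristic SD > RMS inversion seen after filtering.
On the noisy-saccade exemplar the ordering unfiltered > SG > IIR ≈ FIR
holds for SD and RMS-S2S, with the FIR marginally the quietest.

## Synthetic data generator

`FixationModel` is a minimal three-component stationary Gaussian model:

| component | default | rationale |
|---|---|---|
| drift: low-passed random walk | 0.11 dva RMS, 30 Hz corner | dominates below ~30 Hz as in real fixation spectra |
| tremor: band-limited noise | 0.007 dva RMS, 15–65 Hz | fills the mid band so the spectrum declines smoothly |
| sensor noise: shaped white noise | 0.012 dva RMS, floor 0.022, rise exponent 2.5 | flat-then-rising; places the spectral minimum near 120–150 Hz and the rise toward 500 Hz |

Defaults were fixed once, before the acceptance checks were written, to
realise the stated qualitative structure: block-averaged amplitude
spectrum maximal below 30 Hz, local minimum inside 100–200 Hz
(typically ≈ 120 Hz), monotone rise toward Nyquist after 5-bin
smoothing, and six-point velocity below the 25 deg/s screen for ≥ 99 %
of seeds 0–99 (observed: 100/100, max ≈ 17 deg/s).  Identical seeds give
bit-identical traces.

`SaccadeModel` uses a raised-cosine position sigmoid (bell-shaped
velocity, peak πA/2T ≈ 82 deg/s for the default 1.25 dva / 24 ms), with
additive white noise of 0.07 dva SD so the unfiltered
instantaneous-velocity SD is of order 100 deg/s — the dynamic range of a
very noisy real recording.

What the generator does *not* emulate: blinks and other artifacts,
calibration error, pupil-size coupling, saccade main-sequence
variability, or the specific spectra of any individual subject.  A green
test on synthetic data therefore establishes that the pipeline measures
what it should under the stated noise structure — not that any
particular real recording will produce particular numbers.  Real-data
quantities (e.g. a median unfiltered lag-1 ACF near 0.58, or specific
velocity-SD values) require the original recordings; the pipeline
ingests such recordings in the same CSV dialect and emits tables of
identical shape.

## Numerical choices and degenerate inputs

* Crossing search: linear interpolation between bracketing grid points;
  NaN bins (undefined ratio) are skipped; a response that never reaches
  the level returns NaN; a response starting at or below the level is an
  error.
* ACF of a (near-)constant block is undefined and raises, with a
  relative variance threshold so additive-constant traces behave the
  same at any offset.
* `detrend_poly2` solves the least-squares problem on a standardised
  time axis for conditioning; results equal the raw normal-equations
  solve to ~1e-8.
* Sampling rates inferred from CSV time columns are snapped to the
  nearest integer when within 1e-4 relative, undoing text round-off.
* `run_study` is deterministic end to end: per-trace seeds are derived
  as `seed + trace_index`, CSVs are written with fixed float formats,
  and two runs with the same config produce byte-identical numeric
  outputs.  Any stage failure removes the partial output directory and
  raises a stage-labelled error.

## Known limitations

* The heuristic on-tracker filters (sample-to-sample rules, no
  coefficients) cannot be synthesised; their response can only be
  measured from recorded data via the ratio method.  The pipeline
  accepts such recordings as extra conditions but ships none.
* The ratio method is leakage-limited below about −50 dB (see above);
  stop-band attenuation beyond that is a statement about the
  coefficients, not about anything measurable from 256-sample blocks.
* The greedy segment search assumes non-overlapping segments; overlap
  was not used in the reference analysis and is not offered.
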