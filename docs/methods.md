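# Methods

This note documents the models behind `gazelab`, the parameter defaults
and why they were chosen, the numerical details, and what the synthetic
generator does and does not emulate.

## Slow-phase gain and phase

The stimulus is a velocity sinusoid `h(t) = A sin(2πft)` (defaults: f ∈
{0.2, 0.4, 0.8, 1, 2} Hz, A = 16 °/s, 60 s per recording, 1 kHz sampling).
The slow-phase response is modeled as a sinusoid at the stimulus frequency;
`fit_sinusoid` solves the linear least-squares problem in the
`(sin, cos, offset)` basis by normal equations (`numpy.linalg.lstsq`),
which is the global optimum — no iteration or initialization is involved.
On an integer number of cycles with no mask the solution coincides with
the discrete Fourier projection at f (tested to 1e-8).

Gain is the ratio of fitted eye to fitted head amplitude; head amplitudes
below 1 °/s raise a stimulus-absent error rather than returning an
unstable ratio. Phase is measured against the ideal response and wrapped
to (−180°, 180°]:

* VOR conditions (dark, light, pre/post learning): ideal is eye = −head,
  so `phase = eye_phase − head_phase − 180°`.
* OKR: the eye follows the surround, ideal is eye = +stimulus, so
  `phase = eye_phase − head_phase`.

Positive phase means the eye leads the ideal response. The convention is
applied uniformly from the recording's condition metadata, so a perfect
response reports phase 0 in every condition.

The default fit uses the whole trace at once (lowest variance). A
per-cycle mode (`per_cycle=True`, CLI `--per-cycle`) fits each stimulus
cycle separately and averages amplitudes arithmetically and phases as
unit vectors; it exists as a robustness check for nonstationary traces.

## Quick-phase detection (desaccading)

The detector iterates at most 10 times:

1. fit the sinusoid with the current exclusion mask (initially empty);
2. compute the residual r = eye − fit;
3. mark samples with `|r| > max(velocity_floor, k · 1.4826 · MAD(r))`,
   defaults `velocity_floor = 10 °/s`, `k = 3`;
4. drop marked runs shorter than `min_duration = 10 ms`;
5. dilate surviving runs by 20 ms before and 40 ms after;
6. stop when the mask no longer changes.

The MAD-based threshold tolerates up to ~50 % contaminated samples; the
absolute floor keeps the threshold meaningful on nearly noise-free
records. The minimum-duration criterion is standard practice in saccade
detection: band-limited noise (125 Hz) decorrelates in a few milliseconds,
so its rare threshold crossings last 1–3 ms, while murine quick phases
last tens of milliseconds. With the defaults, suprathreshold noise
excursions are filtered out and injected pulses with peak velocity well
above the noise floor are detected essentially completely (tested: 100 %
detection, zero spurious events over 20 × 60 s traces).

A mask covering more than 80 % of samples raises a degenerate-input error:
the trace is dominated by saccades or the threshold is mis-set.

Each contiguous masked run is reported as one quick phase with signed
amplitude `∫ r dt` and peak velocity `max |r|`. Because the margins are
included in the integral, amplitude estimates are nearly unbiased (median
relative error ≈ 0.5 % on synthetic cohorts).

## Synthetic eye traces

The generator produces
`eye(t) = ∓ gain · A sin(2πft + φ) + quick phases + noise`
(− for compensatory conditions, + for OKR-like following):

* **Noise** is Gaussian white noise passed through a 4th-order zero-phase
  Butterworth low-pass at 125 Hz — mirroring typical video-oculography
  acquisition filtering — and rescaled so the post-filter SD equals
  `noise_sd` (default 2 °/s).
* **Quick phases** are raised-cosine velocity pulses
  `v(τ) = (P/2)(1 − cos 2πτ/w)`: smooth, compactly supported, with
  integral `P·w/2`. Each event draws an amplitude uniform on [2°, 10°],
  takes its peak velocity from the main-sequence line
  `P = ms_slope·a + ms_intercept` (defaults 35 s⁻¹ and 5 °/s), and its
  width follows as `w = 2a/P` (≈ 55 ms) so that amplitude, peak velocity
  and the main-sequence relation are all satisfied simultaneously — a
  fixed-width pulse cannot honor all three at once. `qp_duration`
  (50 ms) is the nominal width; the inter-event refractory gap is twice
  it. Onsets otherwise follow a Poisson stream at `qp_rate`
  (default 1.5 /s, resembling murine vestibular nystagmus).
* **Direction** resets against the ongoing slow-phase drift (physiological
  nystagmus); a configuration flag randomizes it instead.
* Pulses that would overrun the trace end are discarded and logged.

Every generated file is accompanied by a ground-truth log (true gain and
phase, every injected event). Per-file random streams are derived by
SHA-256 hashing of (master seed, animal, condition, frequency), so cohorts
are bit-reproducible regardless of generation order, and individual files
can be regenerated in isolation.

What the generator does **not** emulate: eye-position drift and blinks,
torsional/vertical components, pursuit intrusions, calibration error,
per-animal gain variability (group members differ only by noise and
quick-phase realizations), and any trial-to-trial adaptation dynamics —
learning appears only as a different post-training gain. Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated noise model, not robustness to every artifact of real recordings.

## Spike-train generators and metrics

`gamma_renewal` draws i.i.d. gamma ISIs with shape `k = 1/CV²` and mean
`1/rate`; `k = 1` is exactly Poisson, `k < 1` gives supra-Poisson
irregularity. Shapes above 1e6 (CV < 1e-3) fall back to a metronome train
with a warning. `burst_pause` draws ISIs from a two-state Markov-modulated
mixture — gamma(2) intervals in the burst state, exponential pauses —
with the stationary burst weight fixed at 0.9 and an expected burst run
length of 10 intervals; the two state means are solved numerically
(Brent's method) so the stationary marginal matches the requested mean
and CV. Markov switching shapes the serial clustering without changing
the marginal moments. CVs below the mixture's attainable minimum (≈ 0.8)
raise an error directing the user to `gamma_renewal`.

Metrics: rate is spikes-per-spiking-span `(n−1)/(t_n−t_1)` by default
(robust to silent padding at the record edges; a per-duration variant is
exposed). CV uses the population SD (divide by n); at the ISI counts
involved (10³–10⁴) the difference from the sample SD is far below
sampling error, and the choice is pinned by a test. CV2 is the unweighted
mean of `2|ISI_{n+1} − ISI_n|/(ISI_{n+1} + ISI_n)` over consecutive
pairs — bounded by [0, 2], equal to 1 in expectation for a Poisson train,
and insensitive to slow rate drift (a 2× rate ramp inflates CV by ~30 %
at baseline CV 0.25 while CV2 moves < 10 %; tested).

## Group statistics

* **Mixed-design ANOVA** (genotype between subjects, frequency within,
  subject nested in genotype) is computed through `pingouin.mixed_anova`
  behind a strict balance check — missing cells raise, nothing is
  imputed. The decomposition is verified in the tests against a
  from-scratch sums-of-squares oracle. No sphericity correction is
  applied by default (a Greenhouse–Geisser flag exists). Post hoc
  contrasts are independent two-sample t tests per frequency with
  Bonferroni multiplier equal to the number of frequencies (default 5);
  per-frequency error terms were preferred over pooled-error contrasts
  for transparency.
* **Mann–Whitney U** uses `U = Σ [x_i > y_j] + ½[x_i = y_j]`, the exact
  null distribution when tie-free and `n1+n2 ≤ 40`, otherwise the normal
  approximation with continuity and tie correction (via
  `scipy.stats.mannwhitneyu`); two-sided throughout. Exact p-values are
  verified against a full enumeration oracle in the tests.
* **Slope comparison** uses the extra-sum-of-squares F test with the
  reduced model sharing the slope but keeping group intercepts
  (df_num = 1): constraining intercepts too would conflate offset
  differences with slope differences. The statistic equals the squared
  t of the interaction coefficient in the pooled regression (tested).
* Main-sequence events are pooled across animals within genotype and
  rectified (absolute amplitude and peak velocity); a per-animal mixed
  model is out of scope.

Type-I error of all three procedures is verified by null simulation
(rejection rate at α = 0.05 within [0.03, 0.07] over 500–1000 replicates).

## Default cohort

The default configuration encodes the emulated study design: 7 control
and 8 mutant animals across three gaze conditions at five frequencies;
6 + 7 animals in the gain-down learning arm (pre gain 0.650, post 0.3497
vs. 0.5096 at the trained 2 Hz); spike populations of 32/38 anesthetized
and 30/30 awake cells with rates 30.49/38.83 and 38.49/24.22 sp/s and CVs
0.41/0.68 and 0.43/1.06. Where only the 2 Hz group values are pinned
down, the remaining per-frequency gains follow typical murine frequency
response curves (VOR gain rising with frequency, OKR falling, VOR-in-light
near constant). Trial duration defaults to 60 s per recording —
unspecified in the emulated protocol, chosen as a realistic session
length that gives ~120 stimulus cycles at 2 Hz — and is configurable.

## Problem sizes and numerical choices

Tests and the acceptance script run on one CPU in a few minutes: spike
populations use 120 s (anesthetized) and 300 s (awake) trains; trace
pipelines use 60 s recordings at 1 kHz; statistical calibration uses
500–1000 null replicates. Phase wrapping maps to (−180°, 180°]; variance
accounted for is clipped at 0; the fitted-cycle span check allows ~1
sample of grid truncation; report floats are rounded to 10 significant
digits before serialization so reruns are byte-identical.

## Known limitations

* Group comparisons on real data will not reproduce published p-values
  bit-for-bit: the underlying raw recordings are not public, and ANOVA
  software options vary; correctness here rests on oracle equivalence
  and calibrated error rates.
* The detector assumes velocity input; a position-differentiation
  preprocessor is deliberately not the canonical path.
* The burst-pause generator targets marginal moments only; it does not
  model state-dependent rate modulation by behavior.
* Per-animal biological variability is not simulated; SEMs on synthetic
  cohorts reflect measurement noise only and are smaller than those of
  real cohorts.
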