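# gazelab

Analysis pipeline for murine gaze-stabilization experiments: vestibulo-ocular
reflex (VOR) and optokinetic reflex (OKR) gain/phase estimation from
head/eye velocity recordings, quick-phase (nystagmus) main-sequence
analysis, VOR gain-down motor-learning quantification, and Purkinje-cell
spike-train regularity metrics — together with the group-statistics layer
(mixed-design ANOVA with Bonferroni post hoc, Mann–Whitney U) and a
synthetic cohort generator with ground-truth logs.

It is written for oculomotor and cerebellar physiologists who record eye
movements during sinusoidal rotation (head turntable or visual surround)
and extracellular Purkinje-cell activity, and who need a tested, scriptable
replacement for ad-hoc per-lab analysis code.

## The quantities it computes

**Slow-phase gain and phase.** For a sinusoidal stimulus
`h(t) = A sin(2πft)`, the desaccaded eye-velocity trace is fitted by least
squares with `a sin(2πft) + b cos(2πft) + c`. The response amplitude is
`√(a² + b²)`, the gain is `eye amplitude / head amplitude`, and the phase
is reported relative to the ideal response (eye = −head for VOR, eye =
+stimulus for OKR), wrapped to (−180°, 180°], positive when the eye leads.

**Desaccading.** Quick phases are detected iteratively: fit the sinusoid,
threshold the residual at `max(10 °/s, 3 robust SD)` (robust SD =
1.4826·MAD), drop suprathreshold runs shorter than 10 ms, dilate surviving
runs by 20 ms before / 40 ms after, and refit until the mask is stable.
Each masked run becomes a quick-phase event with amplitude `∫ residual dt`
and peak velocity `max |residual|`.

**Main sequence.** Quick-phase peak velocity is regressed on amplitude per
group; group slopes are compared with the extra-sum-of-squares F test on
nested models (common slope + group intercepts vs. free slopes),
`F = (ΔSSE/Δdf) / (SSE_full/df_full)`.

**Motor learning.** Gain-down learning is `100·(g_pre − g_post)/g_pre`
per animal per frequency, positive for a gain decrease.

**Spike regularity.** From sorted spike times: firing rate
`(n−1)/(t_n − t_1)`, `CV = σ_ISI/μ_ISI`, and
`CV2 = mean( 2|ISI_{n+1} − ISI_n| / (ISI_{n+1} + ISI_n) )`, a local
measure bounded by [0, 2] that is robust to slow rate drift and equals 1
in expectation for a Poisson train.

## Worked example

```python
import gazelab as gl

stim = gl.StimulusSpec(frequency=2.0, peak_velocity=16.0, duration=60.0)
head = gl.gen_head_stimulus(stim)
eye = gl.EyeModelSpec(gain=0.65, phase=0.0, noise_sd=2.0, qp_rate=1.5)
rec, truth = gl.gen_eye_response(head, stim, eye, seed=42)

events, mask = gl.detect_quick_phases(rec)
fit = gl.estimate_gain_phase(rec)
print(f"injected quick phases: {len(truth['quick_phases'])}, detected: {len(events)}")
print(f"gain  = {fit.gain:.3f}   (true 0.650)")
print(f"phase = {fit.phase:.2f} deg (true 0.00)")
print(f"samples retained after desaccading: {100*fit.fraction_retained:.1f}%")

train = gl.gen_spike_train(
    gl.SpikeModelSpec(rate=38.83, target_cv=0.68, duration=120.0), seed=42)
s = gl.isi_stats(train)
print(f"rate = {s.rate:.2f} sp/s, CV = {s.cv:.3f}, CV2 = {s.cv2:.3f}")
```

prints

```
injected quick phases: 73, detected: 73
gain  = 0.650   (true 0.650)
phase = 0.07 deg (true 0.00)
samples retained after desaccading: 86.9%
rate = 38.66 sp/s, CV = 0.675, CV2 = 0.704
```

The recording carries 73 superimposed quick phases riding on a 0.65-gain
compensatory response in 2 °/s band-limited noise; the detector finds all
of them, and the desaccaded fit recovers the generating gain to three
decimals. The spike train is a gamma renewal process whose empirical rate
and CV sit within sampling error of the targets.

## Command line

```bash
gazelab config --defaults                     # print the cohort defaults
gazelab simulate --config cohort.yaml --seed 1 --out data/
gazelab analyze-gaze   --manifest data/manifest.json --out out/
gazelab main-sequence  --in out/quick_phases.csv --out out/main_sequence.json
gazelab learning       --manifest data/manifest.json --out out/
gazelab analyze-spikes --manifest data/manifest.json --out out/
gazelab run-all --config cohort.yaml --seed 1 --out out/   # everything
```

Input formats: trace CSVs (`time_s,head_vel_dps,eye_vel_dps`), spike files
(one time in seconds per line), and a JSON manifest mapping files to
animal / genotype / condition / frequency.

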