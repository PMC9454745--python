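"""Synthetic cohort generator.

Emulates sinusoidal rotation experiments (0.2–2 Hz, ±16 °/s peak head
velocity, 1 kHz sampling, 125 Hz acquisition low-pass) and floccular
Purkinje-cell spike trains, with a ground-truth log written next to every
generated file so downstream estimators can be validated without the
original recordings.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from scipy import optimize, signal

from .types import (
    EyeModelSpec,
    QuickPhase,
    SpikeModelSpec,
    SpikeTrain,
    StimulusSpec,
    ValidationError,
    VelocityRecording,
)

ACQUISITION_LOWPASS_HZ = 125.0

# Gamma shape exceeding this corresponds to CV < 1e-3; the gamma sampler
# loses accuracy and a metronome train is statistically indistinguishable.
_MAX_GAMMA_SHAPE = 1e6


def derive_seed(master_seed: int, *key: object) -> int:
    """Derive an independent 63-bit child seed from a master seed and a key.

    Hash-based so each generated file is reproducible in isolation,
    independent of generation order.
    """
    h = hashlib.sha256(repr((int(master_seed),) + tuple(key)).encode()).digest()
    return int.from_bytes(h[:8], "big") % (2**63 - 1)


def gen_head_stimulus(spec: StimulusSpec) -> np.ndarray:
    """Sinusoidal head-velocity trace ``h(t) = A sin(2π f t)``."""
    t = np.arange(spec.n_samples) / spec.sampling_rate
    return spec.peak_velocity * np.sin(2.0 * np.pi * spec.frequency * t)


def _bandlimited_noise(n: int, sampling_rate: float, sd: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise low-passed at the acquisition cutoff, rescaled so the
    post-filter SD equals ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    wn = ACQUISITION_LOWPASS_HZ / (sampling_rate / 2.0)
    if wn < 1.0:
        b, a = signal.butter(4, wn)
        white = signal.filtfilt(b, a, white)
    s = white.std()
    return white * (sd / s) if s > 0 else white


def _draw_quick_phases(spec: EyeModelSpec, stim: StimulusSpec,
                       slow_eye: np.ndarray,
                       rng: np.random.Generator) -> tuple[list[dict], list[dict]]:
    """Draw quick-phase events (onset, amplitude, peak velocity, width).

    Onsets follow a Poisson stream with a refractory dead time of
    2×qp_duration between events.  Each event's unsigned amplitude is
    uniform over ``qp_amp_range``; its peak velocity follows the
    main-sequence line; its width is then fixed by the raised-cosine shape
    (integral = peak·width/2).  Direction resets against the ongoing
    slow-phase drift when ``alternate_directions`` is set.
    """
    events: list[dict] = []
    discarded: list[dict] = []
    if spec.qp_rate <= 0:
        return events, discarded
    refractory = 2.0 * spec.qp_duration
    t = refractory + rng.exponential(1.0 / spec.qp_rate)
    lo, hi = spec.qp_amp_range
    while t < stim.duration:
        amp = rng.uniform(lo, hi)
        peak = spec.ms_slope * amp + spec.ms_intercept
        width = 2.0 * amp / peak
        if spec.alternate_directions:
            i = min(int(t * stim.sampling_rate), slow_eye.size - 1)
            drift = slow_eye[i]
            direction = 1 if drift <= 0 else -1
        else:
            direction = 1 if rng.random() < 0.5 else -1
        ev = dict(onset=float(t), amplitude=float(direction * amp),
                  peak_velocity=float(peak), width=float(width),
                  direction=direction)
        if t + width > stim.duration:
            discarded.append(ev)
        else:
            events.append(ev)
        t += width + refractory + rng.exponential(1.0 / spec.qp_rate)
    return events, discarded


def _render_pulse(eye: np.ndarray, ev: dict, sampling_rate: float) -> None:
    """Add one raised-cosine velocity pulse in place.

    ``v(t) = dir · (P/2)(1 − cos(2π (t−t0)/w))`` on [t0, t0+w): peak P,
    integral dir·P·w/2 = signed amplitude.
    """
    i0 = int(np.ceil(ev["onset"] * sampling_rate))
    i1 = int(np.floor((ev["onset"] + ev["width"]) * sampling_rate))
    idx = np.arange(i0, min(i1 + 1, eye.size))
    tau = idx / sampling_rate - ev["onset"]
    eye[idx] += (ev["direction"] * ev["peak_velocity"] / 2.0
                 * (1.0 - np.cos(2.0 * np.pi * tau / ev["width"])))


def gen_eye_response(head: np.ndarray, stim: StimulusSpec, spec: EyeModelSpec,
                     seed: int, metadata: dict | None = None,
                     following: bool = False) -> tuple[VelocityRecording, dict]:
    """Synthesize an eye-velocity trace for a given head stimulus.

    eye(t) = −gain · A · sin(2π f t + phase) + quick-phase pulses +
    band-limited noise.  With ``following=True`` (optokinetic conditions,
    where the eye tracks the moving surround) the slow-phase sign flips to
    ``+gain · A · sin(·)``.  Returns the recording and a ground-truth log
    with the true gain/phase and every injected quick phase.
    """
    head = np.asarray(head, dtype=float)
    if head.size != stim.n_samples:
        raise ValidationError("head trace length does not match stimulus spec")
    rng = np.random.default_rng(seed)
    t = np.arange(stim.n_samples) / stim.sampling_rate
    phi = np.deg2rad(spec.phase)
    sense = 1.0 if following else -1.0
    slow = sense * spec.gain * stim.peak_velocity * np.sin(
        2.0 * np.pi * stim.frequency * t + phi)
    events, discarded = _draw_quick_phases(spec, stim, slow, rng)
    eye = slow.copy()
    for ev in events:
        _render_pulse(eye, ev, stim.sampling_rate)
    eye += _bandlimited_noise(stim.n_samples, stim.sampling_rate,
                              spec.noise_sd, rng)
    rec = VelocityRecording(time=t, head_vel=head, eye_vel=eye,
                            sampling_rate=stim.sampling_rate,
                            stimulus_frequency=stim.frequency,
                            metadata=dict(metadata or {}))
    truth = dict(gain=spec.gain, phase=spec.phase, noise_sd=spec.noise_sd,
                 following=following, quick_phases=events,
                 discarded_quick_phases=discarded)
    return rec, truth


def injected_quick_phases(truth: dict) -> list[QuickPhase]:
    """Ground-truth log entries as :class:`QuickPhase` objects."""
    return [QuickPhase(onset=ev["onset"], offset=ev["onset"] + ev["width"],
                       amplitude=ev["amplitude"],
                       peak_velocity=ev["peak_velocity"],
                       direction=ev["direction"])
            for ev in truth["quick_phases"]]


# ---------------------------------------------------------------------------
# spike-train generators

def _gamma_isis(rate: float, cv: float, duration: float,
                rng: np.random.Generator) -> np.ndarray:
    shape = 1.0 / cv**2
    if shape > _MAX_GAMMA_SHAPE:
        import warnings
        warnings.warn("target_cv implies gamma shape > 1e6; "
                      "falling back to a regular train", stacklevel=3)
        n = int(np.floor(duration * rate))
        return np.full(n + 1, 1.0 / rate)
    scale = cv**2 / rate   # mean ISI = shape*scale = 1/rate
    n_expect = int(np.ceil(duration * rate + 10 * np.sqrt(duration * rate) + 10))
    isis = rng.gamma(shape, scale, size=n_expect)
    while isis.sum() < duration:
        isis = np.concatenate([isis, rng.gamma(shape, scale, size=n_expect)])
    return isis


def _burst_pause_mixture(rate: float, cv: float) -> tuple[float, float, float]:
    """Calibrate the two-state ISI mixture to a target mean and CV.

    Burst-state ISIs are gamma(shape 2, mean m1); pause-state ISIs are
    exponential(mean m2).  With stationary burst weight w the marginal
    mean is w·m1 + (1−w)·m2 and the marginal second moment
    w·1.5·m1² + (1−w)·2·m2²; m1 is solved so the marginal CV equals the
    target.
    """
    mu = 1.0 / rate
    w = 0.9
    target_m2 = mu**2 * (cv**2 + 1.0)

    def excess(m1: float) -> float:
        m2 = (mu - w * m1) / (1.0 - w)
        return w * 1.5 * m1**2 + (1.0 - w) * 2.0 * m2**2 - target_m2

    eps = mu * 1e-9
    hi = mu / w - eps
    if excess(eps) * excess(hi) > 0:
        raise ValidationError(
            f"burst_pause cannot reach target_cv={cv:g} at rate={rate:g}; "
            "use gamma_renewal for low-CV trains")
    m1 = optimize.brentq(excess, eps, hi, xtol=1e-15)
    m2 = (mu - w * m1) / (1.0 - w)
    return m1, m2, w


def _burst_pause_isis(rate: float, cv: float, duration: float,
                      rng: np.random.Generator) -> np.ndarray:
    m1, m2, w = _burst_pause_mixture(rate, cv)
    # Markov switching with expected burst run length 10 intervals keeps the
    # stationary weight at w while clustering burst ISIs together.
    p_leave_burst = 0.1
    p_leave_pause = p_leave_burst * w / (1.0 - w)
    isis = []
    total = 0.0
    state = 0 if rng.random() < w else 1   # 0 = burst, 1 = pause
    while total < duration:
        if state == 0:
            isi = rng.gamma(2.0, m1 / 2.0)
            if rng.random() < p_leave_burst:
                state = 1
        else:
            isi = rng.exponential(m2)
            if rng.random() < min(1.0, p_leave_pause):
                state = 0
        isis.append(isi)
        total += isi
    return np.asarray(isis)


def gen_spike_train(spec: SpikeModelSpec, seed: int,
                    metadata: dict | None = None) -> SpikeTrain:
    """Simulate a spike train with target rate and ISI coefficient of
    variation; see :class:`SpikeModelSpec` for the two processes."""
    rng = np.random.default_rng(seed)
    if spec.process == "gamma_renewal":
        isis = _gamma_isis(spec.rate, spec.target_cv, spec.duration, rng)
    else:
        isis = _burst_pause_isis(spec.rate, spec.target_cv, spec.duration, rng)
    times = np.cumsum(isis)
    times = times[times <= spec.duration]
    return SpikeTrain(spike_times=times, duration=spec.duration,
                      metadata=dict(metadata or {}))


# ---------------------------------------------------------------------------
# cohort generation

#: Study-design defaults: two genotypes tested in darkness (VORd), with a
#: moving visual surround (OKR) and in light (VORl) at five frequencies;
#: gain-down learning assessed pre/post at the same frequencies; spike
#: populations recorded anesthetized and awake.  Gains follow the published
#: group profiles where printed (2 Hz VORd deficit, learning percent changes,
#: spike rate/CV group means); the remaining per-frequency values are chosen
#: to resemble murine frequency-response curves.
DEFAULT_CONFIG: dict = {
    "stimulus": {
        "frequencies_hz": [0.2, 0.4, 0.8, 1.0, 2.0],
        "peak_velocity_dps": 16.0,
        "duration_s": 60.0,
        "sampling_rate_hz": 1000.0,
    },
    "eye": {
        "noise_sd_dps": 2.0,
        "qp_rate_hz": 1.5,
        "ms_slope": 35.0,
        "ms_intercept_dps": 5.0,
        "qp_duration_s": 0.05,
    },
    "groups": {
        "WT": {
            "n_animals": 7,
            "gain": {
                "VORd": {0.2: 0.35, 0.4: 0.45, 0.8: 0.60, 1.0: 0.70, 2.0: 0.80},
                "OKR": {0.2: 0.75, 0.4: 0.65, 0.8: 0.45, 1.0: 0.35, 2.0: 0.20},
                "VORl": {0.2: 0.90, 0.4: 0.90, 0.8: 0.90, 1.0: 0.90, 2.0: 0.90},
            },
            "phase": {
                "VORd": {0.2: 10.0, 0.4: 6.0, 0.8: 3.0, 1.0: 2.0, 2.0: 0.0},
                "OKR": {0.2: -2.0, 0.4: -4.0, 0.8: -8.0, 1.0: -10.0, 2.0: -15.0},
                "VORl": {0.2: 2.0, 0.4: 1.0, 0.8: 0.5, 1.0: 0.0, 2.0: 0.0},
            },
        },
        "SCA6": {
            "n_animals": 8,
            "gain": {
                "VORd": {0.2: 0.35, 0.4: 0.45, 0.8: 0.48, 1.0: 0.53, 2.0: 0.576},
                "OKR": {0.2: 0.60, 0.4: 0.52, 0.8: 0.42, 1.0: 0.33, 2.0: 0.19},
                "VORl": {0.2: 0.75, 0.4: 0.75, 0.8: 0.75, 1.0: 0.75, 2.0: 0.75},
            },
            "phase": {
                "VORd": {0.2: 10.0, 0.4: 6.0, 0.8: 3.0, 1.0: 2.0, 2.0: 0.0},
                "OKR": {0.2: -2.0, 0.4: -4.0, 0.8: -8.0, 1.0: -10.0, 2.0: -15.0},
                "VORl": {0.2: 2.0, 0.4: 1.0, 0.8: 0.5, 1.0: 0.0, 2.0: 0.0},
            },
        },
    },
    "learning": {
        # gain-down training at 2 Hz; largest decrease at the trained
        # frequency, tapering toward 0.2 Hz
        "WT": {
            "n_animals": 6,
            "gain_pre": {0.2: 0.35, 0.4: 0.45, 0.8: 0.60, 1.0: 0.70, 2.0: 0.650},
            "gain_post": {0.2: 0.32, 0.4: 0.38, 0.8: 0.45, 1.0: 0.48, 2.0: 0.3497},
        },
        "SCA6": {
            "n_animals": 7,
            "gain_pre": {0.2: 0.35, 0.4: 0.45, 0.8: 0.48, 1.0: 0.53, 2.0: 0.650},
            "gain_post": {0.2: 0.34, 0.4: 0.42, 0.8: 0.44, 1.0: 0.48, 2.0: 0.5096},
        },
    },
    "spikes": {
        "duration_s": 120.0,
        "process": "gamma_renewal",
        "anesthetized": {
            "WT": {"n_cells": 32, "rate_sps": 30.49, "cv": 0.41},
            "SCA6": {"n_cells": 38, "rate_sps": 38.83, "cv": 0.68},
        },
        "awake": {
            "WT": {"n_cells": 30, "rate_sps": 38.49, "cv": 0.43},
            "SCA6": {"n_cells": 30, "rate_sps": 24.22, "cv": 1.06},
        },
    },
    "stats": {
        "bonferroni_comparisons": 5,
        "alpha": 0.05,
    },
}


def _deep_get(cfg: dict, *keys: str) -> object:
    cur: object = cfg
    for k in keys:
        if not isinstance(cur, dict) or k not in cur:
            raise ValidationError(f"cohort config missing key {'.'.join(keys)!r}")
        cur = cur[k]
    return cur


def _get(d: dict, key: str, ctx: str) -> object:
    if key not in d:
        raise ValidationError(f"cohort config missing {ctx}.{key}")
    return d[key]


def gen_cohort(config: dict, seed: int, out_dir: str | Path) -> dict:
    """Write a full synthetic cohort to disk: trace CSVs, spike-time files,
    ``manifest.json`` and ``ground_truth.json``.

    Per-file random streams are derived by hashing (seed, animal, condition,
    frequency), so re-running with the same config and seed is byte
    identical regardless of generation order.  Returns the ground-truth log.
    """
    from .io import write_manifest, write_spike_file, write_trace_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stim_cfg = _deep_get(config, "stimulus")
    eye_cfg = _deep_get(config, "eye")
    manifest: list[dict] = []
    truth: dict = {"seed": int(seed), "recordings": {}, "spike_trains": {}}

    def make_trace(fname: str, genotype: str, animal: str, condition: str,
                   freq: float, gain: float, phase: float) -> None:
        stim = StimulusSpec(frequency=freq,
                            peak_velocity=stim_cfg["peak_velocity_dps"],
                            duration=stim_cfg["duration_s"],
                            sampling_rate=stim_cfg["sampling_rate_hz"])
        eye_spec = EyeModelSpec(gain=gain, phase=phase,
                                noise_sd=eye_cfg["noise_sd_dps"],
                                qp_rate=eye_cfg["qp_rate_hz"],
                                ms_slope=eye_cfg["ms_slope"],
                                ms_intercept=eye_cfg["ms_intercept_dps"],
                                qp_duration=eye_cfg["qp_duration_s"])
        head = gen_head_stimulus(stim)
        file_seed = derive_seed(seed, animal, condition, freq)
        rec, rec_truth = gen_eye_response(head, stim, eye_spec, file_seed,
                                          following=condition == "OKR")
        write_trace_csv(out / fname, rec)
        manifest.append(dict(file=fname, animal_id=animal, genotype=genotype,
                             condition=condition, frequency_hz=freq))
        truth["recordings"][fname] = rec_truth

    groups = _deep_get(config, "groups")
    for genotype, gcfg in groups.items():
        ctx = f"groups.{genotype}"
        n_animals = int(_get(gcfg, "n_animals", ctx))
        gain_cfg = _get(gcfg, "gain", ctx)
        phase_cfg = _get(gcfg, "phase", ctx)
        for a in range(n_animals):
            animal = f"{genotype}_{a + 1:02d}"
            for condition, per_freq in gain_cfg.items():
                for freq, gain in per_freq.items():
                    freq = float(freq)
                    phase = float(_get(phase_cfg, condition, ctx + ".phase")[freq])
                    fname = f"{animal}_{condition}_{freq:g}Hz.csv"
                    make_trace(fname, genotype, animal, condition, freq,
                               float(gain), phase)

    learning = config.get("learning", {})
    for genotype, lcfg in learning.items():
        ctx = f"learning.{genotype}"
        for a in range(int(_get(lcfg, "n_animals", ctx))):
            animal = f"{genotype}_L{a + 1:02d}"
            for condition, gains in (("pre", _get(lcfg, "gain_pre", ctx)),
                                     ("post", _get(lcfg, "gain_post", ctx))):
                for freq, gain in gains.items():
                    freq = float(freq)
                    fname = f"{animal}_{condition}_{freq:g}Hz.csv"
                    make_trace(fname, genotype, animal, condition, freq,
                               float(gain), 0.0)

    spikes = config.get("spikes", {})
    sp_dur = float(spikes.get("duration_s", 120.0))
    process = spikes.get("process", "gamma_renewal")
    for state in ("anesthetized", "awake"):
        for genotype, scfg in spikes.get(state, {}).items():
            ctx = f"spikes.{state}.{genotype}"
            for c in range(int(_get(scfg, "n_cells", ctx))):
                cell = f"{genotype}_{state}_{c + 1:03d}"
                spec = SpikeModelSpec(rate=float(_get(scfg, "rate_sps", ctx)),
                                      target_cv=float(_get(scfg, "cv", ctx)),
                                      duration=sp_dur, process=process)
                cell_seed = derive_seed(seed, cell, state, "spikes")
                train = gen_spike_train(spec, cell_seed)
                fname = f"{cell}.spk"
                write_spike_file(out / fname, train)
                manifest.append(dict(file=fname, animal_id=cell,
                                     genotype=genotype, state=state,
                                     condition="spontaneous",
                                     frequency_hz=None))
                truth["spike_trains"][fname] = dict(
                    rate=spec.rate, cv=spec.target_cv,
                    n_spikes=int(train.n_spikes))

    write_manifest(out / "manifest.json", manifest)
    (out / "ground_truth.json").write_text(
        json.dumps(truth, indent=1, sort_keys=True) + "\n")
    return truth
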