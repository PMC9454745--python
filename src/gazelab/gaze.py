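"""Slow-phase gain/phase estimation with iterative desaccading.

The slow-phase (compensatory) response to sinusoidal stimulation is
estimated by least-squares fitting ``a·sin(2πft) + b·cos(2πft) + c`` to the
eye-velocity trace after excluding quick phases.  Quick phases are found by
an iterative robust procedure: fit, threshold the residual, mask, refit,
until the mask stabilizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    DegenerateInputError,
    QuickPhase,
    SlowPhaseFit,
    ValidationError,
    VelocityRecording,
)

#: Conditions whose ideal response is eye = +stimulus (the eye follows the
#: visual surround); everything else is compensatory (eye = -head).
FOLLOWING_CONDITIONS = frozenset({"OKR"})


class StimulusAbsentError(DegenerateInputError):
    """Head (stimulus) channel carries no measurable sinusoid."""


def wrap_phase(deg: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    w = float(deg) % 360.0
    if w > 180.0:
        w -= 360.0
    return w


def fit_sinusoid(signal: np.ndarray, frequency: float, sampling_rate: float,
                 mask: np.ndarray | None = None,
                 time: np.ndarray | None = None
                 ) -> tuple[float, float, float]:
    """Least-squares sinusoid fit at a known frequency.

    Minimizes ``Σ_unmasked (s - a·sin(2πft) - b·cos(2πft) - c)²`` by the
    closed-form normal equations and returns ``(amplitude, phase_deg,
    offset)`` with ``s ≈ amplitude·sin(2πft + phase) + offset``.

    ``mask`` marks samples to exclude (True = excluded).
    """
    if frequency <= 0:
        raise ValidationError(f"frequency must be > 0, got {frequency}")
    signal = np.asarray(signal, dtype=float)
    if time is None:
        time = np.arange(signal.size) / sampling_rate
    keep = np.ones(signal.size, bool) if mask is None else ~np.asarray(mask, bool)
    t = time[keep]
    s = signal[keep]
    if s.size < 10:
        raise DegenerateInputError(
            f"sinusoid fit needs >= 10 unmasked samples, got {s.size}")
    # one-cycle span requirement, slack of ~1 sample for grid truncation
    if t.max() - t.min() < 1.0 / frequency - 1.5 / sampling_rate:
        raise DegenerateInputError(
            "unmasked samples must span at least one stimulus cycle")
    w = 2.0 * np.pi * frequency * t
    X = np.column_stack([np.sin(w), np.cos(w), np.ones_like(w)])
    coef, *_ = np.linalg.lstsq(X, s, rcond=None)
    a, b, c = coef
    amplitude = float(np.hypot(a, b))
    phase = float(np.degrees(np.arctan2(b, a)))
    return amplitude, phase, float(c)


def _predict_sinusoid(n: int, sampling_rate: float, frequency: float,
                      amplitude: float, phase_deg: float,
                      offset: float) -> np.ndarray:
    t = np.arange(n) / sampling_rate
    return amplitude * np.sin(2.0 * np.pi * frequency * t
                              + np.deg2rad(phase_deg)) + offset


@dataclass(frozen=True)
class DesaccadeOptions:
    """Quick-phase detector settings.

    The residual threshold is ``max(velocity_floor, k · robust_SD)`` with
    ``robust_SD = 1.4826 · MAD``.  Suprathreshold runs shorter than
    ``min_duration`` are treated as noise excursions; surviving runs are
    dilated by ``margin_before``/``margin_after`` to also exclude the pulse
    tails that sit below threshold.
    """

    k: float = 3.0
    velocity_floor: float = 10.0    # °/s
    margin_before: float = 0.020    # s
    margin_after: float = 0.040     # s
    min_duration: float = 0.010     # s
    max_iter: int = 10
    max_masked_fraction: float = 0.8


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], flags.view(np.int8), [0]])))
    return list(zip(idx[0::2], idx[1::2]))


def detect_quick_phases(rec: VelocityRecording,
                        opts: DesaccadeOptions | None = None
                        ) -> tuple[list[QuickPhase], np.ndarray]:
    """Detect quick phases in the eye-velocity trace.

    Iterates: (1) sinusoid fit with the current mask, (2) residual
    thresholding, (3) run filtering and margin dilation — until the mask is
    stable or ``max_iter`` is reached.  Returns the events and the boolean
    exclusion mask (True = sample excluded).
    """
    opts = opts or DesaccadeOptions()
    sr = rec.sampling_rate
    n = rec.n_samples
    dt = 1.0 / sr
    mask = np.zeros(n, dtype=bool)
    resid = rec.eye_vel.copy()
    min_len = max(1, int(round(opts.min_duration * sr)))
    before = int(round(opts.margin_before * sr))
    after = int(round(opts.margin_after * sr))

    for _ in range(opts.max_iter):
        amp, ph, off = fit_sinusoid(rec.eye_vel, rec.stimulus_frequency, sr,
                                    mask=mask)
        resid = rec.eye_vel - _predict_sinusoid(n, sr, rec.stimulus_frequency,
                                                amp, ph, off)
        mad = np.median(np.abs(resid - np.median(resid)))
        thresh = max(opts.velocity_floor, opts.k * 1.4826 * mad)
        above = np.abs(resid) > thresh
        new_mask = np.zeros(n, dtype=bool)
        for start, stop in _runs(above):
            if stop - start < min_len:
                continue
            new_mask[max(0, start - before):min(n, stop + after)] = True
        if new_mask.mean() > opts.max_masked_fraction:
            raise DegenerateInputError(
                f"desaccade mask covers {100 * new_mask.mean():.0f}% of "
                "samples; trace is dominated by saccades or the threshold "
                "is mis-set")
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask

    events: list[QuickPhase] = []
    for start, stop in _runs(mask):
        seg = resid[start:stop]
        amp_deg = float(np.sum(seg) * dt)
        peak = float(np.max(np.abs(seg)))
        events.append(QuickPhase(onset=start * dt, offset=stop * dt,
                                 amplitude=amp_deg, peak_velocity=peak,
                                 direction=1 if amp_deg >= 0 else -1))
    return events, mask


def estimate_gain_phase(rec: VelocityRecording, desaccade: bool = True,
                        opts: DesaccadeOptions | None = None,
                        per_cycle: bool = False) -> SlowPhaseFit:
    """Gain and phase of the slow-phase response at the stimulus frequency.

    The head channel is fitted unmasked; the eye channel is fitted with the
    quick-phase exclusion mask.  ``gain = eye_amplitude / head_amplitude``.
    Phase is relative to the ideal response — compensatory (eye = -head)
    for VOR conditions, following (eye = +stimulus) for OKR — so phase 0
    means an ideal response and positive phase means the eye leads.
    """
    f = rec.stimulus_frequency
    sr = rec.sampling_rate
    head_amp, head_ph, _ = fit_sinusoid(rec.head_vel, f, sr)
    if head_amp < 1.0:
        raise StimulusAbsentError(
            f"head-velocity amplitude {head_amp:.3g} °/s < 1 °/s; "
            "no stimulus present")
    if desaccade:
        _, mask = detect_quick_phases(rec, opts)
    else:
        mask = np.zeros(rec.n_samples, dtype=bool)

    amp2, ph2, off2 = fit_sinusoid(rec.eye_vel, f, sr, mask=mask)
    if per_cycle:
        eye_amp, eye_ph = _per_cycle_fit(rec, mask)
    else:
        eye_amp, eye_ph = amp2, ph2

    condition = rec.metadata.get("condition", "")
    if condition in FOLLOWING_CONDITIONS:
        phase = wrap_phase(eye_ph - head_ph)
    else:
        phase = wrap_phase(eye_ph - head_ph - 180.0)

    keep = ~mask
    model = _predict_sinusoid(rec.n_samples, sr, f, amp2, ph2, off2)
    res = rec.eye_vel[keep] - model[keep]
    tot = rec.eye_vel[keep] - rec.eye_vel[keep].mean()
    ss_tot = float(np.sum(tot**2))
    vaf = max(0.0, 1.0 - float(np.sum(res**2)) / ss_tot) if ss_tot > 0 else 0.0

    return SlowPhaseFit(frequency=f, gain=eye_amp / head_amp, phase=phase,
                        eye_amplitude=eye_amp, head_amplitude=head_amp,
                        fraction_retained=float(keep.mean()), vaf=vaf)


def _per_cycle_fit(rec: VelocityRecording, mask: np.ndarray
                   ) -> tuple[float, float]:
    """Fit each full stimulus cycle separately and average.

    Amplitudes average arithmetically; phases average as unit vectors.
    Cycles with too few retained samples are skipped.
    """
    sr = rec.sampling_rate
    f = rec.stimulus_frequency
    cyc = int(round(sr / f))
    n_cycles = rec.n_samples // cyc
    amps, phs = [], []
    for c in range(n_cycles):
        sl = slice(c * cyc, (c + 1) * cyc)
        try:
            a, p, _ = fit_sinusoid(rec.eye_vel[sl], f, sr, mask=mask[sl],
                                   time=rec.time[sl])
        except DegenerateInputError:
            continue
        amps.append(a)
        phs.append(p)
    if not amps:
        raise DegenerateInputError("no cycle had enough retained samples")
    mean_vec = np.mean(np.exp(1j * np.deg2rad(phs)))
    return float(np.mean(amps)), float(np.degrees(np.angle(mean_vec)))


def frequency_response(dataset_dir, manifest: list[dict],
                       conditions: tuple[str, ...] = ("VORd", "OKR", "VORl"),
                       desaccade: bool = True,
                       opts: DesaccadeOptions | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-recording gain/phase table plus group mean ± SEM per frequency.

    Returns ``(table, summary)``: ``table`` is long-format (animal,
    genotype, condition, frequency_hz, gain, phase, fraction_retained,
    vaf); ``summary`` aggregates to (genotype, condition, frequency_hz)
    with ``SEM = SD/√n_animals``.  If the manifest lists repeated trials
    (a ``trial`` key), trials are averaged per animal; duplicate entries
    without a trial key are an error.
    """
    from pathlib import Path

    from .io import read_trace_csv

    rows = []
    seen: set[tuple] = set()
    for entry in manifest:
        if entry["condition"] not in conditions:
            continue
        key = (entry["animal_id"], entry["condition"], entry["frequency_hz"],
               entry.get("trial"))
        if key in seen:
            raise ValidationError(
                f"duplicate manifest entry for animal={key[0]} "
                f"condition={key[1]} frequency={key[2]}")
        seen.add(key)
        rec = read_trace_csv(Path(dataset_dir) / entry["file"],
                             stimulus_frequency=entry["frequency_hz"],
                             metadata=entry)
        fit = estimate_gain_phase(rec, desaccade=desaccade, opts=opts)
        rows.append(dict(animal=entry["animal_id"], genotype=entry["genotype"],
                         condition=entry["condition"],
                         frequency_hz=entry["frequency_hz"], gain=fit.gain,
                         phase=fit.phase,
                         fraction_retained=fit.fraction_retained, vaf=fit.vaf))
    if not rows:
        raise ValidationError("no manifest entries matched the requested "
                              f"conditions {conditions}")
    table = pd.DataFrame(rows)
    # average repeated trials per animal before group statistics
    table = (table.groupby(["animal", "genotype", "condition", "frequency_hz"],
                           as_index=False)
             .agg(gain=("gain", "mean"), phase=("phase", "mean"),
                  fraction_retained=("fraction_retained", "mean"),
                  vaf=("vaf", "mean")))
    summary = group_summary(table, ["genotype", "condition", "frequency_hz"],
                            ["gain", "phase"])
    return table, summary


def collect_quick_phases(dataset_dir, manifest: list[dict],
                         conditions: tuple[str, ...] = ("VORd",),
                         opts: DesaccadeOptions | None = None) -> pd.DataFrame:
    """Detect quick phases across a dataset and pool the events.

    Returns one row per event (animal, genotype, condition, frequency_hz,
    amplitude_deg, peak_vel_dps, direction) — the input to the
    main-sequence analysis.
    """
    from pathlib import Path

    from .io import read_trace_csv

    rows = []
    for entry in manifest:
        if entry["condition"] not in conditions:
            continue
        rec = read_trace_csv(Path(dataset_dir) / entry["file"],
                             stimulus_frequency=entry["frequency_hz"],
                             metadata=entry)
        events, _ = detect_quick_phases(rec, opts)
        for ev in events:
            rows.append(dict(animal=entry["animal_id"],
                             genotype=entry["genotype"],
                             condition=entry["condition"],
                             frequency_hz=entry["frequency_hz"],
                             amplitude_deg=abs(ev.amplitude),
                             peak_vel_dps=ev.peak_velocity,
                             direction=ev.direction))
    return pd.DataFrame(rows, columns=["animal", "genotype", "condition",
                                       "frequency_hz", "amplitude_deg",
                                       "peak_vel_dps", "direction"])


def group_summary(table: pd.DataFrame, by: list[str],
                  metrics: list[str]) -> pd.DataFrame:
    """Mean ± SEM (SD/√n, sample SD) of each metric per group."""
    def agg(g: pd.DataFrame) -> pd.Series:
        out = {}
        n = len(g)
        for m in metrics:
            out[f"mean_{m}"] = g[m].mean()
            out[f"sem_{m}"] = g[m].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        out["n"] = n
        return pd.Series(out)

    summary = table.groupby(by, as_index=False).apply(agg, include_groups=False)
    summary["n"] = summary["n"].astype(int)
    return summary
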