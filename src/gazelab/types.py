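"""Domain containers shared across the pipeline.

All velocity quantities are in degrees per second (°/s, ``dps`` in file
headers), times in seconds, frequencies in Hz, phases in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class DegenerateInputError(ValueError):
    """Raised when an input is formally valid but cannot support the analysis
    (e.g. a trace dominated by saccades, or too few samples to fit)."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class StimulusSpec:
    """Sinusoidal head (or visual-surround) velocity stimulus.

    ``peak_velocity`` is the amplitude A of ``h(t) = A sin(2π f t)``.
    """

    frequency: float            # Hz
    peak_velocity: float = 16.0  # °/s
    duration: float = 60.0      # s
    sampling_rate: float = 1000.0  # Hz

    def __post_init__(self) -> None:
        _require(self.frequency > 0, f"frequency must be > 0, got {self.frequency}")
        _require(self.peak_velocity >= 0,
                 f"peak_velocity must be >= 0, got {self.peak_velocity}")
        _require(self.duration >= 2.0 / self.frequency,
                 f"duration must cover >= 2 stimulus cycles "
                 f"(>= {2.0 / self.frequency:g} s), got {self.duration}")
        _require(self.sampling_rate >= 100.0,
                 f"sampling_rate must be >= 100 Hz, got {self.sampling_rate}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


@dataclass(frozen=True)
class EyeModelSpec:
    """Generative model of the slow-phase eye response plus nystagmus.

    ``gain``/``phase`` define the compensatory component
    ``eye(t) = -gain * A * sin(2π f t + phase)``; phase 0 means perfect
    compensation (eye = -head).  Quick phases ride on top as raised-cosine
    velocity pulses whose peak velocity follows the main-sequence line
    ``peak = ms_slope * amplitude + ms_intercept``.
    """

    gain: float
    phase: float = 0.0          # degrees; 0 = perfectly compensatory
    noise_sd: float = 0.0       # °/s, SD after 125 Hz low-pass
    qp_rate: float = 0.0        # quick phases / s
    ms_slope: float = 35.0      # (°/s) per degree of amplitude
    ms_intercept: float = 5.0   # °/s
    qp_duration: float = 0.05   # s, nominal pulse width (sets refractory gap)
    qp_amp_range: tuple[float, float] = (2.0, 10.0)  # degrees
    alternate_directions: bool = True

    def __post_init__(self) -> None:
        _require(self.gain >= 0, f"gain must be >= 0, got {self.gain}")
        _require(self.noise_sd >= 0, f"noise_sd must be >= 0, got {self.noise_sd}")
        _require(self.qp_rate >= 0, f"qp_rate must be >= 0, got {self.qp_rate}")
        if self.qp_rate > 0:
            _require(self.ms_slope > 0,
                     f"ms_slope must be > 0 when qp_rate > 0, got {self.ms_slope}")
            _require(self.qp_duration > 0,
                     f"qp_duration must be > 0, got {self.qp_duration}")
            lo, hi = self.qp_amp_range
            _require(0 < lo <= hi, f"invalid qp_amp_range {self.qp_amp_range}")


@dataclass(frozen=True)
class SpikeModelSpec:
    """Renewal-process spike generator settings.

    ``gamma_renewal`` draws i.i.d. gamma inter-spike intervals with shape
    ``k = 1/target_cv**2`` and mean ``1/rate``.  ``burst_pause`` draws ISIs
    from a two-state (burst/pause) Markov-modulated gamma mixture whose
    stationary marginal is calibrated to the same mean and CV, producing
    bursty trains for CV > 1 regimes.
    """

    rate: float                 # spikes/s
    target_cv: float            # dimensionless
    duration: float = 120.0     # s
    process: str = "gamma_renewal"

    def __post_init__(self) -> None:
        _require(self.rate > 0, f"rate must be > 0, got {self.rate}")
        _require(self.target_cv > 0, f"target_cv must be > 0, got {self.target_cv}")
        _require(self.duration > 0, f"duration must be > 0, got {self.duration}")
        _require(self.process in ("gamma_renewal", "burst_pause"),
                 f"unknown process {self.process!r}")


@dataclass
class VelocityRecording:
    """Paired head/eye velocity traces on a uniform time grid."""

    time: np.ndarray            # s
    head_vel: np.ndarray        # °/s
    eye_vel: np.ndarray         # °/s
    sampling_rate: float        # Hz
    stimulus_frequency: float   # Hz
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.head_vel = np.asarray(self.head_vel, dtype=float)
        self.eye_vel = np.asarray(self.eye_vel, dtype=float)
        n = self.time.size
        _require(self.head_vel.size == n and self.eye_vel.size == n,
                 "time, head_vel and eye_vel must have equal length")
        _require(n >= 2, "recording needs at least 2 samples")
        dt = np.diff(self.time)
        _require(bool(np.all(np.abs(dt - 1.0 / self.sampling_rate) < 1e-9)),
                 "time grid must be uniform at 1/sampling_rate")
        _require(self.stimulus_frequency > 0, "stimulus_frequency must be > 0")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class QuickPhase:
    """One detected (or injected) rapid resetting eye movement."""

    onset: float                # s
    offset: float               # s
    amplitude: float            # degrees, signed integral of residual velocity
    peak_velocity: float        # °/s, max |residual velocity| in the event
    direction: int              # +1 or -1

    def __post_init__(self) -> None:
        _require(self.offset > self.onset, "offset must exceed onset")
        _require(self.peak_velocity >= 0, "peak_velocity must be >= 0")


@dataclass(frozen=True)
class SlowPhaseFit:
    """Gain/phase of the desaccaded sinusoidal response at one frequency.

    ``phase`` is relative to the ideal compensatory response (positive =
    eye leads), wrapped to (-180, 180].
    """

    frequency: float
    gain: float
    phase: float
    eye_amplitude: float
    head_amplitude: float
    fraction_retained: float
    vaf: float

    def __post_init__(self) -> None:
        _require(self.gain >= 0, "gain must be >= 0")
        _require(-180.0 < self.phase <= 180.0, "phase must lie in (-180, 180]")
        _require(0.0 < self.fraction_retained <= 1.0,
                 "fraction_retained must lie in (0, 1]")


@dataclass
class SpikeTrain:
    """Sorted spike times of one cell over a known recording span."""

    spike_times: np.ndarray     # s, strictly increasing
    duration: float             # s
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        t = self.spike_times
        if t.size:
            d = np.diff(t)
            bad = np.nonzero(d <= 0)[0]
            _require(bad.size == 0,
                     f"spike times must be strictly increasing; "
                     f"first violation at index {int(bad[0]) + 1 if bad.size else -1}")
            _require(t[0] >= 0.0, "spike times must be non-negative")
            _require(t[-1] <= self.duration + 1e-12,
                     "spike times must not exceed duration")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


@dataclass(frozen=True)
class ISIStats:
    """Per-train summary: count, mean rate, CV, CV2."""

    n_isi: int
    rate: float
    cv: float
    cv2: float
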