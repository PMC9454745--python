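"""On-disk formats: trace CSVs, spike-time files, cohort manifests.

Trace CSV: header ``time_s,head_vel_dps,eye_vel_dps``, one row per sample.
Spike file: one ascending spike time (seconds) per line.
Manifest: JSON array of ``{file, animal_id, genotype, condition,
frequency_hz[, state]}`` entries.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import SpikeTrain, ValidationError, VelocityRecording

_TRACE_COLUMNS = ["time_s", "head_vel_dps", "eye_vel_dps"]


def write_trace_csv(path: str | Path, rec: VelocityRecording) -> None:
    df = pd.DataFrame({"time_s": rec.time, "head_vel_dps": rec.head_vel,
                       "eye_vel_dps": rec.eye_vel})
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def read_trace_csv(path: str | Path, sampling_rate: float | None = None,
                   stimulus_frequency: float | None = None,
                   metadata: dict | None = None) -> VelocityRecording:
    df = pd.read_csv(path)
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing trace columns {missing}")
    t = df["time_s"].to_numpy(float)
    if sampling_rate is None:
        dt = np.median(np.diff(t))
        sampling_rate = 1.0 / dt
    # snap the grid: CSV rounding must not fail the uniform-grid invariant
    t = np.arange(t.size) / sampling_rate + t[0]
    if stimulus_frequency is None:
        raise ValidationError(f"{path}: stimulus_frequency is required "
                              "(taken from the manifest)")
    return VelocityRecording(time=t, head_vel=df["head_vel_dps"].to_numpy(float),
                             eye_vel=df["eye_vel_dps"].to_numpy(float),
                             sampling_rate=float(sampling_rate),
                             stimulus_frequency=float(stimulus_frequency),
                             metadata=dict(metadata or {}))


def write_spike_file(path: str | Path, train: SpikeTrain) -> None:
    lines = "".join(f"{t:.6f}\n" for t in train.spike_times)
    Path(path).write_text(lines)


def read_spike_file(path: str | Path, duration: float | None = None,
                    metadata: dict | None = None) -> SpikeTrain:
    text = Path(path).read_text().split()
    times = np.array([float(x) for x in text])
    if duration is None:
        duration = float(times[-1]) if times.size else 0.0
    return SpikeTrain(spike_times=times, duration=duration,
                      metadata=dict(metadata or {}))


def write_manifest(path: str | Path, entries: list[dict]) -> None:
    Path(path).write_text(json.dumps(entries, indent=1, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> list[dict]:
    entries = json.loads(Path(path).read_text())
    if not isinstance(entries, list):
        raise ValidationError(f"{path}: manifest must be a JSON array")
    for i, e in enumerate(entries):
        for key in ("file", "animal_id", "genotype", "condition"):
            if key not in e:
                raise ValidationError(f"{path}: entry {i} missing {key!r}")
    return entries


def load_config(path: str | Path) -> dict:
    """Read a cohort config (YAML or JSON) and merge it over the defaults.

    Scalar sections (stimulus, eye, stats) merge key-by-key; the study
    design sections (groups, learning, spikes) replace the default design
    wholesale when present, since partial gain tables would silently mix
    two cohorts.
    """
    from .synthetic import DEFAULT_CONFIG

    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return merge_config(DEFAULT_CONFIG, cfg)


_REPLACE_SECTIONS = frozenset({"groups", "learning", "spikes"})


def merge_config(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if (k not in _REPLACE_SECTIONS and isinstance(v, dict)
                and isinstance(out.get(k), dict)):
            out[k] = merge_config(out[k], v)
        else:
            out[k] = v
    return out
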