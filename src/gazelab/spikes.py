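"""Spike-train regularity metrics: firing rate, CV, CV2.

CV (SD/mean of inter-spike intervals) measures global regularity and is
inflated by slow rate drift; CV2, the mean of
``2|ISI_{n+1} - ISI_n| / (ISI_{n+1} + ISI_n)`` over consecutive interval
pairs, measures short-timescale regularity and is robust to drift, bursts
and pauses.  CV2 is bounded in [0, 2] and equals 1 in expectation for a
Poisson process.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ISIStats, SpikeTrain, ValidationError


def isi(train: SpikeTrain) -> np.ndarray:
    """Inter-spike intervals (s) of a sorted spike train."""
    if train.n_spikes < 2:
        raise ValidationError("ISI computation needs >= 2 spikes")
    return np.diff(train.spike_times)


def firing_rate(train: SpikeTrain, over: str = "span") -> float:
    """Mean firing rate in spikes/s.

    ``over='span'`` (default) uses ``(n_spikes - 1) / (t_last - t_first)``
    — the reciprocal mean ISI, robust to silent padding at the record
    edges.  ``over='duration'`` uses ``n_spikes / duration``.
    """
    if train.n_spikes < 2:
        raise ValidationError("firing rate is undefined for < 2 spikes")
    if over == "span":
        span = train.spike_times[-1] - train.spike_times[0]
        return float((train.n_spikes - 1) / span)
    if over == "duration":
        return float(train.n_spikes / train.duration)
    raise ValidationError(f"unknown rate convention {over!r}")


def cv(train: SpikeTrain) -> float:
    """Coefficient of variation of the ISIs: population SD / mean."""
    if train.n_spikes < 3:
        raise ValidationError("CV needs >= 3 spikes (>= 2 ISIs)")
    intervals = isi(train)
    return float(intervals.std(ddof=0) / intervals.mean())


def cv2(train: SpikeTrain) -> float:
    """Local regularity: mean of 2|ΔISI| / (ISI_{n+1} + ISI_n)."""
    if train.n_spikes < 3:
        raise ValidationError("CV2 needs >= 3 spikes (>= 2 ISIs)")
    intervals = isi(train)
    a, b = intervals[:-1], intervals[1:]
    return float(np.mean(2.0 * np.abs(b - a) / (b + a)))


def isi_stats(train: SpikeTrain) -> ISIStats:
    """Rate, CV and CV2 of one train in a single summary object."""
    return ISIStats(n_isi=train.n_spikes - 1, rate=firing_rate(train),
                    cv=cv(train), cv2=cv2(train))


def population_summary(trains: list[SpikeTrain],
                       grouping: tuple[str, ...] = ("genotype", "state")
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell metric table and per-group mean ± SEM.

    Each train's metadata must carry a ``cell_id`` plus the grouping keys
    (by default genotype and behavioural state).  Returns ``(table,
    summary)``; between-group inference is delegated to the stats layer.
    """
    from .gaze import group_summary

    rows = []
    for train in trains:
        meta = train.metadata
        missing = [k for k in grouping if k not in meta]
        if missing:
            raise ValidationError(
                f"train {meta.get('cell_id', '?')} missing group labels "
                f"{missing}")
        s = isi_stats(train)
        row = dict(cell_id=meta.get("cell_id", ""), n_spikes=train.n_spikes,
                   rate_sps=s.rate, cv=s.cv, cv2=s.cv2)
        row.update({k: meta[k] for k in grouping})
        rows.append(row)
    if not rows:
        raise ValidationError("population_summary needs >= 1 train")
    table = pd.DataFrame(rows)
    summary = group_summary(table, list(grouping), ["rate_sps", "cv", "cv2"])
    return table, summary
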