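"""VOR motor-learning quantification.

Gain-down training (visual surround rotating with the head, target VOR
gain 0) is assessed as the percent change in VOR gain between matched pre-
and post-training recordings:
``100 · (gain_pre − gain_post) / gain_pre`` — positive for a gain decrease,
i.e. learning toward the target.
"""

from __future__ import annotations

import pandas as pd

from .gaze import DesaccadeOptions, estimate_gain_phase, group_summary
from .types import ValidationError


def percent_change(gain_pre: float, gain_post: float) -> float:
    """Percent decrease in gain; positive = learning toward target 0."""
    if gain_pre <= 0:
        raise ValidationError(f"gain_pre must be > 0, got {gain_pre}")
    return 100.0 * (gain_pre - gain_post) / gain_pre


def learning_table(dataset_dir, manifest: list[dict],
                   desaccade: bool = True,
                   opts: DesaccadeOptions | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal, per-frequency learning records plus group mean ± SEM.

    The manifest must contain matched ``pre`` and ``post`` recordings for
    every (animal, frequency).  Gains are estimated with the full
    desaccade-and-fit pipeline on each trace.  Returns ``(table, summary)``
    with columns (animal, genotype, frequency_hz, gain_pre, gain_post,
    pct_change).
    """
    from pathlib import Path

    from .io import read_trace_csv

    gains: dict[tuple, dict] = {}
    for entry in manifest:
        if entry["condition"] not in ("pre", "post"):
            continue
        key = (entry["animal_id"], entry["frequency_hz"])
        rec = read_trace_csv(Path(dataset_dir) / entry["file"],
                             stimulus_frequency=entry["frequency_hz"],
                             metadata=entry)
        fit = estimate_gain_phase(rec, desaccade=desaccade, opts=opts)
        slot = gains.setdefault(key, {"genotype": entry["genotype"]})
        if entry["condition"] in slot:
            raise ValidationError(
                f"duplicate {entry['condition']} recording for "
                f"animal={key[0]} frequency={key[1]}")
        slot[entry["condition"]] = fit.gain

    unmatched = [k for k, v in gains.items() if "pre" not in v or "post" not in v]
    if unmatched:
        raise ValidationError(
            f"unmatched pre/post pairs for (animal, frequency): {sorted(unmatched)}")
    if not gains:
        raise ValidationError("manifest contains no pre/post recordings")

    rows = [dict(animal=k[0], genotype=v["genotype"], frequency_hz=k[1],
                 gain_pre=v["pre"], gain_post=v["post"],
                 pct_change=percent_change(v["pre"], v["post"]))
            for k, v in sorted(gains.items())]
    table = pd.DataFrame(rows)
    summary = group_summary(table, ["genotype", "frequency_hz"],
                            ["gain_pre", "gain_post", "pct_change"])
    return table, summary
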