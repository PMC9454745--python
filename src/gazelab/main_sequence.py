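"""Quick-phase main-sequence analysis.

Rapid eye movements obey a stereotyped linear amplitude–peak-velocity
relation (the "main sequence").  A per-group ordinary-least-squares line is
fitted to rectified (absolute) amplitudes and peak velocities, and group
slopes are compared with the extra-sum-of-squares F test on nested linear
models: the reduced model shares one slope across groups but keeps
group-specific intercepts; the full model frees both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import ValidationError


@dataclass(frozen=True)
class LineFit:
    slope: float        # (°/s) per degree
    intercept: float    # °/s
    sse: float          # (°/s)^2
    df: int
    n: int
    stderr: float       # standard error of the slope


@dataclass(frozen=True)
class SlopeComparison:
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    slope_a: float
    slope_b: float


def _clean(amplitude, peak_velocity) -> tuple[np.ndarray, np.ndarray]:
    amp = np.abs(np.asarray(amplitude, dtype=float))
    pv = np.abs(np.asarray(peak_velocity, dtype=float))
    if amp.size != pv.size:
        raise ValidationError("amplitude and peak_velocity lengths differ")
    if amp.size < 3:
        raise ValidationError(
            f"main-sequence fit needs >= 3 events, got {amp.size}")
    if np.ptp(amp) == 0:
        raise ValidationError("all amplitudes identical; slope is undefined")
    return amp, pv


def fit_main_sequence(amplitude, peak_velocity) -> LineFit:
    """OLS regression of peak velocity on amplitude (both rectified)."""
    amp, pv = _clean(amplitude, peak_velocity)
    res = stats.linregress(amp, pv)
    pred = res.slope * amp + res.intercept
    sse = float(np.sum((pv - pred) ** 2))
    return LineFit(slope=float(res.slope), intercept=float(res.intercept),
                   sse=sse, df=amp.size - 2, n=amp.size,
                   stderr=float(res.stderr))


def compare_slopes(amp_a, pv_a, amp_b, pv_b) -> SlopeComparison:
    """Extra-sum-of-squares F test for equality of two main-sequence slopes.

    Reduced model: common slope, group intercepts (3 parameters).
    Full model: separate slopes and intercepts (4 parameters).
    ``F = ((SSE_red - SSE_full) / 1) / (SSE_full / (n - 4))``.
    """
    a_amp, a_pv = _clean(amp_a, pv_a)
    b_amp, b_pv = _clean(amp_b, pv_b)
    amp = np.concatenate([a_amp, b_amp])
    pv = np.concatenate([a_pv, b_pv])
    grp = np.concatenate([np.zeros(a_amp.size), np.ones(b_amp.size)])

    full_fit_a = fit_main_sequence(a_amp, a_pv)
    full_fit_b = fit_main_sequence(b_amp, b_pv)
    sse_full = full_fit_a.sse + full_fit_b.sse
    df_full = amp.size - 4

    X_red = np.column_stack([amp, grp, np.ones_like(amp)])
    if np.linalg.matrix_rank(X_red) < 3:
        raise ValidationError("degenerate design: cannot fit common-slope model")
    coef, *_ = np.linalg.lstsq(X_red, pv, rcond=None)
    sse_red = float(np.sum((pv - X_red @ coef) ** 2))
    df_red = amp.size - 3

    if df_full < 1:
        raise ValidationError("too few events for the full model")
    num = max(0.0, sse_red - sse_full) / (df_red - df_full)
    den = sse_full / df_full
    f_stat = num / den if den > 0 else 0.0
    p = float(stats.f.sf(f_stat, df_red - df_full, df_full))
    return SlopeComparison(f_stat=float(f_stat), df_num=df_red - df_full,
                           df_den=df_full, p_value=p,
                           slope_a=full_fit_a.slope, slope_b=full_fit_b.slope)
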